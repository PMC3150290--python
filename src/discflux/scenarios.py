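"""Coupled scenario drivers: the diurnal cycle, short cyclic compression,
the one-at-a-time degeneration sensitivity study and the healthy-versus-
degenerated comparison.

The coupling between poromechanics and transport is sequential and one-way:
mechanics is solved first along the load protocol, then oxygen and lactate
march over the same clock, exchanging geometry, porosity and fluid velocity
at a configurable cadence (finer near load transitions).  Within each
transport increment the metabolic update is staggered -- oxygen consumes
with the previous pH, lactate produces from the new oxygen field, and the
updated lactate sets the pH seen by the next oxygen step.

Coupling modes (independently switchable):
  * undeformed        -- transport on the reference mesh, diffusivities from
                         the initial porosities; mechanics ignored.
  * distance-only     -- the mesh is scaled axially by the mechanical height
                         history (shorter diffusion distances) while
                         diffusivities stay at their initial-porosity values.
  * deformed          -- transport on the displaced mesh; strain-dependent
                         diffusivity and advection can be toggled on top.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import metabolism as met
from .geometry import DiscGeometrySpec, DiscMesh, build_disc_mesh
from .parameters import ParameterSet
from .poromechanics import (LoadProtocol, PoroSolver, PoroState,
                            SolverConfig, peak_fluid_speed)
from .transport import SoluteSpec, SoluteState, TransportSolver
from .units import SECONDS_PER_HOUR

#: cyclic load amplitudes (MPa about the 0.5 MPa mean), defined graphically
#: in the load-history figure; A0 is the constant-creep comparator
CYCLIC_AMPLITUDES = {"A0": 0.0, "A1": 0.1, "A2": 0.2}

#: mechanics-relevant region fields (used to decide whether a parameter
#: variant can reuse the base mechanical solution)
_MECH_FIELDS = {"phi0", "k0", "M", "L", "G", "K", "delta_pi", "k1", "k2",
                "fibre_angle_deg"}


@dataclass
class CouplingConfig:
    """Independent mechano-transport coupling switches."""

    deform_geometry: bool = True
    strain_diffusivity: bool = True
    advection: bool = True
    distance_only: bool = False
    constant_ph: Optional[float] = None
    exchange_plateau: float = 900.0      # s between exchanges in plateaus
    exchange_transient: float = 60.0     # s near load transitions

    @classmethod
    def undeformed(cls, **kw) -> "CouplingConfig":
        return cls(deform_geometry=False, strain_diffusivity=False,
                   advection=False, **kw)

    @classmethod
    def distance_shortening(cls, **kw) -> "CouplingConfig":
        return cls(deform_geometry=False, strain_diffusivity=False,
                   advection=False, distance_only=True, **kw)

    @property
    def uses_mechanics(self) -> bool:
        return (self.deform_geometry or self.strain_diffusivity
                or self.advection or self.distance_only)


@dataclass
class ScenarioResult:
    """Probe series, event snapshots and scalar summaries of one run."""

    probes: pd.DataFrame            # time_h, o2/lac/ph at NP and AFO probes
    height: pd.DataFrame            # time_h, height_mm, traction_MPa
    snapshots: dict                 # event -> {solute -> nodal field, ...}
    summaries: dict
    mesh: DiscMesh
    coupling: CouplingConfig

    def probe_series(self, solute: str, probe: str) -> pd.Series:
        s = self.probes.set_index("time_h")[f"{solute}_{probe}"]
        return s


def _exchange_grid(protocol: LoadProtocol, coupling: CouplingConfig
                   ) -> np.ndarray:
    """Transport/coupling exchange times: fine after each load transition,
    coarse within plateaus, one step per cycle under sinusoidal load."""
    events = sorted({p["t0"] for p in protocol.pieces})
    times = {0.0, protocol.duration}
    for piece in protocol.pieces:
        t0, t1 = piece["t0"], piece["t1"]
        if piece["kind"] == "sin":
            dt = min(coupling.exchange_transient, 1.0 / piece["freq"])
            times.update(np.arange(t0, t1, dt))
            continue
        t = t0
        while t < t1:
            recent = min((t - e for e in events if e <= t), default=np.inf)
            dt = (coupling.exchange_transient if recent < 1800.0
                  else coupling.exchange_plateau)
            t = min(t + dt, t1)
            times.add(t)
    grid = np.array(sorted(times))
    return grid[np.concatenate([[True], np.diff(grid) > 1e-9])]


class CoupledModel:
    """One disc model instance: mesh + mechanics + two solutes + metabolism.

    Carries its state between scenario phases, so a cyclic run can continue
    from the preconditioned end of a diurnal run.
    """

    def __init__(self, params: ParameterSet,
                 coupling: Optional[CouplingConfig] = None,
                 resolution: int = 1,
                 geometry: Optional[DiscGeometrySpec] = None,
                 solver_config: Optional[SolverConfig] = None):
        self.params = params
        self.coupling = coupling or CouplingConfig()
        spec = geometry or DiscGeometrySpec(height=params.height,
                                            resolution=resolution)
        if abs(spec.height - params.height) > 1e-9:
            spec = dataclasses.replace(spec, height=params.height)
        self.geometry_spec = spec
        self.mesh = build_disc_mesh(spec)
        self.solver_config = solver_config or SolverConfig()
        self.metabolic = met.MetabolicParams.from_parameter_set(params)
        if self.coupling.constant_ph is not None:
            self.metabolic.constant_ph = self.coupling.constant_ph
        self.oxygen = TransportSolver(self.mesh, params,
                                      SoluteSpec.oxygen(params))
        self.lactate = TransportSolver(self.mesh, params,
                                       SoluteSpec.lactate(params))
        self.mech: Optional[PoroSolver] = None
        self.state_oxygen: Optional[SoluteState] = None
        self.state_lactate: Optional[SoluteState] = None
        #: (states, trace) injected to reuse an identical mechanical
        #: solution (e.g. variants altering only metabolic fields)
        self.preset_mechanics: Optional[tuple] = None
        self.last_mechanics: Optional[tuple] = None
        self._clock = 0.0

    # ---- mechanics -----------------------------------------------------
    def _ensure_mech(self) -> PoroSolver:
        if self.mech is None:
            self.mech = PoroSolver(self.mesh, self.params,
                                   self.solver_config)
        return self.mech

    def run_mechanics(self, protocol: LoadProtocol,
                      exchange: np.ndarray) -> tuple[list[PoroState], list]:
        solver = self._ensure_mech()
        trace: list = []
        states = solver.run_protocol(protocol, sample_times=exchange,
                                     record_times=exchange, trace=trace)
        return states, trace

    # ---- coupled marching ----------------------------------------------
    def _transport_setup(self, mech_state: Optional[PoroState],
                         h0: Optional[float]) -> None:
        cp = self.coupling
        mesh = self.mesh
        if mech_state is None or not cp.uses_mechanics:
            coords, phi, vel = mesh.nodes, None, None
        elif cp.distance_only:
            scale = mech_state.height / h0
            coords = mesh.nodes.copy()
            zmid = 0.5 * sum(mesh.disc_z)
            coords[:, 1] = zmid + (coords[:, 1] - zmid) * scale
            phi, vel = None, None
        else:
            coords = (mesh.nodes + mech_state.displacement
                      if cp.deform_geometry else mesh.nodes)
            phi = (mech_state.phi_qp.mean(axis=1)[self.oxygen.elements]
                   if cp.strain_diffusivity else None)
            vel = (mech_state.velocity[self.oxygen.elements]
                   if cp.advection else None)
        for solver in (self.oxygen, self.lactate):
            solver.set_geometry(coords, phi_elem=phi, velocity_elem=vel)
        self._current_velocity = vel

    def _metabolic_step(self, dt: float) -> np.ndarray:
        """One staggered oxygen -> lactate -> pH increment; returns pH.

        Subdivides the increment when the advective Courant number exceeds
        one on the (locally refined) mesh.
        """
        nsub = 1
        vel = getattr(self, "_current_velocity", None)
        if vel is not None:
            h = self.mesh.element_sizes()[self.oxygen.elements]
            speed = (np.linalg.norm(vel, axis=1)
                     if vel.ndim > 1 else np.abs(vel))
            C = float((speed * dt / h).max()) if len(h) else 0.0
            nsub = min(int(np.ceil(C)), 64) if C > 1.0 else 1
        moving = self.coupling.uses_mechanics
        pH = None
        for i in range(nsub):
            so, sl = self.state_oxygen, self.state_lactate
            pH = met.ph_from_lactate(sl.c, self.metabolic.constant_ph)
            sink = met.oxygen_consumption_coeff(
                so.c, pH, self.oxygen.rho_node,
                self.metabolic.activity) / SECONDS_PER_HOUR
            self.state_oxygen = self.oxygen.step(
                so, dt / nsub, sink_coeff=sink,
                use_prev_mass=moving and i == 0)
            source = met.lactate_production(
                self.state_oxygen.c, pH, self.lactate.rho_node,
                self.metabolic.activity) / SECONDS_PER_HOUR
            self.state_lactate = self.lactate.step(
                sl, dt / nsub, source=source,
                use_prev_mass=moving and i == 0)
        return pH

    def run_coupled(self, protocol: LoadProtocol,
                    reset_solutes: bool = True,
                    snapshot_times: Optional[dict] = None,
                    equilibrate: bool = True) -> ScenarioResult:
        """March mechanics + transport + metabolism through a protocol."""
        cp = self.coupling
        exchange = _exchange_grid(protocol, cp)
        mech_states, trace = ([], [])
        if cp.uses_mechanics:
            if self.preset_mechanics is not None:
                mech_states, trace = self.preset_mechanics
                self.preset_mechanics = None
            else:
                mech_states, trace = self.run_mechanics(protocol, exchange)
            self.last_mechanics = (mech_states, trace)
        if reset_solutes or self.state_oxygen is None:
            self.state_oxygen = self.oxygen.initial_state()
            self.state_lactate = self.lactate.initial_state()
            self._clock = 0.0
        t_offset = self._clock

        mech_at = {}
        for st in mech_states:
            mech_at[round(st.time, 6)] = st
        h0 = mech_states[0].height if mech_states else None

        rows = []
        snaps: dict = {}
        snapshot_times = snapshot_times or {}

        def record(t: float) -> None:
            so, sl = self.state_oxygen, self.state_lactate
            ph_np = float(met.ph_from_lactate(
                self.lactate.probe_value(sl, "NP"),
                self.metabolic.constant_ph))
            ph_af = float(met.ph_from_lactate(
                self.lactate.probe_value(sl, "AFO"),
                self.metabolic.constant_ph))
            rows.append({
                "time_h": (t_offset + t) / SECONDS_PER_HOUR,
                "o2_NP": self.oxygen.probe_value(so, "NP"),
                "o2_AFO": self.oxygen.probe_value(so, "AFO"),
                "lac_NP": self.lactate.probe_value(sl, "NP"),
                "lac_AFO": self.lactate.probe_value(sl, "AFO"),
                "ph_NP": ph_np, "ph_AFO": ph_af,
            })

        def snap(name: str, t: float) -> None:
            ms = mech_at.get(round(t, 6))
            snaps[name] = {
                "time_h": (t_offset + t) / SECONDS_PER_HOUR,
                "oxygen": self.oxygen.field_on_mesh(self.state_oxygen),
                "lactate": self.lactate.field_on_mesh(self.state_lactate),
                "displacement": (None if ms is None
                                 else ms.displacement.copy()),
                "height": None if ms is None else ms.height,
            }

        # initial geometry / record
        self._transport_setup(mech_states[0] if mech_states else None, h0)
        record(0.0)
        pending = dict(snapshot_times)
        for t_prev, t_next in zip(exchange[:-1], exchange[1:]):
            ms = mech_at.get(round(t_next, 6))
            self._transport_setup(ms, h0)
            self._metabolic_step(t_next - t_prev)
            record(t_next)
            for name, t_ev in list(pending.items()):
                if t_next >= t_ev - 1e-6:
                    snap(name, t_next)
                    del pending[name]
        self._clock = t_offset + exchange[-1]

        probes = pd.DataFrame(rows)
        if trace:
            tr = np.array(trace)
            height = pd.DataFrame({
                "time_h": (t_offset + tr[:, 0]) / SECONDS_PER_HOUR,
                "height_mm": tr[:, 1], "peak_speed_mm_s": tr[:, 2]})
        else:
            height = pd.DataFrame(
                {"time_h": [], "height_mm": [], "peak_speed_mm_s": []})
        summaries = {
            "final_o2_NP": probes["o2_NP"].iloc[-1],
            "final_lac_NP": probes["lac_NP"].iloc[-1],
        }
        if trace:
            summaries["peak_fluid_speed_mm_s"] = float(tr[:, 2].max())
            summaries["height_change_max"] = float(
                1.0 - tr[:, 1].min() / h0)
        return ScenarioResult(probes=probes, height=height, snapshots=snaps,
                              summaries=summaries, mesh=self.mesh,
                              coupling=cp)


# ---------------------------------------------------------------------------
# scenario entry points
# ---------------------------------------------------------------------------
def run_diurnal(params: ParameterSet,
                coupling: Optional[CouplingConfig] = None,
                days: int = 2, resolution: int = 1,
                model: Optional[CoupledModel] = None,
                solver_config: Optional[SolverConfig] = None
                ) -> ScenarioResult:
    """Diurnal loading-recovery cycles (16 h at 0.5 MPa / 8 h at 0.1 MPa)
    from zero solute initial conditions, repeated ``days`` times."""
    if days < 1:
        raise ValueError("days must be >= 1")
    model = model or CoupledModel(params, coupling, resolution,
                                  solver_config=solver_config)
    protocol = LoadProtocol.diurnal(days=days)
    snapshot_times = {}
    for d in range(1, days + 1):
        base = (d - 1) * 24.0 * SECONDS_PER_HOUR
        snapshot_times[f"end_creep_day{d}"] = base + 16.0 * SECONDS_PER_HOUR
        snapshot_times[f"end_rest_day{d}"] = base + 24.0 * SECONDS_PER_HOUR
    result = model.run_coupled(protocol, snapshot_times=snapshot_times)
    result.summaries["model"] = model      # enables preconditioned restarts
    return result


def run_cyclic(params: ParameterSet, frequency: float, amplitude: str,
               preconditioned: Optional[ScenarioResult] = None,
               duration: float = 400.0, resolution: int = 1,
               coupling: Optional[CouplingConfig] = None
               ) -> ScenarioResult:
    """400 s cyclic compression about 0.5 MPa from the preconditioned state
    (end of the two-day diurnal run).

    ``amplitude`` is one of A0 (creep comparator), A1, A2.
    """
    if amplitude not in CYCLIC_AMPLITUDES:
        raise KeyError(f"unknown amplitude label {amplitude!r}")
    amp = CYCLIC_AMPLITUDES[amplitude]
    if preconditioned is not None and "model" in preconditioned.summaries:
        import copy
        model = copy.deepcopy(preconditioned.summaries["model"])
        model.last_mechanics = None
    else:
        pre = run_diurnal(params, coupling, days=2, resolution=resolution)
        model = pre.summaries["model"]
    protocol = LoadProtocol.cyclic(amp, frequency, duration=duration)
    result = model.run_coupled(protocol, reset_solutes=False,
                               snapshot_times={"end": protocol.duration})
    result.summaries["amplitude"] = amplitude
    result.summaries["frequency_hz"] = frequency
    return result


def run_sensitivity(base: ParameterSet,
                    variants: Sequence[ParameterSet],
                    days: int = 2, resolution: int = 1,
                    coupling: Optional[CouplingConfig] = None
                    ) -> pd.DataFrame:
    """One-at-a-time sensitivity: each variant's probe concentrations at the
    end of the last simulated day, normalised to the base model.

    Variants that only alter transport/metabolic fields (cell density,
    constant pH) reuse the base mechanical solution.
    """
    results = {}
    base_cp = coupling or CouplingConfig()
    base_model = CoupledModel(base, dataclasses.replace(base_cp),
                              resolution)
    base_res = run_diurnal(base, days=days, model=base_model)
    results["base"] = base_res
    rows = []
    for var in variants:
        diffs = var.diff_fields(base)
        mech_diff = any(
            f in _MECH_FIELDS
            for region, fields in diffs.items() if region != "_global"
            for f in fields) or "height" in diffs.get("_global", {})
        cp = dataclasses.replace(base_cp, constant_ph=var.constant_ph)
        model = CoupledModel(var, cp, resolution)
        if not mech_diff:
            # identical mechanics: reuse the base solution history
            model.preset_mechanics = base_model.last_mechanics
        res = run_diurnal(var, days=days, model=model)
        results[var.name] = res
        row = {"variant": var.name}
        for sol in ("o2", "lac"):
            for probe in ("NP", "AFO"):
                col = f"{sol}_{probe}"
                row[col] = res.probes[col].iloc[-1]
                row[f"{col}_norm"] = (res.probes[col].iloc[-1]
                                      / base_res.probes[col].iloc[-1])
        row["o2_norm_mean"] = 0.5 * (row["o2_NP_norm"] + row["o2_AFO_norm"])
        row["lac_norm_mean"] = 0.5 * (row["lac_NP_norm"]
                                      + row["lac_AFO_norm"])
        rows.append(row)
    table = pd.DataFrame(rows).set_index("variant")
    table.attrs["results"] = results
    return table


def run_degeneration_comparison(healthy: ParameterSet,
                                degenerated: ParameterSet,
                                days: int = 2, resolution: int = 1) -> dict:
    """Healthy vs fully degenerated disc, each with and without the
    mechanical coupling, plus mid-height anteroposterior solute profiles at
    the end of the last creep phase."""
    out: dict = {"runs": {}, "profiles": {}}
    for label, params in (("healthy", healthy),
                          ("degenerated", degenerated)):
        for mode in ("deformed", "undeformed"):
            cp = (CouplingConfig() if mode == "deformed"
                  else CouplingConfig.undeformed())
            res = run_diurnal(params, cp, days=days, resolution=resolution)
            out["runs"][(label, mode)] = res
            snap = res.snapshots[f"end_creep_day{days}"]
            out["profiles"][(label, mode)] = {
                sol: midline_profile(res.mesh, snap[sol])
                for sol in ("oxygen", "lactate")}
    return out


def midline_profile(mesh: DiscMesh, field: np.ndarray) -> pd.DataFrame:
    """Mid-height solute profile vs the (mirrored) anteroposterior
    position: the axisymmetric radius maps to both +/- positions."""
    zmid = 0.5 * sum(mesh.disc_z)
    dz = np.diff(np.unique(np.round(mesh.nodes[:, 1], 9))).min()
    sel = np.flatnonzero(
        (np.abs(mesh.nodes[:, 1] - zmid) < 0.51 * dz)
        & np.isfinite(field))
    order = np.argsort(mesh.nodes[sel, 0])
    sel = sel[order]
    r = mesh.nodes[sel, 0]
    vals = field[sel]
    pos = np.concatenate([-r[::-1], r[1:]])
    v = np.concatenate([vals[::-1], vals[1:]])
    return pd.DataFrame({"position_mm": pos, "value": v})


def relative_change(test: pd.Series, reference: pd.Series,
                    window: Optional[tuple[float, float]] = None) -> float:
    """Signed extremum of (test - reference)/reference in percent over the
    common time window (series indexed by time in hours; the test series is
    interpolated onto the reference grid)."""
    t_ref = np.asarray(reference.index, dtype=float)
    lo = max(t_ref.min(), float(np.asarray(test.index, dtype=float).min()))
    hi = min(t_ref.max(), float(np.asarray(test.index, dtype=float).max()))
    if window is not None:
        lo, hi = max(lo, window[0]), min(hi, window[1])
    mask = (t_ref >= lo - 1e-9) & (t_ref <= hi + 1e-9)
    t = t_ref[mask]
    ref_v = np.asarray(reference, dtype=float)[mask]
    test_v = np.interp(t, np.asarray(test.index, dtype=float),
                       np.asarray(test, dtype=float))
    if np.any(ref_v <= 0.0):
        raise ZeroDivisionError(
            "reference series crosses zero: relative change undefined")
    rel = (test_v - ref_v) / ref_v * 100.0
    return float(rel[np.argmax(np.abs(rel))])
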