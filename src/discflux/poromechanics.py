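"""Large-strain biphasic (displacement - pore pressure) finite elements.

Solves quasi-static momentum balance with the effective-stress split
sigma_total = sigma_eff(F) - p I together with fluid mass balance under
intrinsically incompressible phases, in a total-Lagrangian setting:

    div_X( P_eff - J p F^-T ) = 0
    d(J)/dt + Div_X( -J F^-1 k(J) F^-T Grad_X mu ) = 0,    p = mu + dpi

where mu is the water chemical potential (the continuous FE unknown; the
osmotic swelling pressure dpi jumps at the NP boundary), k(J) the
strain-dependent permeability and backward Euler is used in time.
Displacements use quadratic (P2) and pressure linear (P1) interpolation --
the inf-sup stable Taylor-Hood pairing -- on the axisymmetric disc section
or the 1D benchmark column.  The Newton tangent is assembled by elementwise
finite differences of the exact residual and re-factorised lazily (modified
Newton), which keeps multi-day creep histories cheap.

Loads are nominal compressive tractions on the top vertebral surface;
free drainage (mu = 0) applies on the configured exterior facets (by
default the vascularised outer annulus surface).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import constitutive as law
from . import fem
from .geometry import DiscMesh
from .parameters import ParameterSet
from .units import SECONDS_PER_HOUR


class SolverError(RuntimeError):
    """Newton divergence or element inversion, carrying time/residual."""

    def __init__(self, msg: str, time: float = np.nan,
                 residual: float = np.nan):
        super().__init__(f"{msg} (t={time:.1f}s, |R|={residual:.3e})")
        self.time = time
        self.residual = residual


# ---------------------------------------------------------------------------
# load protocols
# ---------------------------------------------------------------------------
@dataclass
class LoadProtocol:
    """Piecewise compressive-traction history on the top surface (MPa).

    Pieces are dicts with keys ``t0, t1, kind`` and either ``p0, p1``
    (kind="ramp"/"const") or ``mean, amp, freq`` (kind="sin").
    """

    pieces: list[dict]

    @property
    def duration(self) -> float:
        return self.pieces[-1]["t1"]

    def piece_at(self, t: float) -> dict:
        t = min(max(t, 0.0), self.duration)
        for piece in self.pieces:
            if t <= piece["t1"] + 1e-9:
                return piece
        return self.pieces[-1]

    def traction(self, t: float) -> float:
        t = min(max(t, 0.0), self.duration)
        for piece in self.pieces:
            if t <= piece["t1"] + 1e-9:
                if piece["kind"] == "sin":
                    return piece["mean"] + piece["amp"] * np.sin(
                        2.0 * np.pi * piece["freq"] * (t - piece["t0"]))
                if piece["kind"] == "const":
                    return piece["p0"]
                s = (t - piece["t0"]) / max(piece["t1"] - piece["t0"], 1e-12)
                return piece["p0"] + s * (piece["p1"] - piece["p0"])
        return 0.0

    # ---- constructors --------------------------------------------------
    @classmethod
    def constant(cls, sigma: float, duration: float,
                 start_from: float = 0.1, ramp: float = 60.0
                 ) -> "LoadProtocol":
        return cls([
            {"t0": 0.0, "t1": ramp, "kind": "ramp",
             "p0": start_from, "p1": sigma},
            {"t0": ramp, "t1": duration, "kind": "const", "p0": sigma},
        ])

    @classmethod
    def diurnal(cls, days: int = 2, creep: float = 0.5, rest: float = 0.1,
                creep_hours: float = 16.0, rest_hours: float = 8.0,
                ramp: float = 60.0) -> "LoadProtocol":
        """Daily cycle: 16 h creep at 0.5 MPa, 8 h rest at 0.1 MPa."""
        if days < 1:
            raise ValueError("days must be >= 1")
        pieces = []
        t = 0.0
        for _ in range(days):
            t_creep = t + creep_hours * SECONDS_PER_HOUR
            t_rest = t_creep + rest_hours * SECONDS_PER_HOUR
            pieces += [
                {"t0": t, "t1": t + ramp, "kind": "ramp",
                 "p0": rest, "p1": creep},
                {"t0": t + ramp, "t1": t_creep, "kind": "const", "p0": creep},
                {"t0": t_creep, "t1": t_creep + ramp, "kind": "ramp",
                 "p0": creep, "p1": rest},
                {"t0": t_creep + ramp, "t1": t_rest, "kind": "const",
                 "p0": rest},
            ]
            t = t_rest
        return cls(pieces)

    @classmethod
    def cyclic(cls, amplitude: float, freq: float, duration: float = 400.0,
               mean: float = 0.5, start_from: float = 0.1,
               ramp: float = 10.0) -> "LoadProtocol":
        """Sinusoidal compression about a mean load; amplitude 0 is the
        creep comparator (A0)."""
        pieces = [{"t0": 0.0, "t1": ramp, "kind": "ramp",
                   "p0": start_from, "p1": mean}]
        if amplitude == 0.0:
            pieces.append({"t0": ramp, "t1": ramp + duration,
                           "kind": "const", "p0": mean})
        else:
            pieces.append({"t0": ramp, "t1": ramp + duration, "kind": "sin",
                           "mean": mean, "amp": amplitude, "freq": freq})
        return cls(pieces)


@dataclass
class PoroState:
    """Converged poromechanical fields at one time instant."""

    time: float                     # s (protocol clock)
    displacement: np.ndarray        # (nn, 2) mm [axisym] or (nn,) [column]
    mu: np.ndarray                  # water chemical potential at P1 nodes
    pressure: np.ndarray            # fluid pressure mu + dpi at P1 nodes
    J_qp: np.ndarray                # (ne, nq) deformation Jacobian
    phi_qp: np.ndarray              # (ne, nq) porosity
    k_elem: np.ndarray              # (ne,) permeability
    velocity: np.ndarray            # (ne, 2) or (ne,) Darcy flux, mm/s
    height: float                   # current NP+AF height, mm
    traction: float = 0.0


@dataclass
class SolverConfig:
    #: exterior facet tags with free drainage (mu = 0).  The disc's fluid
    #: leaves through the vascularised outer annulus ("disc_lateral");
    #: adding "lateral"/"top"/"bottom" opens the vertebral route
    #: (config-exposed: the sustained-creep validation selects the
    #: outer-annulus-only choice, see docs/methods.md)
    drained: tuple = ("disc_lateral",)
    dt_min: float = 10.0            # s, after load transitions
    dt_max: float = 600.0           # s, within creep plateaus
    growth: float = 1.6
    ramp_steps: int = 6
    steps_per_cycle: int = 20
    newton_tol: float = 1e-8        # relative to the external force scale
    newton_max: int = 30
    fd_step: float = 1e-6
    equil_rate_tol: float = 1e-4    # height-rate fraction per hour
    equil_max_hours: float = 60.0


def _step_times(protocol: LoadProtocol, cfg: SolverConfig,
                sample_times: Optional[Sequence[float]] = None) -> np.ndarray:
    times = {0.0, protocol.duration}
    for piece in protocol.pieces:
        t0, t1 = piece["t0"], piece["t1"]
        times.add(t0)
        times.add(t1)
        if piece["kind"] == "ramp":
            times.update(np.linspace(t0, t1, cfg.ramp_steps + 1))
        elif piece["kind"] == "sin":
            n = int(np.ceil((t1 - t0) * piece["freq"] * cfg.steps_per_cycle))
            times.update(t0 + (t1 - t0) * np.arange(1, n) / n)
        else:
            t, dt = t0, cfg.dt_min
            while t < t1:
                t = min(t + dt, t1)
                times.add(t)
                dt = min(dt * cfg.growth, cfg.dt_max)
    if sample_times is not None:
        times.update(float(t) for t in sample_times
                     if 0.0 <= t <= protocol.duration + 1e-9)
    out = np.array(sorted(times))
    return out[np.concatenate([[True], np.diff(out) > 1e-9])]


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------
class PoroSolver:
    """Biphasic solver bound to one mesh and parameter set."""

    def __init__(self, mesh: DiscMesh, params: ParameterSet,
                 config: Optional[SolverConfig] = None):
        self.mesh = mesh
        self.params = params
        self.cfg = config or SolverConfig()
        self._axisym = mesh.kind == "axisym"
        self._setup()
        self.reset()

    # ---- setup ---------------------------------------------------------
    def _setup(self) -> None:
        mesh = self.mesh
        self.nn = mesh.n_nodes
        self.ne = mesh.n_elements
        self.vmap = -np.ones(self.nn, dtype=int)
        self.vmap[mesh.vertex_ids] = np.arange(len(mesh.vertex_ids))
        self.nv = len(mesh.vertex_ids)
        self.ncomp = 2 if self._axisym else 1
        self.nu = self.ncomp * self.nn
        self.ndof = self.nu + self.nv
        self.region_groups = {
            str(r): np.flatnonzero(mesh.region == r)
            for r in np.unique(mesh.region)}
        self._setup_material_arrays()

        if self._axisym:
            self.qw = fem.TRI_QW
            N, dNref = fem.tri_p2_shape(fem.TRI_QP)
            N1, _ = fem.tri_p1_shape(fem.TRI_QP)
            _, detJ, invJ = fem.tri_geometry(mesh.nodes, mesh.elems_p1)
            self.detJ = detJ
            # P2 gradients per qp, P1 gradients constant
            self.dNdX = [np.einsum("im,emk->eik", dNref[q], invJ)
                         for q in range(len(self.qw))]
            dL = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
            self.dN1dX = np.einsum("im,emk->eik", dL, invJ)
            self.N = N
            self.N1 = N1
            elem_r = mesh.nodes[mesh.elems_p2, 0]          # (ne, 6)
            self.r_qp = [elem_r @ N[q] for q in range(len(self.qw))]
            # batched (nq, ne, ...) views for the vectorised assembly
            self._dN_b = np.stack(self.dNdX)
            self._r_b = np.stack(self.r_qp)
            self._w_detJ = self.qw[:, None] * detJ[None, :]
            # traction facets on the top surface
            self._setup_facets()
        else:
            self.qw = fem.LINE_QW
            N, dN = fem.line_p2_shape(fem.LINE_QP)
            N1, dN1 = fem.line_p1_shape(fem.LINE_QP)
            z = mesh.nodes[:, 0]
            h = z[mesh.elems_p2[:, 1]] - z[mesh.elems_p2[:, 0]]
            self.detJ = h
            self.dNdX = [np.repeat(dN[q][None, :], self.ne, axis=0)
                         / h[:, None] for q in range(len(self.qw))]
            self.dN1dX = (np.repeat(dN1[0][None, :], self.ne, axis=0)
                          / h[:, None])
            self.N = N
            self.N1 = N1
            self.top_node = int(self.mesh.facets["top"][0, 0])

        self.nq = len(self.qw)
        nloc_u = (6 if self._axisym else 3) * self.ncomp
        nloc = nloc_u + (3 if self._axisym else 2)
        self.nloc_u, self.nloc = nloc_u, nloc

        # element -> global dof map
        eu = mesh.elems_p2
        if self._axisym:
            udofs = np.stack([2 * eu + c for c in range(2)],
                             axis=2).reshape(self.ne, -1)   # (ne, 12)
        else:
            udofs = eu
        pdofs = self.nu + self.vmap[mesh.elems_p1]
        self.edofs = np.hstack([udofs, pdofs])

        rows = np.repeat(self.edofs, nloc, axis=1).ravel()
        cols = np.tile(self.edofs, (1, nloc)).ravel()
        self._coo_rows, self._coo_cols = rows, cols

        self._setup_dirichlet()

    def _setup_material_arrays(self) -> None:
        """Per-element parameter arrays so the constitutive laws evaluate
        in one vectorised pass over all elements (regions differ only in
        their coefficients)."""
        from types import SimpleNamespace
        rps = [self.params.regions[str(r)] for r in self.mesh.region]
        ne = self.ne
        self.solid = SimpleNamespace(
            G=np.array([rp.G for rp in rps]),
            K=np.array([rp.K for rp in rps]))
        self.dpi_e = np.array([rp.delta_pi for rp in rps])
        self.phi0_e = np.array([rp.phi0 for rp in rps])
        k1 = np.zeros(ne)
        k2 = np.ones(ne)
        dirs = np.zeros((ne, 2, 3))
        dirs[:, :, 2] = 1.0
        for e, rp in enumerate(rps):
            if rp.has_fibres:
                k1[e], k2[e] = rp.k1, rp.k2
                dirs[e] = law.fibre_directions(rp)
        self._has_fibres = bool(k1.any())
        self.fibres = SimpleNamespace(k1=k1, k2=k2, has_fibres=True,
                                      fibre_angle_deg=None)
        self.fibre_dirs = dirs
        # permeability law groups: strain-independent / M-law / M+L-law
        groups: dict[str, list[int]] = {"none": [], "M": [], "ML": []}
        for e, rp in enumerate(rps):
            groups["none" if rp.M is None else
                   "M" if rp.L is None else "ML"].append(e)
        self.perm_groups = []
        for kind, idx in groups.items():
            if not idx:
                continue
            idx = np.array(idx)
            ns = SimpleNamespace(
                k0=np.array([rps[e].k0 for e in idx]),
                M=None if kind == "none" else np.array(
                    [rps[e].M for e in idx]),
                L=None if kind != "ML" else np.array(
                    [rps[e].L for e in idx]),
                phi0=np.array([rps[e].phi0 for e in idx]))
            self.perm_groups.append((idx, ns))

    def _stress_and_flowprops(self, F: np.ndarray):
        """Effective stress, Jacobian and permeability for all elements."""
        J = np.linalg.det(F)
        if np.any(J <= 1e-6):
            raise FloatingPointError("element inversion")
        P = law.neo_hookean_stress(F, self.solid)
        if self._has_fibres:
            P = P + law.fibre_stress(F, self.fibres,
                                     directions=self.fibre_dirs)
        k = np.empty(len(J))
        for idx, ns in self.perm_groups:
            k[idx] = law.permeability(J[idx], ns)
        return P, J, k

    def _setup_facets(self) -> None:
        mesh = self.mesh
        self.top_facets = mesh.facets["top"]
        tN, _ = fem.line_p2_shape(fem.LINE_QP)
        self._edgeN = tN
        # unit consistent load vector for sigma = 1 MPa on the top surface
        f = np.zeros(self.ndof)
        for (a, b, m) in self.top_facets:
            r = mesh.nodes[[a, b, m], 0]
            dr = abs(r[1] - r[0])
            for q, w in enumerate(fem.LINE_QW):
                r_q = tN[q] @ r
                for i, node in enumerate((a, b, m)):
                    # t_z = -1 MPa (compression), acts on u_z dofs
                    f[2 * node + 1] += -w * dr * r_q * tN[q, i]
        self._traction_vector = f

    def _setup_dirichlet(self) -> None:
        mesh = self.mesh
        fixed = []
        if self._axisym:
            coords = mesh.nodes
            bottom = np.flatnonzero(np.abs(coords[:, 1]
                                           - coords[:, 1].min()) < 1e-9)
            axis = np.flatnonzero(np.abs(coords[:, 0]) < 1e-9)
            fixed += [2 * n + 1 for n in bottom]       # u_z = 0
            fixed += [2 * n for n in axis]             # u_r = 0
            drained_nodes = set()
            for tag in self.cfg.drained:
                drained_nodes.update(mesh.facets[tag][:, :2].ravel())
            drained = [self.nu + self.vmap[n] for n in sorted(drained_nodes)
                       if self.vmap[n] >= 0]
        else:
            fixed += [int(mesh.facets["bottom"][0, 0])]
            drained = [self.nu + self.vmap[self.top_node]]
        self.fixed_dofs = np.array(sorted(set(fixed) | set(drained)),
                                   dtype=int)

    def __getstate__(self) -> dict:
        # factorisation handles cannot be copied/pickled; drop them
        state = self.__dict__.copy()
        state["_lu"] = None
        state["_lu_phase"] = {}
        return state

    # ---- state ---------------------------------------------------------
    def reset(self) -> None:
        self.x = np.zeros(self.ndof)
        self.J_old = np.ones((self.ne, self.nq))
        self.time = 0.0
        self._lu = None
        self._lu_phase: dict = {}
        self._x_prev = None
        self._dt_prev = 0.0
        self.equilibrated = False

    # ---- residual ------------------------------------------------------
    def _gather(self, x: np.ndarray):
        if self._axisym:
            ue = x[:self.nu].reshape(self.nn, 2)[self.mesh.elems_p2]
        else:
            ue = x[:self.nu][self.mesh.elems_p2]
        pe = x[self.nu:][self.vmap[self.mesh.elems_p1]]
        return ue, pe

    def _local_residual(self, ue, pe, dt, dpi_scale):
        if self._axisym:
            return self._local_residual_axi(ue, pe, dt, dpi_scale)
        return self._local_residual_col(ue, pe, dt, dpi_scale)

    def _axisym_kinematics(self, ue):
        """F, J and the (2x2, hoop) inverse blocks at every qp, batched
        (..., nq, ne, ...); exploits the axisymmetric sparsity of F.  Extra
        leading axes on ``ue`` (FD-perturbation batches) broadcast through.
        """
        gu = np.einsum("...eia,qeik->...qeak", ue, self._dN_b)
        ur = np.einsum("...ei,qi->...qe", ue[..., 0], self.N)
        F = np.zeros(gu.shape[:-2] + (3, 3))
        F[..., 0, 0] = 1.0 + gu[..., 0, 0]
        F[..., 0, 1] = gu[..., 0, 1]
        F[..., 1, 0] = gu[..., 1, 0]
        F[..., 1, 1] = 1.0 + gu[..., 1, 1]
        Fzz = 1.0 + ur / self._r_b
        F[..., 2, 2] = Fzz
        det2 = (F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0])
        J = det2 * Fzz
        if np.any(J <= 1e-6):
            raise FloatingPointError("element inversion")
        Finv = np.zeros_like(F)
        Finv[..., 0, 0] = F[..., 1, 1] / det2
        Finv[..., 0, 1] = -F[..., 0, 1] / det2
        Finv[..., 1, 0] = -F[..., 1, 0] / det2
        Finv[..., 1, 1] = F[..., 0, 0] / det2
        Finv[..., 2, 2] = 1.0 / Fzz
        return F, J, Finv

    def _effective_stress_batch(self, F, J, Finv):
        P = law.neo_hookean_stress(
            F, self.solid, J=J, Finv_T=np.swapaxes(Finv, -1, -2))
        if self._has_fibres:
            with np.errstate(over="raise", invalid="raise"):
                P = P + law.fibre_stress(F, self.fibres,
                                         directions=self.fibre_dirs)
        return P

    def _local_residual_axi(self, ue, pe, dt, dpi_scale):
        """Element residuals; extra leading axes on (ue, pe) -- used to
        evaluate all tangent FD perturbations in one vectorised call --
        broadcast straight through."""
        grad_mu = np.einsum("ejk,...ej->...ek", self.dN1dX, pe)
        F, J, Finv = self._axisym_kinematics(ue)
        P = self._effective_stress_batch(F, J, Finv)
        mu_q = np.einsum("...ej,qj->...qe", pe, self.N1)
        p_tot = mu_q + dpi_scale * self.dpi_e
        k_q = np.empty_like(J)
        for idx, ns in self.perm_groups:
            k_q[..., idx] = law.permeability(J[..., idx], ns)
        P = P - (J * p_tot)[..., None, None] * np.swapaxes(Finv, -1, -2)
        wd = self._w_detJ                       # (nq, ne)
        wdr = wd * self._r_b
        # momentum: r * P_ra dN_a + P_theta N  [u_r];  r * P_za dN_a  [u_z]
        ru0 = (np.einsum("qe,qeik,...qek->...ei", wdr, self._dN_b,
                         P[..., 0, :2])
               + np.einsum("...qe,qi->...ei", wd * P[..., 2, 2], self.N))
        ru1 = np.einsum("qe,qeik,...qek->...ei", wdr, self._dN_b,
                        P[..., 1, :2])
        res_u = np.stack([ru0, ru1], axis=-1)
        # mass: int J_dot q + int (J k C^-1 Grad mu) . Grad q
        Finv2 = Finv[..., :2, :2]
        C2 = np.einsum("...qeam,...qebm->...qeab", Finv2, Finv2)
        G = (J * k_q)[..., None] * np.einsum("...qeab,...eb->...qea",
                                             C2, grad_mu)
        res_p = (np.einsum("...qe,qj->...ej",
                           wdr * (J - self._Jold_step.T) / dt, self.N1)
                 + np.einsum("qe,ejk,...qek->...ej", wdr, self.dN1dX, G))
        return np.concatenate(
            [res_u.reshape(res_u.shape[:-2] + (12,)), dt * res_p], axis=-1)

    def _local_residual_col(self, ue, pe, dt, dpi_scale):
        ne = self.ne
        res_u = np.zeros((ne, 3))
        res_p = np.zeros((ne, 2))
        dmu = np.einsum("ej,ej->e", self.dN1dX, pe)
        for q in range(self.nq):
            dNdX = self.dNdX[q]
            w = self.qw[q]
            lam = 1.0 + np.einsum("ei,ei->e", ue, dNdX)
            if np.any(lam <= 1e-6):
                raise FloatingPointError("element inversion")
            F = np.zeros((ne, 3, 3))
            F[:, 0, 0] = 1.0
            F[:, 2, 2] = 1.0
            F[:, 1, 1] = lam
            mu_q = pe @ self.N1[q]
            P, _, k_q = self._stress_and_flowprops(F)
            Pzz = P[:, 1, 1] - (mu_q + dpi_scale * self.dpi_e)
            wd = w * self.detJ
            res_u += wd[:, None] * dNdX * Pzz[:, None]
            Gz = (k_q / lam) * dmu      # -(J F^-1 k F^-T Grad mu)_z
            res_p += wd[:, None] * (
                ((lam - self._Jold_step[:, q]) / dt)[:, None] * self.N1[q]
                + self.dN1dX * Gz[:, None])
        return np.concatenate([res_u, dt * res_p], axis=1)

    def _global_residual(self, x, dt, traction, dpi_scale):
        ue, pe = self._gather(x)
        loc = self._local_residual(ue, pe, dt, dpi_scale)
        R = np.zeros(self.ndof)
        np.add.at(R, self.edofs.ravel(), loc.ravel())
        if self._axisym:
            R -= traction * self._traction_vector
        else:
            R[self.top_node] -= -traction   # t_z = -sigma on unit area
        R[self.fixed_dofs] = x[self.fixed_dofs]
        return R

    def _tangent(self, x, dt, traction, dpi_scale):
        """Element-wise central-difference tangent (the saddle structure of
        the nearly-incompressible small-step limit amplifies first-order
        truncation error enough to stall Newton; second order keeps the
        quadratic rate)."""
        ue, pe = self._gather(x)
        nloc = self.nloc
        h_u = self.cfg.fd_step
        h_p = 0.1 * self.cfg.fd_step
        if self._axisym:
            # all +/- perturbations in one vectorised residual evaluation,
            # on the reduced quadrature rule
            B = 2 * nloc
            ue_b = np.broadcast_to(ue, (B,) + ue.shape).copy()
            pe_b = np.broadcast_to(pe, (B,) + pe.shape).copy()
            steps = np.empty(nloc)
            for j in range(nloc):
                if j < self.nloc_u:
                    ue_b[j, :, j // 2, j % 2] += h_u
                    ue_b[nloc + j, :, j // 2, j % 2] -= h_u
                    steps[j] = h_u
                else:
                    pe_b[j, :, j - self.nloc_u] += h_p
                    pe_b[nloc + j, :, j - self.nloc_u] -= h_p
                    steps[j] = h_p
            loc = self._local_residual(ue_b, pe_b, dt, dpi_scale)
            K = np.transpose(
                (loc[:nloc] - loc[nloc:]) / (2.0 * steps)[:, None, None],
                (1, 2, 0))
        else:
            K = np.empty((self.ne, nloc, nloc))
            for j in range(nloc):
                ue_p, pe_p = ue.copy(), pe.copy()
                ue_m, pe_m = ue.copy(), pe.copy()
                if j < self.nloc_u:
                    ue_p[:, j] += h_u
                    ue_m[:, j] -= h_u
                    h = h_u
                else:
                    pe_p[:, j - self.nloc_u] += h_p
                    pe_m[:, j - self.nloc_u] -= h_p
                    h = h_p
                K[:, :, j] = (
                    self._local_residual(ue_p, pe_p, dt, dpi_scale)
                    - self._local_residual(ue_m, pe_m, dt, dpi_scale)
                ) / (2.0 * h)
        A = sp.coo_matrix(
            (K.reshape(self.ne, -1).ravel(),
             (self._coo_rows, self._coo_cols)),
            shape=(self.ndof, self.ndof)).tocsr()
        # Dirichlet rows -> identity
        mask = np.zeros(self.ndof, bool)
        mask[self.fixed_dofs] = True
        d = sp.diags(np.where(mask, 0.0, 1.0))
        A = d @ A + sp.diags(mask.astype(float))
        return A

    # ---- stepping ------------------------------------------------------
    def _force_scale(self, traction: float) -> float:
        if self._axisym:
            base = abs(traction) * np.linalg.norm(self._traction_vector)
            return max(base, 1.0)
        return max(abs(traction), 1e-3)

    def _newton(self, dt, traction, dpi_scale):
        cfg = self.cfg
        x = self.x.copy()
        tol = cfg.newton_tol * self._force_scale(traction)
        prev_norm = np.inf
        x_base = None           # state before the last update
        dx_last = None
        damping = 1.0
        norm = np.inf
        stalled = 0
        it = 0
        while it < cfg.newton_max:
            try:
                R = self._global_residual(x, dt, traction, dpi_scale)
                norm = float(np.linalg.norm(R))
                if not np.isfinite(norm):
                    raise FloatingPointError("non-finite residual")
            except FloatingPointError as exc:
                # overshoot into inversion/overflow: backtrack the update
                if dx_last is None or damping < 1.0 / 64.0:
                    raise SolverError(str(exc), self.time) from exc
                damping *= 0.5
                x = x_base - damping * dx_last
                it += 1
                continue
            if norm < tol:
                self.x = x
                self._last_iters = it
                return it
            # stagnation at the finite-difference noise floor: accept if
            # the residual is already far below the load scale
            if (norm > 0.5 * prev_norm and norm < 1e3 * tol
                    and stalled >= 2):
                self.x = x
                self._last_iters = it
                return it
            stalled = stalled + 1 if norm > 0.5 * prev_norm else 0
            if (norm > 50.0 * prev_norm and dx_last is not None
                    and damping >= 1.0 / 64.0):
                damping *= 0.5
                x = x_base - damping * dx_last
                it += 1
                continue
            if (self._lu is None
                    or (norm > 0.5 * prev_norm and prev_norm < np.inf)):
                A = self._tangent(x, dt, traction, dpi_scale)
                self._lu = spla.splu(A.tocsc())
            dx_last = self._lu.solve(R)
            x_base = x
            x = x - dx_last
            damping = 1.0
            prev_norm = norm
            it += 1
        raise SolverError("Newton divergence", self.time, norm)

    def _update_history(self) -> None:
        ue, _ = self._gather(self.x)
        if self._axisym:
            _, J, _ = self._axisym_kinematics(ue)
            self.J_old = J.T.copy()
        else:
            for q in range(self.nq):
                self.J_old[:, q] = 1.0 + np.einsum("ei,ei->e", ue,
                                                   self.dNdX[q])

    def step(self, dt: float, traction: float,
             dpi_scale: float = 1.0, phase_key=None) -> None:
        """Advance one implicit time step (with automatic subdivision on
        Newton failure).

        ``phase_key`` identifies the phase of a periodic load cycle: the
        Jacobian factorisation is cached per phase, so after the first
        cycle each step reuses the factorisation from the same phase of
        the previous cycle (an excellent preconditioner under cyclic
        loading).
        """
        if phase_key is not None:
            cached = self._lu_phase.get(phase_key)
            if cached is not None:
                self._lu = cached
        remaining, level = dt, 0
        while remaining > 1e-9:
            sub = remaining if level == 0 else dt / (4 ** level)
            sub = min(sub, remaining)
            x_old = self.x.copy()
            try:
                self._Jold_step = self.J_old.copy()
                # extrapolation predictor: start (and, if needed, assemble
                # the tangent) near the incoming solution
                if (self._x_prev is not None and level == 0
                        and self._dt_prev > 0.0):
                    self.x = x_old + (x_old - self._x_prev) * (
                        sub / self._dt_prev)
                self._newton(sub, traction, dpi_scale)
                self._update_history()
                self._x_prev = x_old
                self._dt_prev = sub
                self.time += sub
                remaining -= sub
            except SolverError:
                self.x = x_old
                level += 1
                self._lu = None
                if level > 4:
                    raise
        self._lu = None if level else self._lu
        if phase_key is not None and self._lu is not None:
            self._lu_phase[phase_key] = self._lu

    # ---- recording -----------------------------------------------------
    def state(self, traction: float = 0.0,
              protocol_time: Optional[float] = None) -> PoroState:
        ue, pe = self._gather(self.x)
        ne = self.ne
        phi = np.empty((ne, self.nq))
        k_el = np.zeros(ne)
        if self._axisym:
            vel = np.zeros((ne, 2))
        else:
            vel = np.zeros(ne)
        grad_mu = (np.einsum("ejk,ej->ek", self.dN1dX, pe)
                   if self._axisym else
                   np.einsum("ej,ej->e", self.dN1dX, pe))
        if self._axisym:
            _, Jq, Finvq = self._axisym_kinematics(ue)
            for q in range(self.nq):
                phi[:, q] = law.update_porosity(self.phi0_e, Jq[q],
                                                floor=0.01)
                for idx, ns in self.perm_groups:
                    k_el[idx] += law.permeability(Jq[q][idx], ns) / self.nq
            # seepage (pore fluid) velocity v = -k F^-T Grad mu / phi at
            # the mid quadrature point
            Finv = Finvq[self.nq // 2]
            gx = np.einsum("emk,ek->em",
                           np.swapaxes(Finv[:, :2, :2], 1, 2), grad_mu)
            vel = -(k_el / phi.mean(axis=1))[:, None] * gx
        if not self._axisym:
            for q in range(self.nq):
                J = 1.0 + np.einsum("ei,ei->e", ue, self.dNdX[q])
                phi[:, q] = law.update_porosity(self.phi0_e, J, floor=0.01)
                for idx, ns in self.perm_groups:
                    k_el[idx] += law.permeability(J[idx], ns) / self.nq
            lam = 1.0 + np.einsum("ei,ei->e", ue, self.dNdX[1])
            vel = -k_el * grad_mu / lam / phi.mean(axis=1)
        dpi_nodal = np.zeros(self.nv)
        for region, idx in self.region_groups.items():
            dpi = self.params.regions[region].delta_pi
            if dpi > 0.0:
                nodes = self.vmap[np.unique(self.mesh.elems_p1[idx])]
                dpi_nodal[nodes] = np.maximum(dpi_nodal[nodes], dpi)
        mu = self.x[self.nu:]
        u_field = (self.x[:self.nu].reshape(self.nn, 2)
                   if self._axisym else self.x[:self.nu])
        return PoroState(
            time=self.time if protocol_time is None else protocol_time,
            displacement=u_field.copy(), mu=mu.copy(),
            pressure=mu + dpi_nodal, J_qp=self.J_old.copy(), phi_qp=phi,
            k_elem=k_el, velocity=vel,
            height=self.mesh.disc_height(u_field), traction=traction)

    # ---- drivers -------------------------------------------------------
    def equilibrate(self, preload: float = 0.1) -> PoroState:
        """Free-swelling initialisation: ramp up the osmotic pressure and
        the resting preload, then creep until the height rate drops below
        the configured tolerance."""
        cfg = self.cfg
        n = cfg.ramp_steps
        for i in range(1, n + 1):
            self.step(60.0 / n, preload * i / n, dpi_scale=i / n)
        t_equil, dt = 60.0, 120.0
        h_prev = self.mesh.disc_height(
            self.x[:self.nu].reshape(self.nn, self.ncomp).squeeze()
            if self._axisym else self.x[:self.nu])
        while t_equil < cfg.equil_max_hours * SECONDS_PER_HOUR:
            self.step(dt, preload)
            u = (self.x[:self.nu].reshape(self.nn, 2)
                 if self._axisym else self.x[:self.nu])
            h = self.mesh.disc_height(u)
            rate = abs(h - h_prev) / h / (dt / SECONDS_PER_HOUR)
            h_prev = h
            t_equil += dt
            dt = min(dt * 2.0, 4.0 * SECONDS_PER_HOUR)
            if rate < cfg.equil_rate_tol:
                break
        self.time = 0.0
        self.equilibrated = True
        return self.state(traction=preload)

    def run_protocol(self, protocol: LoadProtocol,
                     sample_times: Optional[Sequence[float]] = None,
                     preload: Optional[float] = 0.1,
                     equilibrate: bool = True,
                     record_times: Optional[Sequence[float]] = None,
                     trace: Optional[list] = None) -> list[PoroState]:
        """March through a load protocol (free-swelling equilibration first
        unless disabled).

        Returns full states at ``record_times`` (default: every grid point;
        the initial state is always included).  If a list is passed as
        ``trace``, a (time, height, peak disc Darcy-flux) tuple is appended
        at every internal step -- cyclic runs then stay cheap while the
        velocity history remains observable.
        """
        states = []
        if equilibrate and not self.equilibrated:
            pre = protocol.traction(0.0) if preload is None else preload
            states.append(self.equilibrate(pre))
        else:
            states.append(self.state(traction=protocol.traction(0.0)))
        grid = _step_times(protocol, self.cfg, sample_times)
        rec = None
        if record_times is not None:
            rec = np.asarray(sorted(set(float(t) for t in record_times)))
        disc_mask = np.isin(self.mesh.region, ("NP", "AFI", "AFO"))
        for t_prev, t_next in zip(grid[:-1], grid[1:]):
            trac = protocol.traction(t_next)
            piece = protocol.piece_at(t_next)
            key = None
            if piece["kind"] == "sin":
                spc = self.cfg.steps_per_cycle
                phase = ((t_next - piece["t0"]) * piece["freq"]) % 1.0
                key = int(round(phase * spc)) % spc
            self.step(t_next - t_prev, trac, phase_key=key)
            self.time = t_next
            st = self.state(traction=trac, protocol_time=t_next)
            if trace is not None:
                v = st.velocity
                speed = (np.abs(v) if v.ndim == 1
                         else np.linalg.norm(v, axis=1))
                trace.append((t_next, st.height,
                              float(speed[disc_mask].max())))
            if rec is None or np.any(np.abs(rec - t_next) < 1e-6):
                states.append(st)
        return states


# ---------------------------------------------------------------------------
# summary quantities
# ---------------------------------------------------------------------------
def run_protocol(mesh: DiscMesh, params: ParameterSet,
                 protocol: LoadProtocol,
                 sample_times: Optional[Sequence[float]] = None,
                 config: Optional[SolverConfig] = None) -> list[PoroState]:
    """Convenience wrapper: build a solver, equilibrate, run the protocol."""
    return PoroSolver(mesh, params, config).run_protocol(
        protocol, sample_times)


def disc_height_change(state: PoroState, reference: PoroState) -> float:
    """(h_ref - h) / h_ref over the NP+AF region."""
    return (reference.height - state.height) / reference.height


def peak_fluid_speed(states: Sequence[PoroState],
                     mesh: Optional[DiscMesh] = None,
                     regions: Optional[Sequence[str]] = None) -> float:
    """Maximum Darcy-flux magnitude over the (filtered) elements and all
    supplied states, mm/s."""
    if len(states) == 0:
        raise ValueError("empty state sequence")
    mask = None
    if mesh is not None and regions is not None:
        mask = np.isin(mesh.region, list(regions))
    peak = 0.0
    for st in states:
        v = st.velocity
        speed = np.abs(v) if v.ndim == 1 else np.linalg.norm(v, axis=1)
        if mask is not None:
            speed = speed[mask]
        if speed.size:
            peak = max(peak, float(speed.max()))
    return peak
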