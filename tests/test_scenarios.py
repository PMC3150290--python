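"""Scenario drivers: coupling configs, exchange cadence, summaries."""

import numpy as np
import pandas as pd
import pytest

import discflux as dx
from discflux.poromechanics import LoadProtocol
from discflux.scenarios import (CYCLIC_AMPLITUDES, CoupledModel,
                                CouplingConfig, _exchange_grid,
                                midline_profile, relative_change,
                                run_diurnal, run_sensitivity)


def test_relative_change_trivial_cases():
    t = np.linspace(0.0, 10.0, 50)
    ref = pd.Series(2.0 + 0.1 * t, index=t)
    assert relative_change(ref, ref) == 0.0
    assert relative_change(1.5 * ref, ref) == pytest.approx(50.0)
    assert relative_change(0.8 * ref, ref) == pytest.approx(-20.0)


def test_relative_change_rejects_zero_reference():
    t = np.linspace(0.0, 1.0, 5)
    ref = pd.Series(np.zeros(5), index=t)
    with pytest.raises(ZeroDivisionError):
        relative_change(ref + 1.0, ref)


def test_diurnal_rejects_zero_days(healthy):
    with pytest.raises(ValueError):
        run_diurnal(healthy, days=0)


def test_unknown_cyclic_amplitude_rejected(healthy):
    from discflux.scenarios import run_cyclic
    with pytest.raises(KeyError):
        run_cyclic(healthy, 1.0, "A9")


def test_cyclic_amplitude_defaults():
    assert CYCLIC_AMPLITUDES == {"A0": 0.0, "A1": 0.1, "A2": 0.2}


def test_exchange_grid_refines_near_transitions():
    protocol = LoadProtocol.diurnal(days=1)
    cp = CouplingConfig()
    grid = _exchange_grid(protocol, cp)
    dt = np.diff(grid)
    t16h = 16 * 3600.0
    after = dt[(grid[:-1] >= t16h) & (grid[:-1] < t16h + 1500.0)]
    assert after.max() <= cp.exchange_transient + 1e-6
    assert dt.max() <= cp.exchange_plateau + 1e-6
    # transition instants are on the grid exactly
    assert np.any(np.abs(grid - t16h) < 1e-9)


def test_midline_profile_is_mirrored(disc_mesh):
    field = np.full(disc_mesh.n_nodes, np.nan)
    idx = disc_mesh.disc_elements()
    nodes = np.unique(disc_mesh.elems_p2[idx])
    field[nodes] = disc_mesh.nodes[nodes, 0] ** 2
    prof = midline_profile(disc_mesh, field)
    v = prof["value"].to_numpy()
    assert np.allclose(v, v[::-1])
    assert prof["position_mm"].iloc[0] == -prof["position_mm"].iloc[-1]


def test_undeformed_mode_ignores_mechanics(healthy):
    cp = CouplingConfig.undeformed()
    assert not cp.uses_mechanics
    model = CoupledModel(healthy, cp, resolution=1)
    res = model.run_coupled(LoadProtocol.diurnal(days=1))
    assert model.mech is None                 # mechanics never built
    assert len(res.height) == 0
    assert res.probes["o2_NP"].iloc[-1] > 0.0


def test_variant_identical_to_base_normalises_to_one(healthy):
    """Sensitivity against an identical variant: all normalised values 1
    (transport-only coupling keeps this cheap)."""
    import dataclasses
    clone = dataclasses.replace(healthy, name="clone")
    table = run_sensitivity(healthy, [clone], days=1,
                            coupling=CouplingConfig.undeformed())
    row = table.loc["clone"]
    for col in ("o2_NP_norm", "o2_AFO_norm", "lac_NP_norm",
                "lac_AFO_norm"):
        assert row[col] == pytest.approx(1.0, abs=1e-12)


def test_zero_cell_density_reduces_to_pure_diffusion(healthy):
    """With no cells anywhere the coupled run equals the reaction-free
    diffusion solution."""
    import dataclasses
    dead = dataclasses.replace(
        healthy, name="acellular",
        regions={k: dataclasses.replace(v, rho_cell=0.0)
                 for k, v in healthy.regions.items()})
    cp = CouplingConfig.undeformed()
    model = CoupledModel(dead, cp, resolution=1)
    res = model.run_coupled(LoadProtocol.diurnal(days=1))
    from discflux.transport import SoluteSpec, TransportSolver
    ref = TransportSolver(model.mesh, dead, SoluteSpec.oxygen(dead))
    st = ref.initial_state()
    grid = _exchange_grid(LoadProtocol.diurnal(days=1), cp)
    for dt in np.diff(grid):
        st = ref.step(st, dt)
    assert model.state_oxygen.c == pytest.approx(st.c, abs=1e-10)
    # lactate likewise relaxes to its boundary-driven diffusion field
    assert res.probes["lac_NP"].iloc[-1] < 0.9 + 1e-6


def test_geometry_spec_yaml_round_trip():
    spec = dx.DiscGeometrySpec(height=12.3, resolution=2)
    back = dx.DiscGeometrySpec.from_yaml(spec.to_yaml())
    assert back == spec


def test_degeneration_comparison_identity(healthy):
    """Identical parameter sets in both slots give identical paired
    outputs (one-day desk run)."""
    from discflux.scenarios import run_degeneration_comparison
    out = run_degeneration_comparison(healthy, healthy, days=1)
    for mode in ("deformed", "undeformed"):
        a = out["runs"][("healthy", mode)].probes
        b = out["runs"][("degenerated", mode)].probes
        pd.testing.assert_frame_equal(a, b)
        pa = out["profiles"][("healthy", mode)]["oxygen"]
        pb = out["profiles"][("degenerated", mode)]["oxygen"]
        pd.testing.assert_frame_equal(pa, pb)
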