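"""Biphasic solver: load protocols, consolidation physics, summaries."""

import dataclasses

import numpy as np
import pytest

import discflux as dx
from discflux.poromechanics import (LoadProtocol, PoroSolver, PoroState,
                                    disc_height_change, peak_fluid_speed)
from discflux.verification import (consolidation_coefficient,
                                   terzaghi_oracle)


@pytest.fixture(scope="module")
def np_nosw(healthy):
    """NP material with swelling off (consolidation benchmarks)."""
    ps = dx.load_parameter_set("healthy")
    ps.regions["NP"] = dataclasses.replace(ps.regions["NP"], delta_pi=0.0)
    return ps


# ---- load protocols -------------------------------------------------------
def test_diurnal_protocol_traction_pattern():
    p = LoadProtocol.diurnal(days=2)
    assert p.duration == 2 * 24 * 3600.0
    assert p.traction(8 * 3600.0) == pytest.approx(0.5)
    assert p.traction(20 * 3600.0) == pytest.approx(0.1)
    assert p.traction(24 * 3600.0 + 7200.0) == pytest.approx(0.5)


def test_diurnal_rejects_zero_days():
    with pytest.raises(ValueError):
        LoadProtocol.diurnal(days=0)


def test_cyclic_zero_amplitude_is_creep():
    a0 = LoadProtocol.cyclic(0.0, 1.0)
    sin = LoadProtocol.cyclic(0.2, 1.0)
    t = np.linspace(15.0, 410.0, 200)
    assert np.allclose([a0.traction(x) for x in t], 0.5)
    tr = np.array([sin.traction(x) for x in t])
    assert tr.max() == pytest.approx(0.7, abs=0.01)
    assert tr.min() == pytest.approx(0.3, abs=0.01)


# ---- trivial and oracle solutions -----------------------------------------
def test_unloaded_without_swelling_stays_at_rest(np_nosw):
    col = dx.build_column_mesh(1.0, 6, region="NP")
    s = PoroSolver(col, np_nosw)
    for _ in range(3):
        s.step(100.0, 0.0)
    assert np.allclose(s.x, 0.0, atol=1e-12)


def test_terzaghi_consolidation_profile(np_nosw, column):
    """Pore pressure matches the classical series within 2% L2."""
    mat = np_nosw.regions["NP"]
    cv = consolidation_coefficient(mat)
    sigma = 0.001                       # small strain limit
    s = PoroSolver(column, np_nosw)
    T_target = 0.1 / cv                 # dimensionless time 0.1
    nsteps = 50
    for _ in range(nsteps):
        s.step(T_target / nsteps, sigma)
    st = s.state(traction=sigma)
    z = column.nodes[column.vertex_ids, 0]
    report = terzaghi_oracle(z, st.mu, T_target, 1.0, mat, sigma)
    assert report.passed, f"L2 error {report.l2_error:.3%}"
    assert report.l2_error < 0.02


def test_step_response_monotone_in_time(np_nosw, column):
    s = PoroSolver(column, np_nosw)
    tops = []
    for _ in range(20):
        s.step(200.0, 0.001)
        tops.append(s.state().displacement[
            int(column.facets["top"][0, 0])])
    assert np.all(np.diff(tops) < 1e-15)     # settles monotonically


def test_volume_change_balances_boundary_flux(np_nosw, column):
    """Discrete mass conservation: total J change equals the drained-
    boundary flux (from the eliminated Dirichlet row) within 1%."""
    s = PoroSolver(column, np_nosw)
    dt = 500.0
    s.step(dt, 0.001)
    # recompute the raw (un-eliminated) mass residual at convergence
    ue, pe = s._gather(s.x)
    s._Jold_step = np.ones_like(s.J_old)
    loc = s._local_residual(ue, pe, dt, 1.0)
    R = np.zeros(s.ndof)
    np.add.at(R, s.edofs.ravel(), loc.ravel())
    res_p = R[s.nu:] / dt               # undo the dt equation scaling
    # interior rows vanish at convergence, so the drained-row residual is
    # the net efflux; it must balance the total rate of volume change
    drained_row = s.vmap[int(column.facets["top"][0, 0])]
    efflux = res_p[drained_row] - (res_p.sum() - res_p[drained_row]) * 0.0
    total_Jdot = res_p.sum()            # = int (J - J_old)/dt dV
    interior = np.delete(res_p, drained_row)
    assert np.abs(interior).max() < 1e-2 * abs(efflux)
    assert total_Jdot == pytest.approx(efflux, rel=0.01)


def test_drained_long_time_limit_with_swelling(healthy):
    """Constant load: chemical potential relaxes to 0 (so NP pressure to
    its swelling value) and fluid velocity to ~0."""
    col = dx.build_column_mesh(1.0, 8, region="NP")
    s = PoroSolver(col, healthy)
    for _ in range(30):
        s.step(2000.0, 0.05)
    st = s.state()
    assert np.abs(st.mu).max() < 1e-4
    assert np.abs(st.velocity).max() < 1e-8
    assert st.pressure.max() == pytest.approx(0.15, abs=1e-3)


def test_mesh_translation_invariance(healthy):
    """Rigid axial translation of the mesh leaves outputs unchanged."""
    spec = dx.DiscGeometrySpec(resolution=1)
    m1 = dx.build_disc_mesh(spec)
    m2 = dx.build_disc_mesh(spec)
    m2.nodes = m2.nodes + np.array([0.0, 5.0])
    out = []
    for m in (m1, m2):
        s = PoroSolver(m, healthy)
        s.step(60.0, 0.3)
        st = s.state()
        out.append((st.height, st.mu.copy(), st.J_qp.copy()))
    assert out[0][0] == pytest.approx(out[1][0], abs=1e-10)
    assert np.allclose(out[0][1], out[1][1], atol=1e-9)
    assert np.allclose(out[0][2], out[1][2], atol=1e-12)


# ---- summary quantities ---------------------------------------------------
def _mock_state(mesh, displacement, velocity=None):
    ne = mesh.n_elements
    vel = np.zeros((ne, 2)) if velocity is None else velocity
    return PoroState(time=0.0, displacement=displacement,
                     mu=np.zeros(1), pressure=np.zeros(1),
                     J_qp=np.ones((ne, 6)), phi_qp=np.ones((ne, 6)),
                     k_elem=np.zeros(ne), velocity=vel,
                     height=mesh.disc_height(displacement))


def test_disc_height_change_trivial_and_affine(disc_mesh):
    u0 = np.zeros_like(disc_mesh.nodes)
    ref = _mock_state(disc_mesh, u0)
    assert disc_height_change(ref, ref) == 0.0
    z0, z1 = disc_mesh.disc_z
    u = np.zeros_like(disc_mesh.nodes)
    u[:, 1] = -0.10 * (disc_mesh.nodes[:, 1] - z0)   # uniform 10% squeeze
    st = _mock_state(disc_mesh, u)
    assert disc_height_change(st, ref) == pytest.approx(0.10, rel=1e-9)


def test_peak_fluid_speed_examples(disc_mesh):
    u0 = np.zeros_like(disc_mesh.nodes)
    st = _mock_state(disc_mesh, u0)
    assert peak_fluid_speed([st]) == 0.0
    v = np.zeros((disc_mesh.n_elements, 2))
    idx = disc_mesh.disc_elements()[0]
    v[idx] = [6e-4, 8e-4]               # norm 1e-3 mm/s
    st2 = _mock_state(disc_mesh, u0, velocity=v)
    assert peak_fluid_speed([st, st2], disc_mesh,
                            ("NP", "AFI", "AFO")) == pytest.approx(1e-3)
    with pytest.raises(ValueError):
        peak_fluid_speed([])
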