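"""ADR transport: oracles, stability, conservation and toggles."""

import numpy as np
import pytest

import discflux as dx
from discflux.transport import (SoluteSpec, TransportSolver, advance_solute,
                                courant_check, steady_state_time)
from discflux.verification import (advection_diffusion_profile,
                                   exponential_settling_time,
                                   reaction_diffusion_oracle)
from discflux.constitutive import mackie_meares_diffusivity


@pytest.fixture(scope="module")
def slab(healthy):
    mesh = dx.build_column_mesh(10.0, 24, region="NP")
    spec = SoluteSpec("oxygen", "kPa", d_water=3.0e-3, bc_af=5.0,
                      bc_cep=5.0)
    return TransportSolver(mesh, healthy, spec)


def _steady(solver, source=None, sink=None, n=400, dt=2000.0, c0=None):
    st = solver.initial_state()
    if c0 is not None:
        st.c[:] = c0
        st.c[solver.dirichlet] = solver.dirichlet_values
    for _ in range(n):
        st = solver.step(st, dt, source=source, sink_coeff=sink)
    return st


def test_courant_number_examples(disc_mesh):
    ne = disc_mesh.n_elements
    assert courant_check(np.zeros((ne, 2)), 1000.0, disc_mesh) == 0.0
    col = dx.build_column_mesh(10.0, 10)     # h = 1 mm
    v = np.full(col.n_elements, 5e-4)
    assert courant_check(v, 1000.0, col) == pytest.approx(0.5)
    col2 = dx.build_column_mesh(1.0, 10)     # h = 0.1 mm
    assert courant_check(np.full(10, 5e-4), 1000.0,
                         col2) == pytest.approx(5.0)


def test_uniform_boundary_gives_uniform_steady_field(slab):
    st = _steady(slab, n=200)
    assert np.allclose(st.c, 5.0, atol=1e-8)


def test_reaction_diffusion_steady_profile_matches_parabola(slab, healthy):
    """Zeroth-order consumption between fixed edges: parabola within 1%."""
    phi = healthy.regions["NP"].phi0
    D = float(mackie_meares_diffusivity(phi, 3.0e-3))
    S = 2e-4                                  # kPa/s consumed
    st = _steady(slab, source=-S * np.ones(slab.nn), c0=5.0)
    z = slab.mesh.nodes[slab.tnodes, 0]
    report = reaction_diffusion_oracle(z, st.c, 10.0, D, S, 5.0, 5.0)
    assert report.passed, f"L2 {report.l2_error:.3%}"


def test_advection_diffusion_matches_exponential_layer(slab, healthy):
    """Steady advection between fixed ends reproduces the Peclet-layer
    closed form (moderate Peclet, resolved mesh)."""
    phi = healthy.regions["NP"].phi0
    D = float(mackie_meares_diffusivity(phi, 3.0e-3))
    v = 5.0 * D / 10.0                        # Pe_L = 5
    slab.set_geometry(slab.mesh.nodes,
                      velocity_elem=np.full(len(slab.elements), v))
    st = _steady(slab, n=600, dt=5000.0)
    z = slab.mesh.nodes[slab.tnodes, 0]
    # column Dirichlet tags: bottom = "cep" value, top = "af" value
    c_exact = advection_diffusion_profile(z, 10.0, D, v, slab.spec.bc_cep,
                                          slab.spec.bc_af)
    err = np.linalg.norm(st.c - c_exact) / np.linalg.norm(c_exact)
    assert err < 0.01


def test_supg_stabilises_sharp_layer(healthy):
    """At high element Peclet number the stabilised solution remains
    bounded (no blow-up oscillations)."""
    mesh = dx.build_column_mesh(10.0, 10, region="NP")
    spec = SoluteSpec("oxygen", "kPa", d_water=3.0e-3, bc_af=5.0,
                      bc_cep=1.0)
    solver = TransportSolver(mesh, healthy, spec)
    D = float(mackie_meares_diffusivity(0.83, 3.0e-3))
    v = 60.0 * D / 10.0                      # element Peclet = 3
    solver.set_geometry(mesh.nodes,
                        velocity_elem=np.full(len(solver.elements), v))
    st = _steady(solver, n=300, dt=5000.0)
    assert st.c.min() > -0.05
    assert st.c.max() < 5.3


def test_maximum_principle_no_reaction(disc_mesh, healthy):
    """Pure diffusion from zero initial conditions stays (essentially)
    within the hull of boundary and initial values; early quadratic
    undershoots decay away."""
    spec = SoluteSpec.oxygen(healthy)
    solver = TransportSolver(disc_mesh, healthy, spec)
    st = solver.initial_state()
    worst_late = 0.0
    for i in range(120):
        st = solver.step(st, 900.0)
        if i > 8:
            worst_late = min(worst_late, st.c.min())
    assert st.c.max() <= 5.8 + 1e-9
    assert worst_late >= -0.01 * 5.8


def test_advection_toggle_with_zero_velocity_is_identity(disc_mesh,
                                                         healthy):
    spec = SoluteSpec.oxygen(healthy)
    a = TransportSolver(disc_mesh, healthy, spec)
    b = TransportSolver(disc_mesh, healthy, spec)
    a.set_geometry(disc_mesh.nodes, velocity_elem=None)
    b.set_geometry(disc_mesh.nodes,
                   velocity_elem=np.zeros((len(b.elements), 2)))
    sa = a.step(a.initial_state(), 900.0)
    sb = b.step(b.initial_state(), 900.0)
    assert np.array_equal(sa.c, sb.c)


def test_deforming_mesh_conserves_closed_content(disc_mesh, healthy):
    """Axial squeeze-and-release with closed boundaries conserves total
    solute content within 0.5%."""
    spec = SoluteSpec.oxygen(healthy)
    solver = TransportSolver(disc_mesh, healthy, spec)
    solver.dirichlet = np.array([], dtype=int)
    solver.dirichlet_values = np.array([])
    st = solver.initial_state()
    st.c[:] = 3.0 + 0.5 * np.sin(disc_mesh.nodes[solver.tnodes, 0])
    solver.set_geometry(disc_mesh.nodes)
    total0 = solver.total_content(st)
    zmid = 0.5 * sum(disc_mesh.disc_z)
    for scale in (0.97, 0.94, 0.97, 1.0):
        coords = disc_mesh.nodes.copy()
        coords[:, 1] = zmid + (coords[:, 1] - zmid) * scale
        solver.set_geometry(coords)
        st = solver.step(st, 600.0, use_prev_mass=True)
    assert solver.total_content(st) == pytest.approx(total0, rel=0.005)


def test_negative_concentration_guard(disc_mesh, healthy):
    spec = SoluteSpec.oxygen(healthy)
    solver = TransportSolver(disc_mesh, healthy, spec)
    st = solver.initial_state()
    sink = np.full(solver.nn, 5e-3)          # absurdly strong uptake
    with pytest.raises(RuntimeError, match="negative|Courant"):
        for _ in range(50):
            st = solver.step(st, 900.0, source=-0.05 * np.ones(solver.nn))


def test_steady_state_time_examples():
    t = np.linspace(0.0, 48.0, 200)
    const = np.full((200, 2), 3.0)
    assert steady_state_time(t, const) == 0.0
    tau = 3.0
    c = 5.0 * (1.0 - np.exp(-t / tau))
    got = steady_state_time(t, c[:, None])
    expected = exponential_settling_time(tau)
    assert got == pytest.approx(expected, rel=0.1)
    growing = np.exp(t / 10.0)
    assert steady_state_time(t, growing[:, None]) is None


def test_advance_solute_courant_violation_raises(disc_mesh, healthy):
    from discflux.poromechanics import PoroSolver
    solver = TransportSolver(disc_mesh, healthy,
                             SoluteSpec.oxygen(healthy))
    ps = PoroSolver(disc_mesh, healthy)
    st_poro = ps.state()
    st_poro.velocity[:] = 5e-3               # fast flow, h ~ 0.2 mm
    with pytest.raises(RuntimeError, match="Courant"):
        advance_solute(solver, solver.initial_state(), 3600.0,
                       poro=st_poro)
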