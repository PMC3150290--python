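"""Material laws against independent symbolic/finite-difference oracles."""

import numpy as np
import pytest
import sympy as sp

import discflux.constitutive as law


@pytest.fixture(scope="module")
def np_params(healthy):
    return healthy.regions["NP"]


@pytest.fixture(scope="module")
def af_params(healthy):
    return healthy.regions["AFO"]


def _sympy_neo_hookean_P(F_val, G, K):
    """dW/dF from an independent symbolic derivation."""
    Fs = sp.Matrix(3, 3, lambda i, j: sp.Symbol(f"f{i}{j}"))
    J = Fs.det()
    I1 = sp.trace(Fs.T * Fs)
    W = sp.Rational(1, 2) * G * (J ** sp.Rational(-2, 3) * I1 - 3) \
        + sp.Rational(1, 2) * K * (J - 1) ** 2
    subs = {sp.Symbol(f"f{i}{j}"): F_val[i, j]
            for i in range(3) for j in range(3)}
    P = np.array([[float(sp.diff(W, Fs[i, j]).subs(subs))
                   for j in range(3)] for i in range(3)])
    return P


def test_zero_stress_at_identity(np_params, af_params):
    F = np.eye(3)
    assert np.allclose(law.neo_hookean_stress(F, np_params), 0.0,
                       atol=1e-14)
    assert np.allclose(law.fibre_stress(F, af_params), 0.0, atol=1e-14)


def test_small_strain_moduli_recover_G_and_K(np_params):
    h = 1e-7
    # volumetric: P_kk/3 = K * (dJ) for F = (1+e)I
    F = (1.0 + h) * np.eye(3)
    P = law.neo_hookean_stress(F, np_params)
    K_num = np.trace(P) / 3.0 / (3.0 * h)
    assert K_num == pytest.approx(np_params.K, rel=1e-4)
    # simple shear: P_01 = G * gamma
    F = np.eye(3)
    F[0, 1] = h
    P = law.neo_hookean_stress(F, np_params)
    assert P[0, 1] / h == pytest.approx(np_params.G, rel=1e-4)


def test_pure_dilation_matches_symbolic_oracle(np_params):
    F = 1.1 ** (1.0 / 3.0) * np.eye(3)       # J = 1.1
    P = law.neo_hookean_stress(F, np_params)
    P_sym = _sympy_neo_hookean_P(F, np_params.G, np_params.K)
    assert np.allclose(P, P_sym, rtol=1e-9, atol=1e-12)


def test_random_state_matches_symbolic_oracle(np_params, rng):
    F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
    assert np.linalg.det(F) > 0
    P = law.neo_hookean_stress(F, np_params)
    P_sym = _sympy_neo_hookean_P(F, np_params.G, np_params.K)
    assert np.allclose(P, P_sym, rtol=1e-8, atol=1e-12)


def test_energy_consistency_finite_difference(np_params, af_params, rng):
    """PK1 equals dW/dF to 1e-6 relative (matrix + fibre energy)."""
    F = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
    F[1, 1] += 0.08     # stretch a fibre family into tension
    P = law.effective_stress(F, af_params)
    h = 1e-6
    P_fd = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, j] += h
            Fm[i, j] -= h
            P_fd[i, j] = (law.strain_energy(Fp, af_params)
                          - law.strain_energy(Fm, af_params)) / (2 * h)
    assert np.allclose(P, P_fd, rtol=1e-5, atol=1e-8)


def test_objectivity_under_rotation(af_params, rng):
    """PK1 transforms as P -> R P under F -> R F."""
    from scipy.spatial.transform import Rotation
    F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
    for _ in range(5):
        R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
        P1 = law.effective_stress(R @ F, af_params)
        P2 = R @ law.effective_stress(F, af_params)
        assert np.allclose(P1, P2, rtol=1e-10, atol=1e-12)


def test_fibre_tension_only_switch(af_params):
    # axial shortening + no hoop change: both families shortened -> zero
    F = np.diag([1.0, 0.9, 1.0])
    assert np.allclose(law.fibre_stress(F, af_params), 0.0)
    # hoop stretch engages both families
    F = np.diag([1.0, 1.0, 1.1])
    assert np.trace(law.fibre_stress(F, af_params)) > 0.0


def test_fibre_uniaxial_matches_symbolic_oracle(af_params):
    """Stretch along one fibre direction vs sympy derivative of the
    exponential fibre energy."""
    a = law.fibre_directions(af_params)[0]
    lam_v = 1.05
    F_val = np.eye(3) + (lam_v - 1.0) * np.outer(a, a)
    P = law.fibre_stress(F_val, af_params)

    k1, k2 = af_params.k1, af_params.k2
    lam = sp.Symbol("lam")
    I4 = lam ** 2
    W = k1 / (2 * k2) * (sp.exp(k2 * (I4 - 1) ** 2) - 1)
    # dW/dF along a x a: chain rule dW/dlam / dI4 terms handled symbolically
    dW_dlam = sp.diff(W, lam)
    # P : (a x a) = dW/dlam for this one-parameter family
    P_aa = float(dW_dlam.subs(lam, lam_v))
    # only one family is in tension for generic (non-symmetric) stretch?
    # here both families share I4 only if symmetric in axial; compute both
    a2 = law.fibre_directions(af_params)[1]
    I4_2 = a2 @ (F_val.T @ F_val) @ a2
    contrib2 = 0.0
    if I4_2 > 1.0:
        E2 = I4_2 - 1.0
        contrib2 = float(
            2 * k1 * E2 * np.exp(k2 * E2 ** 2)
            * (a2 @ F_val.T @ a2) * 1.0)  # placeholder, checked below
    P_num = float(np.einsum("ij,i,j->", P, a, a))
    if contrib2 == 0.0:
        assert P_num == pytest.approx(P_aa, rel=1e-9)
    else:
        # both in tension: subtract the independently computed second family
        Fa2 = F_val @ a2
        P2 = 2 * k1 * (I4_2 - 1) * np.exp(k2 * (I4_2 - 1) ** 2) \
            * np.outer(Fa2, a2)
        P_num1 = float(np.einsum("ij,i,j->", P - P2, a, a))
        assert P_num1 == pytest.approx(P_aa, rel=1e-9)


def test_fibre_requires_directions(af_params):
    import dataclasses
    broken = dataclasses.replace(af_params, fibre_angle_deg=None)
    with pytest.raises(ValueError):
        law.fibre_stress(np.diag([1.0, 1.0, 1.2]), broken)


def test_porosity_update_examples():
    assert law.update_porosity(0.83, 1.0) == pytest.approx(0.83)
    assert law.update_porosity(0.83, 0.9) == pytest.approx(1 - 0.17 / 0.9)
    assert law.update_porosity(0.83, 50.0) == pytest.approx(1.0, abs=0.01)
    with pytest.raises(FloatingPointError):
        law.update_porosity(0.83, 0.17)


def test_permeability_reference_state(healthy):
    for region, p in healthy.regions.items():
        assert law.permeability(1.0, p) == pytest.approx(p.k0, rel=1e-12)


def test_permeability_strain_independent_when_M_zero(np_params):
    import dataclasses
    p = dataclasses.replace(np_params, M=0.0)
    J = np.array([0.8, 1.0, 1.2])
    assert np.allclose(law.permeability(J, p), p.k0)


def test_permeability_np_compaction_matches_symbolic(np_params):
    J = 0.9
    k_sym = float(np_params.k0 * sp.exp(sp.Float(np_params.M)
                                        * (sp.Float(J) - 1)))
    assert law.permeability(J, np_params) == pytest.approx(k_sym, rel=1e-12)


def test_permeability_cep_combined_law_matches_symbolic(healthy):
    cep = healthy.regions["CEP"]
    J = 0.95
    Js, phis = sp.Float(J), sp.Float(cep.phi0)
    k_sym = float(cep.k0 * ((Js - 1 + phis) / phis) ** cep.L
                  * sp.exp(cep.M * (Js ** 2 - 1) / 2))
    assert law.permeability(J, cep) == pytest.approx(k_sym, rel=1e-12)


def test_permeability_decreases_under_compaction(healthy):
    for region in ("NP", "AFO", "CEP"):
        p = healthy.regions[region]
        k = law.permeability(np.array([0.85, 0.95, 1.0]), p)
        assert np.all(np.diff(k) > 0)


def test_mackie_meares_examples():
    assert law.mackie_meares_diffusivity(1.0, 2.0) == pytest.approx(2.0)
    ratio = law.mackie_meares_diffusivity(0.83, 1.0)
    assert ratio == pytest.approx((0.83 / 1.17) ** 2, rel=1e-12)
    phis = np.linspace(0.2, 1.0, 20)
    D = law.mackie_meares_diffusivity(phis, 1.0)
    assert np.all(np.diff(D) > 0)
    with pytest.raises(ValueError):
        law.mackie_meares_diffusivity(0.0, 1.0)


def test_swelling_pressure_examples(healthy, degenerated):
    assert law.swelling_augmented_pressure(
        0.0, healthy.regions["NP"].delta_pi) == pytest.approx(0.15)
    assert law.swelling_augmented_pressure(
        0.0, degenerated.regions["NP"].delta_pi) == pytest.approx(0.05)
    assert law.swelling_augmented_pressure(0.3, 0.0) == pytest.approx(0.3)


def test_compaction_chain_consistency(np_params, healthy):
    """J < 1 simultaneously lowers porosity, permeability, diffusivity."""
    J = 0.9
    phi = law.update_porosity(np_params.phi0, J)
    assert phi < np_params.phi0
    assert law.permeability(J, np_params) < np_params.k0
    D0 = law.mackie_meares_diffusivity(np_params.phi0,
                                       healthy.d_water_oxygen)
    assert law.mackie_meares_diffusivity(phi, healthy.d_water_oxygen) < D0


# ---- property-based checks (derandomised) ---------------------------------
from hypothesis import given, settings, strategies as st


@settings(deadline=None, max_examples=50, derandomize=True)
@given(phi0=st.floats(0.05, 0.95), J=st.floats(0.5, 2.0))
def test_porosity_bounds_property(phi0, J):
    if J <= 1.0 - phi0:
        with pytest.raises(FloatingPointError):
            law.update_porosity(phi0, J)
    else:
        phi = law.update_porosity(phi0, J)
        assert 0.0 < phi < 1.0


@settings(deadline=None, max_examples=50, derandomize=True)
@given(phi=st.floats(0.01, 1.0), dw=st.floats(1e-4, 1e-2))
def test_mackie_meares_bounded_by_free_water(phi, dw):
    D = law.mackie_meares_diffusivity(phi, dw)
    assert 0.0 < D <= dw + 1e-18
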