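"""Pointwise constitutive laws of the biphasic disc tissues.

Solid skeleton: compressible neo-Hookean matrix (shear modulus G, bulk
modulus K) with, in the annulus, a tension-only exponential fibre term acting
along two criss-crossed fibre families.  Fluid: Darcy flow with
strain-dependent permeability (exponential law for AF/NP, combined
exponential/power law for the cartilage endplate) and porosity updated from
the deformation Jacobian under intrinsically incompressible phases.  Solute
diffusivity follows the Mackie-Meares tortuosity relation; the NP fluid
pressure is the water chemical potential augmented by a constant osmotic
swelling pressure.

All functions are vectorised over leading batch axes; F has shape (..., 3, 3)
in an (r, z, theta) or (x, y, z) frame.
"""

from __future__ import annotations

import numpy as np

from .parameters import RegionParameters

_EYE = np.eye(3)


def jacobian(F: np.ndarray) -> np.ndarray:
    J = np.linalg.det(F)
    if np.any(J <= 0.0):
        raise FloatingPointError(
            "element inversion: non-positive deformation Jacobian")
    return J


def first_invariant(F: np.ndarray) -> np.ndarray:
    """I1 = tr(F^T F)."""
    return np.einsum("...ij,...ij->...", F, F)


def neo_hookean_energy(F: np.ndarray, params: RegionParameters) -> np.ndarray:
    """Volumetric/isochoric split strain energy density (MPa)."""
    J = jacobian(F)
    I1 = first_invariant(F)
    I1_bar = J ** (-2.0 / 3.0) * I1
    return (params.G / 2.0 * (I1_bar - 3.0)
            + params.K / 2.0 * (J - 1.0) ** 2)


def neo_hookean_stress(F: np.ndarray, params: RegionParameters,
                       kind: str = "pk1", J: np.ndarray | None = None,
                       Finv_T: np.ndarray | None = None) -> np.ndarray:
    """Effective solid-matrix stress from the neo-Hookean energy.

    ``kind="pk1"`` returns the first Piola-Kirchhoff stress dW/dF (the
    measure the momentum residual integrates over the reference mesh);
    ``kind="cauchy"`` pushes it forward.  ``J``/``Finv_T`` may be supplied
    by callers that have them already (assembly hot path).
    """
    if J is None:
        J = jacobian(F)
    if Finv_T is None:
        Finv_T = np.swapaxes(np.linalg.inv(F), -1, -2)
    I1 = first_invariant(F)
    Jm23 = J ** (-2.0 / 3.0)
    # scalar factors grouped first so G, K may be per-point arrays
    P = ((params.G * Jm23)[..., None, None]
         * (F - (I1 / 3.0)[..., None, None] * Finv_T)
         + (params.K * (J - 1.0) * J)[..., None, None] * Finv_T)
    if kind == "pk1":
        return P
    if kind == "cauchy":
        return np.einsum("...ij,...kj->...ik", P, F) / J[..., None, None]
    raise ValueError(f"unknown stress kind {kind!r}")


def fibre_directions(params: RegionParameters) -> np.ndarray:
    """Reference unit vectors of the two fibre families, (2, 3).

    Fibres lie in the circumferential-axial surface of the annulus at
    +/- ``fibre_angle_deg`` from the transverse plane: components are
    (radial, axial, hoop) = (0, +/-sin g, cos g).
    """
    if params.fibre_angle_deg is None:
        raise ValueError("fibre parameters set but no fibre angle defined "
                         "for this annulus region")
    g = np.deg2rad(params.fibre_angle_deg)
    return np.array([[0.0, np.sin(g), np.cos(g)],
                     [0.0, -np.sin(g), np.cos(g)]])


def fibre_energy(F: np.ndarray, params: RegionParameters,
                 directions: np.ndarray | None = None) -> np.ndarray:
    if not params.has_fibres:
        return np.zeros(np.shape(F)[:-2])
    a0 = fibre_directions(params) if directions is None else directions
    k1, k2 = params.k1, params.k2
    W = np.zeros(np.shape(F)[:-2])
    for fam in range(a0.shape[-2]):
        a = a0[..., fam, :]
        Fa = np.einsum("...ij,...j->...i", F, a)
        I4 = np.einsum("...i,...i->...", Fa, Fa)
        E = np.maximum(I4 - 1.0, 0.0)   # tension-only switch
        W = W + k1 / (2.0 * k2) * (np.exp(k2 * E ** 2) - 1.0)
    return W


def fibre_stress(F: np.ndarray, params: RegionParameters,
                 directions: np.ndarray | None = None,
                 kind: str = "pk1") -> np.ndarray:
    """Tension-only fibre contribution to the effective stress (MPa).

    Zero whenever both fibre families are at or below their reference
    length, and identically zero in regions without fibres (NP, CEP, bone).
    """
    if not params.has_fibres:
        return np.zeros(np.shape(F))
    a0 = fibre_directions(params) if directions is None else directions
    k1, k2 = params.k1, params.k2
    P = np.zeros(np.shape(F))
    for fam in range(a0.shape[-2]):
        a = a0[..., fam, :]
        Fa = np.einsum("...ij,...j->...i", F, a)
        I4 = np.einsum("...i,...i->...", Fa, Fa)
        E = np.maximum(I4 - 1.0, 0.0)
        coef = 2.0 * k1 * E * np.exp(k2 * E ** 2)
        P = P + coef[..., None, None] * np.einsum("...i,...j->...ij",
                                                  Fa, a)
    if kind == "pk1":
        return P
    if kind == "cauchy":
        J = jacobian(F)
        return np.einsum("...ij,...kj->...ik", P, F) / J[..., None, None]
    raise ValueError(f"unknown stress kind {kind!r}")


def update_porosity(phi0, J, floor=None):
    """Porosity under incompressible solid grains: phi = 1 - (1 - phi0)/J.

    Compaction to (or beyond) J = 1 - phi0 expels all fluid and raises an
    error; a solver evaluating heavily squeezed boundary-layer quadrature
    points may instead pass ``floor`` to clamp the porosity at a small
    positive residual value.
    """
    phi0 = np.asarray(phi0, dtype=float)
    J = np.asarray(J, dtype=float)
    if floor is not None:
        J = np.maximum(J, (1.0 - phi0) / (1.0 - floor))
    if np.any(J <= (1.0 - phi0)):
        raise FloatingPointError(
            "non-physical compaction: J <= 1 - phi0 (all fluid expelled)")
    return 1.0 - (1.0 - phi0) / J


def permeability(J, params: RegionParameters):
    """Strain-dependent isotropic hydraulic permeability (mm^4 N^-1 s^-1).

    Regions without a printed exponent (bone) are strain-independent;
    AF/NP follow the single-exponent law k0*exp(M*(J-1)); the CEP, the only
    region with both exponents, follows the combined power/exponential law
    k0*((J-1+phi0)/phi0)^L * exp(M*(J^2-1)/2).
    """
    J = np.asarray(J, dtype=float)
    if params.M is None:
        return np.full(J.shape, params.k0)
    if params.L is None:
        return params.k0 * np.exp(params.M * (J - 1.0))
    ratio = (J - 1.0 + params.phi0) / params.phi0   # = J*phi/phi0
    if np.any(ratio <= 0.0):
        raise FloatingPointError(
            "non-physical compaction: J <= 1 - phi0 (all fluid expelled)")
    return (params.k0 * ratio ** params.L
            * np.exp(params.M * (J ** 2 - 1.0) / 2.0))


def mackie_meares_diffusivity(phi, d_water):
    """Tissue diffusivity D = D_w * (phi / (2 - phi))^2."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0.0) or np.any(phi > 1.0):
        raise ValueError("porosity must lie in (0, 1]")
    return d_water * (phi / (2.0 - phi)) ** 2


def swelling_augmented_pressure(mu_w, delta_pi):
    """Fluid pressure p = mu_w + delta_pi (delta_pi constant, NP only)."""
    return np.asarray(mu_w, dtype=float) + delta_pi


def effective_stress(F: np.ndarray, params: RegionParameters,
                     kind: str = "pk1") -> np.ndarray:
    """Matrix plus fibre effective stress."""
    P = neo_hookean_stress(F, params, kind=kind)
    if params.has_fibres:
        P = P + fibre_stress(F, params, kind=kind)
    return P


def strain_energy(F: np.ndarray, params: RegionParameters) -> np.ndarray:
    return neo_hookean_energy(F, params) + fibre_energy(F, params)
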