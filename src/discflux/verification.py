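"""Analytic verification oracles for the solvers.

All oracles are independent closed forms (series solutions, parabolic
profiles, exponential relaxations); none calls back into the finite-element
code they are used to check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .parameters import RegionParameters


@dataclass
class OracleReport:
    """Outcome of one analytic comparison."""

    name: str
    l2_error: float
    max_error: float
    tolerance: float
    grid: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return self.l2_error <= self.tolerance


def terzaghi_pressure(z: np.ndarray, t: float, height: float, c_v: float,
                      load: float, n_terms: int = 200) -> np.ndarray:
    """Series solution of 1D consolidation: drained top (z = H), rigid
    impermeable bottom (z = 0), step load applied at t = 0."""
    z = np.asarray(z, dtype=float)
    p = np.zeros_like(z)
    Tv = c_v * t / height ** 2
    for m in range(n_terms):
        M = (2 * m + 1) * np.pi / 2.0
        p += 2.0 / M * np.sin(M * (1.0 - z / height)) * np.exp(-M ** 2 * Tv)
    return load * p


def consolidation_coefficient(material: RegionParameters) -> float:
    """c_v = k0 (K + 4G/3) in the linearised limit."""
    return material.k0 * (material.K + 4.0 * material.G / 3.0)


def terzaghi_oracle(z: np.ndarray, p_numeric: np.ndarray, t: float,
                    height: float, material: RegionParameters, load: float,
                    tolerance: float = 0.02) -> OracleReport:
    """Compare a small-strain column pressure profile with the series."""
    p_exact = terzaghi_pressure(z, t, height,
                                consolidation_coefficient(material), load)
    ref = np.linalg.norm(p_exact)
    l2 = float(np.linalg.norm(p_numeric - p_exact) / max(ref, 1e-300))
    return OracleReport("terzaghi", l2,
                        float(np.abs(p_numeric - p_exact).max()),
                        tolerance, {"n_points": len(z), "time_s": t})


def reaction_diffusion_profile(z: np.ndarray, length: float, D: float,
                               consumption: float, c_left: float,
                               c_right: float) -> np.ndarray:
    """Steady 1D profile with zeroth-order consumption S and fixed edges:
    c(z) = linear - S/(2D) z (L - z)."""
    z = np.asarray(z, dtype=float)
    lin = c_left + (c_right - c_left) * z / length
    return lin - consumption / (2.0 * D) * z * (length - z)


def reaction_diffusion_oracle(z: np.ndarray, c_numeric: np.ndarray,
                              length: float, D: float, consumption: float,
                              c_left: float, c_right: float,
                              tolerance: float = 0.01) -> OracleReport:
    c_exact = reaction_diffusion_profile(z, length, D, consumption,
                                         c_left, c_right)
    ref = np.linalg.norm(c_exact)
    l2 = float(np.linalg.norm(c_numeric - c_exact) / max(ref, 1e-300))
    return OracleReport("reaction_diffusion", l2,
                        float(np.abs(c_numeric - c_exact).max()),
                        tolerance, {"n_points": len(z)})


def advection_diffusion_profile(z: np.ndarray, length: float, D: float,
                                velocity: float, c_in: float,
                                c_out: float) -> np.ndarray:
    """Steady 1D advection-diffusion between fixed ends (Peclet layer):
    c = c_in + (c_out - c_in) (exp(v z / D) - 1)/(exp(v L / D) - 1)."""
    z = np.asarray(z, dtype=float)
    if abs(velocity) < 1e-300:
        return c_in + (c_out - c_in) * z / length
    a = np.expm1(velocity * z / D)
    b = np.expm1(velocity * length / D)
    return c_in + (c_out - c_in) * a / b


def exponential_settling_time(time_constant_h: float,
                              tolerance_per_h: float = 0.005) -> float:
    """Settling time of c(t) = c_inf (1 - exp(-t/tau)) under the
    'relative change per hour below tolerance' criterion: the rate
    |dc/dt|/c = 1/(tau (exp(t/tau) - 1)) first drops below tol at
    t = tau ln(1 + 1/(tau tol))."""
    tau = time_constant_h
    return tau * np.log(1.0 + 1.0 / (tau * tolerance_per_h))
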