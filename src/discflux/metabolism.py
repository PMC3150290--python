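"""Cell-metabolic rate laws and the sequential oxygen->lactate->pH update.

Disc cells live mainly on anaerobic glycolysis.  Oxygen consumption follows
a Michaelis-Menten law in oxygen tension modulated linearly by pH; lactate
production is an exponential glycolytic law that falls with rising oxygen
(so extra oxygen supply depresses lactate accumulation) and with falling pH
(acidic feedback); pH itself is slaved to the local lactate concentration.
Coefficients are transcribed once, below, from the cell-culture regressions
the transport literature uses for disc cells.

The per-cell rates are multiplied by the regional cell density times a
metabolic-activity factor :data:`METABOLIC_ACTIVITY` that anchors the
volumetric rates to in-vivo oxygen microelectrode measurements (central
oxygen tension ~1 kPa in the healthy lumbar disc); see docs/methods.md for
the calibration argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional
import warnings

import numpy as np

from .parameters import ParameterSet
from .units import OXYGEN_SOLUBILITY

# --- rate-law constants (one versioned block; oracle tests re-derive the ---
# --- laws from these same numbers symbolically, never from copies) --------
#: Michaelis-Menten numerator coefficient, nmol O2 / (1e6 cells h kPa-free)
OXY_VMAX = 7.28
#: Michaelis constant, kPa (multiplies the pH factor)
OXY_KM = 1.46
#: pH offset: metabolic rates vanish as pH -> 4.95
PH_OFFSET = 4.95
#: lactate production: exp(LAC_A + LAC_PH*pH + LAC_O1*pO2 + LAC_O2*pO2^2),
#: nmol / (1e6 cells h)
LAC_A = -2.47
LAC_PH = 0.93
LAC_O1 = -0.21
LAC_O2 = 0.016
#: pH-lactate coupling: pH = PH_INTERCEPT + PH_SLOPE * c_lactate
PH_INTERCEPT = 7.5
PH_SLOPE = -0.1
PH_MIN, PH_MAX = 6.0, 7.6
#: metabolically active fraction applied to the tabulated cell densities
#: (calibrated once against the in-vivo central oxygen tension, ~0.7-1 kPa)
METABOLIC_ACTIVITY = 0.05

#: documented validity range of the cell-culture regressions
PO2_RANGE = (0.0, 5.8)
PH_RANGE = (6.0, 7.5)


def _warn_range(pO2, pH) -> None:
    if np.any(np.asarray(pO2) > PO2_RANGE[1] + 1e-9) or \
            np.any((np.asarray(pH) < PH_RANGE[0]) |
                   (np.asarray(pH) > PH_RANGE[1])):
        warnings.warn("metabolic rate evaluated outside the documented "
                      "validity range (pO2 in [0, 5.8] kPa, pH in "
                      "[6.0, 7.5])", stacklevel=3)


def oxygen_consumption(pO2, pH, rho_cell, activity: float = 1.0):
    """Volumetric oxygen consumption rate, kPa h^-1 (non-negative).

    ``rho_cell`` in 1e6 cells mm^-3; the per-cell nmol rate is converted to
    partial-pressure units through the oxygen solubility.
    """
    pO2 = np.maximum(np.asarray(pO2, dtype=float), 0.0)
    pH = np.asarray(pH, dtype=float)
    _warn_range(pO2, pH)
    ph_f = np.maximum(pH - PH_OFFSET, 0.0)
    per_cell = OXY_VMAX * pO2 * ph_f / (OXY_KM * ph_f + pO2 + 1e-300)
    return activity * np.asarray(rho_cell) * per_cell / OXYGEN_SOLUBILITY


def lactate_production(pO2, pH, rho_cell, activity: float = 1.0):
    """Volumetric lactate production rate, nmol mm^-3 h^-1 (non-negative).

    Decreasing in oxygen tension over the physiological range (glycolysis is
    partly suppressed by oxygen) and decreasing as the tissue acidifies.
    """
    pO2 = np.maximum(np.asarray(pO2, dtype=float), 0.0)
    pH = np.asarray(pH, dtype=float)
    _warn_range(pO2, pH)
    per_cell = np.exp(LAC_A + LAC_PH * pH + LAC_O1 * pO2 + LAC_O2 * pO2 ** 2)
    return activity * np.asarray(rho_cell) * per_cell


def oxygen_consumption_coeff(pO2_prev, pH, rho_cell, activity: float = 1.0):
    """Linearised Michaelis-Menten coefficient k (1/h) with
    consumption = k * pO2_new, evaluated at the previous oxygen field
    (semi-implicit treatment keeps the transport step positivity-friendly).
    """
    pO2_prev = np.maximum(np.asarray(pO2_prev, dtype=float), 0.0)
    ph_f = np.maximum(np.asarray(pH, dtype=float) - PH_OFFSET, 0.0)
    return (activity * np.asarray(rho_cell) * OXY_VMAX * ph_f
            / (OXY_KM * ph_f + pO2_prev + 1e-300) / OXYGEN_SOLUBILITY)


def ph_from_lactate(c_lactate, constant_ph: Optional[float] = None):
    """Local pH slaved to lactate (clipped to [6.0, 7.6]); a constant-pH
    override (e.g. 7.1) decouples the oxygen reaction from lactate."""
    c = np.asarray(c_lactate, dtype=float)
    if constant_ph is not None:
        return np.full(c.shape, float(constant_ph))
    return np.clip(PH_INTERCEPT + PH_SLOPE * np.maximum(c, 0.0),
                   PH_MIN, PH_MAX)


@dataclass
class MetabolicParams:
    """Regional cell densities plus the rate-law configuration."""

    rho_cell: dict[str, float]          # region -> 1e6 cells mm^-3
    activity: float = METABOLIC_ACTIVITY
    constant_ph: Optional[float] = None

    @classmethod
    def from_parameter_set(cls, params: ParameterSet) -> "MetabolicParams":
        return cls(rho_cell={r: p.rho_cell
                             for r, p in params.regions.items()},
                   constant_ph=params.constant_ph)


def metabolic_increment(oxygen: np.ndarray, lactate: np.ndarray,
                        rho_cell: np.ndarray, params: MetabolicParams):
    """One sequential metabolic update on nodal fields.

    Order mirrors the staggered transport routine: the oxygen step consumes
    using the *previous* pH (from the incoming lactate field), the lactate
    step produces using the *new* oxygen field, and the returned pH (from
    the incoming lactate) is what the next oxygen step will see.

    Returns ``(oxygen_sink, lactate_source, pH)`` with rates per hour;
    the sink is positive (consumption).
    """
    pH = ph_from_lactate(lactate, params.constant_ph)
    o2_sink = oxygen_consumption(oxygen, pH, rho_cell, params.activity)
    lac_source = lactate_production(oxygen, pH, rho_cell, params.activity)
    return o2_sink, lac_source, pH
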