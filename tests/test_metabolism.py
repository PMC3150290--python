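"""Metabolic rate laws against independent arithmetic oracles."""

import numpy as np
import pytest

import discflux.metabolism as met
from discflux.units import OXYGEN_SOLUBILITY


def _oracle_oxygen(pO2, pH, rho, activity=1.0):
    """Independent re-derivation from the published constants."""
    ph_f = pH - met.PH_OFFSET
    nmol_rate = met.OXY_VMAX * pO2 * ph_f / (met.OXY_KM * ph_f + pO2)
    return activity * rho * nmol_rate / OXYGEN_SOLUBILITY


def _oracle_lactate(pO2, pH, rho, activity=1.0):
    return activity * rho * np.exp(met.LAC_A + met.LAC_PH * pH
                                   + met.LAC_O1 * pO2
                                   + met.LAC_O2 * pO2 ** 2)


def test_zero_cells_zero_rates():
    assert met.oxygen_consumption(5.8, 7.1, 0.0) == 0.0
    assert met.lactate_production(5.8, 7.1, 0.0) == 0.0


def test_no_oxygen_no_consumption():
    assert met.oxygen_consumption(0.0, 7.1, 0.032) == 0.0


def test_oxygen_consumption_matches_oracle():
    got = met.oxygen_consumption(5.8, 7.1, 0.032)
    assert got == pytest.approx(_oracle_oxygen(5.8, 7.1, 0.032), rel=1e-12)


def test_oxygen_consumption_scales_linearly_with_density():
    r1 = met.oxygen_consumption(3.0, 7.0, 0.01)
    r2 = met.oxygen_consumption(3.0, 7.0, 0.02)
    assert r2 == pytest.approx(2.0 * r1, rel=1e-12)


def test_lactate_production_matches_oracle():
    got = met.lactate_production(5.1, 7.1, 0.02)
    assert got == pytest.approx(_oracle_lactate(5.1, 7.1, 0.02), rel=1e-12)


def test_lactate_production_decreases_with_oxygen():
    assert met.lactate_production(1.0, 7.1, 0.032) > \
        met.lactate_production(5.0, 7.1, 0.032)


def test_rates_nonnegative_over_physiological_range():
    pO2 = np.linspace(0.0, 5.8, 30)
    pH = np.linspace(6.0, 7.5, 30)
    P, H = np.meshgrid(pO2, pH)
    assert np.all(met.oxygen_consumption(P, H, 0.063) >= 0.0)
    assert np.all(met.lactate_production(P, H, 0.063) >= 0.0)


def test_out_of_range_warns_but_returns():
    with pytest.warns(UserWarning):
        val = met.oxygen_consumption(9.0, 7.1, 0.032)
    assert val > 0.0


def test_ph_constant_override():
    assert met.ph_from_lactate(3.0, constant_ph=7.1) == 7.1
    assert met.ph_from_lactate(0.0, constant_ph=7.1) == 7.1


def test_ph_monotone_nonincreasing_in_lactate():
    c = np.linspace(0.0, 10.0, 50)
    ph = met.ph_from_lactate(c)
    assert np.all(np.diff(ph) <= 1e-12)


def test_ph_at_boundary_lactate_matches_oracle():
    expected = np.clip(met.PH_INTERCEPT + met.PH_SLOPE * 0.9,
                       met.PH_MIN, met.PH_MAX)
    assert met.ph_from_lactate(0.9) == pytest.approx(expected, rel=1e-12)


def test_consumption_coeff_linearisation_consistent():
    """coeff * pO2 equals the nonlinear rate at the linearisation point."""
    pO2, pH, rho = 2.5, 7.2, 0.032
    k = met.oxygen_consumption_coeff(pO2, pH, rho, activity=0.05)
    rate = met.oxygen_consumption(pO2, pH, rho, activity=0.05)
    assert k * pO2 == pytest.approx(rate, rel=1e-12)


def test_metabolic_increment_sequential_fields():
    rho = np.full(5, 0.032)
    oxy = np.full(5, 3.0)
    lac = np.full(5, 1.5)
    params = met.MetabolicParams(rho_cell={}, activity=0.05)
    sink, source, pH = met.metabolic_increment(oxy, lac, rho, params)
    assert np.allclose(pH, met.ph_from_lactate(1.5))
    assert np.allclose(sink, met.oxygen_consumption(3.0, pH[0], 0.032,
                                                    0.05))
    assert np.allclose(source, met.lactate_production(3.0, pH[0], 0.032,
                                                      0.05))
    # zero-cell neutrality
    sink0, source0, _ = met.metabolic_increment(oxy, lac, np.zeros(5),
                                                params)
    assert np.all(sink0 == 0.0) and np.all(source0 == 0.0)
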