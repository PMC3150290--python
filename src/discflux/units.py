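"""Unit conventions and the single conversion layer.

Mechanics works in mm-N-MPa-s (permeability mm^4 N^-1 s^-1, so Darcy flux
comes out in mm/s).  Solutes are tracked as oxygen partial pressure in kPa
and lactate concentration in nmol mm^-3 (numerically equal to mM).  Metabolic
rate laws are per hour; everything inside the solvers runs in seconds, and
hours appear only at reporting surfaces.
"""

SECONDS_PER_HOUR = 3600.0

#: Oxygen solubility in tissue water, nmol mm^-3 kPa^-1 (Henry's law, 37 C).
OXYGEN_SOLUBILITY = 1.0268e-2


def hours_to_seconds(t_h: float) -> float:
    return t_h * SECONDS_PER_HOUR


def seconds_to_hours(t_s: float) -> float:
    return t_s / SECONDS_PER_HOUR


def per_hour_to_per_second(rate: float) -> float:
    return rate / SECONDS_PER_HOUR
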