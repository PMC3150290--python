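"""Material, transport and metabolic parameter sets for the disc model.

Holds the per-region poromechanical and transport properties of the healthy
and degenerated human L4-L5 disc, plus the one-at-a-time sensitivity variants
(porosity, cell density, pH, endplate permeability, solid-phase stiffness,
swelling pressure, endplate stiffness).  Regions are labelled
``NP`` (nucleus pulposus), ``AFI``/``AFO`` (inner/outer annulus fibrosus),
``CEP``/``BEP`` (cartilage/bony endplate), ``cortical`` and ``trabecular``
(vertebral bone).

Units: lengths mm, stresses MPa, permeability mm^4 N^-1 s^-1, cell density
1e6 cells mm^-3, diffusivities mm^2 s^-1, oxygen kPa, lactate nmol mm^-3.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Optional

import yaml

REGIONS = ("NP", "AFI", "AFO", "CEP", "BEP", "cortical", "trabecular")
DISC_REGIONS = ("NP", "AFI", "AFO")

#: Disc heights (mm): degenerated is the healthy height reduced by 10%.
HEALTHY_HEIGHT = 13.7
DEGENERATED_HEIGHT = 12.3


@dataclass
class RegionParameters:
    """Poromechanical/transport properties of one tissue region.

    ``M``/``L`` are the exponents of the strain-dependent permeability laws
    (``L is None`` selects the single-exponent law, both ``None`` means
    strain-independent permeability).  ``delta_pi`` is the constant osmotic
    swelling pressure (NP only).  ``k1``/``k2`` and ``fibre_angle_deg``
    parameterise the tension-only collagen-fibre term of the annulus.
    """

    phi0: float                      # initial porosity, dimensionless
    k0: float                        # initial permeability, mm^4 N^-1 s^-1
    G: float                         # shear modulus, MPa
    K: float                         # bulk modulus, MPa
    M: Optional[float] = None        # permeability exponent
    L: Optional[float] = None        # second permeability exponent (CEP)
    delta_pi: float = 0.0            # swelling pressure, MPa
    rho_cell: float = 0.0            # cell density, 1e6 cells mm^-3
    k1: Optional[float] = None       # fibre stiffness, MPa (AF only)
    k2: Optional[float] = None       # fibre exponent, dimensionless (AF only)
    fibre_angle_deg: Optional[float] = None  # from the transverse plane

    def __post_init__(self) -> None:
        if not 0.0 < self.phi0 < 1.0:
            raise ValueError(f"phi0 must lie in (0,1), got {self.phi0}")
        if self.k0 <= 0.0:
            raise ValueError(f"k0 must be positive, got {self.k0}")
        if self.G <= 0.0 or self.K <= 0.0:
            raise ValueError("G and K must be positive")
        if self.rho_cell < 0.0:
            raise ValueError("rho_cell must be non-negative")
        if self.delta_pi < 0.0:
            raise ValueError("delta_pi must be non-negative")

    @property
    def has_fibres(self) -> bool:
        return self.k1 is not None


# Fibre defaults: calibrated (scripts/calibrate_fibres.py) against the
# ~10-15% in-vivo height loss under sustained 0.5 MPa; angles follow the
# criss-cross lamellar architecture (steeper towards the nucleus).
FIBRE_K1 = 20.0      # MPa
FIBRE_K2 = 100.0
FIBRE_ANGLE_AFI = 35.0  # degrees from transverse plane
FIBRE_ANGLE_AFO = 25.0


def _healthy_regions() -> dict[str, RegionParameters]:
    return {
        "AFO": RegionParameters(phi0=0.73, k0=0.0002, M=1.18, G=0.28, K=0.37,
                                rho_cell=0.063, k1=FIBRE_K1, k2=FIBRE_K2,
                                fibre_angle_deg=FIBRE_ANGLE_AFO),
        "AFI": RegionParameters(phi0=0.78, k0=0.0002, M=1.18, G=0.28, K=0.37,
                                rho_cell=0.048, k1=FIBRE_K1, k2=FIBRE_K2,
                                fibre_angle_deg=FIBRE_ANGLE_AFI),
        "NP": RegionParameters(phi0=0.83, k0=0.0009, M=8.5, G=0.12, K=0.16,
                               delta_pi=0.15, rho_cell=0.032),
        "CEP": RegionParameters(phi0=0.8, k0=0.0025, M=4.63, L=0.08,
                                G=7.14, K=33.3),
        "BEP": RegionParameters(phi0=0.05, k0=26800.0, G=3846.0, K=8333.0),
        "cortical": RegionParameters(phi0=0.05, k0=5.0, G=3846.0, K=8333.0),
        "trabecular": RegionParameters(phi0=0.8, k0=26800.0, G=42.0, K=56.0),
    }


def _degenerated_regions() -> dict[str, RegionParameters]:
    regions = _healthy_regions()
    regions["AFO"] = dataclasses.replace(
        regions["AFO"], phi0=0.57, G=0.41, K=0.55, rho_cell=0.048)
    regions["AFI"] = dataclasses.replace(
        regions["AFI"], phi0=0.6, G=0.41, K=0.55, rho_cell=0.032)
    regions["NP"] = dataclasses.replace(
        regions["NP"], phi0=0.71, G=0.19, K=0.25, delta_pi=0.05,
        rho_cell=0.02)
    return regions


@dataclass
class ParameterSet:
    """Complete model input: per-region properties plus solute boundary data.

    ``constant_ph`` decouples oxygen consumption from lactate by pinning pH
    (``None`` keeps the lactate-coupled pH law).
    """

    name: str
    regions: dict[str, RegionParameters]
    height: float = HEALTHY_HEIGHT                  # disc height, mm
    oxygen_bc_af: float = 5.8                       # kPa at outer AF edge
    oxygen_bc_cep: float = 5.1                      # kPa at CEP interface
    lactate_bc_af: float = 0.9                      # nmol mm^-3
    lactate_bc_cep: float = 0.8                     # nmol mm^-3
    d_water_oxygen: float = 3.0e-3                  # mm^2 s^-1
    d_water_lactate: float = 1.28e-3                # mm^2 s^-1
    constant_ph: Optional[float] = None

    def __post_init__(self) -> None:
        for val in (self.oxygen_bc_af, self.oxygen_bc_cep,
                    self.lactate_bc_af, self.lactate_bc_cep):
            if val < 0.0:
                raise ValueError("boundary concentrations must be >= 0")
        missing = [r for r in REGIONS if r not in self.regions]
        if missing:
            raise ValueError(f"parameter set missing regions: {missing}")

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        d = dict(d)
        d["regions"] = {k: RegionParameters(**v)
                        for k, v in d["regions"].items()}
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ParameterSet":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh)
            except (OSError, ValueError):
                d = yaml.safe_load(io.StringIO(source))
        return cls.from_dict(d)

    # ---- comparison ----------------------------------------------------
    def diff_fields(self, other: "ParameterSet") -> dict[str, dict[str, tuple]]:
        """Region->field map of values differing from ``other``."""
        out: dict[str, dict[str, tuple]] = {}
        for region in REGIONS:
            a = dataclasses.asdict(self.regions[region])
            b = dataclasses.asdict(other.regions[region])
            diff = {k: (b[k], a[k]) for k in a if a[k] != b[k]}
            if diff:
                out[region] = diff
        for fld in ("height", "constant_ph"):
            a, b = getattr(self, fld), getattr(other, fld)
            if a != b:
                out.setdefault("_global", {})[fld] = (b, a)
        return out


def _variant(name: str, **region_updates) -> ParameterSet:
    regions = _healthy_regions()
    for region, updates in region_updates.items():
        regions[region] = dataclasses.replace(regions[region], **updates)
    return ParameterSet(name=name, regions=regions)


SENSITIVITY_VARIANTS = (
    "porosity_decrease",
    "cell_density_decrease",
    "ph_decrease",
    "cep_permeability_increase",
    "solid_stiffening",
    "np_swelling_decrease",
    "cep_stiffness_decrease",
    "bep_stiffness_decrease",
)

VARIANTS = ("healthy", "degenerated") + SENSITIVITY_VARIANTS


def load_parameter_set(variant: str = "healthy") -> ParameterSet:
    """Return the transcribed parameter set for a named model variant.

    ``healthy``/``degenerated`` are the full property sets (the degenerated
    disc also carries the 10% height reduction); the remaining names are the
    one-at-a-time sensitivity alterations, each differing from ``healthy`` in
    exactly one property group.
    """
    if variant == "healthy":
        return ParameterSet(name="healthy", regions=_healthy_regions())
    if variant == "degenerated":
        return ParameterSet(name="degenerated",
                            regions=_degenerated_regions(),
                            height=DEGENERATED_HEIGHT)
    if variant == "porosity_decrease":
        return _variant(variant, AFO={"phi0": 0.57}, AFI={"phi0": 0.6},
                        NP={"phi0": 0.71})
    if variant == "cell_density_decrease":
        return _variant(variant, AFO={"rho_cell": 0.048},
                        AFI={"rho_cell": 0.032}, NP={"rho_cell": 0.02})
    if variant == "ph_decrease":
        ps = _variant(variant)
        ps.constant_ph = 6.2
        return ps
    if variant == "cep_permeability_increase":
        return _variant(variant, CEP={"k0": 0.025})
    if variant == "solid_stiffening":
        return _variant(variant, AFO={"G": 0.41, "K": 0.55},
                        AFI={"G": 0.41, "K": 0.55},
                        NP={"G": 0.19, "K": 0.25})
    if variant == "np_swelling_decrease":
        return _variant(variant, NP={"delta_pi": 0.05})
    if variant == "cep_stiffness_decrease":
        return _variant(variant, CEP={"G": 2.14, "K": 2.53})
    if variant == "bep_stiffness_decrease":
        return _variant(variant, BEP={"G": 384.6, "K": 833.3})
    raise KeyError(f"unknown parameter variant {variant!r}; "
                   f"choose one of {VARIANTS}")
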