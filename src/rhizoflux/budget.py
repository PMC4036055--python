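"""Reactor mass balance, stoichiometric O2/N partitioning, and root-census
upscaling of radial oxygen loss to areal sediment oxygen release.

The arithmetic chain mirrors how microsensor studies extrapolate a
single-root measurement to the field: a root census (roots per 100 cm2 of
sediment, mean diameter, O2-releasing tip length) gives the active root
surface area; multiplying by the radial oxygen loss gives the areal O2
release; a nitrification stoichiometry (default 1.5 mol O2 per mol NH4+,
ammonia oxidation to nitrite) splits the oxygen budget; and the ratio of
NO3- production to NH4+ consumption measures how much oxidised nitrogen
actually accumulates rather than being taken up or denitrified.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .exceptions import ProfileValidationError

__all__ = [
    "RootCensus",
    "ReactorBalance",
    "BudgetResult",
    "reactor_mass_balance",
    "active_root_area",
    "areal_o2_release",
    "to_grams_per_m2_day",
    "grams_per_m2_day_to_areal",
    "ammonia_oxidation_o2_fraction",
    "nitrate_yield_fraction",
    "oxygen_budget",
]

#: molar mass of O2, g/mol
O2_MOLAR_MASS = 32.00

#: default ammonia-oxidation stoichiometry, mol O2 per mol NH4+
#: (NH4+ + 1.5 O2 -> NO2- + H2O + 2 H+)
DEFAULT_O2_PER_NH4 = 1.5


@dataclass(frozen=True)
class RootCensus:
    """Field root statistics per 100 cm2 of sediment surface."""

    roots_per_100cm2: float
    mean_diameter_mm: float
    active_tip_length_mm: float

    def __post_init__(self):
        if min(self.roots_per_100cm2, self.mean_diameter_mm, self.active_tip_length_mm) < 0:
            raise ProfileValidationError("census fields must be >= 0")
        if self.roots_per_100cm2 <= 0 or self.mean_diameter_mm <= 0:
            raise ProfileValidationError("root count and diameter must be > 0")


@dataclass(frozen=True)
class ReactorBalance:
    """Influent/effluent mass balance of a flow-through sediment reactor."""

    solute: str
    c_in_uM: float
    c_out_uM: float
    flow_L_h: float
    area_cm2: float

    @property
    def rate(self) -> float:
        return reactor_mass_balance(self.c_in_uM, self.c_out_uM, self.flow_L_h, self.area_cm2)


@dataclass(frozen=True)
class BudgetResult:
    """Areal O2 release and its stoichiometric partition.

    All per-sediment-area quantities refer to 100 cm2 of sediment
    surface; fractions are dimensionless with > 1 flagged as
    stoichiometrically impossible.
    """

    active_root_area_cm2: float
    areal_o2_release_umol_per_100cm2_h: float
    o2_release_g_m2_d: float
    o2_fraction_ammonia_oxidation: float | None = None
    no3_yield_fraction: float | None = None
    stoichiometry_impossible: bool = False


def reactor_mass_balance(
    c_in_uM: float, c_out_uM: float, flow_L_h: float, area_cm2: float
) -> float:
    """Net areal consumption rate from reactor influent/effluent.

    rate = (c_in - c_out) * flow / area, in umol cm-2 h-1 (uM == umol/L
    cancels the litre); negative when the reactor is a net producer.
    """
    if flow_L_h <= 0 or area_cm2 <= 0:
        raise ProfileValidationError("flow and area must be > 0")
    if min(c_in_uM, c_out_uM) < 0:
        raise ProfileValidationError("concentrations must be >= 0")
    return (c_in_uM - c_out_uM) * flow_L_h / area_cm2


def active_root_area(census: RootCensus) -> float:
    """O2-releasing root surface area, cm2 per 100 cm2 of sediment.

    Root tips are modelled as open cylinders (lateral area only):
    area = pi * diameter * active_length * count.  A zero active length
    is degenerate (no releasing surface) and triggers a warning.
    """
    if census.active_tip_length_mm == 0:
        warnings.warn("active tip length is zero: no O2-releasing surface")
    return (
        math.pi
        * (census.mean_diameter_mm / 10.0)
        * (census.active_tip_length_mm / 10.0)
        * census.roots_per_100cm2
    )


def areal_o2_release(rol: float, active_area_cm2: float) -> float:
    """O2 released per 100 cm2 sediment per hour: rol * active_area.

    ``rol`` in umol O2 cm-2 root surface h-1 (>= 0), ``active_area_cm2``
    per 100 cm2 of sediment.
    """
    if rol < 0:
        raise ProfileValidationError("ROL must be >= 0 for an O2-releasing root")
    return rol * active_area_cm2


#: umol O2 per 100 cm2 h-1  ->  g O2 m-2 d-1
_G_M2_D_PER_AREAL = 100.0 * 24.0 * O2_MOLAR_MASS * 1e-6


def to_grams_per_m2_day(areal_umol_per_100cm2_h: float) -> float:
    """Convert umol O2 per 100 cm2 h-1 to g O2 m-2 d-1.

    Factors: x100 (100 cm2 -> m2), x24 (h -> d), x32e-6 (umol O2 -> g).
    """
    if areal_umol_per_100cm2_h < 0:
        raise ProfileValidationError("areal release must be >= 0")
    return areal_umol_per_100cm2_h * _G_M2_D_PER_AREAL


def grams_per_m2_day_to_areal(g_m2_d: float) -> float:
    """Inverse of :func:`to_grams_per_m2_day`."""
    return g_m2_d / _G_M2_D_PER_AREAL


def ammonia_oxidation_o2_fraction(
    nh4_rate: float, o2_rate: float, stoich: float = DEFAULT_O2_PER_NH4
) -> float:
    """Fraction of the O2 consumption spent on ammonia oxidation.

    fraction = stoich * nh4_rate / o2_rate, with both rates areal
    (umol cm-2 h-1) over the same interface.  A fraction above 1 means
    the stated rates cannot both be right under the stoichiometry and is
    flagged with a warning.
    """
    if o2_rate <= 0:
        raise ProfileValidationError("O2 consumption rate must be > 0")
    if nh4_rate < 0:
        raise ProfileValidationError("NH4+ consumption rate must be >= 0")
    frac = stoich * nh4_rate / o2_rate
    if frac > 1:
        warnings.warn(
            f"O2 fraction {frac:.2f} > 1: ammonia oxidation would need more "
            f"O2 than is consumed (stoichiometrically impossible)"
        )
    return frac


def nitrate_yield_fraction(no3_production: float, nh4_consumption: float) -> float:
    """NO3- production as a fraction of NH4+ consumption.

    Complete nitrification with no plant uptake or denitrification gives
    1; lower values mean NO2-/NO3- is intercepted along the way.
    """
    if nh4_consumption <= 0:
        raise ProfileValidationError("NH4+ consumption must be > 0")
    return no3_production / nh4_consumption


def oxygen_budget(
    census: RootCensus,
    rol: float,
    nh4_rate: float | None = None,
    o2_rate: float | None = None,
    no3_production: float | None = None,
    stoich: float = DEFAULT_O2_PER_NH4,
) -> BudgetResult:
    """Full budget chain: census -> active area -> areal release -> fractions.

    ``nh4_rate``/``o2_rate``/``no3_production`` are areal rates at the
    interface of interest (umol cm-2 h-1); the corresponding fractions
    are left as None when the inputs are not supplied.  Deterministic:
    identical inputs give identical results.
    """
    area = active_root_area(census)
    release = areal_o2_release(rol, area)
    frac = None
    impossible = False
    if nh4_rate is not None and o2_rate is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frac = ammonia_oxidation_o2_fraction(nh4_rate, o2_rate, stoich)
        impossible = frac > 1
    yield_frac = None
    if no3_production is not None and nh4_rate is not None:
        yield_frac = nitrate_yield_fraction(no3_production, nh4_rate)
    return BudgetResult(
        active_root_area_cm2=area,
        areal_o2_release_umol_per_100cm2_h=release,
        o2_release_g_m2_d=to_grams_per_m2_day(release),
        o2_fraction_ammonia_oxidation=frac,
        no3_yield_fraction=yield_frac,
        stoichiometry_impossible=impossible,
    )
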