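"""Domain types and I/O for 1-D microsensor concentration profiles.

A microprofile is a steady-state transect of O2, NH4+, NO3- or pH measured
with a needle microsensor at ~50 um steps, starting at a named reference
interface (the sediment surface for vertical profiles, the root surface for
radial ones) and moving away from it.

Internal units are fixed once and used everywhere:

========================  =======================
quantity                  unit
========================  =======================
position                  cm from the reference
solute concentration      umol cm-3  (== mM)
diffusion coefficient     cm2 s-1
volumetric rate           umol cm-3 h-1 (consumption positive)
interface flux            umol cm-2 h-1
========================  =======================

Files at the boundary use the field-typical um / uM columns; conversion
happens on read/write so that flux arithmetic never mixes unit systems.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    ProfileFormatError,
    ProfileValidationError,
    UnderDeterminedError,
    UnitError,
)

__all__ = [
    "Analyte",
    "Geometry",
    "MicroProfile",
    "DiffusionCoefficients",
    "BCKind",
    "BoundaryCondition",
    "BoundaryConditions",
    "ZoneModel",
    "convert_concentration",
    "read_profile",
    "write_profile",
]


class Analyte(str, enum.Enum):
    """Measured species. pH is carried along but is not a solute."""

    O2 = "O2"
    NH4 = "NH4"
    NO3 = "NO3"
    PH = "pH"

    @property
    def is_solute(self) -> bool:
        return self is not Analyte.PH


class Geometry(str, enum.Enum):
    """Orientation of the transect relative to the root/sediment system."""

    VERTICAL_DEPTH = "vertical_depth"        # downward from the sediment surface
    RADIAL_FROM_ROOT = "radial_from_root"    # outward from the root surface
    AXIAL_ALONG_ROOT = "axial_along_root"    # along the root from the apex


# --------------------------------------------------------------------------
# concentration units

# scale factors to the internal unit, umol cm-3 (= mM = mmol L-1)
_TO_UMOL_CM3 = {
    "uM": 1e-3,
    "mM": 1.0,
    "umol_cm3": 1.0,
    "nmol_cm3": 1e-3,
}

_UNIT_ALIASES = {
    "μM": "uM",
    "µM": "uM",
    "umol/cm3": "umol_cm3",
    "μmol cm-3": "umol_cm3",
    "nmol/cm3": "nmol_cm3",
}


def _norm_unit(unit: str) -> str:
    unit = _UNIT_ALIASES.get(unit, unit)
    if unit not in _TO_UMOL_CM3:
        raise UnitError(
            f"unknown concentration unit {unit!r}; "
            f"known: {sorted(_TO_UMOL_CM3)}"
        )
    return unit


def convert_concentration(value, from_unit: str, to_unit: str):
    """Convert a concentration between {uM, mM, umol_cm3, nmol_cm3}.

    Exact scalar rescaling; works elementwise on arrays.

    >>> convert_concentration(55.0, "uM", "umol_cm3")
    0.055
    """
    f = _TO_UMOL_CM3[_norm_unit(from_unit)]
    t = _TO_UMOL_CM3[_norm_unit(to_unit)]
    return value * (f / t)


# --------------------------------------------------------------------------
# core types


@dataclass(frozen=True)
class MicroProfile:
    """One steady-state 1-D concentration transect.

    Parameters
    ----------
    analyte : Analyte
        Measured species; pH profiles carry pH units in ``concentrations``.
    positions : ndarray
        Distances from the reference interface, cm, strictly increasing,
        ``positions[0]`` at the interface itself.
    concentrations : ndarray
        Solute concentrations in umol cm-3 (pH values for pH profiles).
    temperature_c : float
        Measurement temperature; diffusion coefficients are matched to it
        by the caller (defaults are 20 C values).
    geometry : Geometry
        Which interface position 0 refers to and which way it points.
    apex_distance_mm : float or None
        Axial position of the transect along the root, mm from the apex.
    """

    analyte: Analyte
    positions: np.ndarray
    concentrations: np.ndarray
    temperature_c: float = 20.0
    geometry: Geometry = Geometry.VERTICAL_DEPTH
    apex_distance_mm: float | None = None

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "analyte", Analyte(self.analyte))
        object.__setattr__(self, "geometry", Geometry(self.geometry))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "concentrations", conc)
        if pos.ndim != 1 or conc.ndim != 1:
            raise ProfileValidationError("positions and concentrations must be 1-D")
        if pos.size != conc.size:
            raise ProfileValidationError(
                f"length mismatch: {pos.size} positions, {conc.size} concentrations"
            )
        if pos.size < 3:
            raise ProfileValidationError("a profile needs at least 3 points")
        if not np.all(np.isfinite(pos)) or not np.all(np.isfinite(conc)):
            raise ProfileValidationError("non-finite values in profile")
        if np.any(np.diff(pos) <= 0):
            raise ProfileValidationError("positions must be strictly increasing")
        if self.analyte.is_solute and np.any(conc < 0):
            raise ProfileValidationError("solute concentrations must be >= 0")

    # convenience views ----------------------------------------------------

    @property
    def n(self) -> int:
        return self.positions.size

    @property
    def domain_length(self) -> float:
        """Extent of the transect, cm."""
        return float(self.positions[-1] - self.positions[0])

    def spacing(self, rtol: float = 1e-6) -> float:
        """Grid step in cm; raises if the grid is not uniform.

        The solver and the zone inversion require a uniform grid (the
        instrument steps at a fixed 50 um in practice).
        """
        d = np.diff(self.positions)
        h = float(d.mean())
        if np.any(np.abs(d - h) > rtol * h):
            raise ProfileValidationError("profile grid is not uniform")
        return h

    def with_concentrations(self, conc) -> "MicroProfile":
        return replace(self, concentrations=np.asarray(conc, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        col = "value_pH" if self.analyte is Analyte.PH else "concentration_uM"
        vals = (
            self.concentrations
            if self.analyte is Analyte.PH
            else convert_concentration(self.concentrations, "umol_cm3", "uM")
        )
        return pd.DataFrame({"position_um": self.positions * 1e4, col: vals})


@dataclass(frozen=True)
class DiffusionCoefficients:
    """Molecular diffusion coefficients, cm2 s-1, at a reference temperature.

    Defaults are free-water values at 20 C: 2.06e-5 (O2), 1.93e-5 (NH4+),
    1.89e-5 (NO3-). No porosity/tortuosity correction is folded in here;
    porosity enters the flux formulas explicitly.
    """

    o2: float = 2.06e-5
    nh4: float = 1.93e-5
    no3: float = 1.89e-5
    reference_temperature_c: float = 20.0

    def __post_init__(self):
        for name in ("o2", "nh4", "no3"):
            if getattr(self, name) <= 0:
                raise ProfileValidationError(f"diffusion coefficient {name} must be > 0")

    def get(self, analyte: Analyte) -> float:
        analyte = Analyte(analyte)
        if analyte is Analyte.PH:
            raise UnitError("pH has no diffusion coefficient")
        return {Analyte.O2: self.o2, Analyte.NH4: self.nh4, Analyte.NO3: self.no3}[analyte]


#: package-wide default 20 C coefficients
DEFAULT_D = DiffusionCoefficients()


class BCKind(str, enum.Enum):
    FIXED_CONCENTRATION = "fixed_concentration"
    FIXED_FLUX = "fixed_flux"


@dataclass(frozen=True)
class BoundaryCondition:
    """One end condition: a concentration (umol cm-3) or a flux
    (umol cm-2 h-1, positive toward increasing position)."""

    kind: BCKind
    value: float

    def __post_init__(self):
        object.__setattr__(self, "kind", BCKind(self.kind))


@dataclass(frozen=True)
class BoundaryConditions:
    """Conditions at the two ends of the domain (lower = position 0)."""

    lower: BoundaryCondition
    upper: BoundaryCondition

    def __post_init__(self):
        if (
            self.lower.kind is not BCKind.FIXED_CONCENTRATION
            and self.upper.kind is not BCKind.FIXED_CONCENTRATION
        ):
            raise UnderDeterminedError(
                "at least one end must fix the concentration; two flux "
                "conditions leave the level undetermined"
            )

    @classmethod
    def dirichlet(cls, c0: float, c1: float) -> "BoundaryConditions":
        return cls(
            BoundaryCondition(BCKind.FIXED_CONCENTRATION, c0),
            BoundaryCondition(BCKind.FIXED_CONCENTRATION, c1),
        )


@dataclass(frozen=True)
class ZoneModel:
    """Piecewise-constant net volumetric rate structure.

    ``boundaries`` (cm, length k+1, strictly increasing) span the profile
    domain; ``rates`` (umol cm-3 h-1, length k) follow the microsensor
    convention: consumption positive, production negative.
    """

    boundaries: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "rates", r)
        if b.ndim != 1 or r.ndim != 1 or b.size != r.size + 1:
            raise ProfileValidationError(
                "need k+1 boundaries for k zone rates"
            )
        if r.size < 1:
            raise ProfileValidationError("at least one zone required")
        if np.any(np.diff(b) <= 0):
            raise ProfileValidationError("zone boundaries must be strictly increasing")

    @property
    def k(self) -> int:
        return self.rates.size

    @property
    def thicknesses(self) -> np.ndarray:
        return np.diff(self.boundaries)

    def rate_at(self, z) -> np.ndarray:
        """Rate at position(s) z; right-inclusive at the top boundary."""
        z = np.asarray(z, dtype=float)
        idx = np.clip(np.searchsorted(self.boundaries, z, side="right") - 1, 0, self.k - 1)
        return self.rates[idx]

    def integral(self, z0: float, z1: float) -> float:
        """Exact integral of the rate field over [z0, z1], umol cm-2 h-1."""
        lo = np.maximum(self.boundaries[:-1], z0)
        hi = np.minimum(self.boundaries[1:], z1)
        return float(np.sum(self.rates * np.clip(hi - lo, 0.0, None)))

    def depth_integrated(self) -> float:
        """Total areal rate, sum(R_i * h_i), umol cm-2 h-1."""
        return float(np.sum(self.rates * self.thicknesses))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_start_cm": self.boundaries[:-1],
                "z_end_cm": self.boundaries[1:],
                "rate_umol_cm3_h": self.rates,
            }
        )


# --------------------------------------------------------------------------
# CSV I/O
#
# Fixed dialect: UTF-8, comma separated, dot decimal, required header with
# position_um and either concentration_uM or value_pH. Metadata travels in
# leading '# key: value' comment lines so a profile round-trips with its
# context intact.

_META_KEYS = ("analyte", "geometry", "temperature_c", "apex_distance_mm")


def write_profile(profile: MicroProfile, path) -> None:
    """Write a profile as CSV (positions in um, concentrations in uM).

    Values are printed with 17 significant digits, so
    ``read_profile(write_profile(p)) == p`` to better than 1e-12 relative.
    """
    path = Path(path)
    frame = profile.to_frame()
    lines = ["# rhizoflux microprofile"]
    lines.append(f"# analyte: {profile.analyte.value}")
    lines.append(f"# geometry: {profile.geometry.value}")
    lines.append(f"# temperature_c: {profile.temperature_c!r}")
    if profile.apex_distance_mm is not None:
        lines.append(f"# apex_distance_mm: {profile.apex_distance_mm!r}")
    body = frame.to_csv(index=False, float_format="%.17g")
    path.write_text("\n".join(lines) + "\n" + body, encoding="utf-8")


def _parse_meta(path: Path) -> dict:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            text = line.lstrip("#").strip()
            if ":" in text:
                key, _, val = text.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_profile(path, dialect: dict | None = None) -> MicroProfile:
    """Read a microprofile CSV into internal units.

    Parameters
    ----------
    path : path-like
        CSV with header columns ``position_um`` and ``concentration_uM``
        (or ``value_pH`` for pH transects); optional ``# key: value``
        metadata lines on top.
    dialect : dict, optional
        Overrides for metadata not present in the file: keys ``analyte``,
        ``geometry``, ``temperature_c``, ``apex_distance_mm``, and
        ``delimiter``.

    Returns
    -------
    MicroProfile
        Positions in cm, solute concentrations in umol cm-3, validated.
    """
    path = Path(path)
    dialect = dict(dialect or {})
    meta = _parse_meta(path)
    try:
        frame = pd.read_csv(path, comment="#", sep=dialect.get("delimiter", ","))
    except Exception as exc:  # malformed CSV
        raise ProfileFormatError(f"cannot parse {path}: {exc}") from exc

    if "position_um" not in frame.columns:
        raise ProfileFormatError(f"{path}: missing required column 'position_um'")
    if "value_pH" in frame.columns:
        analyte = Analyte.PH
        values = frame["value_pH"].to_numpy(dtype=float)
    elif "concentration_uM" in frame.columns:
        analyte = Analyte(dialect.get("analyte", meta.get("analyte", "O2")))
        values = convert_concentration(
            frame["concentration_uM"].to_numpy(dtype=float), "uM", "umol_cm3"
        )
    else:
        raise ProfileFormatError(
            f"{path}: need a 'concentration_uM' or 'value_pH' column"
        )
    if analyte is Analyte.PH and "concentration_uM" in frame.columns:
        raise ProfileFormatError(f"{path}: both value_pH and concentration_uM present")

    apex = dialect.get("apex_distance_mm", meta.get("apex_distance_mm"))
    return MicroProfile(
        analyte=analyte,
        positions=frame["position_um"].to_numpy(dtype=float) * 1e-4,
        concentrations=values,
        temperature_c=float(dialect.get("temperature_c", meta.get("temperature_c", 20.0))),
        geometry=Geometry(
            dialect.get("geometry", meta.get("geometry", Geometry.VERTICAL_DEPTH))
        ),
        apex_distance_mm=None if apex is None else float(apex),
    )
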