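"""qPCR standard-curve calibration and absolute copy-number quantification.

A dilution series of known template (copies per well) against measured
quantification cycles Cq calibrates the assay:

    Cq = intercept + S * log10(copies),      S < 0

with amplification efficiency  eps = 10**(-1/S) - 1  (S = -3.32 is
perfect doubling, eps = 1).  Unknowns are read back through the inverse,
copies = 10**((Cq - intercept)/S), and compared against per-assay
detection limits; below-limit samples carry the limit, never zero.

Defaults cover three nitrifier 16S rRNA gene assays (betaproteobacterial
AOB, Nitrospira-like NOB, Nitrobacter-like NOB) with per-well detection
limits of 27, 160 and 54 copies.  Per-volume or per-mass conversion
factors depend on elution volume, template volume per well and sample
mass, so they are always explicit caller-supplied configuration.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InvalidAssayError, UnknownAssayError

__all__ = [
    "Assay",
    "StandardCurve",
    "StandardCurveModel",
    "QuantResult",
    "fit_standard_curve",
    "efficiency_from_slope",
    "slope_from_efficiency",
    "predict_cq",
    "quantify",
    "apply_detection_limit",
    "copies_to_cells",
    "DEFAULT_DETECTION_LIMITS",
]


class Assay(str, enum.Enum):
    AOB = "AOB"
    NITROSPIRA = "Nitrospira"
    NITROBACTER = "Nitrobacter"


#: per-well detection limits (lowest reliably quantified standard), copies
DEFAULT_DETECTION_LIMITS = {
    Assay.AOB: 27.0,
    Assay.NITROSPIRA: 160.0,
    Assay.NITROBACTER: 54.0,
}


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency from a standard-curve slope.

    eps = 10**(-1/S) - 1;  requires S < 0 (Cq falls as template rises).
    """
    if slope >= 0:
        raise InvalidAssayError(f"standard-curve slope must be < 0, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


def slope_from_efficiency(efficiency: float) -> float:
    """Inverse of :func:`efficiency_from_slope`: S = -1/log10(1 + eps)."""
    if efficiency <= -1:
        raise InvalidAssayError("efficiency must be > -1")
    return -1.0 / math.log10(1.0 + efficiency)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted qPCR calibration (the Results object of StandardCurveModel)."""

    slope: float               # Cq per log10(copies)
    intercept: float           # Cq at 1 copy
    efficiency: float          # 10**(-1/slope) - 1
    r_squared: float
    slope_se: float
    intercept_se: float
    dynamic_range: tuple[float, float]  # (min, max) standard copies per well
    n_standards: int

    def predict_cq(self, copies) -> np.ndarray | float:
        """Expected Cq for a template amount (copies per well)."""
        return self.intercept + self.slope * np.log10(copies)

    def quantify(self, cq, warn_extrapolation: bool = True):
        """Copies per well from a measured Cq: 10**((Cq - intercept)/S).

        Values outside the calibrated dynamic range are still returned
        but flagged with a warning, since the line is extrapolated there.
        """
        copies = 10.0 ** ((np.asarray(cq, dtype=float) - self.intercept) / self.slope)
        lo, hi = self.dynamic_range
        if warn_extrapolation and np.any((copies < lo) | (copies > hi)):
            warnings.warn(
                "quantification outside the standard-curve dynamic range "
                f"[{lo:g}, {hi:g}] copies/well (extrapolated)"
            )
        return float(copies) if np.isscalar(cq) else copies

    def summary(self) -> str:
        return "\n".join(
            [
                "qPCR standard curve",
                "===================",
                f"Cq = {self.intercept:.3f} + {self.slope:.4f} * log10(copies)",
                f"slope SE {self.slope_se:.4f}   intercept SE {self.intercept_se:.3f}",
                f"efficiency = {self.efficiency * 100:.1f}%   r^2 = {self.r_squared:.5f}",
                f"dynamic range: {self.dynamic_range[0]:g} - "
                f"{self.dynamic_range[1]:g} copies/well ({self.n_standards} standards)",
            ]
        )


class StandardCurveModel:
    """Least-squares calibration of Cq against log10(template copies).

    Parameters
    ----------
    copies : array-like
        Template amounts of the dilution series, copies per well (> 0);
        at least 3 distinct levels.
    cq : array-like
        Measured quantification cycles, same length.
    """

    def __init__(self, copies, cq):
        self.copies = np.asarray(copies, dtype=float)
        self.cq = np.asarray(cq, dtype=float)
        if self.copies.shape != self.cq.shape or self.copies.ndim != 1:
            raise InvalidAssayError("copies and cq must be 1-D arrays of equal length")
        if np.any(self.copies <= 0):
            raise InvalidAssayError("standard copies must be > 0")
        if np.unique(self.copies).size < 3:
            raise InvalidAssayError(
                "need at least 3 distinct dilution levels to calibrate"
            )

    def fit(self) -> StandardCurve:
        x = np.log10(self.copies)
        res = stats.linregress(x, self.cq)
        if res.slope >= 0:
            raise InvalidAssayError(
                f"fitted slope {res.slope:.3f} >= 0: Cq must decrease with "
                f"template amount; assay invalid"
            )
        return StandardCurve(
            slope=float(res.slope),
            intercept=float(res.intercept),
            efficiency=efficiency_from_slope(res.slope),
            r_squared=float(res.rvalue**2),
            slope_se=float(res.stderr),
            intercept_se=float(res.intercept_stderr),
            dynamic_range=(float(self.copies.min()), float(self.copies.max())),
            n_standards=int(self.copies.size),
        )


def fit_standard_curve(standards) -> StandardCurve:
    """Fit a standard curve from (copies_per_well, Cq) pairs."""
    arr = np.asarray(list(standards), dtype=float)
    return StandardCurveModel(arr[:, 0], arr[:, 1]).fit()


def predict_cq(curve: StandardCurve, copies):
    return curve.predict_cq(copies)


def quantify(curve: StandardCurve, cq, warn_extrapolation: bool = True):
    return curve.quantify(cq, warn_extrapolation=warn_extrapolation)


@dataclass(frozen=True)
class QuantResult:
    """Per-sample absolute quantification with detection-limit handling.

    ``copies_per_well`` is the measured value; when it falls below the
    assay's limit, ``below_detection`` is set and ``detection_limit``
    carries the reporting bound (the result is never collapsed to 0).
    ``copies_per_cm3`` is present only when a conversion factor was
    supplied; ``conversion_factor`` records its provenance.
    """

    assay: Assay
    copies_per_well: float
    below_detection: bool
    detection_limit: float
    copies_per_cm3: float | None = None
    conversion_factor: float | None = None


def apply_detection_limit(
    copies_per_well: float,
    assay,
    limits: dict | None = None,
    per_cm3_factor: float | None = None,
) -> QuantResult:
    """Flag a quantification against the assay's detection limit.

    The comparison is boundary-inclusive: a value exactly at the limit is
    quantifiable, because the limit is defined as the lowest quantifiable
    standard.  ``per_cm3_factor`` (copies/cm3 per copy/well) converts to
    a per-volume number when provided; it folds in elution volume,
    template volume per well and sample size, and is deliberately never
    inferred.
    """
    try:
        assay = Assay(assay)
    except ValueError:
        raise UnknownAssayError(assay) from None
    table = DEFAULT_DETECTION_LIMITS if limits is None else limits
    if assay not in table:
        raise UnknownAssayError(assay)
    limit = float(table[assay])
    below = copies_per_well < limit
    per_cm3 = None if per_cm3_factor is None else copies_per_well * per_cm3_factor
    return QuantResult(
        assay=assay,
        copies_per_well=float(copies_per_well),
        below_detection=below,
        detection_limit=limit,
        copies_per_cm3=per_cm3,
        conversion_factor=per_cm3_factor,
    )


def copies_to_cells(copies: float, gene_copies_per_genome: float = 1.0) -> float:
    """Convert gene copies to cell numbers.

    AOB and NOB typically carry a single 16S rRNA gene copy per genome,
    so the default divisor is 1.
    """
    if gene_copies_per_genome < 1:
        raise InvalidAssayError("gene copies per genome must be >= 1")
    return copies / gene_copies_per_genome
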