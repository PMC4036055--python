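"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`RhizofluxError`, so callers can catch one type at a pipeline
boundary while still distinguishing validation, format, and numerical
failures when they need to.
"""


class RhizofluxError(Exception):
    """Base class for all rhizoflux errors."""


class ProfileValidationError(RhizofluxError, ValueError):
    """A microprofile violates a structural invariant (ordering, sign, length)."""


class ProfileFormatError(RhizofluxError, ValueError):
    """A profile file does not follow the expected CSV dialect."""


class UnitError(RhizofluxError, ValueError):
    """Unknown or unsupported concentration unit."""


class UnderDeterminedError(RhizofluxError, ValueError):
    """Boundary conditions do not pin the concentration level anywhere."""


class InfeasibleScenarioError(RhizofluxError, RuntimeError):
    """A forward scenario's rates are inconsistent with its boundary values
    (the steady-state solution goes negative)."""


class DegenerateZoneError(RhizofluxError, RuntimeError):
    """A zone layout produced a rank-deficient least-squares system."""


class UnsupportedAnalyteError(RhizofluxError, ValueError):
    """Operation not defined for this analyte (e.g. flux from a pH profile)."""


class InvalidAssayError(RhizofluxError, ValueError):
    """A qPCR standard curve is unusable (positive slope, too few levels)."""


class UnknownAssayError(RhizofluxError, KeyError):
    """Assay id without configured detection limit."""


class PipelineError(RhizofluxError, RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""
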