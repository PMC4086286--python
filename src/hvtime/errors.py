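"""Exception hierarchy for the hvtime pipeline.

Every stage raises a subclass of :class:`HvtimeError`, so callers can catch
one base type at pipeline level while tests discriminate precisely.
"""


class HvtimeError(Exception):
    """Base class for all hvtime errors."""


class FormatError(HvtimeError):
    """Malformed input file (ragged rows, non-numeric cells, bad dialect)."""


class DuplicateProbe(FormatError):
    """A probe identifier occurs more than once."""


class DegenerateDistribution(HvtimeError):
    """Input distribution is constant; no background can be fitted."""


class InsufficientData(HvtimeError):
    """Too few values, genes or arrays for the requested operation."""


class InvalidModel(HvtimeError):
    """A background model violates its invariants (e.g. sd <= 0)."""


class AlignmentFailure(HvtimeError):
    """Robust cross-array regression produced a non-positive slope."""


class InsufficientReplication(HvtimeError):
    """Residual degrees of freedom below 1."""


class ReferenceCollapse(HvtimeError):
    """Iterative reference-group trimming removed every gene."""


class ZeroVector(HvtimeError):
    """Uncentered correlation is undefined for an all-zero vector."""


class BackgroundMismatch(HvtimeError):
    """Enrichment gene list is not a subset of the declared background."""


class InvalidAbsorbance(HvtimeError):
    """Non-positive baseline absorbance in a viability ratio."""


class NoCrossing(HvtimeError):
    """Relative viability never crosses 50% in the tested dilution range."""


class ConfigError(HvtimeError):
    """Inconsistent simulation or pipeline configuration."""
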