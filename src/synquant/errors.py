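"""Exception hierarchy for synquant.

All domain-specific failures derive from :class:`SynquantError` so callers
can catch one base class at pipeline boundaries.
"""


class SynquantError(Exception):
    """Base class for all synquant errors."""


class InvalidAnnotationError(SynquantError):
    """Trace epoch annotations are missing, out of order, or out of range."""


class DegenerateTraceError(SynquantError):
    """A trace has no usable dynamic range (flat or inverted)."""


class PlacementError(SynquantError):
    """Synthetic objects could not be placed under the stated separation
    constraints (the generator never silently overlaps events)."""


class ShellWidthError(SynquantError):
    """Requested membrane shell is thinner than one pixel."""


class UndefinedFractionError(SynquantError):
    """A ratio of intensities is undefined (zero denominator)."""


class UndefinedMOCError(SynquantError):
    """Manders overlap is undefined because a channel is identically zero."""


class ResidueTableError(SynquantError):
    """Residue tables cannot be combined (no overlap, bad numbering, or a
    residue type missing from a reference table)."""


class CalibrationError(SynquantError):
    """Densitometry calibration cannot be fitted or applied."""


class SequenceError(SynquantError):
    """A protein sequence contains non-canonical residues or is empty."""


class QuenchCurveError(SynquantError):
    """A quench time course cannot be normalized or summarized."""
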