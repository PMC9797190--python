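"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`ChipdynError`
so callers can catch one type at pipeline boundaries.
"""


class ChipdynError(Exception):
    """Base class for all chipdyn errors."""


class LayoutError(ChipdynError):
    """Track/annotation does not match the genome layout (shape, chromosome set)."""


class FormatError(ChipdynError):
    """Malformed input file (bedGraph/BED/TSV)."""


class ValidationError(ChipdynError):
    """Records that parse but violate the data model; carries offending rows."""

    def __init__(self, message, offenders=None):
        super().__init__(message)
        self.offenders = list(offenders) if offenders is not None else []


class PlacementError(ChipdynError):
    """Synthetic annotation cannot be placed at the requested density."""


class DesignError(ChipdynError):
    """Sample design is inconsistent (e.g. IP sample without matched input)."""


class DegeneratePartitionError(ChipdynError):
    """A normalization partition has zero total counts in one of the samples."""


class DegenerateInputError(ChipdynError):
    """Statistically degenerate input (all-zero values, constant predictor, ...)."""
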