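"""Exception hierarchy shared across the pipeline.

Exit-code mapping for the CLI lives in :mod:`blastotrack.cli`; library code
raises these types and never calls ``sys.exit``.
"""


class BlastotrackError(Exception):
    """Base class for all package errors."""


class LineageFormatError(BlastotrackError):
    """The lineage table violates the dialect (missing column, duplicate id,
    broken predecessor link)."""


class LineageValidationError(BlastotrackError):
    """A lineage failed semantic validation and a downstream stage refused it."""


class DegenerateGeometryError(BlastotrackError):
    """A frame's nuclei are too few or coplanar for convex-hull operations."""


class CollapseNotFoundError(BlastotrackError):
    """No volume drop exceeding the threshold exists in the series."""


class StatisticsError(BlastotrackError):
    """A statistic's precondition is not met (no deaths, single embryo, ...)."""
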