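"""Exception hierarchy.

All telocomb-specific failures derive from :class:`TelocombError` so callers
can catch the package's errors without masking programming mistakes.
"""


class TelocombError(Exception):
    """Base class for all telocomb errors."""


class ConfigurationError(TelocombError, ValueError):
    """Invalid parameter value or unknown option (bad distribution family,
    non-positive scale, inconsistent thresholds, ...)."""


class PlacementError(TelocombError, ValueError):
    """A simulated fiber cannot be placed inside the image bounds."""


class DegenerateImageError(TelocombError, ValueError):
    """An image does not carry enough structure for the requested operation
    (e.g. thresholding a constant image)."""


class MeasurementError(TelocombError, ValueError):
    """An object violates the preconditions of a measurement (e.g. branched
    skeleton where an unbranched fiber is required)."""


class FormatError(TelocombError, ValueError):
    """Malformed input file or incompatible image geometry."""
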