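"""Exception hierarchy for the morphometry pipeline.

Three broad families, mirrored by the CLI's exit codes:

* :class:`ConfigError` — an invalid specification or configuration (exit 2)
* :class:`DataError` — inputs that violate a data contract (exit 3)
* anything else — internal error (exit 1)
"""


class FibmorphError(Exception):
    """Base class for all package errors."""


class ConfigError(FibmorphError):
    """Invalid configuration or specification."""


class InvalidSpecError(ConfigError):
    """A phantom or cohort specification violates its invariants."""


class DataError(FibmorphError):
    """Input data violate a pipeline contract."""


class AlignmentError(DataError):
    """Image and mask grids disagree in shape or spacing."""


class MetadataError(DataError):
    """Required metadata (e.g. pixel spacing) is missing."""


class InsufficientSlicesError(DataError):
    """Fewer usable slices than the configured central-slice count."""


class TopologyError(DataError):
    """A bone mask does not have the expected ring topology."""


class AnisotropicSpacingError(DataError):
    """Morphometry requires isotropic in-plane pixel spacing."""


class EmptyMaskError(DataError):
    """A mask passed to morphometry has no foreground pixels."""


class DegenerateSampleError(DataError):
    """A statistical sample is degenerate (e.g. zero variance, unequal means)."""


class UndefinedCorrelationError(DataError):
    """Correlation is undefined (constant input)."""


class UndefinedCVError(DataError):
    """Coefficient of variation is undefined (zero mean)."""


class ImplausibleNoiseError(ConfigError):
    """Requested noise fraction exceeds the plausible range."""


class CohortTooSmallError(ConfigError):
    """A cohort group is too small for the requested analysis."""
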