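"""Exception hierarchy for the pipeline.

All pipeline-specific failures derive from :class:`MirsigError` so callers
(and the CLI) can distinguish validation problems (exit status 2) from bugs.
"""


class MirsigError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(MirsigError):
    """An invalid parameter value; the message names the offending field."""


class FormatError(MirsigError):
    """A malformed input file (bad cell, duplicate key, missing column)."""


class NormalizationError(MirsigError):
    """Size-factor computation impossible (no feature positive in all samples)."""


class GroupingError(MirsigError):
    """A sample group required for a contrast is empty or degenerate."""


class SaturationError(MirsigError):
    """A ddPCR well with zero negative droplets: concentration not estimable."""


class EmptyWellError(MirsigError):
    """A ddPCR well with zero droplets."""


class RangeError(MirsigError):
    """A control reference range cannot be formed (fewer than two controls)."""


class DegenerateDataError(MirsigError):
    """Input without the variation a statistic requires (constant vector...)."""
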