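"""Exception hierarchy for the screen-analysis pipeline.

All pipeline stages raise subclasses of :class:`GrscreenError` so callers can
distinguish data problems (bad wells, failed controls) from programming
errors.
"""


class GrscreenError(Exception):
    """Base class for all package errors."""


class ConfigError(GrscreenError):
    """Invalid screen design, truth table or pipeline configuration."""


class ParseError(GrscreenError):
    """Malformed input file; message lists the offending rows."""


class InvalidWellError(GrscreenError):
    """A well whose baseline viability makes growth undefined (V0 <= 0)."""


class ControlQCError(GrscreenError):
    """Vehicle or positive-control wells did not behave as required."""


class DegenerateFitError(GrscreenError):
    """A dose-response fit where the outlier rule rejected every point."""
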