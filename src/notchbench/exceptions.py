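"""Exception hierarchy.

All package errors derive from :class:`NotchBenchError` so callers can catch
one base class; each subclass also derives from ``ValueError`` to behave well
with generic validation code.
"""


class NotchBenchError(ValueError):
    """Base class for all notchbench errors."""


class FormatError(NotchBenchError):
    """An input file does not have the expected structure (e.g. missing column)."""


class ParseError(NotchBenchError):
    """A cell in an input file could not be parsed."""


class ConfigurationError(NotchBenchError):
    """Invalid or incomplete configuration."""


class DesignError(NotchBenchError):
    """Invalid experimental design (mixing masses, groups)."""


class ParameterError(NotchBenchError):
    """Invalid simulation or analysis parameter."""


class NormalizationError(NotchBenchError):
    """Normalization cannot proceed (e.g. a channel has no finite values)."""


class IntegrityError(NotchBenchError):
    """Internal consistency violated (e.g. mixed-species feature)."""
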