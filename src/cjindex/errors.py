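"""Exception hierarchy for the climate-justice pipeline.

Every pipeline stage raises a subclass of :class:`CJIndexError`, so callers
(and the CLI) can distinguish user-input problems from internal bugs.
"""


class CJIndexError(Exception):
    """Base class for all package errors."""


class SchemaError(CJIndexError):
    """An indicator table does not match its indicator schema."""


class InputError(CJIndexError):
    """Invalid input data (mixed space types, non-finite values, ...)."""


class ParseError(CJIndexError):
    """A cell in a delimited input file could not be parsed."""


class ConsistencyError(CJIndexError):
    """Tables that must share unit ids (or columns) disagree."""


class ConfigError(CJIndexError):
    """Invalid configuration value (weights, class counts, presets, ...)."""


class ClassificationError(CJIndexError):
    """A score vector cannot be partitioned as requested."""
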