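"""Exception hierarchy.

Errors are split so callers (and the CLI exit codes) can distinguish bad
configuration, malformed data, and genuinely undefined numerics.
"""


class PsymapError(Exception):
    """Base class for all package errors."""


class ConfigError(PsymapError):
    """Invalid run configuration (missing path, bad constant)."""


class SchemaError(PsymapError):
    """A file does not match the documented schema (missing/duplicate column)."""


class RowError(PsymapError):
    """A data row could not be parsed; message carries the line number."""


class AlignmentError(PsymapError):
    """Data refer to parcels unknown to the atlas, or atlases differ."""


class ZeroVarianceError(PsymapError):
    """A column/parcel is constant where variance is required."""


class UndefinedCorrelationError(PsymapError):
    """Too few shared observations, or zero variance, for a Pearson r."""
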