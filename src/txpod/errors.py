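"""Exception hierarchy for the pipeline.

All input-validation failures raise a subclass of :class:`TxpodError` so
callers can distinguish bad data from programming errors.
"""


class TxpodError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(TxpodError):
    """Input table columns or keys do not match the documented schema."""


class DesignError(TxpodError):
    """Experimental design violates a requirement (e.g. too few concentrations)."""


class DataError(TxpodError):
    """A value in an input table is invalid (negative count, zero library, ...)."""


class FormatError(TxpodError):
    """A file does not parse under its declared dialect (e.g. malformed GMT line)."""


class ConfigError(TxpodError):
    """A configuration value is inconsistent or out of range."""


class ModelingError(TxpodError):
    """A dose-response fit or inversion cannot be carried out."""
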