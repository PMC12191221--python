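"""Exception hierarchy shared across the package."""


class LNRADSError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(LNRADSError):
    """Input table does not match the documented CSV schema."""


class ParseError(LNRADSError):
    """A cell could not be parsed; the message names the row and column."""


class ConfigError(LNRADSError):
    """A configuration object violates its invariants."""


class DegenerateMeasurementError(LNRADSError):
    """Morphometric input leaves a derived ratio undefined (e.g. CTD + MTD = 0)."""


class SingleClassError(LNRADSError):
    """ROC-style analysis requested on data containing only one outcome class."""


class MissingTruthError(LNRADSError):
    """An operation requiring histopathology truth received records without it."""
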