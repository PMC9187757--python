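"""Exception hierarchy shared across the package."""


class SPTError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SPTError):
    """A required column or field is missing from an input table."""


class TableParseError(SPTError):
    """A cell in an input table could not be parsed as a number."""


class DataError(SPTError):
    """Input data violates a structural constraint (e.g. duplicate frames)."""


class DomainError(SPTError):
    """An operation was called on input outside its mathematical domain."""


class FitError(SPTError):
    """A model fit could not be performed or did not converge."""


class ClassificationError(SPTError):
    """A trajectory could not be classified (e.g. NaN at a tested property)."""


class SchemaError(SPTError):
    """A serialized artifact (tree JSON, config JSON) is malformed."""
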