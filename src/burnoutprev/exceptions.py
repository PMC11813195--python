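"""Exception hierarchy shared across the package."""


class BurnoutPrevError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BurnoutPrevError):
    """A configuration object failed validation; the message names the field."""


class ValidationError(BurnoutPrevError):
    """Input data failed validation (e.g. an item value outside 0-4)."""


class DomainError(BurnoutPrevError):
    """A value lies outside the mathematical domain of an operation."""


class DegenerateOutcomeError(BurnoutPrevError):
    """An outcome vector has a single class, so a classifier cannot be fit."""


class SchemaError(BurnoutPrevError):
    """A feature table does not match the schema a model was trained on."""
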