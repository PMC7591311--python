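"""Exception hierarchy shared across the package."""


class NutrineqError(Exception):
    """Base class for all package errors."""


class ValidationError(NutrineqError):
    """A record or scalar input violates a domain invariant."""


class SchemaError(NutrineqError):
    """An input table is missing a mandatory column or uses an unknown code."""


class DegenerateDataError(NutrineqError):
    """The data carry no usable variation for the requested computation."""


class UndefinedIndexError(NutrineqError):
    """A concentration index or decomposition is undefined (zero mean / zero CI)."""


class SeparationError(NutrineqError):
    """Logistic MLE does not exist because a column perfectly separates the outcome."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"perfect separation detected on column {column!r}")


class ConfigError(NutrineqError):
    """An invalid configuration value (probability outside (0,1), unknown preset, ...)."""
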