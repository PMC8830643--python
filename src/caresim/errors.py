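"""Exception taxonomy shared across the package."""


class CaresimError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(CaresimError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class InvalidParameterError(CaresimError, ValueError):
    """A swept care parameter is structurally invalid (not merely out of range)."""


class SchemaError(CaresimError, ValueError):
    """A CSV/config file does not match the required column schema."""


class DataError(CaresimError, ValueError):
    """Input data contain non-finite or otherwise unusable values."""


class ZeroVarianceError(DataError):
    """A column is constant and cannot be z-scored."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"column {column!r} has zero variance")


class SpecError(CaresimError, ValueError):
    """A surrogate specification names an unknown method or bad hyperparameters."""


class InvalidSpaceError(CaresimError, ValueError):
    """A parameter space is degenerate (lower >= upper) or malformed."""
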