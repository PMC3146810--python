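"""Exception hierarchy shared across the package."""


class DsqmError(Exception):
    """Base class for all package errors."""


class MatrixLookupError(DsqmError, KeyError):
    """Requested a builtin matrix that is not registered."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class MatrixFormatError(DsqmError, ValueError):
    """A matrix TSV violates the documented dialect (carries a line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FbeFormatError(DsqmError, ValueError):
    """A free-binding-energy table is malformed or incomplete."""


class DegenerateScopeError(DsqmError, ValueError):
    """A normalization scope has too few binding records to define statistics."""


class ModelParseError(DsqmError, ValueError):
    """A position-model string does not conform to the model grammar."""


class ConfigurationError(DsqmError, ValueError):
    """Mutually inconsistent objects (e.g. model positions absent from matrix)."""


class TestSetError(DsqmError, ValueError):
    """A benchmark test set is invalid (unknown protein, binder too short...)."""

    __test__ = False  # exception type, not a pytest case
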