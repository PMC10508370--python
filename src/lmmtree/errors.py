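"""Exception hierarchy shared across the package."""


class LmmTreeError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(LmmTreeError, ValueError):
    """A simulation / fitting configuration violates its invariants."""


class SchemaError(LmmTreeError, KeyError):
    """A required column is missing or vectors have incompatible shapes."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class DomainError(LmmTreeError, ValueError):
    """A scalar argument lies outside the function's mathematical domain."""


class SingularDesignError(LmmTreeError, ValueError):
    """The fixed-effect design matrix is rank deficient."""

    def __init__(self, message: str, collinear: list[str] | None = None):
        super().__init__(message)
        self.collinear = collinear or []


class DegenerateGroupingError(LmmTreeError, ValueError):
    """Fewer than two grouping units: random effects are unidentifiable."""


class InvalidModeratorError(LmmTreeError, ValueError):
    """A partitioning variable is not constant within user."""


class UnsupportedModeratorError(LmmTreeError, ValueError):
    """A categorical partitioning variable with more than two levels."""


class IncompleteFitError(LmmTreeError, ValueError):
    """A fitted object lacks the pieces a downstream report needs."""


class CannotSplitError(LmmTreeError, ValueError):
    """Too few users to honour the requested data partition."""
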