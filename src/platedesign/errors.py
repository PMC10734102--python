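"""Exception hierarchy shared across the package.

Every error carries a short machine-greppable ``code`` so the CLI can emit
single-line ``code: message`` diagnostics and exit non-zero.
"""

from __future__ import annotations


class PlateDesignError(Exception):
    """Base class for all package errors."""

    code = "error"

    def __init__(self, message: str):
        super().__init__(message)
        self.message = message

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.message


class FormatError(PlateDesignError):
    """A file or table does not have the expected structure."""

    code = "format-error"


class ValidationError(PlateDesignError):
    """Input values violate a documented invariant."""

    code = "validation-error"


class CapacityError(PlateDesignError):
    """More samples than available wells / batch slots."""

    code = "capacity-error"


class UnbalancedCategoriesError(ValidationError):
    """Plain block randomization called on unequal category counts."""

    code = "unbalanced-categories"


class ConsistencyError(PlateDesignError):
    """Cross-references between design artifacts do not line up."""

    code = "consistency-error"


class SchemaError(PlateDesignError):
    """A persisted project file is malformed or has a wrong version."""

    code = "schema-error"
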