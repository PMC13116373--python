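"""Exception hierarchy for the AGCES toolkit."""

from __future__ import annotations

from .model import Violation


class AgcesError(Exception):
    """Base class for all package errors."""


class CaseValidationError(AgcesError):
    """A case record breaks one or more model invariants."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        lines = "; ".join(str(v) for v in violations)
        super().__init__(f"invalid case: {lines}")


class SchemaError(AgcesError):
    """A JSON case document does not conform to the published schema."""


class CodeParseError(AgcesError):
    """A string is not a well-formed AGCES code."""


class BatchParseError(AgcesError):
    """A CSV batch cell could not be parsed; carries row and column."""

    def __init__(self, row: int, column: str, message: str):
        self.row = row
        self.column = column
        super().__init__(f"row {row}, column {column!r}: {message}")
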