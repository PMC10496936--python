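"""Exception hierarchy shared across the package."""

from __future__ import annotations


class AmhAgeError(Exception):
    """Base class for all errors raised by amhage."""


class UsageError(AmhAgeError):
    """A function was called with arguments that violate its contract."""


class DomainError(AmhAgeError):
    """A numeric input lies outside the model's domain (e.g. AMH <= 0)."""


class CohortFormatError(AmhAgeError):
    """The cohort CSV is structurally invalid (e.g. a mandatory column is missing)."""


class CohortValidationError(AmhAgeError):
    """One or more rows violate subject-level invariants.

    Attributes
    ----------
    row_errors : list of (row_index, message)
        0-based data-row index (header excluded) paired with the violated invariant.
    """

    def __init__(self, row_errors: list[tuple[int, str]]):
        self.row_errors = list(row_errors)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.row_errors)
        super().__init__(f"{len(self.row_errors)} invalid row(s): {lines}")


class DegenerateDesignError(AmhAgeError):
    """The regression design is rank-deficient (fewer than 3 distinct AMH values)."""


class NonInvertibleModelError(AmhAgeError):
    """The fitted power model cannot be inverted (beta1 = 0)."""


class PipelineStageError(AmhAgeError):
    """A pipeline stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
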