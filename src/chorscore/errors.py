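"""Exception types shared across the package."""


class CohortValidationError(ValueError):
    """Raised when a cohort file or record fails validation.

    Carries an ``items`` list of per-field / per-row messages so callers can
    report every problem at once instead of failing on the first.
    """

    def __init__(self, message: str, items: list[str] | None = None):
        self.items = list(items or [])
        if self.items:
            message = message + "\n  - " + "\n  - ".join(self.items)
        super().__init__(message)


class ClassificationError(ValueError):
    """A response classifier cannot be applied (required input missing)."""


class ScoringError(ValueError):
    """A composite score cannot be computed (patient not evaluable)."""


class EstimationError(RuntimeError):
    """A statistical estimate is undefined on the given data."""
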