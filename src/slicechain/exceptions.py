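"""Exception hierarchy shared across the package."""


class SlicechainError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SlicechainError, ValueError):
    """Inputs violate a documented precondition (shapes, spacing, config)."""


class DegenerateInputError(SlicechainError, ValueError):
    """Input is formally valid but the operation is undefined on it
    (constant image for Otsu, zero-variance differences for a t-test)."""


class UndefinedMetricError(SlicechainError, ValueError):
    """A metric has no defined value for this mask pair (e.g. both empty).
    Callers decide the policy; the metric functions never guess."""


class GenerationError(SlicechainError, RuntimeError):
    """Phantom generation failed after the allowed number of redraws."""


class TrainingError(SlicechainError, RuntimeError):
    """Training diverged (non-finite loss)."""
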