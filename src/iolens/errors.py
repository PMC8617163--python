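"""Exception and warning hierarchy shared across the package."""


class IolensError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(IolensError, ValueError):
    """An input value violates a documented physiological or numeric range."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class SingularGeometryError(IolensError, ArithmeticError):
    """A vergence denominator is (numerically) zero — the optical geometry is degenerate."""


class NoSolutionError(IolensError, ArithmeticError):
    """A back-calculation has no root in the anatomically plausible range."""


class DataQualityError(IolensError):
    """Too large a fraction of a cohort failed a preprocessing step."""


class OptimizationError(IolensError):
    """Lens-constant optimization could not bracket a root in the published range."""


class CohortSchemaError(IolensError):
    """A cohort CSV is missing required columns or has an invalid header."""


class CohortValidationError(IolensError):
    """One or more cohort rows failed validation; carries per-row details."""

    def __init__(self, failures):
        self.failures = list(failures)  # (line_number, message) pairs
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in self.failures[:10])
        more = "" if len(self.failures) <= 10 else f" (+{len(self.failures) - 10} more)"
        super().__init__(f"{len(self.failures)} invalid row(s): {lines}{more}")


class ModelStateError(IolensError):
    """A model object was used before fitting, or loaded across incompatible versions."""


class CrossValidationError(IolensError):
    """Too many Monte-Carlo repetitions failed for the run to be trustworthy."""


class DegenerateSampleError(IolensError):
    """A statistical test received a sample it cannot handle (e.g. constant input)."""


class AmbiguousRootWarning(UserWarning):
    """Both quadratic roots of a lens-position back-calculation were anatomically plausible."""


class ClampWarning(UserWarning):
    """An input or prediction was clamped to a formula's published validity range."""
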