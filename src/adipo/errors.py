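"""Exception hierarchy for the adipo pipeline.

Validation problems (bad inputs, bad configuration) derive from
:class:`ValidationError`; failures of the computation itself (packing
saturation, non-convergence, undefined quantities) derive from
:class:`ComputationError`.  The CLI maps the former to exit code 1 and the
latter to exit code 2.
"""


class AdipoError(Exception):
    """Base class for all package errors."""


class ValidationError(AdipoError):
    """Invalid input data or configuration."""


class ComputationError(AdipoError):
    """A computation failed or is undefined for the given input."""


class PackingError(ComputationError):
    """Disc packing could not reach the requested density.

    Carries the area fraction that *was* achieved so callers can decide
    whether to retry with a looser spec.
    """

    def __init__(self, requested: float, achieved: float):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"packing saturated at adipocyte fraction {achieved:.3f} "
            f"(requested {requested:.3f})"
        )


class InfeasibleCorrelationError(ValidationError):
    """Target correlation matrix is not positive semi-definite."""


class InsufficientCellsError(ComputationError):
    """Fewer complete cells than the per-sample minimum."""

    def __init__(self, observed: int, required: int):
        self.observed = observed
        self.required = required
        super().__init__(
            f"only {observed} complete adipocytes measured; {required} required"
        )


class UndefinedIndexError(ComputationError):
    """Adipocyte index undefined (no adipocyte pixels in the mask)."""


class ImageTooSmallError(ValidationError):
    """Image area below the minimum required for a valid AI."""

    def __init__(self, area_um2: float, minimum_um2: float):
        self.area_um2 = area_um2
        self.minimum_um2 = minimum_um2
        super().__init__(
            f"image area {area_um2:.1f} um^2 is below the minimum "
            f"{minimum_um2:.4f} um^2 required for a valid AI (use force=True "
            "to override)"
        )


class SeparationError(ComputationError):
    """Complete or quasi-complete separation in a logistic fit."""


class ConvergenceError(ComputationError):
    """Logistic fit failed to converge."""
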