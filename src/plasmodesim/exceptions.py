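"""Exception types shared across the package."""


class PlasmodeSimError(Exception):
    """Base class for all package-specific errors."""


class NotPositiveDefiniteError(PlasmodeSimError):
    """A covariance/correlation matrix is not positive definite."""

    def __init__(self, message: str, min_eigenvalue: float | None = None):
        super().__init__(message)
        self.min_eigenvalue = min_eigenvalue


class FeasibilityError(PlasmodeSimError):
    """A target Pearson correlation is unattainable for a marginal pair."""

    def __init__(self, message: str, attainable: tuple[float, float] | None = None):
        super().__init__(message)
        self.attainable = attainable


class RepairToleranceError(PlasmodeSimError):
    """Repairing a latent correlation matrix perturbed it beyond tolerance."""


class EstimabilityError(PlasmodeSimError):
    """A design matrix is rank deficient (coefficients not estimable)."""


class SingularCovarianceError(PlasmodeSimError):
    """A sample covariance matrix is singular."""
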