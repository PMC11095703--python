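"""Outcome generation, least-squares estimation, and the true-MSE oracle.

The outcome-generating model (OGM) is the linear model y = X beta + eps
with X an n x (p+1) design matrix whose first column is the intercept.
All simulation methods in this package are scored against the "true"
component-wise MSE of the least-squares estimator (LSE) under a known DGP,
computed here either by brute-force squared errors or by a Rao-
Blackwellized conditional-variance average (the LSE is conditionally
unbiased given X, so its MSE reduces to sigma^2 * diag((X'X)^{-1})
averaged over X).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dgp import FeatureDGP, sample_features
from .exceptions import EstimabilityError

__all__ = [
    "ErrorSpec",
    "OutcomeModel",
    "MSEEstimate",
    "add_intercept",
    "generate_outcome",
    "fit_lse",
    "batched_lse_deviation",
    "true_mse",
]

#: Condition-number threshold above which fit_lse emits a warning.
CONDITION_WARN = 1e8


@dataclass(frozen=True)
class ErrorSpec:
    """Distribution of the regression error term.

    All families are centered and scaled so the errors have mean 0 and
    standard deviation ``sd`` exactly:

    - ``normal``: ``sd * Z``
    - ``scaled_t``: ``sd * sqrt((df-2)/df) * T_df`` (requires df > 2)
    - ``shifted_scaled_chisq``: ``(Chi2_df - df) * sd / sqrt(2 df)``
    """

    family: str = "normal"
    sd: float = 0.3
    df: int | None = None

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("error sd must be positive")
        if self.family == "scaled_t":
            if self.df is None or self.df <= 2:
                raise ValueError("scaled_t requires df > 2 for a finite variance")
        elif self.family == "shifted_scaled_chisq":
            if self.df is None or self.df < 1:
                raise ValueError("shifted_scaled_chisq requires df >= 1")
        elif self.family != "normal":
            raise ValueError(f"unknown error family {self.family!r}")

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.family == "normal":
            return self.sd * rng.standard_normal(size)
        if self.family == "scaled_t":
            scale = self.sd * math.sqrt((self.df - 2) / self.df)
            return scale * rng.standard_t(self.df, size)
        # shifted_scaled_chisq
        scale = self.sd / math.sqrt(2 * self.df)
        return (rng.chisquare(self.df, size) - self.df) * scale


@dataclass(frozen=True)
class OutcomeModel:
    """Coefficient vector (intercept first) plus an error distribution."""

    beta: np.ndarray
    error: ErrorSpec = field(default_factory=ErrorSpec)

    def __post_init__(self):
        object.__setattr__(self, "beta", np.asarray(self.beta, float))

    @property
    def p(self) -> int:
        return len(self.beta) - 1

    @classmethod
    def unit(cls, p: int, error: ErrorSpec | None = None) -> "OutcomeModel":
        """The study default: beta = (1, ..., 1) of length p+1."""
        return cls(beta=np.ones(p + 1), error=error or ErrorSpec())


@dataclass(frozen=True)
class MSEEstimate:
    """Component-wise MSE vector (length p+1, intercept first)."""

    values: np.ndarray
    n_models: int
    source: str

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if np.any(v < 0):
            raise ValueError("MSE values must be nonnegative")
        object.__setattr__(self, "values", v)


def add_intercept(features: np.ndarray) -> np.ndarray:
    """Prepend the all-ones intercept column (works on batches too)."""
    ones = np.ones(features.shape[:-1] + (1,))
    return np.concatenate([ones, features], axis=-1)


def generate_outcome(
    design: np.ndarray, model: OutcomeModel, rng: np.random.Generator
) -> np.ndarray:
    """y = X beta + eps with eps i.i.d. from the model's error spec."""
    if design.shape[-1] != len(model.beta):
        raise ValueError(
            f"design has {design.shape[-1]} columns but beta has length {len(model.beta)}"
        )
    return design @ model.beta + model.error.draw(rng, design.shape[:-1])


def fit_lse(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares fit via QR; raises EstimabilityError if rank deficient."""
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    if diag.min() <= 1e-12 * max(diag.max(), 1.0):
        raise EstimabilityError("design matrix is rank deficient")
    cond = diag.max() / diag.min()
    if cond > CONDITION_WARN:
        warnings.warn(
            f"design matrix badly conditioned (condition estimate {cond:.2e})",
            stacklevel=2,
        )
    return np.linalg.solve(r, q.T @ y)


def batched_lse_deviation(designs: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """LSE deviations beta_hat - beta_a for a batch of datasets.

    By linearity of least squares, beta_hat - beta_a = (X'X)^{-1} X' eps,
    which depends on the noise but not on the assumed coefficients.
    Computing the deviation directly keeps MSE estimates bitwise invariant
    under coefficient misspecification with common random numbers.

    ``designs``: (B, n, p+1); ``eps``: (B, n).  Returns (B, p+1).
    """
    q, r = np.linalg.qr(designs)
    diag = np.abs(np.diagonal(r, axis1=-2, axis2=-1))
    bad = diag.min(axis=-1) <= 1e-12 * np.maximum(diag.max(axis=-1), 1.0)
    if np.any(bad):
        raise EstimabilityError(
            f"{int(bad.sum())} of {len(bad)} generated datasets are rank deficient"
        )
    rhs = np.einsum("bnk,bn->bk", q, eps)
    return np.linalg.solve(r, rhs[..., None])[..., 0]


def true_mse(
    dgp: FeatureDGP,
    model: OutcomeModel,
    n: int,
    reps: int,
    rng: np.random.Generator,
    method: str = "conditional_variance",
    chunk: int = 2000,
) -> MSEEstimate:
    """Monte-Carlo oracle for the component-wise MSE of the LSE.

    ``conditional_variance`` averages sigma^2 * diag((X'X)^{-1}) over X
    draws only (exact in eps; much lower variance).  ``squared_error``
    replicates the naive definition: draw X and eps, fit, and average the
    squared coefficient deviations.  Both target the same estimand.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    if n <= dgp.p + 1:
        raise ValueError("need n > p + 1 for a finite LSE variance")
    if method not in ("conditional_variance", "squared_error"):
        raise ValueError(f"unknown method {method!r}")

    sigma2 = model.error.sd**2
    total = np.zeros(dgp.p + 1)
    done = 0
    rejected = 0
    eye = np.eye(dgp.p + 1)
    while done < reps:
        b = min(chunk, reps - done)
        feats = sample_features(dgp, b * n, rng).reshape(b, n, dgp.p)
        designs = add_intercept(feats)
        gram = designs.transpose(0, 2, 1) @ designs
        try:
            if method == "conditional_variance":
                inv = np.linalg.solve(gram, np.broadcast_to(eye, gram.shape))
                contrib = sigma2 * np.diagonal(inv, axis1=-2, axis2=-1)
            else:
                eps = model.error.draw(rng, (b, n))
                y = designs @ model.beta + eps
                q, r = np.linalg.qr(designs)
                rhs = np.einsum("bnk,bn->bk", q, y)
                beta_hat = np.linalg.solve(r, rhs[..., None])[..., 0]
                contrib = (beta_hat - model.beta) ** 2
        except np.linalg.LinAlgError:
            rejected += b
            if rejected > max(1, reps // 100):
                warnings.warn(
                    f"more than 1% of oracle draws rejected as singular "
                    f"({rejected} so far)",
                    stacklevel=2,
                )
            continue
        total += contrib.sum(axis=0)
        done += b

    return MSEEstimate(values=total / reps, n_models=reps, source="true_oracle")
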