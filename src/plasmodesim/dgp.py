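"""Feature data-generating processes (DGPs).

Feature matrices are generated with a latent-Gaussian (NORTA-style)
construction: a multivariate normal vector Z with a *latent* correlation
matrix is transformed componentwise into the requested marginal
distributions (normal, log-normal, Bernoulli, or Gaussian mixtures).  The
latent correlation is solved so that the *observed* Pearson correlations hit
a user-specified target.  This module owns the covariance targets, the
marginal specifications, the latent-correlation solver, the samplers, and
moment-matching estimation of an all-normal DGP from data.

Coordinate convention: features are columns 1..p of the eventual design
matrix; the intercept column is owned by :mod:`plasmodesim.outcome`, never
by the DGP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .exceptions import (
    FeasibilityError,
    NotPositiveDefiniteError,
    RepairToleranceError,
    SingularCovarianceError,
)

__all__ = [
    "MarginalSpec",
    "CovarianceTarget",
    "FeatureDGP",
    "make_covariance",
    "latent_corr_entry",
    "build_dgp",
    "sample_features",
    "sample_mvn",
    "estimate_dgp",
    "read_matrix",
]

_SQRT10 = math.sqrt(10.0)

# Gauss-Hermite quadrature (probabilists' weight), order 64.  Used as the
# generic oracle for E[h_i(Z_i) h_j(Z_j)] when no closed form applies.
_GH_ORDER = 64
_gh_nodes, _gh_weights = np.polynomial.hermite_e.hermegauss(_GH_ORDER)
_gh_weights = _gh_weights / _gh_weights.sum()

#: Solver tolerance for the latent-correlation root finding, on the
#: observed-correlation scale.
LATENT_RHO_TOL = 1e-6


@dataclass(frozen=True)
class MarginalSpec:
    """Marginal distribution of one feature.

    Every marginal is realized as a transformation of a standard normal
    latent variable ``Z`` (plus, for mixtures, an independent Bernoulli
    component indicator):

    - ``normal``: ``X = mean + sd * Z``
    - ``lognormal``: ``X = exp(log_mean + log_sd * Z)``
    - ``bernoulli``: ``X = 1{Z > Phi^{-1}(1 - prob)}``
    - ``gaussian_mixture_shift``: ``X = Z + component_mean * I``,
      ``I ~ Bern(alpha)`` -- the bimodal mixture
      ``(1-alpha) N(0,1) + alpha N(component_mean, 1)``
    - ``gaussian_mixture_scale``: ``X = Z * (1 + (component_sd - 1) * I)``
      -- the contamination mixture
      ``(1-alpha) N(0,1) + alpha N(0, component_sd^2)``
    """

    kind: str
    mean_: float = 0.0
    sd_: float = 1.0
    log_mean: float = 0.0
    log_sd: float = 1.0
    prob: float = 0.5
    alpha: float = 0.0
    component_mean: float = 3.0
    component_sd: float = _SQRT10

    # -- constructors ------------------------------------------------------
    @classmethod
    def normal(cls, mean: float = 0.0, sd: float = 1.0) -> "MarginalSpec":
        if sd <= 0:
            raise ValueError("normal marginal requires sd > 0")
        return cls(kind="normal", mean_=mean, sd_=sd)

    @classmethod
    def lognormal(cls, log_mean: float = 0.0, log_sd: float = 1.0) -> "MarginalSpec":
        if log_sd <= 0:
            raise ValueError("lognormal marginal requires log_sd > 0")
        return cls(kind="lognormal", log_mean=log_mean, log_sd=log_sd)

    @classmethod
    def bernoulli(cls, prob: float) -> "MarginalSpec":
        if not 0.0 < prob < 1.0:
            raise ValueError("bernoulli marginal requires prob in (0, 1)")
        return cls(kind="bernoulli", prob=prob)

    @classmethod
    def mixture_shift(cls, alpha: float, component_mean: float = 3.0) -> "MarginalSpec":
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("mixture proportion alpha must lie in [0, 1]")
        return cls(kind="gaussian_mixture_shift", alpha=alpha, component_mean=component_mean)

    @classmethod
    def mixture_scale(cls, alpha: float, component_sd: float = _SQRT10) -> "MarginalSpec":
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("mixture proportion alpha must lie in [0, 1]")
        if component_sd <= 0:
            raise ValueError("mixture component sd must be positive")
        return cls(kind="gaussian_mixture_scale", alpha=alpha, component_sd=component_sd)

    # -- analytic moments --------------------------------------------------
    def mean(self) -> float:
        if self.kind == "normal":
            return self.mean_
        if self.kind == "lognormal":
            return math.exp(self.log_mean + self.log_sd**2 / 2.0)
        if self.kind == "bernoulli":
            return self.prob
        if self.kind == "gaussian_mixture_shift":
            return self.alpha * self.component_mean
        if self.kind == "gaussian_mixture_scale":
            return 0.0
        raise ValueError(f"unknown marginal kind {self.kind!r}")

    def var(self) -> float:
        if self.kind == "normal":
            return self.sd_**2
        if self.kind == "lognormal":
            s2 = self.log_sd**2
            return (math.exp(s2) - 1.0) * math.exp(2.0 * self.log_mean + s2)
        if self.kind == "bernoulli":
            return self.prob * (1.0 - self.prob)
        if self.kind == "gaussian_mixture_shift":
            a, m = self.alpha, self.component_mean
            return 1.0 + m**2 * a * (1.0 - a)
        if self.kind == "gaussian_mixture_scale":
            a, s = self.alpha, self.component_sd
            return (1.0 - a) + a * s**2
        raise ValueError(f"unknown marginal kind {self.kind!r}")

    def sd(self) -> float:
        return math.sqrt(self.var())

    # -- latent-Gaussian structure ----------------------------------------
    @property
    def is_linear(self) -> bool:
        """True if E[X | Z=z] is affine in z (normal and both mixtures)."""
        return self.kind in ("normal", "gaussian_mixture_shift", "gaussian_mixture_scale")

    def latent_loading(self) -> float:
        """Cov(Z, X) for the latent standard normal Z driving this marginal."""
        if self.kind == "normal":
            return self.sd_
        if self.kind == "lognormal":
            return self.log_sd * math.exp(self.log_mean + self.log_sd**2 / 2.0)
        if self.kind == "bernoulli":
            # Cov(Z, 1{Z > t}) = phi(t)
            return stats.norm.pdf(self._threshold())
        if self.kind == "gaussian_mixture_shift":
            return 1.0
        if self.kind == "gaussian_mixture_scale":
            return 1.0 + (self.component_sd - 1.0) * self.alpha
        raise ValueError(f"unknown marginal kind {self.kind!r}")

    def _threshold(self) -> float:
        """Latent threshold t with P(Z > t) = prob (Bernoulli only)."""
        return stats.norm.ppf(1.0 - self.prob)

    def cond_mean(self, z: np.ndarray) -> np.ndarray:
        """E[X | Z=z]; mixture indicators are integrated out analytically."""
        if self.kind == "normal":
            return self.mean_ + self.sd_ * z
        if self.kind == "lognormal":
            return np.exp(self.log_mean + self.log_sd * z)
        if self.kind == "bernoulli":
            return (z > self._threshold()).astype(float)
        if self.kind == "gaussian_mixture_shift":
            return z + self.component_mean * self.alpha
        if self.kind == "gaussian_mixture_scale":
            return z * (1.0 + (self.component_sd - 1.0) * self.alpha)
        raise ValueError(f"unknown marginal kind {self.kind!r}")

    def transform(self, z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Map latent standard-normal draws to the observed marginal.

        Mixture kinds consume additional uniform draws from ``rng`` for the
        independent component indicator; all other kinds are deterministic
        maps and leave the stream untouched.
        """
        if self.kind == "normal":
            return self.mean_ + self.sd_ * z
        if self.kind == "lognormal":
            return np.exp(self.log_mean + self.log_sd * z)
        if self.kind == "bernoulli":
            return (z > self._threshold()).astype(float)
        if self.kind == "gaussian_mixture_shift":
            ind = rng.random(z.shape) < self.alpha
            return z + self.component_mean * ind
        if self.kind == "gaussian_mixture_scale":
            ind = rng.random(z.shape) < self.alpha
            return z * (1.0 + (self.component_sd - 1.0) * ind)
        raise ValueError(f"unknown marginal kind {self.kind!r}")


@dataclass(frozen=True)
class CovarianceTarget:
    """A symmetric positive-definite covariance/correlation target."""

    p: int
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (self.p, self.p):
            raise ValueError(f"matrix shape {m.shape} does not match p={self.p}")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance target must be symmetric")
        if np.any(np.diag(m) <= 0):
            raise ValueError("covariance target needs a positive diagonal")
        eigvals = np.linalg.eigvalsh(m)
        if eigvals[0] <= 0:
            raise NotPositiveDefiniteError(
                f"covariance target is not positive definite "
                f"(smallest eigenvalue {eigvals[0]:.3e})",
                min_eigenvalue=float(eigvals[0]),
            )
        object.__setattr__(self, "matrix", m)

    def correlation(self) -> np.ndarray:
        """Rescale to unit diagonal."""
        d = np.sqrt(np.diag(self.matrix))
        return self.matrix / np.outer(d, d)


def make_covariance(
    kind: str,
    p: int,
    rho: float = 0.0,
    blocks: int | None = None,
    custom: np.ndarray | None = None,
) -> CovarianceTarget:
    """Build one of the study's covariance targets.

    - ``fixed_pairwise``: unit diagonal, ``rho`` everywhere off-diagonal.
    - ``block_power``: block-diagonal with ``blocks`` equal blocks; entry
      (i, j) within a block is ``rho**|i-j|``; zero between blocks.
    - ``custom``: a user-supplied symmetric positive-definite matrix.
    """
    if p < 1:
        raise ValueError("p must be at least 1")
    if kind == "fixed_pairwise":
        m = np.full((p, p), float(rho))
        np.fill_diagonal(m, 1.0)
    elif kind == "block_power":
        if blocks is None or p % blocks != 0:
            raise ValueError("block_power requires p divisible by blocks")
        size = p // blocks
        idx = np.arange(size)
        block = float(rho) ** np.abs(idx[:, None] - idx[None, :])
        m = np.zeros((p, p))
        for b in range(blocks):
            s = b * size
            m[s : s + size, s : s + size] = block
    elif kind == "custom":
        if custom is None:
            raise ValueError("custom covariance requires a matrix")
        m = np.asarray(custom, dtype=float)
        p = m.shape[0]
    else:
        raise ValueError(f"unknown covariance kind {kind!r}")
    return CovarianceTarget(p=p, matrix=m)


# ---------------------------------------------------------------------------
# Latent-correlation solver
# ---------------------------------------------------------------------------

def _observed_corr_quadrature(
    marg_i: MarginalSpec, marg_j: MarginalSpec, r: float
) -> float:
    """Observed Pearson correlation for latent correlation r, by quadrature.

    Because any extra mixture randomness is independent across features,
    Cov(X_i, X_j) = Cov(E[X_i|Z_i], E[X_j|Z_j]); the double expectation is
    evaluated on a tensorized Gauss-Hermite grid with Z_j | Z_i decomposed
    as r*Z_i + sqrt(1-r^2)*W.
    """
    zi = _gh_nodes[:, None]
    w = _gh_weights
    zj = r * zi + math.sqrt(max(0.0, 1.0 - r * r)) * _gh_nodes[None, :]
    hi = marg_i.cond_mean(np.broadcast_to(zi, zj.shape))
    hj = marg_j.cond_mean(zj)
    e_prod = float(w @ (hi * hj) @ w)
    cov = e_prod - marg_i.mean() * marg_j.mean()
    return cov / (marg_i.sd() * marg_j.sd())


def _bernoulli_pair_corr(ti: float, tj: float, r: float) -> float:
    """P(Z_i > t_i, Z_j > t_j) under latent correlation r (exact orthant)."""
    cov = np.array([[1.0, r], [r, 1.0]])
    return float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([-ti, -tj]))


def latent_corr_entry(
    marg_i: MarginalSpec, marg_j: MarginalSpec, rho_target: float
) -> float:
    """Latent Gaussian correlation reproducing a target Pearson correlation.

    Closed forms are used where available (any pair involving a marginal
    with an affine conditional mean, and log-normal pairs); the remaining
    pairs are solved by monotone root finding on the quadrature map
    ``r -> corr(h_i(Z_i), h_j(Z_j))``.

    Raises :class:`FeasibilityError` when no latent correlation in [-1, 1]
    attains the target (Frechet-bound violation).
    """
    if abs(rho_target) > 1:
        raise ValueError("target correlation must lie in [-1, 1]")
    if rho_target == 0.0:
        return 0.0

    li, lj = marg_i.latent_loading(), marg_j.latent_loading()

    # One affine conditional mean is enough for linearity in r (Stein):
    # Cov(X_i, X_j) = r * loading_i * loading_j.
    if marg_i.is_linear or marg_j.is_linear:
        r = rho_target * marg_i.sd() * marg_j.sd() / (li * lj)
        if abs(r) > 1.0:
            bound = li * lj / (marg_i.sd() * marg_j.sd())
            raise FeasibilityError(
                f"target correlation {rho_target} infeasible for "
                f"({marg_i.kind}, {marg_j.kind}); attainable range "
                f"is [{-bound:.4f}, {bound:.4f}]",
                attainable=(-bound, bound),
            )
        return float(r)

    if marg_i.kind == "lognormal" and marg_j.kind == "lognormal":
        si, sj = marg_i.log_sd, marg_j.log_sd
        arg = 1.0 + rho_target * math.sqrt(
            (math.exp(si**2) - 1.0) * (math.exp(sj**2) - 1.0)
        )
        if arg <= 0:
            lo = _observed_corr_quadrature(marg_i, marg_j, -1.0 + 1e-12)
            raise FeasibilityError(
                f"target correlation {rho_target} infeasible for the "
                f"log-normal pair; attainable range is [{lo:.4f}, 1]",
                attainable=(lo, 1.0),
            )
        r = math.log(arg) / (si * sj)
        if abs(r) > 1.0:
            raise FeasibilityError(
                f"target correlation {rho_target} infeasible for the "
                f"log-normal pair (requires latent r = {r:.4f})"
            )
        return r

    if marg_i.kind == "bernoulli" and marg_j.kind == "bernoulli":
        ti, tj = marg_i._threshold(), marg_j._threshold()
        target_joint = (
            rho_target * marg_i.sd() * marg_j.sd() + marg_i.prob * marg_j.prob
        )

        def f(r):
            return _bernoulli_pair_corr(ti, tj, r) - target_joint

        return _solve_monotone(f, marg_i, marg_j, rho_target)

    kinds = {marg_i.kind, marg_j.kind}
    if kinds == {"bernoulli", "lognormal"}:
        bern, logn = (
            (marg_i, marg_j) if marg_i.kind == "bernoulli" else (marg_j, marg_i)
        )
        # Cov(1{Z>t}, exp(mu + s*Z')) = exp(mu + s^2/2) * (Phibar(t - s*r) - prob)
        t, s = bern._threshold(), logn.log_sd
        scale = math.exp(logn.log_mean + s**2 / 2.0)
        target_cov = rho_target * bern.sd() * logn.sd()

        def f(r):
            return scale * (stats.norm.sf(t - s * r) - bern.prob) - target_cov

        return _solve_monotone(f, marg_i, marg_j, rho_target)

    # Generic pair (future marginal kinds): quadrature oracle.
    def f(r):
        return _observed_corr_quadrature(marg_i, marg_j, r) - rho_target

    return _solve_monotone(f, marg_i, marg_j, rho_target)


def _solve_monotone(f, marg_i, marg_j, rho_target) -> float:
    eps = 1e-9
    lo, hi = f(-1.0 + eps), f(1.0 - eps)
    if not (lo <= 0.0 <= hi):
        lo_c = _observed_corr_quadrature(marg_i, marg_j, -1.0 + eps)
        hi_c = _observed_corr_quadrature(marg_i, marg_j, 1.0 - eps)
        raise FeasibilityError(
            f"target correlation {rho_target} infeasible for "
            f"({marg_i.kind}, {marg_j.kind}); attainable range is "
            f"[{lo_c:.4f}, {hi_c:.4f}]",
            attainable=(lo_c, hi_c),
        )
    r = optimize.brentq(f, -1.0 + eps, 1.0 - eps, xtol=1e-10)
    if abs(f(r)) > LATENT_RHO_TOL:
        raise FeasibilityError(
            f"latent-correlation solve did not converge for "
            f"({marg_i.kind}, {marg_j.kind}), residual {f(r):.2e}"
        )
    return float(r)


# ---------------------------------------------------------------------------
# DGP assembly and sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDGP:
    """A fully specified feature-generating process.

    ``target_corr`` holds the Pearson correlations on the observed scale
    (unit diagonal); marginal means/variances live in ``marginals``.
    ``latent_corr`` is the correlation matrix of the underlying Gaussian
    vector, solved entrywise so that sampling reproduces the targets.
    """

    p: int
    marginals: tuple[MarginalSpec, ...]
    target_corr: CovarianceTarget
    latent_corr: np.ndarray
    repair_perturbation: float = 0.0
    _latent_chol: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self._latent_chol is None:
            object.__setattr__(self, "_latent_chol", np.linalg.cholesky(self.latent_corr))

    def mean_vector(self) -> np.ndarray:
        return np.array([m.mean() for m in self.marginals])

    def sd_vector(self) -> np.ndarray:
        return np.array([m.sd() for m in self.marginals])

    def covariance(self) -> np.ndarray:
        """Observed-scale covariance implied by marginals and target_corr."""
        d = self.sd_vector()
        return self.target_corr.matrix * np.outer(d, d)

    @property
    def all_normal(self) -> bool:
        return all(m.kind == "normal" for m in self.marginals)


def mvn_dgp(target: CovarianceTarget, mean: np.ndarray | None = None) -> FeatureDGP:
    """Multivariate-normal DGP with the given covariance target."""
    corr = target.correlation()
    sds = np.sqrt(np.diag(target.matrix))
    if mean is None:
        mean = np.zeros(target.p)
    marginals = tuple(
        MarginalSpec.normal(mean=float(mu), sd=float(s)) for mu, s in zip(mean, sds)
    )
    return FeatureDGP(
        p=target.p,
        marginals=marginals,
        target_corr=CovarianceTarget(p=target.p, matrix=corr),
        latent_corr=corr,
    )


def build_dgp(
    marginals,
    target_corr: CovarianceTarget | np.ndarray,
    repair_tol: float = 1e-3,
) -> FeatureDGP:
    """Assemble a FeatureDGP by solving every pairwise latent correlation.

    If the entrywise-assembled latent matrix is not positive definite, it is
    repaired to the nearest correlation matrix by eigenvalue clipping (at
    1e-8) and rescaling to unit diagonal; a maximum entry perturbation above
    ``repair_tol`` raises :class:`RepairToleranceError`.
    """
    marginals = tuple(marginals)
    p = len(marginals)
    if isinstance(target_corr, np.ndarray):
        target_corr = CovarianceTarget(p=p, matrix=np.asarray(target_corr, float))
    corr = target_corr.correlation()
    target = CovarianceTarget(p=p, matrix=corr)

    if all(m.kind == "normal" for m in marginals):
        # identity map: latent equals the target exactly
        return FeatureDGP(p=p, marginals=marginals, target_corr=target, latent_corr=corr)

    latent = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            r = latent_corr_entry(marginals[i], marginals[j], corr[i, j])
            latent[i, j] = latent[j, i] = r

    eigvals, eigvecs = np.linalg.eigh(latent)
    perturbation = 0.0
    if eigvals[0] <= 1e-8:
        clipped = np.clip(eigvals, 1e-8, None)
        repaired = (eigvecs * clipped) @ eigvecs.T
        d = np.sqrt(np.diag(repaired))
        repaired = repaired / np.outer(d, d)
        perturbation = float(np.max(np.abs(repaired - latent)))
        if perturbation > repair_tol:
            raise RepairToleranceError(
                f"latent correlation repair perturbed entries by "
                f"{perturbation:.2e} (> {repair_tol:.1e})"
            )
        latent = repaired

    return FeatureDGP(
        p=p,
        marginals=marginals,
        target_corr=target,
        latent_corr=latent,
        repair_perturbation=perturbation,
    )


def sample_features(dgp: FeatureDGP, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n i.i.d. feature rows from the DGP.

    Stream discipline: the latent normal block is drawn first (n x p), then
    any mixture indicators column by column.  For all-normal DGPs this is
    bitwise identical to :func:`sample_mvn` with the same generator state.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    z = rng.standard_normal((n, dgp.p)) @ dgp._latent_chol.T
    x = np.empty_like(z)
    for j, marg in enumerate(dgp.marginals):
        x[:, j] = marg.transform(z[:, j], rng)
    return x


def sample_mvn(
    mean: np.ndarray, cov: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Direct multivariate-normal sampler sharing sample_features' stream path."""
    mean = np.asarray(mean, float)
    cov = np.asarray(cov, float)
    sds = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sds, sds)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, len(mean))) @ chol.T
    return mean + sds * z


def estimate_dgp(data: np.ndarray) -> FeatureDGP:
    """Fit an all-normal DGP by the sample mean and covariance.

    This is the "parametric simulation with estimation" input: a dataset
    from the true DGP is summarized by its first two moments, discarding
    any non-Gaussian structure.
    """
    data = np.asarray(data, float)
    n, p = data.shape
    if n <= p:
        raise ValueError("need more observations than features to estimate a DGP")
    mean = data.mean(axis=0)
    cov = np.cov(data, rowvar=False, ddof=1).reshape(p, p)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 1e-12 * max(eigvals[-1], 1.0):
        raise SingularCovarianceError(
            f"sample covariance is singular (smallest eigenvalue {eigvals[0]:.3e})"
        )
    return mvn_dgp(CovarianceTarget(p=p, matrix=cov), mean=mean)


def read_matrix(path) -> np.ndarray:
    """Read a header-free p x p matrix from whitespace- or comma-delimited text."""
    try:
        m = np.loadtxt(path)
    except ValueError:
        m = np.loadtxt(path, delimiter=",")
    m = np.atleast_2d(np.asarray(m, float))
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix file must be square, got shape {m.shape}")
    return m
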