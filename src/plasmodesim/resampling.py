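"""Plasmode feature-resampling schemes.

A Plasmode simulation draws one source dataset of ceil(n / pi) rows from
the true DGP per outer repetition and then produces n-row feature matrices
from it by one of six schemes: n-out-of-n bootstrap, m-out-of-n bootstrap,
subsampling without replacement, no resampling, smoothed bootstrap (kernel
noise with a normal-reference bandwidth), and the wild bootstrap (feature
version).  The outcome is always generated afresh downstream; only the
features are resampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SCHEME_TYPES",
    "ResamplingScheme",
    "silverman_bandwidth",
    "resample",
    "resample_batch",
]

SCHEME_TYPES = ("n_of_n", "m_of_n", "subsample", "none", "smoothed", "wild")

#: Resampling proportions examined in the study for m_of_n and subsample.
PROPORTION_GRID = (0.01, 0.1, 0.5, 0.632, 0.8, 0.9)


@dataclass(frozen=True)
class ResamplingScheme:
    """One resampling scheme plus its proportion pi = n / source size."""

    type: str
    proportion: float = 1.0

    def __post_init__(self):
        if self.type not in SCHEME_TYPES:
            raise ValueError(f"unknown resampling type {self.type!r}")
        if not 0.0 < self.proportion <= 1.0:
            raise ValueError("resampling proportion must lie in (0, 1]")
        if self.type in ("n_of_n", "none", "smoothed", "wild") and self.proportion != 1.0:
            raise ValueError(f"{self.type} requires proportion 1")

    def source_size(self, n: int) -> int:
        """Rows of the source dataset: ceil(n / pi)."""
        return math.ceil(n / self.proportion)

    @property
    def label(self) -> str:
        if self.type in ("m_of_n", "subsample"):
            return f"{self.type}({self.proportion:g})"
        return self.type


def silverman_bandwidth(source: np.ndarray) -> np.ndarray:
    """Multivariate normal-reference (Silverman) bandwidth matrix.

    H = (4 / (n (p + 2)))^{2/(p+4)} * S with S the sample covariance, i.e.
    the sample covariance scaled by the squared per-dimension bandwidth
    factor.  For p = 1 this reduces to the classic
    h = (4/3)^{1/5} n^{-1/5} sd (H carries h^2).  Using the full covariance
    rather than its diagonal preserves the correlation structure of the
    smoothed sample.
    """
    source = np.asarray(source, float)
    n_src, p = source.shape
    if n_src < 2:
        raise ValueError("bandwidth estimation needs at least 2 rows")
    sd = source.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature: bandwidth undefined")
    cov = np.cov(source, rowvar=False, ddof=1).reshape(p, p)
    factor = (4.0 / (n_src * (p + 2.0))) ** (2.0 / (p + 4.0))
    return factor * cov


def _bandwidth_root(bandwidth: np.ndarray) -> np.ndarray:
    """Lower-triangular-ish square root of a PSD bandwidth matrix."""
    try:
        return np.linalg.cholesky(bandwidth)
    except np.linalg.LinAlgError:
        # PSD but singular (e.g. forced to zero): eigenvalue square root
        vals, vecs = np.linalg.eigh(bandwidth)
        return vecs * np.sqrt(np.clip(vals, 0.0, None))


def resample_batch(
    source: np.ndarray,
    scheme: ResamplingScheme,
    n: int,
    n_mod: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n_mod resampled feature matrices of exactly n rows each.

    Returns an array of shape (n_mod, n, p).  Subsampling with a source of
    exactly n rows (proportion 1) returns the source unpermuted, making it
    bitwise equivalent to "no resampling" (row order is irrelevant to the
    downstream least-squares fit).
    """
    source = np.asarray(source, float)
    n_src, p = source.shape

    if scheme.type in ("n_of_n", "m_of_n"):
        idx = rng.integers(0, n_src, size=(n_mod, n))
        return source[idx]

    if scheme.type in ("subsample", "none"):
        if n_src < n:
            raise ValueError(
                f"subsampling needs a source of at least n={n} rows, got {n_src}"
            )
        if n_src == n:
            return np.broadcast_to(source, (n_mod, n, p)).copy()
        # without-replacement draw per dataset via random-key argsort
        keys = rng.random((n_mod, n_src))
        idx = np.argsort(keys, axis=1)[:, :n]
        return source[idx]

    if scheme.type == "smoothed":
        idx = rng.integers(0, n_src, size=(n_mod, n))
        root = _bandwidth_root(silverman_bandwidth(source))
        noise = rng.standard_normal((n_mod, n, p)) @ root.T
        return source[idx] + noise

    if scheme.type == "wild":
        sd = source.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance feature: wild bootstrap undefined")
        standardized = (source - source.mean(axis=0)) / sd
        a = rng.standard_normal((n_mod, p))
        return source[None, :, :] + a[:, None, :] * standardized[None, :, :]

    raise ValueError(f"unknown resampling type {scheme.type!r}")


def resample(
    source: np.ndarray, scheme: ResamplingScheme, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Single resampled n x p feature matrix."""
    return resample_batch(source, scheme, n, 1, rng)[0]
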