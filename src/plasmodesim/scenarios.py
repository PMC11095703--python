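"""Named true-scenario catalog.

Each scenario fixes the true DGP (zero-mean multivariate normal features
with unit variances and a fixed-pairwise or block-power correlation
structure), the sample size n, and the true OGM (all coefficients 1,
normal errors with sd 0.3).  Scenarios with correlation matrices taken
from real data are supported through user-supplied plain-text matrix
files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dgp import CovarianceTarget, FeatureDGP, make_covariance, mvn_dgp, read_matrix
from .outcome import ErrorSpec, OutcomeModel

__all__ = ["Scenario", "catalog", "get_scenario", "custom_scenario"]

TRUE_ERROR_SD = 0.3


@dataclass(frozen=True)
class Scenario:
    name: str
    p: int
    n: int
    dgp: FeatureDGP
    ogm: OutcomeModel
    covariance_kind: str  # fixed_pairwise | block_power | custom
    rho: float | None = None
    blocks: int | None = None


def _make(name, p, n, kind, rho, blocks=None) -> Scenario:
    target = make_covariance(kind, p, rho=rho, blocks=blocks)
    return Scenario(
        name=name,
        p=p,
        n=n,
        dgp=mvn_dgp(target),
        ogm=OutcomeModel.unit(p, ErrorSpec(sd=TRUE_ERROR_SD)),
        covariance_kind=kind,
        rho=rho,
        blocks=blocks,
    )


def catalog() -> dict[str, Scenario]:
    """All synthetic true scenarios of the study."""
    return {
        s.name: s
        for s in [
            _make("p2n100rho0.2", 2, 100, "fixed_pairwise", 0.2),
            _make("p2n50rho0.2", 2, 50, "fixed_pairwise", 0.2),
            _make("p2n100rho0.5", 2, 100, "fixed_pairwise", 0.5),
            _make("p10n100rho0.2", 10, 100, "fixed_pairwise", 0.2),
            _make("p10n50rho0.2", 10, 50, "fixed_pairwise", 0.2),
            _make("p50n100rho0.2", 50, 100, "fixed_pairwise", 0.2),
            _make("p50n100rho0.2_block", 50, 100, "block_power", 0.2, blocks=5),
            _make("p50n100rho0.5_block", 50, 100, "block_power", 0.5, blocks=5),
        ]
    }


def get_scenario(name: str) -> Scenario:
    scenarios = catalog()
    if name not in scenarios:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(scenarios))}"
        )
    return scenarios[name]


def custom_scenario(
    name: str,
    covariance: np.ndarray | str,
    n: int,
    error_sd: float = TRUE_ERROR_SD,
) -> Scenario:
    """Scenario with a user-supplied covariance matrix (array or text file)."""
    if isinstance(covariance, (str, bytes)) or hasattr(covariance, "read"):
        covariance = read_matrix(covariance)
    target = CovarianceTarget(p=covariance.shape[0], matrix=np.asarray(covariance, float))
    p = target.p
    return Scenario(
        name=name,
        p=p,
        n=n,
        dgp=mvn_dgp(target),
        ogm=OutcomeModel.unit(p, ErrorSpec(sd=error_sd)),
        covariance_kind="custom",
    )
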