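"""Error statistics and the threshold scan.

The study's performance measure: for each outer repetition, the
component-wise error of the estimated MSE against the true MSE
(absolute, and relative by dividing by the true MSE), aggregated over
coefficients by the arithmetic mean of absolute values, and aggregated
over repetitions by the median.  The threshold scan orders a family of
parametric misspecifications by increasing deviation magnitude and
reports the first deviation whose parametric median aggregated error
exceeds a Plasmode variant's error under the true model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .dgp import FeatureDGP, MarginalSpec, build_dgp, make_covariance, mvn_dgp
from .outcome import ErrorSpec, MSEEstimate, OutcomeModel
from .scenarios import Scenario

__all__ = [
    "ErrorRecord",
    "StudySummary",
    "ThresholdResult",
    "DeviatedStudy",
    "error_records",
    "summarize",
    "median_aggregate",
    "threshold_scan",
    "deviation_grid",
    "DEVIATION_FAMILIES",
]


@dataclass(frozen=True)
class StudySummary:
    """Median aggregated error plus per-component quartiles."""

    median_aggregate: float
    aggregates: np.ndarray  # one aggregate per repetition
    component_quartiles: pd.DataFrame  # index: coefficient; cols: q1, median, q3
    relative: bool


@dataclass(frozen=True)
class ThresholdResult:
    """First deviation at which parametric falls behind one Plasmode scheme."""

    scenario: str
    family: str
    scheme: str
    first_exceeding_value: float | None


def error_records(
    estimates: Sequence[MSEEstimate], true: MSEEstimate
) -> pd.DataFrame:
    """Long-format per-repetition, per-coefficient error table."""
    rows = []
    t = true.values
    for k, est in enumerate(estimates):
        abs_err = est.values - t
        rel_err = abs_err / t
        for j in range(len(t)):
            rows.append(
                {
                    "rep": k,
                    "coefficient": j,
                    "abs_error": abs_err[j],
                    "rel_error": rel_err[j],
                }
            )
    return pd.DataFrame(rows)


#: Back-compat alias: one row of :func:`error_records` is an error record.
ErrorRecord = dict


def _aggregates(
    estimates: Sequence[MSEEstimate], true: MSEEstimate, relative: bool
) -> np.ndarray:
    t = true.values
    if relative and np.any(t <= 0):
        raise ValueError("relative errors need strictly positive true MSEs")
    errs = np.stack([est.values - t for est in estimates])
    if relative:
        errs = errs / t
    return np.abs(errs).mean(axis=1)


def summarize(
    estimates: Sequence[MSEEstimate], true: MSEEstimate, relative: bool = True
) -> StudySummary:
    """Aggregate errors over coefficients (mean of absolute values) and
    repetitions (median); also report per-component error quartiles."""
    agg = _aggregates(estimates, true, relative)
    t = true.values
    errs = np.stack([est.values - t for est in estimates])
    if relative:
        errs = errs / t
    q1, med, q3 = np.percentile(errs, [25, 50, 75], axis=0)
    quartiles = pd.DataFrame(
        {"q1": q1, "median": med, "q3": q3},
        index=pd.RangeIndex(len(t), name="coefficient"),
    )
    return StudySummary(
        median_aggregate=float(np.median(agg)),
        aggregates=agg,
        component_quartiles=quartiles,
        relative=relative,
    )


def median_aggregate(
    estimates: Sequence[MSEEstimate], true: MSEEstimate, relative: bool = True
) -> float:
    """Median over repetitions of the mean absolute (relative) error."""
    return float(np.median(_aggregates(estimates, true, relative)))


# ---------------------------------------------------------------------------
# Deviation grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeviatedStudy:
    """One misspecified parametric study: the grid value plus the assumed
    DGP/OGM to simulate under."""

    family: str
    value: float
    assumed_dgp: FeatureDGP
    assumed_ogm: OutcomeModel


def _second_half(p: int) -> np.ndarray:
    """Indices of the misspecified features ("second half"; the second
    feature alone when p = 2)."""
    return np.arange(p // 2, p) if p > 2 else np.array([1])


def _normal_marginals(p, means, sds):
    means = np.broadcast_to(means, p)
    sds = np.broadcast_to(sds, p)
    return [MarginalSpec.normal(float(m), float(s)) for m, s in zip(means, sds)]


def _grid(start, stop, step):
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 10)


def _scenario_corr(scenario: Scenario) -> np.ndarray:
    return scenario.dgp.target_corr.matrix


def _mean_shift(scenario, grid, which):
    out = []
    idx = _second_half(scenario.p) if which == "half" else np.arange(scenario.p)
    corr = _scenario_corr(scenario)
    for mu in grid:
        means = np.zeros(scenario.p)
        means[idx] = mu
        dgp = build_dgp(_normal_marginals(scenario.p, means, 1.0), corr)
        out.append(DeviatedStudy("mean_shift", float(mu), dgp, scenario.ogm))
    return out


def _variance_shift(scenario, grid, which):
    out = []
    idx = _second_half(scenario.p) if which == "half" else np.arange(scenario.p)
    corr = _scenario_corr(scenario)
    for v in grid:
        sds = np.ones(scenario.p)
        sds[idx] = math.sqrt(v)
        dgp = build_dgp(_normal_marginals(scenario.p, 0.0, sds), corr)
        out.append(DeviatedStudy("variance_shift", float(v), dgp, scenario.ogm))
    return out


def _correlation(scenario, grid, structure):
    out = []
    for rho in grid:
        if structure == "fixed_pairwise":
            target = make_covariance("fixed_pairwise", scenario.p, rho=rho)
        else:
            blocks = scenario.blocks if scenario.blocks else 1
            if scenario.p == 10:
                blocks = 1
            target = make_covariance("block_power", scenario.p, rho=rho, blocks=blocks)
        out.append(
            DeviatedStudy("correlation", float(rho), mvn_dgp(target), scenario.ogm)
        )
    return out


def _mixture(scenario, grid, variant):
    """Contamination ((1-a)N(0,1) + a N(0,10)) or bimodal
    ((1-a)N(0,1) + a N(3,1)) mixtures for the second half of features,
    with the first half normal with matching moments and all pairwise
    Pearson correlations preserved."""
    out = []
    idx = set(_second_half(scenario.p).tolist())
    corr = _scenario_corr(scenario)
    for a in grid:
        if variant == "contamination":
            mix = MarginalSpec.mixture_scale(float(a))
        else:
            mix = MarginalSpec.mixture_shift(float(a))
        match = MarginalSpec.normal(mix.mean(), mix.sd())
        marginals = [mix if j in idx else match for j in range(scenario.p)]
        dgp = build_dgp(marginals, corr)
        out.append(DeviatedStudy(f"mixture_{variant}", float(a), dgp, scenario.ogm))
    return out


def _lognormal(scenario, grid=None):
    idx = set(_second_half(scenario.p).tolist())
    corr = _scenario_corr(scenario)
    ln = MarginalSpec.lognormal(0.0, 1.0)
    match = MarginalSpec.normal(ln.mean(), ln.sd())
    marginals = [ln if j in idx else match for j in range(scenario.p)]
    dgp = build_dgp(marginals, corr)
    return [DeviatedStudy("lognormal", 1.0, dgp, scenario.ogm)]


def _bernoulli(scenario, grid):
    # only the second feature is replaced; all others stay standard normal
    out = []
    corr = _scenario_corr(scenario)
    for prob in grid:
        marginals = [
            MarginalSpec.bernoulli(float(prob)) if j == 1 else MarginalSpec.normal()
            for j in range(scenario.p)
        ]
        dgp = build_dgp(marginals, corr)
        out.append(DeviatedStudy("bernoulli", float(prob), dgp, scenario.ogm))
    return out


_COEF_VARIANTS = {
    "coefficients_I": lambda p: np.arange(p + 1) / p,
    "coefficients_II": lambda p: np.full(p + 1, 0.05),
    "coefficients_III": lambda p: np.full(p + 1, 10.0),
    "coefficients_IV": lambda p: np.zeros(p + 1),
}


def _coefficients(scenario, grid, variant):
    beta = _COEF_VARIANTS[variant](scenario.p)
    ogm = OutcomeModel(beta=beta, error=scenario.ogm.error)
    variant_no = float(list(_COEF_VARIANTS).index(variant) + 1)
    return [DeviatedStudy(variant, variant_no, scenario.dgp, ogm)]


def _error_sd(scenario, grid):
    out = []
    for c in grid:
        ogm = OutcomeModel(beta=scenario.ogm.beta, error=ErrorSpec(sd=float(c)))
        out.append(DeviatedStudy("error_sd", float(c), scenario.dgp, ogm))
    return out


def _error_family(scenario, grid, family):
    out = []
    sd = scenario.ogm.error.sd
    for df in grid:
        ogm = OutcomeModel(
            beta=scenario.ogm.beta, error=ErrorSpec(family=family, sd=sd, df=int(df))
        )
        out.append(DeviatedStudy(family, float(df), scenario.dgp, ogm))
    return out


def _default_grid(family: str, scenario: Scenario) -> np.ndarray:
    p, rho = scenario.p, (scenario.rho or 0.0)
    if family == "mean_shift_second_half" or family == "mean_shift_all":
        hi = 1.0 if p == 2 else (1.5 if p == 10 else 3.5)
        return _grid(0.05, hi, 0.05)
    if family in ("variance_second_half", "variance_all"):
        hi = 2.0 if p == 2 else 2.5
        return _grid(1.05, hi, 0.05)
    if family in ("variance_second_half_low", "variance_all_low"):
        return _grid(0.9, 0.1, -0.1)
    if family in ("correlation", "correlation_power"):
        return _grid(round(rho + 0.01, 2), min(rho + 0.4, 0.95), 0.01)
    if family in ("mixture_contamination", "mixture_bimodal"):
        return _grid(0.01, 0.30, 0.01)
    if family == "bernoulli":
        return _grid(0.1, 0.9, 0.1)
    if family == "error_sd":
        return np.array([0.1, 0.2, 0.25, 0.35, 0.4, 0.5, 1.0, 3.0])
    if family == "error_t_scaled":
        return np.array([3, 5, 10])
    if family == "error_chisq_scaled":
        return np.array([1, 4, 10])
    return np.array([1.0])


DEVIATION_FAMILIES: dict[str, Callable] = {
    "mean_shift_second_half": lambda s, g: _mean_shift(s, g, "half"),
    "mean_shift_all": lambda s, g: _mean_shift(s, g, "all"),
    "variance_second_half": lambda s, g: _variance_shift(s, g, "half"),
    "variance_second_half_low": lambda s, g: _variance_shift(s, g, "half"),
    "variance_all": lambda s, g: _variance_shift(s, g, "all"),
    "variance_all_low": lambda s, g: _variance_shift(s, g, "all"),
    "correlation": lambda s, g: _correlation(s, g, "fixed_pairwise"),
    "correlation_power": lambda s, g: _correlation(s, g, "block_power"),
    "mixture_contamination": lambda s, g: _mixture(s, g, "contamination"),
    "mixture_bimodal": lambda s, g: _mixture(s, g, "bimodal"),
    "lognormal": lambda s, g: _lognormal(s, g),
    "bernoulli": lambda s, g: _bernoulli(s, g),
    "coefficients_I": lambda s, g: _coefficients(s, g, "coefficients_I"),
    "coefficients_II": lambda s, g: _coefficients(s, g, "coefficients_II"),
    "coefficients_III": lambda s, g: _coefficients(s, g, "coefficients_III"),
    "coefficients_IV": lambda s, g: _coefficients(s, g, "coefficients_IV"),
    "error_sd": lambda s, g: _error_sd(s, g),
    "error_t_scaled": lambda s, g: _error_family(s, g, "scaled_t"),
    "error_chisq_scaled": lambda s, g: _error_family(s, g, "shifted_scaled_chisq"),
}


def deviation_grid(
    family: str, scenario: Scenario, grid: Iterable[float] | None = None
) -> list[DeviatedStudy]:
    """Ordered misspecified parametric studies for one deviation family.

    The grid is ordered by increasing deviation magnitude (decreasing for
    the low-variance families, matching the study's ordering convention).
    """
    if family not in DEVIATION_FAMILIES:
        raise KeyError(
            f"unknown deviation family {family!r}; "
            f"available: {', '.join(sorted(DEVIATION_FAMILIES))}"
        )
    if family == "correlation_power" and scenario.p not in (10, 50):
        raise ValueError("power-structure correlation deviations need p in {10, 50}")
    values = np.asarray(list(grid), float) if grid is not None else _default_grid(family, scenario)
    if values.size == 0:
        raise ValueError("deviation grid is empty")
    return DEVIATION_FAMILIES[family](scenario, values)


# ---------------------------------------------------------------------------
# Threshold scan
# ---------------------------------------------------------------------------

def threshold_scan(
    scenario_name: str,
    family: str,
    deviations: Sequence[DeviatedStudy],
    comparators: dict[str, float],
    runner: Callable[[DeviatedStudy], float],
) -> dict[str, ThresholdResult]:
    """First grid value at which parametric falls behind each Plasmode scheme.

    ``runner`` maps a deviated parametric study to its median aggregated
    relative error; ``comparators`` holds each Plasmode scheme's median
    aggregated relative error under the true model.  Deviations must be
    ordered by increasing magnitude.  The parametric curve is evaluated
    lazily, stopping once every scheme has crossed; the *first* crossing
    is taken literally even though the curve need not be monotone.
    """
    if len(deviations) == 0:
        raise ValueError("threshold scan requires a non-empty deviation grid")
    results: dict[str, ThresholdResult] = {}
    pending = dict(comparators)
    for dev in deviations:
        if not pending:
            break
        par = runner(dev)
        for scheme, level in list(pending.items()):
            if par > level:
                results[scheme] = ThresholdResult(
                    scenario_name, family, scheme, dev.value
                )
                del pending[scheme]
    for scheme in pending:
        results[scheme] = ThresholdResult(scenario_name, family, scheme, None)
    return results
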