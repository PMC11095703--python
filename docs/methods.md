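# Methods

## Problem

`plasmodesim` studies how well a Monte-Carlo simulation estimates the
component-wise mean squared error (MSE) of the ordinary least squares
estimator (LSE) in a linear model, and how sensitive that estimate is to
misspecifying the feature distribution.

The data-generating process is

- features: `x_i ~ F` i.i.d., `i = 1..n`, with `F` a p-variate
  distribution with covariance `Sigma`;
- outcomes: `y = beta_0 + x' beta + eps`, `eps ~ N(0, sigma^2)`,
  independent of `x`.

The target quantity is the vector `MSE_k = E[(betahat_k - beta_k)^2]`,
`k = 0..p`, for the LSE `betahat = (X'X)^{-1} X'y` on an `n x (p+1)`
design with intercept.

Two ways of estimating this target by simulation are compared:

- **parametric**: draw feature matrices from an assumed distribution
  `F_a` (possibly different from the true `F`), generate outcomes from
  the assumed outcome model, fit the LSE, and average squared deviations;
- **Plasmode**: draw one *source* dataset from the true `F`, then build
  each simulated feature matrix by resampling rows of the source;
  outcomes still come from the assumed (known) outcome model.

A parametric study is exactly right when `F_a = F`; Plasmode is immune to
distributional misspecification but pays a price for reusing one finite
source sample. The headline analysis asks: *how wrong does `F_a` have to
be before the parametric study becomes worse than a given Plasmode
variant run under the true model?*

## Study design

One study (`engine.run_study`) runs `n_mse` outer repetitions. Each
repetition builds `n_mod` feature matrices (parametrically or by
resampling), generates one outcome vector per matrix, fits the LSE, and
reports `MSEhat_k = mean over models of (betahat_k - beta_{a,k})^2`. Error
against the truth is summarized as the mean over coefficients of the
absolute relative error (the *aggregate*), then the median of the
aggregate over repetitions.

The deviation of the fit from the assumed coefficients is computed
directly as `(X'X)^{-1} X' eps` rather than as a difference of two fits.
This is algebraically identical and makes MSE estimates bitwise
independent of the assumed coefficient vector, a property the tests
assert exactly.

### True-MSE oracle

The default oracle (`true_mse(..., method="conditional_variance")`)
Rao-Blackwellizes the naive squared-error oracle: conditional on `X`, the
LSE deviation is exactly `N(0, sigma^2 (X'X)^{-1})`, so
`MSE_k = sigma^2 E[((X'X)^{-1})_{kk}]` and only the expectation over `X`
needs Monte Carlo. This gives the same answer as squared-error averaging
with far fewer draws (1e5 instead of tens of millions), and makes the
sigma-scaling law `MSE(sigma=3)/MSE(sigma=0.3) = 100` hold to machine
precision under common `X` draws. A `squared_error` method is kept for
cross-validation of the oracle itself.

For multivariate normal features the slope components also have the
closed form `sigma^2 (Sigma^{-1})_{jj} / (n - p - 2)` (inverse-Wishart
expectation), which the tests check against the oracle.

### Resampling schemes

With resampling proportion `pi`, the source has `ceil(n/pi)` rows and
every resampled dataset has `n` rows:

- `n_of_n`: with-replacement draw of `n` from `n` (`pi = 1`);
- `m_of_n(pi)`: with-replacement draw of `n` from `ceil(n/pi) > n`;
- `subsample(pi)`: without-replacement draw of `n` from `ceil(n/pi)`;
- `none`: the source itself, fixed across all `n_mod` models;
- `smoothed`: `n_of_n` draw plus multivariate normal kernel noise;
- `wild`: source plus one random multiple per dataset of each column's
  standardized values.

Degenerate cases are exact by construction: `m_of_n(1)` produces the same
bitstream as `n_of_n`, and `subsample(1)` returns the source unpermuted,
identical to `none`.

The smoothed bootstrap uses the normal-reference (Silverman) bandwidth
with the full sample covariance, `H = (4 / (n (p+2)))^(2/(p+4)) * S`.
Using the full covariance rather than a diagonal rule matters at p >= 10:
diagonal noise attenuates the correlations of the smoothed sample
(shrinking a correlation of 0.2 to about 0.14 at p=10, n=100), which
inflates the smoothed comparator's true-model error and shifts the
threshold scans that use it. With the full-covariance rule the kernel
noise preserves the source correlation structure.

### Feature distributions

Non-normal marginals are generated by a latent-Gaussian (NORTA)
construction: draw correlated standard normals `Z`, then map each
coordinate through its marginal transform (lognormal `exp(Z)`; Bernoulli
`1{Z > t}`; mean-contamination mixture `Z + 3*I`; scale-contamination
mixture `Z * (1 + (sqrt(10)-1) I)` with independent mixture indicators
`I`). The latent correlation is solved so the *observed* Pearson
correlations hit the target. Closed forms cover every pair used in the
catalog — Stein's identity for pairs with an affine conditional mean,
the exact lognormal-lognormal formula, bivariate orthant probabilities
for Bernoulli-Bernoulli, and an explicit expression for
Bernoulli-lognormal — with 64-point Gauss-Hermite quadrature as a
generic fallback. Infeasible targets raise a `FeasibilityError` that
reports the attainable range. A resulting latent matrix that is not
positive definite is repaired by eigenvalue clipping, with the
perturbation bounded by a tolerance (default 1e-3) beyond which a
`RepairToleranceError` is raised.

### Threshold scans

A deviation family (mean shift of the second half of features, inflated
variance, extra correlation, contamination mixtures, wrong marginal
family, wrong error distribution, wrong coefficients, wrong error sd)
defines a grid of increasingly misspecified assumed DGPs/OGMs. The scan
runs a parametric study at successive grid values — all sharing one seed,
so the error curve is smooth in the deviation (common random numbers) —
and reports the first value whose median aggregated relative error
exceeds each Plasmode comparator's true-model error. Evaluation is lazy:
the scan stops once every comparator has been crossed.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `n_mse` | 50 | outer simulation repetitions (desk profile) |
| `n_mod` | 1000 | model fits per repetition |
| oracle reps | 100 000 | `X` draws for the conditional-variance oracle |
| `sigma` | 0.3 | true error standard deviation |
| `beta` | `1_{p+1}` | true coefficients (intercept included) |
| grids | family-specific | e.g. mean shift 0.05..1.00 step 0.05 (p=2) |

The desk profile (50 x 1000, 1e5-rep oracle) is this package's own
choice of problem size: it reproduces every headline number in minutes on
one CPU. The flagship sizes (100 repetitions, squared-error oracle with
2.5e7 draws) remain reachable through keyword arguments and CLI flags.

## Randomness

All randomness flows from NumPy `SeedSequence`. A study seed spawns one
stream per repetition and role (`features`, `source`, `resampling`,
`noise`), so changing e.g. the resampling scheme never perturbs the
feature draws. Named sub-experiments derive child seeds (< 2^31) from
CRC-32 tags of their path, making every reported number a pure function
of the single user-supplied seed.

## Limitations

- Only the linear model with an intercept and homoskedastic errors is
  implemented; no GLMs, no heteroskedasticity.
- The latent-Gaussian solver covers the marginal kinds in the catalog;
  new kinds fall back to quadrature, which cannot reach tight tolerances
  for discontinuous transforms.
- Threshold estimates inherit Monte-Carlo noise from both the parametric
  curve and the comparator; at desk scale they are reproducible to about
  one or two grid steps, not exactly.
- `parametric_estimated` mode estimates only a multivariate normal DGP
  (moments of the source sample); it does not attempt marginal family
  selection.
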