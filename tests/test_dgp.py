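"""Covariance targets, latent-correlation solving, and feature sampling."""

import math

import numpy as np
import pytest
from scipy import stats

from plasmodesim import (
    MarginalSpec,
    build_dgp,
    estimate_dgp,
    latent_corr_entry,
    make_covariance,
    sample_features,
    sample_mvn,
)
from plasmodesim.dgp import read_matrix
from plasmodesim.exceptions import (
    FeasibilityError,
    NotPositiveDefiniteError,
    SingularCovarianceError,
)


class TestMakeCovariance:
    def test_fixed_pairwise(self):
        t = make_covariance("fixed_pairwise", 2, rho=0.2)
        np.testing.assert_allclose(t.matrix, [[1, 0.2], [0.2, 1]])

    def test_zero_rho_is_identity(self):
        t = make_covariance("fixed_pairwise", 3, rho=0.0)
        np.testing.assert_array_equal(t.matrix, np.eye(3))

    def test_block_power_structure(self):
        t = make_covariance("block_power", 50, rho=0.2, blocks=5)
        assert t.matrix[0, 1] == pytest.approx(0.2)
        assert t.matrix[0, 9] == pytest.approx(0.2**9)
        assert t.matrix[0, 10] == 0.0
        assert np.all(np.diag(t.matrix) == 1.0)

    def test_non_positive_definite_reports_eigenvalue(self):
        # pairwise rho below -1/(p-1) cannot be a correlation matrix
        with pytest.raises(NotPositiveDefiniteError) as err:
            make_covariance("fixed_pairwise", 5, rho=-0.5)
        assert err.value.min_eigenvalue is not None
        assert err.value.min_eigenvalue < 0

    def test_block_requires_divisibility(self):
        with pytest.raises(ValueError):
            make_covariance("block_power", 7, rho=0.2, blocks=3)


class TestLatentCorrEntry:
    def test_normal_pair_is_identity(self):
        n = MarginalSpec.normal()
        assert latent_corr_entry(n, n, 0.2) == pytest.approx(0.2, abs=1e-12)

    def test_bernoulli_normal_closed_form(self):
        r = latent_corr_entry(MarginalSpec.bernoulli(0.5), MarginalSpec.normal(), 0.2)
        expected = 0.2 * math.sqrt(0.25) / stats.norm.pdf(0.0)
        assert r == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize(
        "marg",
        [
            MarginalSpec.lognormal(),
            MarginalSpec.bernoulli(0.3),
            MarginalSpec.mixture_scale(0.2),
            MarginalSpec.mixture_shift(0.3),
        ],
        ids=["lognormal", "bernoulli", "mix_scale", "mix_shift"],
    )
    def test_solved_latent_reproduces_target_empirically(self, marg, rng):
        """Sampling through the solved latent correlation recovers the
        target Pearson correlation within Monte-Carlo error."""
        dgp = build_dgp(
            [marg, MarginalSpec.normal()], make_covariance("fixed_pairwise", 2, 0.2)
        )
        x = sample_features(dgp, 10**6, rng)
        assert np.corrcoef(x.T)[0, 1] == pytest.approx(0.2, abs=0.01)

    @pytest.mark.parametrize(
        "pair",
        [
            (MarginalSpec.bernoulli(0.3), MarginalSpec.bernoulli(0.6)),
            (MarginalSpec.bernoulli(0.4), MarginalSpec.lognormal()),
            (MarginalSpec.lognormal(), MarginalSpec.lognormal()),
            (MarginalSpec.mixture_scale(0.1), MarginalSpec.normal()),
        ],
        ids=["bern-bern", "bern-logn", "logn-logn", "mix-normal"],
    )
    def test_monotone_in_target(self, pair):
        grid = [-0.3, -0.1, 0.0, 0.1, 0.2, 0.4]
        solved = [latent_corr_entry(*pair, rho) for rho in grid]
        assert np.all(np.diff(solved) > 0)

    def test_infeasible_target_reports_range(self):
        with pytest.raises(FeasibilityError) as err:
            latent_corr_entry(MarginalSpec.bernoulli(0.01), MarginalSpec.normal(), 0.9)
        assert err.value.attainable is not None
        assert err.value.attainable[1] < 0.9


class TestBuildDgp:
    def test_all_normal_latent_equals_target(self):
        target = make_covariance("fixed_pairwise", 3, 0.35)
        dgp = build_dgp([MarginalSpec.normal()] * 3, target)
        np.testing.assert_array_equal(dgp.latent_corr, target.matrix)

    def test_bernoulli_latent_value(self):
        dgp = build_dgp(
            [MarginalSpec.normal(), MarginalSpec.bernoulli(0.5)],
            make_covariance("fixed_pairwise", 2, 0.2),
        )
        assert dgp.latent_corr[0, 1] == pytest.approx(0.2507, abs=5e-4)

    def test_infeasible_pair_raises(self):
        with pytest.raises(FeasibilityError):
            build_dgp(
                [MarginalSpec.normal(), MarginalSpec.bernoulli(0.01)],
                make_covariance("fixed_pairwise", 2, 0.9),
            )


class TestSampleFeatures:
    def test_mvn_correlation(self, rng, scenario_p2):
        x = sample_features(scenario_p2.dgp, 10**6, rng)
        assert np.corrcoef(x.T)[0, 1] == pytest.approx(0.2, abs=0.003)

    def test_lognormal_moments(self, rng):
        dgp = build_dgp([MarginalSpec.lognormal()], np.eye(1))
        x = sample_features(dgp, 10**6, rng)[:, 0]
        assert x.mean() == pytest.approx(math.exp(0.5), abs=0.02)
        assert x.var() == pytest.approx(math.e * (math.e - 1), rel=0.02)

    @pytest.mark.parametrize(
        "marg",
        [
            MarginalSpec.normal(1.5, 2.0),
            MarginalSpec.lognormal(),
            MarginalSpec.bernoulli(0.25),
            MarginalSpec.mixture_scale(0.15),
            MarginalSpec.mixture_shift(0.25),
        ],
        ids=["normal", "lognormal", "bernoulli", "mix_scale", "mix_shift"],
    )
    def test_marginal_moments_match_analytic(self, marg, rng):
        """Sample mean/variance within 4 Monte-Carlo standard errors."""
        n = 10**6
        dgp = build_dgp([marg], np.eye(1))
        x = sample_features(dgp, n, rng)[:, 0]
        se_mean = x.std() / math.sqrt(n)
        assert abs(x.mean() - marg.mean()) < 4 * se_mean
        # variance standard error via the fourth moment
        c = x - x.mean()
        se_var = math.sqrt(((c**2 - c.var()) ** 2).mean() / n)
        assert abs(x.var() - marg.var()) < 4 * se_var

    def test_mixture_with_zero_proportion_is_standard_normal(self, rng):
        dgp = build_dgp([MarginalSpec.mixture_shift(0.0)], np.eye(1))
        x = sample_features(dgp, 20000, rng)[:, 0]
        assert stats.kstest(x, "norm").pvalue > 0.01

    def test_all_normal_matches_direct_mvn_bitwise(self, scenario_p2):
        n = 500
        a = sample_features(scenario_p2.dgp, n, np.random.default_rng(9))
        b = sample_mvn(
            np.zeros(2), scenario_p2.dgp.covariance(), n, np.random.default_rng(9)
        )
        np.testing.assert_array_equal(a, b)


class TestEstimateDgp:
    def test_recovers_truth_at_large_n(self, rng, scenario_p2):
        x = sample_features(scenario_p2.dgp, 10**6, rng)
        fitted = estimate_dgp(x)
        np.testing.assert_allclose(
            fitted.covariance(), scenario_p2.dgp.covariance(), atol=0.01
        )
        np.testing.assert_allclose(fitted.mean_vector(), [0, 0], atol=0.01)

    def test_constant_column_is_singular(self):
        data = np.column_stack([np.random.default_rng(0).normal(size=50), np.ones(50)])
        with pytest.raises(SingularCovarianceError):
            estimate_dgp(data)

    def test_needs_more_rows_than_columns(self):
        with pytest.raises(ValueError):
            estimate_dgp(np.eye(3))


def test_read_matrix_formats(tmp_path):
    m = np.array([[1.0, 0.2], [0.2, 1.0]])
    ws = tmp_path / "ws.txt"
    ws.write_text("1 0.2\n0.2 1\n")
    cs = tmp_path / "cs.txt"
    cs.write_text("1,0.2\n0.2,1\n")
    np.testing.assert_array_equal(read_matrix(ws), m)
    np.testing.assert_array_equal(read_matrix(cs), m)
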