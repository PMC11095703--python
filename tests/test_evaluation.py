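"""Error aggregation, deviation grids, and the threshold scan."""

import numpy as np
import pytest

from plasmodesim import (
    ErrorSpec,
    MSEEstimate,
    OutcomeModel,
    StudyConfig,
    deviation_grid,
    error_records,
    get_scenario,
    run_study,
    summarize,
    threshold_scan,
    true_mse,
)
from plasmodesim.evaluation import DeviatedStudy, median_aggregate


def _est(values):
    return MSEEstimate(values=np.asarray(values, float), n_models=1, source="test")


TRUE = _est([1.0, 2.0, 4.0])


class TestSummarize:
    def test_perfect_estimates_have_zero_error(self):
        s = summarize([TRUE] * 5, TRUE)
        assert s.median_aggregate == 0.0

    def test_aggregate_is_mean_absolute_relative(self):
        s = summarize([_est([2.0, 1.0, 4.0])], TRUE)
        # component relative errors: +1, -1/2, 0 -> mean abs = 0.5
        assert s.aggregates[0] == pytest.approx(0.5)

    def test_median_is_robust_to_one_outlier(self):
        ests = [_est([1.1, 2.0, 4.0])] * 100 + [_est([1e6, 2.0, 4.0])]
        s = summarize(ests, TRUE)
        assert s.median_aggregate == pytest.approx(0.1 / 3)

    def test_zero_true_component_rejected_for_relative(self):
        with pytest.raises(ValueError):
            summarize([TRUE], _est([0.0, 2.0, 4.0]))

    def test_absolute_variant(self):
        s = summarize([_est([2.0, 1.0, 4.0])], TRUE, relative=False)
        assert s.aggregates[0] == pytest.approx(2.0 / 3)

    def test_error_records_roundtrip(self):
        df = error_records([_est([2.0, 1.0, 4.0])], TRUE)
        assert set(df.columns) == {"rep", "coefficient", "abs_error", "rel_error"}
        assert df.loc[df.coefficient == 0, "abs_error"].item() == pytest.approx(1.0)

    def test_relative_summary_invariant_to_joint_sigma_rescaling(self, scenario_p2):
        """Scaling sigma in truth and assumption jointly leaves relative
        errors unchanged (conditional-variance oracle, common seeds)."""
        results = {}
        for sd in (0.3, 3.0):
            ogm = OutcomeModel.unit(2, ErrorSpec(sd=sd))
            oracle = true_mse(
                scenario_p2.dgp, ogm, 100, 2000, np.random.default_rng(5)
            )
            cfg = StudyConfig(
                n=100,
                true_dgp=scenario_p2.dgp,
                assumed_ogm=ogm,
                n_mse=5,
                n_mod=100,
                seed=8,
            )
            results[sd] = summarize(run_study(cfg), oracle).aggregates
        np.testing.assert_allclose(results[0.3], results[3.0], rtol=1e-10)


class TestDeviationGrid:
    def test_coefficients_variant_one(self, scenario_p2):
        (dev,) = deviation_grid("coefficients_I", scenario_p2)
        np.testing.assert_allclose(dev.assumed_ogm.beta, [0.0, 0.5, 1.0])

    def test_error_sd_grid_contains_point_four(self, scenario_p2):
        values = [d.value for d in deviation_grid("error_sd", scenario_p2)]
        assert 0.4 in values

    def test_bernoulli_replaces_only_second_feature(self, scenario_p2):
        dev = deviation_grid("bernoulli", scenario_p2, grid=[0.4])[0]
        kinds = [m.kind for m in dev.assumed_dgp.marginals]
        assert kinds == ["normal", "bernoulli"]

    def test_mean_shift_targets_second_half(self):
        sc = get_scenario("p10n100rho0.2")
        dev = deviation_grid("mean_shift_second_half", sc, grid=[0.5])[0]
        np.testing.assert_allclose(
            dev.assumed_dgp.mean_vector(), [0] * 5 + [0.5] * 5
        )

    def test_mixture_contamination_matches_first_half_variance(self, scenario_p2):
        dev = deviation_grid("mixture_contamination", scenario_p2, grid=[0.1])[0]
        m_first, m_second = dev.assumed_dgp.marginals
        assert m_second.kind == "gaussian_mixture_scale"
        assert m_first.kind == "normal"
        assert m_first.var() == pytest.approx(m_second.var())

    def test_low_variance_grid_is_decreasing(self):
        sc = get_scenario("p50n100rho0.2")
        values = [d.value for d in deviation_grid("variance_second_half_low", sc)]
        assert values == sorted(values, reverse=True)

    def test_unknown_family_rejected(self, scenario_p2):
        with pytest.raises(KeyError):
            deviation_grid("nope", scenario_p2)

    def test_power_correlation_needs_p10_or_p50(self, scenario_p2):
        with pytest.raises(ValueError):
            deviation_grid("correlation_power", scenario_p2)


class TestThresholdScan:
    @staticmethod
    def _devs(values):
        sc = get_scenario("p2n100rho0.2")
        return [DeviatedStudy("f", v, sc.dgp, sc.ogm) for v in values]

    def test_first_crossing(self):
        devs = self._devs([0.1, 0.2, 0.3, 0.4])
        curve = {0.1: 0.01, 0.2: 0.05, 0.3: 0.02, 0.4: 0.50}
        res = threshold_scan("s", "f", devs, {"a": 0.04}, lambda d: curve[d.value])
        assert res["a"].first_exceeding_value == 0.2  # first, not largest

    def test_never_crossing_gives_none(self):
        devs = self._devs([0.1, 0.2])
        res = threshold_scan("s", "f", devs, {"a": 10.0}, lambda d: 0.01)
        assert res["a"].first_exceeding_value is None

    def test_zero_comparator_crossed_immediately(self):
        devs = self._devs([0.1, 0.2])
        res = threshold_scan("s", "f", devs, {"a": 0.0}, lambda d: 0.01)
        assert res["a"].first_exceeding_value == 0.1

    def test_monotone_in_comparator(self):
        devs = self._devs([0.1, 0.2, 0.3, 0.4])
        curve = {0.1: 0.01, 0.2: 0.02, 0.3: 0.03, 0.4: 0.04}
        res = threshold_scan(
            "s", "f", devs, {"small": 0.015, "big": 0.035}, lambda d: curve[d.value]
        )
        assert res["small"].first_exceeding_value <= res["big"].first_exceeding_value

    def test_lazy_evaluation_stops_after_all_crossed(self):
        devs = self._devs([0.1, 0.2, 0.3])
        calls = []

        def runner(d):
            calls.append(d.value)
            return 1.0

        threshold_scan("s", "f", devs, {"a": 0.5}, runner)
        assert calls == [0.1]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            threshold_scan("s", "f", [], {"a": 1.0}, lambda d: 0.0)
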