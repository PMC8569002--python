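"""Synthetic learning-cohort generator: closed forms, determinism, calibration."""

import dataclasses
import math

import numpy as np
import pytest

from surglearn.cohort import DEFAULT_TARGETS, METRIC_RANGES, CohortError
from surglearn.simulate import (
    LearningModelParams,
    MetricLearning,
    crossing_case,
    reference_params,
    simulate_cohort,
    tau_for_crossing,
)


def noiseless(params: LearningModelParams) -> LearningModelParams:
    return dataclasses.replace(
        params,
        metrics={
            m: dataclasses.replace(ml, sd_start=0.0, sd_end=0.0)
            for m, ml in params.metrics.items()
        },
    )


def single_metric_params(ml: MetricLearning, metric="flexion", **kw) -> LearningModelParams:
    defaults = dict(p_start=0.0, p_inf=0.0, tau_p=1.0, n_cases=50, seed=0)
    defaults.update(kw)
    return LearningModelParams(metrics={metric: ml}, **defaults)


class TestClosedForms:
    def test_noiseless_values_follow_mean_path(self):
        params = noiseless(reference_params(seed=1))
        cohort = simulate_cohort(params)
        for metric, ml in params.metrics.items():
            for rec in cohort:
                assert rec.outcomes[metric] == pytest.approx(
                    float(ml.mean_at(rec.case_index)), abs=1e-9
                )

    def test_exponential_mean_worked_example(self):
        ml = MetricLearning(80.0, 110.0, 10.0, 0.0, 0.0)
        assert float(ml.mean_at(11)) == pytest.approx(110 - 30 * math.exp(-1))

    def test_huge_tau_is_stationary(self):
        ml = MetricLearning(80.0, 110.0, 1e6, 0.0, 0.0)
        cohort = simulate_cohort(single_metric_params(ml))
        values = [rec.outcomes["flexion"] for rec in cohort]
        # first-order drift over 50 cases is 30 * 49 / 1e6 ≈ 0.0015
        assert all(v == pytest.approx(80.0, abs=0.01) for v in values)


class TestCrossingCase:
    def test_closed_form_example(self):
        ml = MetricLearning(80.0, 110.0, 10.0, 0.0, 0.0)
        params = single_metric_params(ml)
        assert crossing_case(params, "flexion", 95.0) == 8

    def test_midpoint_with_unit_tau(self):
        ml = MetricLearning(80.0, 110.0, 1.0, 0.0, 0.0)
        assert crossing_case(single_metric_params(ml), "flexion", 95.0) == 2

    def test_matches_scan_of_mean_path(self):
        ml = MetricLearning(60.0, 95.0, 7.3, 0.0, 0.0)
        params = single_metric_params(ml, metric="abduction")
        for target in (70.0, 80.0, 90.0, 94.0):
            k = crossing_case(params, "abduction", target)
            means = ml.mean_at(np.arange(1, 200))
            scan = int(np.argmax(means > target)) + 1
            assert k == scan

    def test_target_at_start_level_rejected(self):
        ml = MetricLearning(80.0, 110.0, 10.0, 0.0, 0.0)
        with pytest.raises(CohortError):
            crossing_case(single_metric_params(ml), "flexion", 80.0)

    @pytest.mark.parametrize("case", [5, 10, 20, 30])
    def test_tau_for_crossing_inverts_exactly(self, case):
        ml = MetricLearning(75.0, 110.0, 10.0, 0.0, 0.0)
        tau = tau_for_crossing(ml, 105.0, case)
        tuned = dataclasses.replace(ml, tau=tau)
        assert crossing_case(single_metric_params(tuned), "flexion", 105.0) == case


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = simulate_cohort(reference_params(seed=5))
        b = simulate_cohort(reference_params(seed=5))
        assert a == b

    def test_different_seeds_differ(self):
        a = simulate_cohort(reference_params(seed=1))
        b = simulate_cohort(reference_params(seed=2))
        assert a != b

    def test_params_roundtrip_yaml(self, tmp_path):
        params = reference_params(seed=9)
        path = tmp_path / "params.yaml"
        params.save(path)
        assert LearningModelParams.load(path) == params


class TestValidation:
    def test_wrong_way_asymptote_rejected(self):
        with pytest.raises(CohortError, match="improving side"):
            single_metric_params(MetricLearning(110.0, 80.0, 10.0, 0.0, 0.0))

    def test_operation_time_must_decrease(self):
        with pytest.raises(CohortError, match="improving side"):
            single_metric_params(
                MetricLearning(100.0, 150.0, 10.0, 0.0, 0.0), metric="operation_time"
            )

    def test_probability_ordering_enforced(self):
        with pytest.raises(CohortError):
            LearningModelParams(
                metrics={}, p_start=0.1, p_inf=0.4, tau_p=10, n_cases=10, seed=0
            )

    def test_sd_ordering_enforced(self):
        with pytest.raises(CohortError):
            MetricLearning(80.0, 110.0, 10.0, 1.0, 2.0)


class TestStatisticalCalibration:
    def test_empirical_means_track_mean_path(self):
        """Across 600 replicate cohorts the per-case sample mean stays within
        3 standard errors of the closed-form mean path."""
        params = reference_params()
        n_reps = 600
        checks = [("flexion", 1), ("flexion", 20), ("oss", 50)]
        draws = {key: np.empty(n_reps) for key in checks}
        occurred = np.zeros((n_reps, 3), dtype=bool)
        probe_cases = (1, 10, 40)
        for i in range(n_reps):
            cohort = simulate_cohort(dataclasses.replace(params, seed=10_000 + i))
            for metric, k in checks:
                draws[(metric, k)][i] = cohort[k - 1].outcomes[metric]
            for j, k in enumerate(probe_cases):
                occurred[i, j] = bool(cohort[k - 1].complications)
        for (metric, k), sample in draws.items():
            ml = params.metrics[metric]
            se = float(ml.sd_at(k)) / math.sqrt(n_reps)
            assert abs(sample.mean() - float(ml.mean_at(k))) < 3 * se
        for j, k in enumerate(probe_cases):
            p = float(params.p_at(k))
            se = math.sqrt(p * (1 - p) / n_reps)
            assert abs(occurred[:, j].mean() - p) < 3 * se

    def test_range_truncation_is_rare_under_defaults(self):
        """Clipping to valid ranges touches < 1% of draws, so the calibrated
        dispersions are honest."""
        params = reference_params()
        clipped = total = 0
        for i in range(200):
            cohort = simulate_cohort(dataclasses.replace(params, seed=20_000 + i))
            for rec in cohort:
                for metric, value in rec.outcomes.items():
                    lo, hi = METRIC_RANGES[metric]
                    bound = 1.0 if metric == "operation_time" else lo
                    clipped += value == bound or value == hi
                    total += 1
        assert clipped / total < 0.01

    def test_noiseless_reference_crossings_near_case_20(self):
        """Default calibration: every literature-target metric crosses its
        target close to case 20, the learning-phase length the charts are
        meant to exhibit."""
        params = reference_params()
        for metric in ("oss", "css", "flexion", "extension", "abduction",
                       "external_rotation"):
            c = crossing_case(params, metric, DEFAULT_TARGETS[metric].target)
            assert 15 <= c <= 25
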