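"""Cohort I/O, descriptive summaries and target-ledger configuration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surglearn.cohort import (
    DEFAULT_TARGETS,
    METRICS,
    CaseRecord,
    CohortError,
    Direction,
    TargetSource,
    TargetSpec,
    load_cohort,
    load_targets,
    metric_series,
    summarize_categorical,
    summarize_cohort,
    write_cohort,
)


class TestLoadCohort:
    def test_three_row_round_trip(self, cohort_csv):
        path = cohort_csv(
            [{"case_index": i, "oss": v} for i, v in zip((1, 2, 3), (30, 35, 40))]
        )
        records = load_cohort(path)
        assert [r.case_index for r in records] == [1, 2, 3]
        assert [r.outcomes["oss"] for r in records] == [30.0, 35.0, 40.0]

    def test_empty_cell_stays_missing(self, cohort_csv):
        path = cohort_csv(
            [
                {"case_index": 1, "oss": 30, "css": 40},
                {"case_index": 2, "oss": 35, "css": None},
            ]
        )
        records = load_cohort(path)
        assert records[1].outcomes["css"] is None  # not zero, not dropped

    def test_duplicate_case_index_rejected(self, cohort_csv):
        path = cohort_csv([{"case_index": i, "oss": 30} for i in (1, 1, 2)])
        with pytest.raises(CohortError, match="duplicate case_index 1"):
            load_cohort(path)

    def test_malformed_cell_names_row_and_column(self, cohort_csv):
        path = cohort_csv([{"case_index": 1, "oss": 30}, {"case_index": 2, "oss": "high"}])
        with pytest.raises(CohortError, match=r"row 2.*'oss'"):
            load_cohort(path)

    def test_out_of_range_value_rejected(self, cohort_csv):
        path = cohort_csv([{"case_index": 1, "oss": 49}])
        with pytest.raises(CohortError, match="outside valid range"):
            load_cohort(path)

    def test_non_contiguous_indices_rejected(self, cohort_csv):
        path = cohort_csv([{"case_index": i, "oss": 30} for i in (1, 3)])
        with pytest.raises(CohortError, match="contiguous"):
            load_cohort(path)

    def test_schema_column_mapping(self, cohort_csv):
        path = cohort_csv([{"case": 1, "oxford": 30}])
        records = load_cohort(path, schema={"case_index": "case", "oss": "oxford"})
        assert records[0].outcomes["oss"] == 30.0

    def test_write_then_load_is_identity(self, tmp_path, small_cohort):
        path = tmp_path / "out.csv"
        write_cohort(small_cohort, path)
        loaded = load_cohort(path)
        for orig, back in zip(small_cohort, loaded):
            assert back.case_index == orig.case_index
            for metric in ("oss", "css", "flexion"):
                assert back.outcomes.get(metric) == orig.outcomes.get(metric)


class TestMetricSeries:
    def test_missing_cases_renumbered_consecutively(self, small_cohort):
        positions, values = metric_series(small_cohort, "css")
        assert positions.tolist() == [1, 2]  # case 2 dropped, axis renumbered
        assert values.tolist() == [40.0, 55.0]

    def test_unknown_metric_rejected(self, small_cohort):
        with pytest.raises(CohortError):
            metric_series(small_cohort, "grip_strength")


class TestSummarize:
    @pytest.mark.parametrize(
        "values, median, q1, q3",
        [
            ([1, 2, 3, 4, 5], 3.0, 2.0, 4.0),  # type-7 linear interpolation
            ([7], 7.0, 7.0, 7.0),
            ([4, 4, 4, 4], 4.0, 4.0, 4.0),
        ],
    )
    def test_median_iqr(self, values, median, q1, q3):
        records = [CaseRecord(i + 1, {"oss": float(v)}) for i, v in enumerate(values)]
        summary = summarize_cohort(records).metrics["oss"]
        assert (summary.median, summary.q1, summary.q3) == (median, q1, q3)
        assert summary.q1 <= summary.median <= summary.q3

    def test_all_missing_metric_absent_not_zero(self):
        records = [CaseRecord(1, {"oss": 30.0, "css": None})]
        summary = summarize_cohort(records)
        assert "css" not in summary.metrics

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        values=st.lists(st.floats(0, 48), min_size=1, max_size=30),
        seed=st.integers(0, 2**16),
    )
    def test_permutation_invariant(self, values, seed):
        """Summaries ignore chronology entirely."""
        rng = np.random.default_rng(seed)
        shuffled = list(rng.permutation(values))
        a = [CaseRecord(i + 1, {"oss": v}) for i, v in enumerate(values)]
        b = [CaseRecord(i + 1, {"oss": v}) for i, v in enumerate(shuffled)]
        assert summarize_cohort(a).metrics["oss"] == summarize_cohort(b).metrics["oss"]

    def test_categorical_percentages_sum_to_100(self):
        counts = summarize_categorical(["a", "b", "a", "c", None, "a"])
        assert counts["a"] == (3, 60.0)
        assert sum(pct for _, pct in counts.values()) == pytest.approx(100.0, abs=0.1)


class TestTargets:
    def test_default_ledger(self):
        ledger = load_targets()
        expected = {
            "oss": 34.5,
            "css": 50.0,
            "flexion": 105.0,
            "extension": 40.0,
            "abduction": 90.0,
            "external_rotation": 15.0,
        }
        for metric, target in expected.items():
            assert ledger[metric].target == target
            assert ledger[metric].direction is Direction.HIGHER_BETTER
        assert ledger["operation_time"].source is TargetSource.COHORT_MEAN
        assert ledger["operation_time"].direction is Direction.LOWER_BETTER
        assert ledger["operation_time"].target is None
        assert ledger["complication"].target == 0.20

    def test_empty_config_gives_full_default_ledger(self, tmp_path):
        path = tmp_path / "targets.yaml"
        path.write_text("")
        assert load_targets(path) == DEFAULT_TARGETS

    def test_override_keeps_other_defaults(self, tmp_path):
        path = tmp_path / "targets.yaml"
        path.write_text("css:\n  target: 60\n")
        ledger = load_targets(path)
        assert ledger["css"].target == 60.0
        assert ledger["css"].direction is Direction.HIGHER_BETTER
        assert ledger["oss"] == DEFAULT_TARGETS["oss"]

    def test_json_config(self, tmp_path):
        path = tmp_path / "targets.json"
        path.write_text('{"oss": {"target": 30}}')
        assert load_targets(path)["oss"].target == 30.0

    def test_unknown_direction_rejected(self, tmp_path):
        path = tmp_path / "targets.yaml"
        path.write_text("css:\n  direction: sideways\n")
        with pytest.raises(CohortError, match="direction"):
            load_targets(path)

    def test_negative_angle_target_rejected(self, tmp_path):
        path = tmp_path / "targets.yaml"
        path.write_text("flexion:\n  target: -10\n")
        with pytest.raises(CohortError, match="negative target"):
            load_targets(path)

    def test_cohort_mean_spec_ignores_configured_number(self):
        spec = TargetSpec("operation_time", 120.0, Direction.LOWER_BETTER,
                          TargetSource.COHORT_MEAN)
        assert spec.target is None and not spec.resolved
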