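import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaboqc import (
    SimulationConfig,
    apply_feature_filters,
    blank_filter,
    compute_blank_ratio,
    compute_d_ratio,
    compute_rsd_qc,
    detect_outlier_samples,
    generate_experiment,
)
from metaboqc.peak_table import PeakTableError

from conftest import make_peak_table


def qc_blank_table(qc_values, blank_values, sample_values=None):
    """One-feature table with given QC / blank / study intensities."""
    sample_values = sample_values if sample_values is not None else [50.0, 60.0, 70.0]
    row = list(qc_values) + list(blank_values) + list(sample_values)
    classes = (
        ["qc"] * len(qc_values) + ["blank"] * len(blank_values) + ["sample"] * len(sample_values)
    )
    return make_peak_table(np.array([row], dtype=float), classes)


class TestBlankFilter:
    def test_ratio_exactly_three_retained(self):
        # QC median 3000, blank 80th percentile 1000 -> ratio 3.0, not < 3
        pt = qc_blank_table([3000, 3000, 3000], [1000, 1000, 1000])
        filtered, report = blank_filter(pt, ratio_threshold=3.0)
        assert report.feature_metrics.loc["F1", "blank_ratio"] == pytest.approx(3.0)
        assert filtered.n_features == 1

    def test_ratio_just_below_three_removed(self):
        pt2 = qc_blank_table([2999, 2999, 2999, 100], [1000, 1000, 1000], [5, 5, 5])
        clean_row = [9000.0] * 4 + [np.nan] * 3 + [9000.0] * 3  # absent from blanks
        extra = make_peak_table(
            np.vstack([pt2.intensities.to_numpy(), np.array(clean_row)]),
            list(pt2.samples["sample_class"]),
        )
        with pytest.raises(PeakTableError):
            blank_filter(pt2)  # sole feature removed -> empty table refused
        filtered, report = blank_filter(extra)
        assert report.feature_metrics.loc["F1", "blank_ratio"] < 3
        assert list(filtered.features.index) == ["F2"]

    def test_feature_absent_from_blanks_retained(self):
        pt = qc_blank_table([100, 100, 100], [np.nan, np.nan, 0.0])
        ratios = compute_blank_ratio(pt)
        assert np.isinf(ratios["F1"])
        filtered, _ = blank_filter(pt)
        assert filtered.n_features == 1

    def test_no_blanks_flags_nothing(self):
        pt = qc_blank_table([100, 100, 100], [])
        filtered, report = blank_filter(pt)
        assert filtered.n_features == 1
        assert not report.feature_metrics["uninformative_blank"].any()

    def test_no_qcs_is_error(self):
        pt = make_peak_table(np.ones((1, 4)) * 10, ["sample"] * 4)
        with pytest.raises(PeakTableError, match="QC"):
            compute_blank_ratio(pt)

    def test_idempotent(self, small_config):
        pt, _ = generate_experiment(small_config)
        once, _ = blank_filter(pt)
        twice, report = blank_filter(once)
        assert list(twice.features.index) == list(once.features.index)
        assert not report.feature_metrics["uninformative_blank"].any()


class TestDRatio:
    @pytest.mark.parametrize(
        "qc, study, expected",
        [
            ([10, 10, 10], [5, 10, 15], 0.0),  # MAD_qc = 0
            ([10, 12, 14], [5, 10, 15, 20, 25], 40.0),  # MAD 2 / MAD 5
            ([1, 2, 3], [7, 7, 7], np.inf),  # no biological variation
        ],
    )
    def test_hand_computed_values(self, qc, study, expected):
        pt = qc_blank_table(qc, [], study)
        d = compute_d_ratio(pt)["F1"]
        if np.isinf(expected):
            assert np.isinf(d)
        else:
            assert d == pytest.approx(expected)

    @given(c=st.floats(min_value=1e-3, max_value=1e6))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        qc = list(rng.uniform(90, 110, 5))
        study = list(rng.uniform(50, 200, 8))
        base = compute_d_ratio(qc_blank_table(qc, [], study))["F1"]
        scaled = compute_d_ratio(
            qc_blank_table([v * c for v in qc], [], [v * c for v in study])
        )["F1"]
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_too_few_qcs_error(self):
        pt = qc_blank_table([10, 10], [])
        with pytest.raises(PeakTableError, match="QC"):
            compute_d_ratio(pt)

    def test_both_mads_zero_warns_and_returns_zero(self):
        pt = qc_blank_table([7, 7, 7], [], [7, 7, 7])
        with pytest.warns(UserWarning, match="zero MAD"):
            d = compute_d_ratio(pt)
        assert d["F1"] == 0.0


class TestRsdQc:
    def test_constant_qcs_zero(self):
        assert compute_rsd_qc(qc_blank_table([100, 100, 100], []))["F1"] == 0.0

    def test_hand_computed_ten_percent(self):
        # sample sd 10 (n-1 denominator), mean 100
        assert compute_rsd_qc(qc_blank_table([90, 100, 110], []))["F1"] == pytest.approx(10.0)

    def test_single_qc_error(self):
        with pytest.raises(PeakTableError):
            compute_rsd_qc(qc_blank_table([100], []))

    def test_noiseless_simulation_gives_zero_rsd_and_d_ratio(self):
        cfg = SimulationConfig(
            n_features=10,
            noise_cv=0,
            drift_magnitude=0,
            drift_jitter=0,
            n_batches=2,
            n_passages=2,
            n_treatments=2,
            replicates_per_cell=2,
            n_blanks=0,
            seed=9,
        )
        pt, _ = generate_experiment(cfg)
        assert np.allclose(compute_rsd_qc(pt), 0, atol=1e-9)
        assert np.allclose(compute_d_ratio(pt), 0, atol=1e-9)


class TestFeatureFilters:
    def _table_with_d_ratios(self):
        # three features engineered to D-ratio* 5%, 20%, 25%:
        # study values {0,10,20,30,40} -> MAD_sample 10; QC MADs 0.5, 2, 2.5
        rows = [
            [10, 10.5, 9.5, 10.6, 9.4] + [0, 10, 20, 30, 40],
            [10, 12, 8, 12.4, 7.6] + [0, 10, 20, 30, 40],
            [10, 12.5, 7.5, 13, 7] + [0, 10, 20, 30, 40],
        ]
        classes = ["qc"] * 5 + ["sample"] * 5
        return make_peak_table(np.array(rows, dtype=float), classes)

    def test_boundary_twenty_percent_retained(self):
        pt = self._table_with_d_ratios()
        d = compute_d_ratio(pt)
        assert list(d.round(6)) == [5.0, 20.0, 25.0]
        filtered, report = apply_feature_filters(pt, d_ratio_max=20, rsd_max=np.inf)
        assert list(filtered.features.index) == ["F1", "F2"]  # 20 is not > 20
        assert report.feature_metrics["high_d_ratio"].tolist() == [False, False, True]

    def test_disabled_thresholds_are_identity(self):
        pt = self._table_with_d_ratios()
        filtered, _ = apply_feature_filters(pt, d_ratio_max=np.inf, rsd_max=np.inf)
        assert list(filtered.features.index) == list(pt.features.index)

    def test_all_removed_is_diagnostic_error(self):
        pt = self._table_with_d_ratios()
        with pytest.raises(PeakTableError, match="all features removed"):
            apply_feature_filters(pt, d_ratio_max=1e-6, rsd_max=1e-6)


class TestOutlierSamples:
    def test_equal_totals_no_flags(self):
        pt = make_peak_table(np.full((3, 10), 100.0), ["sample"] * 10)
        assert not detect_outlier_samples(pt)["outlier_flag"].any()

    def test_single_low_sample_flagged(self):
        vals = np.full((2, 10), 500.0)
        vals[:, 4] = 5.0  # one failed extraction
        pt = make_peak_table(vals, ["sample"] * 10)
        flags = detect_outlier_samples(pt, k=3)["outlier_flag"]
        assert flags.sum() == 1 and flags["X5"]

    def test_infinite_k_disables(self):
        vals = np.full((2, 10), 500.0)
        vals[:, 4] = 5.0
        pt = make_peak_table(vals, ["sample"] * 10)
        assert not detect_outlier_samples(pt, k=np.inf)["outlier_flag"].any()

    def test_qcs_never_flagged(self):
        vals = np.full((2, 12), 500.0)
        vals[:, :2] = 1.0  # tiny QCs (e.g. diluted) must not be excluded
        pt = make_peak_table(vals, ["qc"] * 2 + ["sample"] * 10)
        screen = detect_outlier_samples(pt, k=3)
        assert not screen.loc[screen["sample_class"] == "qc", "outlier_flag"].any()
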