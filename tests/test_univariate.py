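import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaboqc import (
    SimulationConfig,
    fold_change_consistency,
    generate_experiment,
    intersect_significant,
    results_frame,
    ttest_contrast,
)
from metaboqc.univariate import StratumTestResult

from conftest import make_peak_table


def two_group_table(values_a, values_b, treatment_b="APAP"):
    n_a, n_b = len(values_a), len(values_b)
    return make_peak_table(
        np.array([list(values_a) + list(values_b)], dtype=float),
        ["sample"] * (n_a + n_b),
        treatments=["CA"] * n_a + [treatment_b] * n_b,
    )


def fake_result(fid, batch, p, fc, passage="P18"):
    return StratumTestResult(
        feature_id=fid,
        stratum=(batch, passage),
        contrast="APAP-vs-CA",
        mean_treatment=1.0,
        mean_control=1.0,
        t_statistic=0.0,
        p_value=p,
        fold_change=fc,
        significant=p < 0.05,
    )


class TestTtestContrast:
    def test_identical_groups_null_result(self):
        pt = two_group_table([10, 10, 10, 10], [10, 10, 10, 10])
        results, _ = ttest_contrast(pt, "APAP", "CA", strata="batch")
        r = results[0]
        assert (r.t_statistic, r.p_value, r.fold_change) == (0.0, 1.0, 1.0)
        assert not r.significant

    def test_separated_groups_strongly_significant(self):
        rng = np.random.default_rng(0)
        a = 20 + rng.normal(0, 0.01, 4)  # control CA
        b = 10 + rng.normal(0, 0.01, 4)  # treatment
        pt = two_group_table(a, b)
        results, _ = ttest_contrast(pt, "APAP", "CA", strata="batch")
        r = results[0]
        assert r.p_value < 1e-6
        assert r.fold_change == pytest.approx(0.5, abs=0.01)
        # closed-form pooled-variance t for the two-sample case
        t_ref, p_ref = stats.ttest_ind(b, a, equal_var=True)
        assert r.t_statistic == pytest.approx(t_ref)
        assert r.p_value == pytest.approx(p_ref)

    def test_full_design_yields_twenty_strata(self):
        cfg = SimulationConfig(
            n_features=3,
            n_batches=5,
            n_passages=4,
            n_treatments=3,
            replicates_per_cell=2,
            n_blanks=0,
            seed=1,
        )
        pt, _ = generate_experiment(cfg)
        results, skipped = ttest_contrast(pt, "APAP", "CA", strata="batch_passage")
        strata = {r.stratum for r in results}
        assert len(strata) == 20  # 5 batches x 4 passages
        assert not skipped

    def test_small_stratum_skipped(self):
        pt = two_group_table([10, 11, 12], [20])  # one treated sample only
        results, skipped = ttest_contrast(pt, "APAP", "CA", strata="batch")
        assert results == [] and skipped == [("B1",)]

    def test_alpha_monotonicity(self):
        cfg = SimulationConfig(
            n_features=20,
            n_batches=2,
            n_passages=2,
            n_treatments=2,
            replicates_per_cell=3,
            n_blanks=0,
            seed=2,
        )
        pt, _ = generate_experiment(cfg)
        r_small, _ = ttest_contrast(pt, "APAP", "CA", strata="batch", alpha=0.01)
        r_large, _ = ttest_contrast(pt, "APAP", "CA", strata="batch", alpha=0.10)
        sig_small = {(r.feature_id, r.stratum) for r in r_small if r.significant}
        sig_large = {(r.feature_id, r.stratum) for r in r_large if r.significant}
        assert sig_small <= sig_large


class TestIntersections:
    def test_enumerable_toy_case(self):
        results = [
            fake_result("A", "B1", 0.01, 1.2),
            fake_result("B", "B1", 0.01, 1.2),
            fake_result("B", "B2", 0.01, 1.2),
            fake_result("C", "B2", 0.01, 1.2),
        ]
        summary = intersect_significant(results)
        assert summary.sets == {"B1": {"A", "B"}, "B2": {"B", "C"}}
        assert summary.in_all == {"B"}
        assert summary.exactly_k == {1: 2, 2: 1}
        assert summary.at_least_k == {1: 3, 2: 1}

    def test_disjoint_sets_empty_intersection(self):
        results = [fake_result("A", "B1", 0.01, 1.2), fake_result("B", "B2", 0.01, 1.2)]
        assert intersect_significant(results).in_all == set()

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(3)
        batches = [f"B{i}" for i in range(4)]
        feats = [f"F{i}" for i in range(25)]
        sig = rng.random((25, 4)) < 0.4
        results = [
            fake_result(f, b, 0.01 if sig[i, j] else 0.5, 1.1)
            for i, f in enumerate(feats)
            for j, b in enumerate(batches)
        ]
        summary = intersect_significant(results)
        counts = sig.sum(axis=1)
        for k in range(1, 5):
            assert summary.exactly_k[k] == int((counts == k).sum())
            assert summary.at_least_k[k] == int((counts >= k).sum())
        assert summary.in_all == {f for i, f in enumerate(feats) if counts[i] == 4}

    def test_annotation_collapses_to_unique_metabolites(self):
        # two features annotated to the same metabolite count once
        ann = pd.Series({"F1": "glycerophosphocholine", "F2": "glycerophosphocholine"})
        results = [
            fake_result("F1", "B1", 0.01, 1.2),
            fake_result("F2", "B1", 0.01, 1.2),
            fake_result("F1", "B2", 0.01, 1.2),
            fake_result("F2", "B2", 0.01, 1.2),
        ]
        plain = intersect_significant(results)
        unique = intersect_significant(results, annotation=ann)
        assert len(plain.in_all) == 2
        assert len(unique.in_all) == 1

    def test_single_batch_rejected(self):
        with pytest.raises(ValueError):
            intersect_significant([fake_result("A", "B1", 0.01, 1.2)])


class TestFoldChangeConsistency:
    def test_same_side_agreement(self):
        results = [fake_result("A", f"B{i}", 0.01, fc) for i, fc in enumerate([1.2, 1.5, 1.1])]
        frame = fold_change_consistency(results)
        assert bool(frame.loc["A", "direction_agreement"])

    def test_opposite_sides_disagree(self):
        results = [fake_result("A", f"B{i}", 0.01, fc) for i, fc in enumerate([1.2, 0.8])]
        assert not fold_change_consistency(results).loc["A", "direction_agreement"]

    def test_responsive_features_agree_across_strata(self):
        cfg = SimulationConfig(
            n_features=20,
            n_batches=3,
            n_passages=2,
            n_treatments=2,
            replicates_per_cell=4,
            treatment_effect_sd=0.5,
            frac_treatment_responsive=1.0,
            noise_cv=0.1,
            drift_magnitude=0,
            n_blanks=0,
            seed=4,
        )
        pt, truth = generate_experiment(cfg)
        results, _ = ttest_contrast(pt, "APAP", "CA", strata="batch_passage")
        # features with a strong log effect should keep their FC direction
        strong = truth.treatment_effect_sizes["APAP"].abs() > 0.4
        frame = fold_change_consistency(results, features=list(strong.index[strong]))
        assert frame["direction_agreement"].mean() >= 0.9


class TestResultsFrame:
    def test_metadata_flags_uncorrected_pvalues(self):
        results = [fake_result("A", "B1", 0.01, 1.2)]
        df = results_frame(results)
        assert "raw p" in df.attrs["multiple_testing"]
        assert set(df.columns) >= {"feature_id", "p_value", "fold_change", "significant"}
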