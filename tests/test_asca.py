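import numpy as np
import pandas as pd
import pytest

from metaboqc import (
    AscaDesign,
    asca_decompose,
    asca_permutation_test,
    autoscale,
    pca_scores,
)


def balanced_design(n_b=2, n_p=2, n_t=2, reps=2, seed=0):
    rows = [
        (f"s{i}", t, b, p)
        for i, (b, p, t, r) in enumerate(
            (b, p, t, r)
            for b in range(n_b)
            for p in range(n_p)
            for t in range(n_t)
            for r in range(reps)
        )
    ]
    labels = pd.DataFrame(
        {
            "treatment": [f"T{t}" for _, t, _, _ in rows],
            "batch": [f"B{b}" for _, _, b, _ in rows],
            "passage": [f"P{p}" for _, _, _, p in rows],
        },
        index=[r[0] for r in rows],
    )
    rng = np.random.default_rng(seed)
    return labels, rng


def brute_force_effects(x, labels):
    """Independent oracle: effect matrices by explicit per-cell averaging."""
    centred = x - x.mean(axis=0)
    effects = {}
    for f in ("treatment", "batch", "passage"):
        e = np.zeros_like(centred)
        for lev in labels[f].unique():
            rows = (labels[f] == lev).to_numpy()
            e[rows] = centred[rows].mean(axis=0)
        effects[f] = e
    for a, b in (("treatment", "batch"), ("treatment", "passage"), ("batch", "passage")):
        e = np.zeros_like(centred)
        for la in labels[a].unique():
            for lb in labels[b].unique():
                rows = ((labels[a] == la) & (labels[b] == lb)).to_numpy()
                if rows.any():
                    e[rows] = centred[rows].mean(axis=0)
        effects[f"{a}x{b}"] = e - effects[a] - effects[b]
    return effects


class TestAutoscale:
    def test_zero_mean_unit_variance(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.lognormal(8, 1, (20, 7)))
        scaled, params = autoscale(m)
        assert np.allclose(scaled.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(scaled.var(axis=0, ddof=1), 1, atol=1e-12)

    def test_constant_feature_dropped_with_warning(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="b"):
            scaled, _ = autoscale(m)
        assert list(scaled.columns) == ["a"]

    def test_stored_parameters_reproduce_transform(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.uniform(1, 100, (15, 4)))
        scaled, params = autoscale(m)
        redo = (m[params.index] - params["mean"]) / params["sd"]
        pd.testing.assert_frame_equal(scaled, redo)


class TestDecompose:
    def test_matches_brute_force_oracle(self):
        labels, rng = balanced_design(seed=3)
        x = rng.normal(0, 1, (len(labels), 6))
        design = AscaDesign(labels)
        res = asca_decompose(pd.DataFrame(x, index=labels.index), design, with_sca=False)
        oracle = brute_force_effects(x, labels)
        for name, e in oracle.items():
            assert np.abs(res.effects[name].to_numpy() - e).max() < 1e-10
        total = sum(res.effect_percent.values()) + res.residual_percent
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_pure_batch_effect_is_all_batch(self):
        labels, _ = balanced_design()
        a = 2.5
        x = np.where((labels["batch"] == "B0").to_numpy()[:, None], a, -a) * np.ones((1, 4))
        res = asca_decompose(pd.DataFrame(x, index=labels.index), AscaDesign(labels), with_sca=False)
        assert res.effect_percent["batch"] == pytest.approx(100.0)
        for name, pct in res.effect_percent.items():
            if name != "batch":
                assert pct == pytest.approx(0.0, abs=1e-10)

    def test_balanced_effects_orthogonal(self):
        labels, rng = balanced_design(n_b=3, n_p=2, n_t=2, reps=3, seed=4)
        x = rng.normal(0, 1, (len(labels), 5))
        res = asca_decompose(pd.DataFrame(x, index=labels.index), AscaDesign(labels), with_sca=False)
        mats = list(res.effects.values())
        scale = max(float((m.to_numpy() ** 2).sum()) for m in mats)
        for i in range(len(mats)):
            for j in range(i + 1, len(mats)):
                inner = float((mats[i].to_numpy() * mats[j].to_numpy()).sum())
                assert abs(inner) < 1e-8 * scale

    def test_single_level_factor_dropped(self):
        labels, rng = balanced_design()
        labels["passage"] = "P0"
        with pytest.warns(UserWarning, match="passage"):
            design = AscaDesign(labels)
        x = rng.normal(0, 1, (len(labels), 3))
        res = asca_decompose(pd.DataFrame(x, index=labels.index), design, with_sca=False)
        assert "passage" not in res.effect_percent
        assert design.dropped_terms == ["passage"]

    def test_sca_scores_span_effect(self):
        labels, rng = balanced_design(seed=6)
        x = rng.normal(0, 1, (len(labels), 6))
        res = asca_decompose(pd.DataFrame(x, index=labels.index), AscaDesign(labels))
        for name, sca in res.sca.items():
            recon = sca.scores.to_numpy() @ sca.loadings.to_numpy().T
            kept = sca.variance_percent.sum()
            if kept > 99.999:
                assert np.allclose(recon, res.effects[name].to_numpy(), atol=1e-8)


class TestPermutation:
    def test_constructed_batch_effect_minimum_p(self):
        labels, rng = balanced_design(n_b=2, n_p=2, n_t=2, reps=3)
        signal = np.where((labels["batch"] == "B0").to_numpy()[:, None], 1.0, -1.0)
        x = signal * np.ones((1, 5)) + rng.normal(0, 0.01, (len(labels), 5))
        n_perm = 200
        p = asca_permutation_test(
            pd.DataFrame(x, index=labels.index), AscaDesign(labels), n_perm=n_perm, seed=0
        )
        assert p["batch"] == pytest.approx(1 / (n_perm + 1))

    def test_minimum_p_with_500_permutations(self):
        # the smallest attainable p at the default permutation count
        labels, rng = balanced_design(n_b=2, n_p=2, n_t=2, reps=2)
        signal = np.where((labels["batch"] == "B0").to_numpy()[:, None], 1.0, -1.0)
        x = signal * np.ones((1, 3)) + rng.normal(0, 0.01, (len(labels), 3))
        p = asca_permutation_test(
            pd.DataFrame(x, index=labels.index), AscaDesign(labels), n_perm=500, seed=1
        )
        assert p["batch"] == pytest.approx(1 / 501)
        assert round(p["batch"], 3) == 0.002

    def test_deterministic_given_seed(self):
        labels, rng = balanced_design(seed=8)
        x = rng.normal(0, 1, (len(labels), 4))
        m = pd.DataFrame(x, index=labels.index)
        d = AscaDesign(labels)
        assert asca_permutation_test(m, d, 50, seed=5) == asca_permutation_test(m, d, 50, seed=5)

    def test_invalid_permutation_count(self):
        labels, rng = balanced_design()
        x = pd.DataFrame(rng.normal(0, 1, (len(labels), 3)), index=labels.index)
        with pytest.raises(ValueError):
            asca_permutation_test(x, AscaDesign(labels), n_perm=0)


class TestPca:
    def test_rank_one_matrix_single_component(self):
        u = np.outer(np.arange(1, 9, dtype=float), [1.0, 2.0, 3.0])
        m = pd.DataFrame(u)
        scores, loadings, var_pct = pca_scores(m, 1)
        assert var_pct[0] == pytest.approx(100.0)

    def test_rotation_invariance_of_variances(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, (12, 5))
        q, _ = np.linalg.qr(rng.normal(0, 1, (5, 5)))
        _, _, v1 = pca_scores(pd.DataFrame(x), 5)
        _, _, v2 = pca_scores(pd.DataFrame(x @ q), 5)
        assert np.allclose(v1, v2, atol=1e-8)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, (10, 4))
        m = pd.DataFrame(x)
        scores, loadings, _ = pca_scores(m, 4)
        recon = scores.to_numpy() @ loadings.to_numpy().T
        centred = x - x.mean(axis=0)
        assert np.abs(recon - centred).max() < 1e-10

    def test_excess_components_truncated_with_warning(self):
        x = pd.DataFrame(np.outer(np.arange(6.0), [1.0, 2.0]))
        with pytest.warns(UserWarning, match="rank"):
            scores, _, _ = pca_scores(x, 2)
        assert scores.shape[1] == 1
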