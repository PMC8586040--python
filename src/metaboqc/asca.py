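"""ANOVA simultaneous component analysis (ASCA) and PCA utilities.

ASCA partitions a multivariate data matrix X (samples x features) according
to the experimental design,

    X = Mean + X_Treatment + X_Batch + X_Passage
             + X_TreatmentxBatch + X_TreatmentxPassage + X_BatchxPassage + E,

estimating each term by (cell-)level means of the mean-centred data in the
fixed order mean -> main effects -> two-way interactions -> residual. On a
balanced design the effect matrices are mutually orthogonal, so the sums of
squares are additive and each term's share of the total mean-removed sum of
squares ("effect percent") sums to 100 with the residual. On an unbalanced
design (e.g. after outlier-sample removal) the same estimators are used and
the shares may not sum exactly to 100; results carry a note.

Significance of each term is assessed by permutation: the tested term's
labels are shuffled across samples (for an interaction, one parent factor is
shuffled within the levels of the other, holding main-effect structure
fixed), the term's sum of squares recomputed, and the one-sided p value is
``(count(SSQ_perm >= SSQ_obs) + 1) / (n_perm + 1)``.

A simultaneous component analysis (an SVD) of each effect matrix provides
per-effect scores and loadings for visualising what the effect does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peak_table import PeakTable

__all__ = [
    "AscaDesign",
    "AscaResult",
    "ScaComponents",
    "autoscale",
    "study_matrix",
    "asca_decompose",
    "asca_permutation_test",
    "pca_scores",
]

MAIN_FACTORS = ("treatment", "batch", "passage")
INTERACTIONS = (("treatment", "batch"), ("treatment", "passage"), ("batch", "passage"))


def _term_name(term) -> str:
    return term if isinstance(term, str) else f"{term[0]}x{term[1]}"


@dataclass
class AscaDesign:
    """Factor labels of the study samples and the ordered model terms."""

    labels: pd.DataFrame  # index = sample ids; columns = treatment, batch, passage
    terms: list = field(default_factory=list)
    dropped_terms: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(MAIN_FACTORS) - set(self.labels.columns)
        if missing:
            raise ValueError(f"design lacks factors: {sorted(missing)}")
        if not self.terms:
            usable = [f for f in MAIN_FACTORS if self.labels[f].nunique() >= 2]
            self.dropped_terms = [f for f in MAIN_FACTORS if f not in usable]
            self.terms = list(usable) + [
                (a, b) for a, b in INTERACTIONS if a in usable and b in usable
            ]
            if self.dropped_terms:
                warnings.warn(
                    f"factors with a single level dropped from the model: "
                    f"{self.dropped_terms}",
                    stacklevel=2,
                )

    @classmethod
    def from_peak_table(cls, pt: PeakTable) -> "AscaDesign":
        study = pt.samples[pt.samples["sample_class"] == "sample"]
        return cls(study[list(MAIN_FACTORS)].astype(str))

    @property
    def is_balanced(self) -> bool:
        joint = self.labels.astype(str).agg("||".join, axis=1)
        return joint.value_counts().nunique() == 1


@dataclass
class ScaComponents:
    """SVD of one effect matrix: scores, loadings, per-component variance %."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_percent: np.ndarray


@dataclass
class AscaResult:
    """Effect matrices, percent contributions, p values and SCA per term."""

    effects: dict[str, pd.DataFrame]
    effect_percent: dict[str, float]
    residual_percent: float
    total_ssq: float
    balanced: bool
    permutation_p: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    sca: dict[str, ScaComponents] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Term / effect % / p value summary, residual last."""
        rows = [
            {
                "term": name,
                "effect_percent": pct,
                "p_value": self.permutation_p.get(name, np.nan),
            }
            for name, pct in self.effect_percent.items()
        ]
        rows.append(
            {"term": "residuals", "effect_percent": self.residual_percent, "p_value": np.nan}
        )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #


def study_matrix(pt: PeakTable, log: bool = True) -> pd.DataFrame:
    """Study-sample intensity matrix as samples x features, optionally logged.

    Peak areas are positive and heteroscedastic; a natural-log transform
    puts the multiplicative factor structure on an additive scale before
    decomposition. Non-positive or missing entries become NaN.
    """
    x = pt.intensity_of("sample").T.astype(float)
    if log:
        with np.errstate(divide="ignore", invalid="ignore"):
            x = pd.DataFrame(
                np.where(x.to_numpy() > 0, np.log(x.to_numpy()), np.nan),
                index=x.index,
                columns=x.columns,
            )
    return x


def autoscale(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Column-wise autoscaling: subtract mean, divide by sd (n-1 denominator).

    Zero-variance and all-missing columns are dropped with a warning naming
    them. Returns the scaled matrix and the parameters (mean, sd per kept
    feature) needed to apply the identical transform elsewhere or invert it.
    """
    mean = matrix.mean(axis=0, skipna=True)
    sd = matrix.std(axis=0, ddof=1, skipna=True)
    bad = sd.index[(sd == 0) | sd.isna()]
    if len(bad):
        warnings.warn(
            f"dropping {len(bad)} zero-variance/all-missing features before "
            f"autoscaling: {list(bad[:10])}{'...' if len(bad) > 10 else ''}",
            stacklevel=2,
        )
    keep = sd.index[(sd > 0) & sd.notna()]
    scaled = (matrix[keep] - mean[keep]) / sd[keep]
    params = pd.DataFrame({"mean": mean[keep], "sd": sd[keep]})
    return scaled, params


def _level_mean_rows(x: np.ndarray, codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Replace each row by its group's mean row (vectorised groupby)."""
    sums = np.zeros((n_levels, x.shape[1]))
    np.add.at(sums, codes, x)
    counts = np.bincount(codes, minlength=n_levels).astype(float)
    return (sums / counts[:, None])[codes]


def _encode(labels: np.ndarray) -> tuple[np.ndarray, int]:
    levels, codes = np.unique(labels, return_inverse=True)
    return codes, len(levels)


def _effect_matrices(
    centred: np.ndarray, labels: dict[str, np.ndarray], terms
) -> dict[str, np.ndarray]:
    mains: dict[str, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for term in terms:
        if isinstance(term, str):
            codes, k = _encode(labels[term])
            mains[term] = out[_term_name(term)] = _level_mean_rows(centred, codes, k)
    for term in terms:
        if not isinstance(term, str):
            a, b = term
            joint = np.char.add(
                np.char.add(labels[a].astype(str), "||"), labels[b].astype(str)
            )
            codes, k = _encode(joint)
            cell = _level_mean_rows(centred, codes, k)
            out[_term_name(term)] = cell - mains[a] - mains[b]
    return out


def asca_decompose(
    matrix: pd.DataFrame,
    design: AscaDesign,
    sca_variance_target: float = 0.95,
    with_sca: bool = True,
) -> AscaResult:
    """Decompose a (scaled) study matrix into per-term effect matrices.

    ``matrix`` is samples x features, already transformed/scaled as desired;
    rows must match the design's sample ids. Missing values are not allowed
    here — impute or drop beforehand.
    """
    x = matrix.loc[design.labels.index].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("ASCA input contains missing values; impute or drop first")
    labels = {f: design.labels[f].to_numpy() for f in MAIN_FACTORS if f in design.labels}
    centred = x - x.mean(axis=0, keepdims=True)
    total = float((centred**2).sum())
    if total == 0:
        raise ValueError("matrix has no variation after mean removal")

    effects_np = _effect_matrices(centred, labels, design.terms)
    residual = centred - sum(effects_np.values())
    effect_percent = {
        name: float((e**2).sum()) / total * 100.0 for name, e in effects_np.items()
    }
    result = AscaResult(
        effects={
            name: pd.DataFrame(e, index=design.labels.index, columns=matrix.columns)
            for name, e in effects_np.items()
        },
        effect_percent=effect_percent,
        residual_percent=float((residual**2).sum()) / total * 100.0,
        total_ssq=total,
        balanced=design.is_balanced,
    )
    if with_sca:
        for name, e in effects_np.items():
            result.sca[name] = _sca(e, design.labels.index, matrix.columns, sca_variance_target)
    return result


def _sca(
    effect: np.ndarray, sample_index, feature_index, variance_target: float
) -> ScaComponents:
    u, s, vt = np.linalg.svd(effect, full_matrices=False)
    var = s**2
    if var.sum() == 0:
        var_pct = np.zeros(1)
        n_keep = 1
    else:
        var_pct = var / var.sum() * 100.0
        cum = np.cumsum(var_pct) / 100.0
        n_keep = max(2, int(np.searchsorted(cum, variance_target) + 1))
        n_keep = min(n_keep, len(s))
    cols = [f"PC{i + 1}" for i in range(n_keep)]
    return ScaComponents(
        scores=pd.DataFrame((u * s)[:, :n_keep], index=sample_index, columns=cols),
        loadings=pd.DataFrame(vt[:n_keep].T, index=feature_index, columns=cols),
        variance_percent=var_pct[:n_keep],
    )


def _term_ssq(centred: np.ndarray, labels: dict[str, np.ndarray], term) -> float:
    """Sum of squares of one term under the sequential cell-mean scheme."""
    if isinstance(term, str):
        codes, k = _encode(labels[term])
        return float((_level_mean_rows(centred, codes, k) ** 2).sum())
    a, b = term
    ca, ka = _encode(labels[a])
    cb, kb = _encode(labels[b])
    joint = ca.astype(np.int64) * kb + cb
    cell = _level_mean_rows(centred, *_encode(joint))
    main_a = _level_mean_rows(centred, ca, ka)
    main_b = _level_mean_rows(centred, cb, kb)
    return float(((cell - main_a - main_b) ** 2).sum())


def asca_permutation_test(
    matrix: pd.DataFrame,
    design: AscaDesign,
    n_perm: int = 500,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation p value per model term.

    Main effects: the factor's label column is shuffled across samples.
    Interactions A x B: A's labels are shuffled within each level of B, which
    preserves both factors' main-effect structure while destroying their
    joint structure. Deterministic given ``seed``. The smallest attainable
    p value is ``1 / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    x = matrix.loc[design.labels.index].to_numpy(dtype=float)
    centred = x - x.mean(axis=0, keepdims=True)
    labels = {f: design.labels[f].to_numpy() for f in MAIN_FACTORS if f in design.labels}

    p_values: dict[str, float] = {}
    for term in design.terms:
        obs = _term_ssq(centred, labels, term)
        count = 0
        for _ in range(n_perm):
            perm_labels = dict(labels)
            if isinstance(term, str):
                perm_labels[term] = rng.permutation(labels[term])
            else:
                a, b = term
                pa = labels[a].copy()
                for lev in np.unique(labels[b]):
                    m = labels[b] == lev
                    pa[m] = rng.permutation(pa[m])
                perm_labels[a] = pa
            if _term_ssq(centred, perm_labels, term) >= obs - 1e-12:
                count += 1
        p_values[_term_name(term)] = (count + 1) / (n_perm + 1)
    return p_values


def pca_scores(
    matrix: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA by SVD of the column-centred matrix.

    Returns scores (samples x components, ordered by decreasing variance),
    loadings (features x components) and per-component variance percentages.
    ``n_components`` beyond the matrix rank is truncated with a warning.
    """
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("PCA input contains missing values")
    centred = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    rank = int((s > s.max() * max(centred.shape) * np.finfo(float).eps).sum()) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
        n_components = max(rank, 1)
    var = s**2
    var_pct = var / var.sum() * 100.0 if var.sum() > 0 else var
    cols = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame((u * s)[:, :n_components], index=matrix.index, columns=cols)
    loadings = pd.DataFrame(vt[:n_components].T, index=matrix.columns, columns=cols)
    return scores, loadings, var_pct[:n_components]
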