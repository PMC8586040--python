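"""Stratified two-group testing and cross-batch reproducibility analysis.

For a toxicant-vs-control contrast (e.g. APAP vs CA), every feature is
tested by a two-sided Student's t test (pooled variance; Welch available by
flag) within each stratum of the design — per batch, or per batch x passage
combination — on corrected, unscaled intensities. No multiple-testing
correction is applied: significance is raw p < alpha, and output metadata
says so explicitly, since the per-feature false-discovery rate is then
uncontrolled.

Reproducibility across processing batches is then summarised two ways:

* **intersection analysis** — which features are significant in exactly /
  at least k of the batches, and which in all of them (the counts an upset
  plot displays);
* **fold-change consistency** — whether a feature's fold change
  (treatment mean / control mean; > 1 increase, < 1 decrease) points the
  same way in every batch x passage stratum.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peak_table import PeakTable

__all__ = [
    "StratumTestResult",
    "IntersectionSummary",
    "ttest_contrast",
    "results_frame",
    "intersect_significant",
    "fold_change_consistency",
]


@dataclass
class StratumTestResult:
    """t test of one feature for one contrast within one stratum."""

    feature_id: str
    stratum: tuple  # (batch,) or (batch, passage)
    contrast: str  # "<treatment>-vs-<control>"
    mean_treatment: float
    mean_control: float
    t_statistic: float
    p_value: float
    fold_change: float
    significant: bool
    n_treatment: int = 0
    n_control: int = 0


@dataclass
class IntersectionSummary:
    """Per-batch significant sets and their intersection structure."""

    sets: dict[str, set]  # batch label -> significant feature ids
    exactly_k: dict[int, int] = field(default_factory=dict)
    at_least_k: dict[int, int] = field(default_factory=dict)
    in_all: set = field(default_factory=set)

    @property
    def n_batches(self) -> int:
        return len(self.sets)


def ttest_contrast(
    pt: PeakTable,
    treatment: str,
    control: str,
    strata: Literal["batch", "batch_passage"] = "batch_passage",
    alpha: float = 0.05,
    equal_var: bool = True,
) -> tuple[list[StratumTestResult], list[tuple]]:
    """Two-group t tests per feature per stratum.

    Returns the result list and the strata that were skipped for having
    fewer than 2 samples in either group.
    """
    study = pt.samples[pt.samples["sample_class"] == "sample"]
    wanted = study[study["treatment"].isin([treatment, control])]
    if strata == "batch":
        groups = [(b,) for b in sorted(wanted["batch"].astype(str).unique())]
        key_cols = ["batch"]
    elif strata == "batch_passage":
        key_cols = ["batch", "passage"]
        groups = sorted(
            set(map(tuple, wanted[key_cols].astype(str).itertuples(index=False)))
        )
    else:
        raise ValueError(f"unknown strata grouping: {strata!r}")

    contrast = f"{treatment}-vs-{control}"
    results: list[StratumTestResult] = []
    skipped: list[tuple] = []
    x = pt.intensities
    for stratum in groups:
        mask = pd.Series(True, index=wanted.index)
        for col, val in zip(key_cols, stratum):
            mask &= wanted[col].astype(str) == val
        sub = wanted[mask]
        t_ids = list(sub.index[sub["treatment"] == treatment])
        c_ids = list(sub.index[sub["treatment"] == control])
        if len(t_ids) < 2 or len(c_ids) < 2:
            skipped.append(stratum)
            continue
        xt = x[t_ids].to_numpy(dtype=float)
        xc = x[c_ids].to_numpy(dtype=float)
        with warnings.catch_warnings():
            # identical groups trigger a harmless precision-loss warning;
            # the resulting t=0/p=1 (or NaN, fixed below) is what we want
            warnings.simplefilter("ignore", RuntimeWarning)
            t_stat, p = stats.ttest_ind(
                xt, xc, axis=1, equal_var=equal_var, nan_policy="omit"
            )
        mt = np.nanmean(xt, axis=1)
        mc = np.nanmean(xc, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = mt / mc
        # identical groups: zero pooled variance makes t 0/0; no evidence
        same = np.all(xt == xt[:, :1], axis=1) & np.all(xc == xc[:, :1], axis=1) & (
            mt == mc
        )
        t_stat = np.where(same, 0.0, t_stat)
        p = np.where(same, 1.0, p)
        for i, fid in enumerate(pt.features.index):
            results.append(
                StratumTestResult(
                    feature_id=fid,
                    stratum=stratum,
                    contrast=contrast,
                    mean_treatment=float(mt[i]),
                    mean_control=float(mc[i]),
                    t_statistic=float(t_stat[i]),
                    p_value=float(p[i]),
                    fold_change=float(fc[i]),
                    significant=bool(p[i] < alpha),
                    n_treatment=len(t_ids),
                    n_control=len(c_ids),
                )
            )
    return results, skipped


def results_frame(results: Sequence[StratumTestResult]) -> pd.DataFrame:
    """Long-format frame of stratum test results.

    The frame's ``attrs['multiple_testing']`` records that p values are raw.
    """
    df = pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "stratum": ["|".join(r.stratum) for r in results],
            "batch": [r.stratum[0] for r in results],
            "contrast": [r.contrast for r in results],
            "mean_treatment": [r.mean_treatment for r in results],
            "mean_control": [r.mean_control for r in results],
            "t_statistic": [r.t_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "fold_change": [r.fold_change for r in results],
            "significant": [r.significant for r in results],
        }
    )
    df.attrs["multiple_testing"] = "none (raw p values; FDR uncontrolled)"
    return df


def intersect_significant(
    results: Sequence[StratumTestResult],
    annotation: pd.Series | None = None,
) -> IntersectionSummary:
    """Intersection structure of per-batch significant feature sets.

    Strata are pooled to their batch (a feature is significant in a batch if
    significant in any of that batch's strata — for batch-level testing, the
    batch itself). ``annotation`` (feature id -> metabolite name) optionally
    collapses features annotated to the same metabolite, the "unique
    metabolites" view.
    """
    batches = sorted({r.stratum[0] for r in results})
    if len(batches) < 2:
        raise ValueError("intersection analysis needs results from >= 2 batches")

    def name(fid: str) -> str:
        if annotation is not None and fid in annotation.index and pd.notna(annotation[fid]):
            return str(annotation[fid])
        return fid

    sets: dict[str, set] = {b: set() for b in batches}
    for r in results:
        if r.significant:
            sets[r.stratum[0]].add(name(r.feature_id))

    universe = set().union(*sets.values())
    membership = {f: sum(f in s for s in sets.values()) for f in universe}
    exactly = {k: sum(v == k for v in membership.values()) for k in range(1, len(batches) + 1)}
    at_least = {k: sum(v >= k for v in membership.values()) for k in range(1, len(batches) + 1)}
    in_all = set(f for f, v in membership.items() if v == len(batches))
    return IntersectionSummary(sets=sets, exactly_k=exactly, at_least_k=at_least, in_all=in_all)


def fold_change_consistency(
    results: Sequence[StratumTestResult],
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fold-change distribution and direction agreement per feature.

    For each feature (default: all tested in >= 2 strata), collects its fold
    changes across strata and flags whether they all fall on the same side
    of 1 (a fold change of exactly 1 agrees with either side).
    """
    by_feature: dict[str, list[float]] = {}
    for r in results:
        by_feature.setdefault(r.feature_id, []).append(r.fold_change)
    wanted = list(features) if features is not None else [
        f for f, v in by_feature.items() if len(v) >= 2
    ]
    rows = []
    for fid in wanted:
        fcs = np.array(by_feature.get(fid, []), dtype=float)
        fcs = fcs[~np.isnan(fcs)]
        if len(fcs) < 2:
            continue
        agree = bool(np.all(fcs >= 1.0) or np.all(fcs <= 1.0))
        rows.append(
            {
                "feature_id": fid,
                "n_strata": len(fcs),
                "fc_median": float(np.median(fcs)),
                "fc_min": float(fcs.min()),
                "fc_max": float(fcs.max()),
                "direction_agreement": agree,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id") if rows else pd.DataFrame(
        columns=["n_strata", "fc_median", "fc_min", "fc_max", "direction_agreement"]
    )
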