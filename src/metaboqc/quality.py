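"""Feature- and sample-level quality rules for untargeted LC-MS peak tables.

Three feature-level metrics, each computed per feature from one class of
injections:

* **blank ratio** — median QC peak area over the 80th percentile of blank
  areas. A feature whose QC signal is not comfortably above the blank
  background (ratio < 3 by default) is uninformative: it reflects solvent,
  medium or carry-over, not cell metabolome.
* **RSD_QC** — relative standard deviation across QC injections, percent.
  QCs are aliquots of one pool, so their spread is purely analytical.
* **D-ratio*** — ``MAD_qc / MAD_sample x 100``: analytical dispersion as a
  percentage of the biological-plus-analytical dispersion in study samples.
  MADs are unscaled (no 1.4826 consistency factor); the constant cancels in
  the ratio. Features above 20% carry more noise than signal and are
  removed.

Removal is strict on the "remove" side: a feature is dropped iff its metric
exceeds the threshold (blank ratio: dropped iff ratio < threshold), so a
feature sitting exactly on the cutoff is retained.

The sample-level rule flags low-total-signal outliers (failed extractions):
study samples whose total intensity falls below median - k*MAD of the study
samples' totals, one-sided. This formalisation of "low total signal" is this
package's own; reports label it as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peak_table import PeakTable, PeakTableError

__all__ = [
    "QualityReport",
    "blank_filter",
    "compute_blank_ratio",
    "compute_rsd_qc",
    "compute_d_ratio",
    "apply_feature_filters",
    "detect_outlier_samples",
]


@dataclass
class QualityReport:
    """Per-feature metrics/flags and per-sample outlier screening results."""

    feature_metrics: pd.DataFrame = field(default_factory=pd.DataFrame)
    sample_metrics: pd.DataFrame = field(default_factory=pd.DataFrame)
    thresholds: dict = field(default_factory=dict)

    def merged_with(self, other: "QualityReport") -> "QualityReport":
        fm = self.feature_metrics.combine_first(other.feature_metrics) if len(
            other.feature_metrics
        ) else self.feature_metrics
        sm = self.sample_metrics.combine_first(other.sample_metrics) if len(
            other.sample_metrics
        ) else self.sample_metrics
        return QualityReport(fm, sm, {**other.thresholds, **self.thresholds})

    def to_csv(self, feature_path, sample_path) -> None:
        self.feature_metrics.rename_axis("feature_id").to_csv(feature_path)
        self.sample_metrics.rename_axis("sample_id").to_csv(sample_path)


def _mad(values: np.ndarray) -> float:
    """Unscaled median absolute deviation about the median, NaNs ignored."""
    v = values[~np.isnan(values)]
    if len(v) == 0:
        return float("nan")
    return float(np.median(np.abs(v - np.median(v))))


def compute_blank_ratio(pt: PeakTable) -> pd.Series:
    """Median QC area / 80th percentile of blank areas, per feature.

    Missing blank measurements are ignored; a feature absent from every
    blank (all missing or zero) gets ratio +inf — there is no background to
    compare against, so it is informative by default. Without any blank
    injections every feature gets +inf.
    """
    if len(pt.qc_ids) < 1:
        raise PeakTableError("blank ratio undefined without QC samples")
    qc_median = pt.intensity_of("qc").median(axis=1, skipna=True)
    ratios = pd.Series(np.inf, index=pt.features.index, dtype=float)
    if pt.blank_ids:
        blanks = pt.intensity_of("blank")
        for fid in pt.features.index:
            vals = blanks.loc[fid].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0 or np.all(vals == 0):
                continue  # absent from blanks -> +inf
            p80 = float(np.percentile(vals, 80, method="linear"))
            ratios[fid] = np.inf if p80 == 0 else float(qc_median[fid]) / p80
    return ratios


def blank_filter(
    pt: PeakTable, ratio_threshold: float = 3.0
) -> tuple[PeakTable, QualityReport]:
    """Drop features whose QC signal is below ``ratio_threshold`` x blank level.

    A feature is uninformative iff its blank ratio is strictly below the
    threshold; a ratio exactly at the threshold is retained. With no blank
    injections nothing is flagged. Idempotent: re-filtering removes nothing.
    """
    ratios = compute_blank_ratio(pt)
    flagged = ratios < ratio_threshold
    metrics = pd.DataFrame(
        {"blank_ratio": ratios, "uninformative_blank": flagged}
    )
    report = QualityReport(
        feature_metrics=metrics, thresholds={"blank_ratio_min": ratio_threshold}
    )
    keep = list(ratios.index[~flagged])
    if not keep:
        raise PeakTableError("blank filter removed every feature")
    return pt.subset_features(keep), report


def compute_rsd_qc(pt: PeakTable) -> pd.Series:
    """Percent relative standard deviation over QC injections, per feature.

    Uses the n-1 (sample) standard deviation. Features with QC mean 0 or
    fewer than 3 non-missing QC values are undefined (NaN).
    """
    qc = pt.intensity_of("qc")
    if qc.shape[1] < 3:
        raise PeakTableError(f"need >= 3 QC samples for RSD_QC, found {qc.shape[1]}")
    n_ok = qc.notna().sum(axis=1)
    mean = qc.mean(axis=1, skipna=True)
    sd = qc.std(axis=1, ddof=1, skipna=True)
    rsd = sd / mean * 100.0
    rsd[(n_ok < 3) | (mean == 0)] = np.nan
    return rsd.astype(float)


def compute_d_ratio(pt: PeakTable) -> pd.Series:
    """D-ratio* per feature: ``MAD_qc / MAD_sample x 100`` (percent).

    Requires >= 3 QC and >= 3 study samples with non-missing values per
    feature. ``MAD_sample = 0`` with ``MAD_qc > 0`` gives +inf (no
    biological variation to measure against); both zero gives 0 with a
    warning (the feature is constant everywhere).
    """
    qc = pt.intensity_of("qc")
    study = pt.intensity_of("sample")
    if qc.shape[1] < 3:
        raise PeakTableError(f"need >= 3 QC samples for D-ratio, found {qc.shape[1]}")
    if study.shape[1] < 3:
        raise PeakTableError(f"need >= 3 study samples for D-ratio, found {study.shape[1]}")
    out = pd.Series(np.nan, index=pt.features.index, dtype=float)
    both_zero = []
    for fid in pt.features.index:
        mad_qc = _mad(qc.loc[fid].to_numpy(dtype=float))
        mad_s = _mad(study.loc[fid].to_numpy(dtype=float))
        if np.isnan(mad_qc) or np.isnan(mad_s):
            continue
        if mad_s == 0.0:
            if mad_qc == 0.0:
                out[fid] = 0.0
                both_zero.append(fid)
            else:
                out[fid] = np.inf
        else:
            out[fid] = mad_qc / mad_s * 100.0
    if both_zero:
        warnings.warn(
            f"{len(both_zero)} features have zero MAD in both QCs and samples; "
            "D-ratio* set to 0",
            stacklevel=2,
        )
    return out


def apply_feature_filters(
    pt: PeakTable,
    d_ratio_max: float = 20.0,
    rsd_max: float = 20.0,
) -> tuple[PeakTable, QualityReport]:
    """Remove features failing the D-ratio* and RSD_QC cutoffs.

    Both filters are strict: a feature is removed iff its metric is strictly
    greater than the threshold (20% exactly passes). Either filter can be
    disabled by passing ``float('inf')``. Undefined metrics (NaN) do not
    remove a feature but are flagged for inspection.
    """
    d_ratio = compute_d_ratio(pt)
    rsd = compute_rsd_qc(pt)
    high_d = d_ratio > d_ratio_max
    high_rsd = rsd > rsd_max
    metrics = pd.DataFrame(
        {
            "d_ratio": d_ratio,
            "rsd_qc": rsd,
            "high_d_ratio": high_d.fillna(False),
            "high_rsd": high_rsd.fillna(False),
            "metric_undefined": d_ratio.isna() | rsd.isna(),
        }
    )
    report = QualityReport(
        feature_metrics=metrics,
        thresholds={"d_ratio_max": d_ratio_max, "rsd_max": rsd_max},
    )
    remove = metrics["high_d_ratio"] | metrics["high_rsd"]
    keep = list(metrics.index[~remove])
    if not keep:
        raise PeakTableError(
            "all features removed by quality filters "
            f"(d_ratio_max={d_ratio_max}, rsd_max={rsd_max}); "
            f"median D-ratio* {float(np.nanmedian(d_ratio)):.1f}%, "
            f"median RSD_QC {float(np.nanmedian(rsd)):.1f}%"
        )
    return pt.subset_features(keep), report


def detect_outlier_samples(pt: PeakTable, k: float = 3.0) -> pd.DataFrame:
    """Flag study samples with anomalously low total signal.

    ``total_signal`` sums non-missing intensities per sample; a study sample
    is flagged iff ``total < median - k * MAD`` of the study-sample totals
    (one-sided — only low totals indicate failed extraction or injection).
    QCs and blanks are reported but never flagged. ``k = inf`` disables
    flagging. This low-total rule is a formalisation chosen by this package;
    downstream reports carry that caveat.
    """
    totals = pt.intensities.sum(axis=0, skipna=True)
    study = pt.study_ids
    if len(study) < 5:
        raise PeakTableError("need >= 5 study samples for outlier screening")
    st = totals[study].to_numpy(dtype=float)
    med = float(np.median(st))
    mad = _mad(st)
    flags = pd.Series(False, index=pt.samples.index)
    if np.isfinite(k):
        cutoff = med - k * mad
        flags[study] = totals[study] < cutoff
    else:
        cutoff = -np.inf
    return pd.DataFrame(
        {
            "total_signal": totals,
            "sample_class": pt.samples["sample_class"],
            "outlier_flag": flags,
            "cutoff": cutoff,
        }
    )
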