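"""Canonical peak-table data model and delimited-text I/O.

A peak table is the features x samples matrix of integrated chromatographic
peak areas produced upstream (e.g. by XCMS), together with per-feature
metadata (m/z, retention time, ionization mode, optional annotation) and
per-sample metadata (injection order, processing batch, cell passage,
treatment, sample class). Every downstream stage of the workflow — blank
filtering, drift correction, quality filtering, ASCA, univariate testing —
consumes and returns this object.

On disk a peak table is three CSV files (intensities, sample metadata,
feature metadata); in memory it wraps three aligned :class:`pandas.DataFrame`
objects. Missing measurements are ``NaN`` in memory and empty cells on disk —
never zero, which would be a real (absent-signal) measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "PeakTableError",
    "SAMPLE_CLASSES",
    "read_peak_table",
    "write_peak_table",
    "merge_ion_modes",
]

SAMPLE_CLASSES = ("sample", "qc", "blank")

#: required columns of the sample-metadata table
SAMPLE_META_COLUMNS = ("injection_order", "sample_class", "batch", "passage", "treatment")
#: required columns of the feature-metadata table
FEATURE_META_COLUMNS = ("mz", "rt", "ion_mode")


class PeakTableError(ValueError):
    """Raised when a peak table violates its structural invariants."""


def _as_str_index(idx: Iterable) -> pd.Index:
    return pd.Index([str(x) for x in idx])


@dataclass
class PeakTable:
    """Features x samples intensity matrix with aligned metadata.

    Parameters
    ----------
    intensities
        DataFrame of non-negative peak areas, index = feature ids,
        columns = sample ids. ``NaN`` marks a missing measurement.
    samples
        DataFrame indexed by sample id with at least ``injection_order``
        (positive int, unique), ``sample_class`` (one of ``sample``, ``qc``,
        ``blank``), and for study samples ``batch``, ``passage``,
        ``treatment``. ``replicate`` is optional.
    features
        DataFrame indexed by feature id with at least ``mz`` (> 0), ``rt``
        (>= 0) and ``ion_mode`` (``positive`` or ``negative``); optional
        ``annotation`` and ``annotation_class``.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.intensities.index = _as_str_index(self.intensities.index)
        self.intensities.columns = _as_str_index(self.intensities.columns)
        self.samples.index = _as_str_index(self.samples.index)
        self.features.index = _as_str_index(self.features.index)
        if self.validate:
            self._validate()
        # canonical column order: ascending injection order
        order = self.samples["injection_order"].astype(int).sort_values().index
        self.samples = self.samples.loc[order]
        self.intensities = self.intensities.loc[self.features.index, order]

    # ------------------------------------------------------------------ #
    def _validate(self) -> None:
        if len(self.features) == 0:
            raise PeakTableError("peak table has no features")
        if len(self.samples) == 0:
            raise PeakTableError("peak table has no samples")

        missing_cols = [c for c in SAMPLE_META_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise PeakTableError(f"sample metadata lacks columns: {missing_cols}")
        missing_cols = [c for c in FEATURE_META_COLUMNS if c not in self.features.columns]
        if missing_cols:
            raise PeakTableError(f"feature metadata lacks columns: {missing_cols}")

        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()].tolist()
            raise PeakTableError(f"duplicate sample ids: {dup}")
        if self.features.index.has_duplicates:
            dup = self.features.index[self.features.index.duplicated()].tolist()
            raise PeakTableError(f"duplicate feature ids: {dup}")

        extra = set(self.intensities.columns) - set(self.samples.index)
        absent = set(self.samples.index) - set(self.intensities.columns)
        if extra or absent:
            raise PeakTableError(
                "intensity columns and sample metadata disagree: "
                f"unknown sample ids {sorted(extra)}, missing columns {sorted(absent)}"
            )
        extra = set(self.intensities.index) - set(self.features.index)
        absent = set(self.features.index) - set(self.intensities.index)
        if extra or absent:
            raise PeakTableError(
                "intensity rows and feature metadata disagree: "
                f"unknown feature ids {sorted(extra)}, missing rows {sorted(absent)}"
            )

        io = self.samples["injection_order"]
        if io.isna().any():
            raise PeakTableError("injection_order contains missing values")
        if io.duplicated().any():
            dup = io[io.duplicated()].tolist()
            raise PeakTableError(f"duplicate injection_order values: {dup}")
        if (io.astype(float) < 1).any():
            raise PeakTableError("injection_order must be a positive integer")

        bad_class = set(self.samples["sample_class"]) - set(SAMPLE_CLASSES)
        if bad_class:
            raise PeakTableError(f"unknown sample_class values: {sorted(bad_class)}")

        treat = self.samples["treatment"]
        nonstudy = self.samples["sample_class"].isin(("qc", "blank"))
        labelled = treat.notna() & (treat.astype(str).str.len() > 0)
        if (nonstudy & labelled).any():
            bad = self.samples.index[nonstudy & labelled].tolist()
            raise PeakTableError(f"qc/blank samples must not carry a treatment label: {bad}")
        study = self.samples["sample_class"] == "sample"
        for col in ("batch", "passage", "treatment"):
            vals = self.samples.loc[study, col]
            if vals.isna().any() or (vals.astype(str).str.len() == 0).any():
                bad = vals.index[vals.isna() | (vals.astype(str).str.len() == 0)].tolist()
                raise PeakTableError(f"study samples missing {col}: {bad}")

        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise PeakTableError("negative intensities are not valid peak areas")
        mz = self.features["mz"].astype(float)
        rt = self.features["rt"].astype(float)
        if (mz <= 0).any():
            raise PeakTableError("feature m/z must be positive")
        if (rt < 0).any():
            raise PeakTableError("feature retention time must be non-negative")

    # ------------------------------------------------------------------ #
    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_features, self.n_samples)

    def sample_ids(self, sample_class: str | None = None) -> list[str]:
        """Sample ids, optionally restricted to one class, in injection order."""
        if sample_class is None:
            return list(self.samples.index)
        return list(self.samples.index[self.samples["sample_class"] == sample_class])

    @property
    def qc_ids(self) -> list[str]:
        return self.sample_ids("qc")

    @property
    def blank_ids(self) -> list[str]:
        return self.sample_ids("blank")

    @property
    def study_ids(self) -> list[str]:
        return self.sample_ids("sample")

    def intensity_of(self, sample_class: str) -> pd.DataFrame:
        """Intensity sub-matrix for one sample class, columns in injection order."""
        return self.intensities[self.sample_ids(sample_class)]

    def subset_features(self, feature_ids: Iterable[str]) -> "PeakTable":
        ids = [str(f) for f in feature_ids]
        return PeakTable(
            self.intensities.loc[ids].copy(),
            self.samples.copy(),
            self.features.loc[ids].copy(),
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "PeakTable":
        ids = [str(s) for s in sample_ids]
        return PeakTable(
            self.intensities[ids].copy(),
            self.samples.loc[ids].copy(),
            self.features.copy(),
        )

    def copy(self) -> "PeakTable":
        return PeakTable(self.intensities.copy(), self.samples.copy(), self.features.copy())

    def with_intensities(self, values: pd.DataFrame | np.ndarray) -> "PeakTable":
        """Same metadata, new intensity values (aligned to current axes)."""
        if isinstance(values, np.ndarray):
            values = pd.DataFrame(values, index=self.intensities.index, columns=self.intensities.columns)
        else:
            values = values.loc[self.intensities.index, self.intensities.columns]
        return PeakTable(values.copy(), self.samples.copy(), self.features.copy())

    def equals(self, other: "PeakTable") -> bool:
        return (
            self.intensities.equals(other.intensities)
            and self.samples.equals(other.samples)
            and self.features.equals(other.features)
        )


# ---------------------------------------------------------------------- #
# I/O


def read_peak_table(
    intensity_path: str | Path,
    sample_meta_path: str | Path,
    feature_meta_path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> PeakTable:
    """Read a peak table from its three CSV files.

    The intensity file has one row per feature; its first column holds the
    feature id and the remaining column headers are sample ids. The two
    metadata files are indexed by their first column (sample id / feature id).

    ``column_map`` renames external metadata headers onto the canonical schema
    (e.g. ``{"order": "injection_order"}``) so exported tables from other
    tools can be adapted without editing files.
    """
    for p in (intensity_path, sample_meta_path, feature_meta_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"peak-table file not found: {p}")
    inten = pd.read_csv(intensity_path, index_col=0, float_precision="round_trip")
    bad = inten.map(lambda v: isinstance(v, str))
    if bad.any().any():
        r = bad.any(axis=1).idxmax()
        c = bad.loc[r].idxmax()
        raise PeakTableError(f"non-numeric intensity at feature {r!r}, sample {c!r}: {inten.loc[r, c]!r}")
    samples = pd.read_csv(sample_meta_path, index_col=0)
    features = pd.read_csv(feature_meta_path, index_col=0)
    if column_map:
        samples = samples.rename(columns=dict(column_map))
        features = features.rename(columns=dict(column_map))
    return PeakTable(inten, samples, features)


def write_peak_table(pt: PeakTable, out_dir: str | Path, prefix: str = "peak_table") -> dict[str, Path]:
    """Write the three CSV files; round-trips bit-exactly through ``read_peak_table``."""
    if pt.n_features == 0:
        raise PeakTableError("refusing to write a peak table with no features")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": out / f"{prefix}_intensities.csv",
        "samples": out / f"{prefix}_samples.csv",
        "features": out / f"{prefix}_features.csv",
    }
    pt.intensities.rename_axis("feature_id").to_csv(paths["intensities"])
    pt.samples.rename_axis("sample_id").to_csv(paths["samples"])
    pt.features.rename_axis("feature_id").to_csv(paths["features"])
    return paths


def merge_ion_modes(pos: PeakTable, neg: PeakTable) -> PeakTable:
    """Merge the positive- and negative-mode tables of one experiment.

    Features are concatenated after prefixing their ids with the ionization
    mode; samples are matched by biological identity (sample id) and the
    merged table keeps the intersection. Sample metadata (injection order
    included) is taken from the positive-mode run; the two modes are acquired
    in separate runs, so drift correction must happen per mode *before*
    merging.
    """
    shared = [s for s in pos.samples.index if s in set(neg.samples.index)]
    if not shared:
        raise PeakTableError("ion-mode tables share no sample ids")

    def prefixed(pt: PeakTable) -> tuple[pd.DataFrame, pd.DataFrame]:
        tag = pt.features["ion_mode"].map({"positive": "pos", "negative": "neg"})
        if tag.isna().any():
            raise PeakTableError("ion_mode must be 'positive' or 'negative' for every feature")
        new_ids = [
            fid if fid.startswith(f"{t}_") else f"{t}_{fid}"
            for fid, t in zip(pt.features.index, tag)
        ]
        feats = pt.features.copy()
        feats.index = pd.Index(new_ids)
        inten = pt.intensities.copy()
        inten.index = pd.Index(new_ids)
        return inten[shared], feats

    inten_p, feats_p = prefixed(pos)
    inten_n, feats_n = prefixed(neg)
    overlap = set(feats_p.index) & set(feats_n.index)
    if overlap:
        raise PeakTableError(f"feature ids collide across modes after prefixing: {sorted(overlap)[:5]}")
    features = pd.concat([feats_p, feats_n])
    intensities = pd.concat([inten_p, inten_n])
    return PeakTable(intensities, pos.samples.loc[shared].copy(), features)
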