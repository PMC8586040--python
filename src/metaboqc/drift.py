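"""QC-based support-vector drift correction (QC-SVRC).

Instrument response in an LC-MS run drifts smoothly with injection order
(source suppression, column fouling...). Pooled QC samples — identical
aliquots injected throughout the run — trace that drift per feature. QC-SVRC
fits, for every feature, an epsilon-insensitive support vector regression
(RBF kernel) of QC intensity on injection order and divides all intensities
by the fitted curve, rescaled to the QC median:

    corrected(i, j) = raw(i, j) * reference_i / predicted_i(order_j)

Hyperparameters per feature:

* ``C`` — the penalty term, preset to the median QC peak area (the signal's
  own scale);
* ``epsilon`` — the insensitivity tube, grid-searched over a fraction of the
  QC median spanning the expected instrumental precision (2.5-8% by
  default);
* ``gamma`` — the RBF kernel width, grid-searched log-spaced over [1, 1e4].

Each (epsilon, gamma) candidate is scored by leave-one-out cross-validation
over the QC injections (RMSECV); ties are broken toward the larger epsilon
and then the smaller gamma — the smoother model. Injection order is rescaled
to [0, 1] per run before fitting so the gamma range means the same thing for
any run length; intensities are rescaled by C before fitting (the SVR
problem is scale-equivariant, so this changes nothing but conditioning).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .peak_table import PeakTable, PeakTableError
from .quality import compute_d_ratio, compute_rsd_qc

__all__ = [
    "SvrHyperParams",
    "DriftModel",
    "DriftModelSet",
    "fit_qc_svrc",
    "correct_intensities",
    "correction_report",
    "CorrectionReport",
]


@dataclass(frozen=True)
class SvrHyperParams:
    """Search space and constraints for per-feature SVR fitting."""

    epsilon_range_frac: tuple[float, float] = (0.025, 0.08)
    n_epsilon: int = 5
    gamma_range: tuple[float, float] = (1.0, 1.0e4)
    n_gamma: int = 13
    min_qc: int = 5
    clamp_floor_frac: float = 0.1

    def __post_init__(self) -> None:
        # YAML/JSON deserialise the range pairs as lists
        object.__setattr__(self, "epsilon_range_frac", tuple(self.epsilon_range_frac))
        object.__setattr__(self, "gamma_range", tuple(self.gamma_range))
        if not 0 <= self.epsilon_range_frac[0] <= self.epsilon_range_frac[1]:
            raise ValueError("epsilon_range_frac must be ordered and non-negative")
        if not 0 < self.gamma_range[0] <= self.gamma_range[1]:
            raise ValueError("gamma_range must be ordered and positive")
        if self.n_epsilon < 1 or self.n_gamma < 1:
            raise ValueError("grid sizes must be >= 1")
        if self.min_qc < 3:
            raise ValueError("min_qc must be >= 3 (leave-one-out needs spare points)")

    def epsilon_fracs(self) -> np.ndarray:
        return np.linspace(*self.epsilon_range_frac, self.n_epsilon)

    def gammas(self) -> np.ndarray:
        return np.logspace(*np.log10(self.gamma_range), self.n_gamma)


@dataclass
class DriftModel:
    """Fitted drift curve of one feature.

    ``svr`` regresses normalised QC intensity (y / reference_level) on
    normalised injection order; ``predict`` undoes both rescalings.
    """

    feature_id: str
    fit_status: str  # ok | skipped_insufficient_qc | degenerate
    reference_level: float = float("nan")  # QC median = C
    epsilon_frac: float = float("nan")
    gamma: float = float("nan")
    rmsecv: float = float("nan")  # intensity units
    svr: SVR | None = None
    qc_span: tuple[float, float] = (0.0, 1.0)  # normalised-order span of the QCs

    @property
    def C(self) -> float:
        return self.reference_level

    @property
    def epsilon(self) -> float:
        """Tolerance threshold in intensity units."""
        return self.epsilon_frac * self.reference_level

    def predict(self, t_norm: np.ndarray) -> np.ndarray:
        """Predicted drift curve at normalised injection orders.

        Orders outside the QC span are clamped to it: the RBF model has no
        support there and would relax to its intercept.
        """
        t = np.clip(np.asarray(t_norm, dtype=float), *self.qc_span)
        if self.fit_status == "degenerate":
            return np.full(t.shape, self.reference_level)
        if self.svr is None:
            raise ValueError(f"feature {self.feature_id}: no fitted model ({self.fit_status})")
        return self.svr.predict(t[:, None]) * self.reference_level


@dataclass
class DriftModelSet:
    """Per-feature drift models plus the run's order normalisation."""

    models: dict[str, DriftModel]
    order_min: float
    order_max: float
    params: SvrHyperParams

    def normalise(self, order: np.ndarray) -> np.ndarray:
        span = max(self.order_max - self.order_min, 1.0)
        return (np.asarray(order, dtype=float) - self.order_min) / span

    def summary(self) -> pd.DataFrame:
        rows = []
        for fid, m in self.models.items():
            rows.append(
                {
                    "feature_id": fid,
                    "fit_status": m.fit_status,
                    "C": m.C,
                    "epsilon": m.epsilon,
                    "gamma": m.gamma,
                    "rmsecv": m.rmsecv,
                }
            )
        return pd.DataFrame(rows).set_index("feature_id")


def _loo_rmse(x: np.ndarray, y: np.ndarray, eps: float, gamma: float) -> float:
    """Leave-one-out RMSE of an SVR(C=1) fit on (x, y)."""
    n = len(x)
    err2 = 0.0
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        svr = SVR(kernel="rbf", C=1.0, epsilon=eps, gamma=gamma)
        svr.fit(x[mask, None], y[mask])
        pred = svr.predict(x[i : i + 1, None])[0]
        err2 += (pred - y[i]) ** 2
    return float(np.sqrt(err2 / n))


def fit_qc_svrc(
    pt: PeakTable,
    params: SvrHyperParams | None = None,
    exclude_qcs: Iterable[str] = (),
) -> DriftModelSet:
    """Fit one drift model per feature from the run's QC injections.

    Features with fewer than ``params.min_qc`` non-missing QC values are
    skipped (passed through uncorrected, flagged); features whose QC
    intensities are all identical get a degenerate constant model. QC
    injections listed in ``exclude_qcs`` (e.g. visually flagged outliers)
    are dropped before fitting; they are never removed automatically.
    """
    params = params or SvrHyperParams()
    qc_ids = [q for q in pt.qc_ids if q not in set(exclude_qcs)]
    if len(qc_ids) == 0:
        raise PeakTableError("no QC samples available for drift fitting")

    orders = pt.samples["injection_order"].astype(float)
    o_min, o_max = float(orders.min()), float(orders.max())
    span = max(o_max - o_min, 1.0)
    qc_t = ((orders[qc_ids] - o_min) / span).to_numpy()

    eps_fracs = params.epsilon_fracs()[::-1]  # descending: ties favour larger epsilon
    gammas = params.gammas()  # ascending: ties favour smaller gamma

    models: dict[str, DriftModel] = {}
    qc_matrix = pt.intensities[qc_ids]
    for fid in pt.features.index:
        y_raw = qc_matrix.loc[fid].to_numpy(dtype=float)
        ok = ~np.isnan(y_raw)
        y, t = y_raw[ok], qc_t[ok]
        if ok.sum() < params.min_qc:
            models[fid] = DriftModel(fid, "skipped_insufficient_qc")
            continue
        ref = float(np.median(y))
        if np.all(y == y[0]) or ref <= 0:
            models[fid] = DriftModel(fid, "degenerate", reference_level=float(y[0]))
            continue
        yn = y / ref
        best = (np.inf, np.nan, np.nan)
        for eps in eps_fracs:
            for gam in gammas:
                rmse = _loo_rmse(t, yn, eps, gam)
                if rmse < best[0]:
                    best = (rmse, eps, gam)
        _, eps_sel, gam_sel = best
        svr = SVR(kernel="rbf", C=1.0, epsilon=eps_sel, gamma=gam_sel)
        svr.fit(t[:, None], yn)
        models[fid] = DriftModel(
            fid,
            "ok",
            reference_level=ref,
            epsilon_frac=float(eps_sel),
            gamma=float(gam_sel),
            rmsecv=float(best[0] * ref),
            svr=svr,
            qc_span=(float(t.min()), float(t.max())),
        )
    return DriftModelSet(models, o_min, o_max, params)


def correct_intensities(
    pt: PeakTable, models: DriftModelSet
) -> tuple[PeakTable, pd.DataFrame]:
    """Divide every intensity by its feature's fitted drift curve.

    Predictions are clamped below at ``clamp_floor_frac x reference_level``
    so a prediction wandering toward zero cannot explode the correction;
    features where the clamp (or a non-positive prediction) triggers are
    flagged ``unstable_correction``. Skipped and degenerate features pass
    through unchanged. QCs are corrected exactly like study samples.

    Returns the corrected table and a per-feature flag frame.
    """
    t_all = models.normalise(pt.samples["injection_order"].to_numpy())
    corrected = pt.intensities.copy().astype(float)
    flags = pd.DataFrame(
        {"corrected": False, "unstable_correction": False},
        index=pt.features.index,
    )
    floor_frac = models.params.clamp_floor_frac
    for fid in pt.features.index:
        m = models.models.get(fid)
        if m is None or m.fit_status != "ok":
            continue
        pred = m.predict(t_all)
        unstable = bool(np.any(pred <= floor_frac * m.reference_level))
        pred = np.maximum(pred, floor_frac * m.reference_level)
        corrected.loc[fid] = pt.intensities.loc[fid].to_numpy() * m.reference_level / pred
        flags.loc[fid, "corrected"] = True
        flags.loc[fid, "unstable_correction"] = unstable
    return pt.with_intensities(corrected), flags


@dataclass
class CorrectionReport:
    """Before/after summary of a drift correction.

    ``d_ratio_cdf`` holds the sorted D-ratio* values (the empirical CDF
    support) per state; ``subbatch_fractions`` re-evaluates the pass
    fraction on nested truncations of the run, mimicking batches of
    increasing injection count.
    """

    d_ratio_before: pd.Series
    d_ratio_after: pd.Series
    frac_pass_before: float
    frac_pass_after: float
    median_rsd_before: float
    median_rsd_after: float
    threshold: float
    subbatch_fractions: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def d_ratio_cdf(self) -> dict[str, np.ndarray]:
        return {
            "before": np.sort(self.d_ratio_before.dropna().to_numpy()),
            "after": np.sort(self.d_ratio_after.dropna().to_numpy()),
        }


def _pass_fraction(d_ratio: pd.Series, threshold: float) -> float:
    vals = d_ratio.dropna()
    if len(vals) == 0:
        return float("nan")
    return float((vals <= threshold).mean())


def correction_report(
    before: PeakTable,
    after: PeakTable,
    threshold: float = 20.0,
    truncations: Sequence[int] | None = None,
) -> CorrectionReport:
    """Compare feature quality before and after drift correction.

    ``truncations`` is a list of injection counts; for each, both tables are
    cut to injections 1..L and the D-ratio* pass fraction recomputed,
    showing how correction quality depends on batch size. Truncations with
    fewer than 3 QCs or 3 study samples are skipped.
    """
    if before.shape != after.shape or list(before.features.index) != list(after.features.index):
        raise PeakTableError("before/after tables must share features and samples")
    d_before = compute_d_ratio(before)
    d_after = compute_d_ratio(after)
    rsd_before = compute_rsd_qc(before)
    rsd_after = compute_rsd_qc(after)

    rows = []
    for length in truncations or ():
        keep = before.samples.index[before.samples["injection_order"] <= length]
        sub_b = before.subset_samples(keep)
        if len(sub_b.qc_ids) < 3 or len(sub_b.study_ids) < 3:
            continue
        sub_a = after.subset_samples(keep)
        rows.append(
            {
                "n_injections": int(length),
                "frac_pass_before": _pass_fraction(compute_d_ratio(sub_b), threshold),
                "frac_pass_after": _pass_fraction(compute_d_ratio(sub_a), threshold),
            }
        )
    return CorrectionReport(
        d_ratio_before=d_before,
        d_ratio_after=d_after,
        frac_pass_before=_pass_fraction(d_before, threshold),
        frac_pass_after=_pass_fraction(d_after, threshold),
        median_rsd_before=float(np.nanmedian(rsd_before)),
        median_rsd_after=float(np.nanmedian(rsd_after)),
        threshold=threshold,
        subbatch_fractions=pd.DataFrame(rows),
    )
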