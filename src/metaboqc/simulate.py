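"""Synthetic in vitro toxico-metabolomics experiments with known ground truth.

The generator emulates the data-generating structure the rest of the workflow
assumes: a multi-factor cell-culture study (processing batch x cell passage x
treatment, replicated), measured in a single LC-MS injection sequence with

* log-normal per-feature baseline intensities,
* multiplicative (log-additive) batch, passage and treatment effects,
* smooth within-run instrumental drift as a function of injection order,
* pooled QC injections interleaved with the study samples, and
* blank wells carrying only a contamination subset of features.

QC samples are synthesised as the pooled mean of the drift-free expected
study intensities, then exposed to the same drift and measurement noise —
so QC dispersion reflects purely analytical variation, which is precisely
the assumption behind RSD_QC and the D-ratio.

Alongside the peak table the generator returns a :class:`SyntheticTruth`
with the realised effect values and variance shares, enabling
parameter-recovery tests of the downstream variance decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

from .peak_table import PeakTable
from .pathway import PathwayTable

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_experiment",
    "generate_pathway_tables",
    "config_for_variance_shares",
    "TREATMENT_LABELS",
]

#: default factor-level labels; the first treatment is the non-toxic control
TREATMENT_LABELS = ("CA", "APAP", "VPA")
PASSAGE_LABELS = ("P18", "P21", "P24", "P27")

_DRIFT_SHAPES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "linear": lambda t: t,
    "exponential": lambda t: (1.0 - np.exp(-3.0 * t)) / (1.0 - np.exp(-3.0)),
    "sigmoid": lambda t: (
        lambda s0, s1, s: (s - s0) / (s1 - s0)
    )(1 / (1 + np.exp(4.0)), 1 / (1 + np.exp(-4.0)), 1 / (1 + np.exp(-8.0 * (t - 0.5)))),
}


@dataclass
class SimulationConfig:
    """Design and noise parameters of a synthetic experiment.

    Defaults mirror a five-batch, four-passage, three-treatment cell study
    with four biological replicates per condition, a pooled QC injected
    every eight study samples, and pronounced within-run drift.
    """

    n_features: int = 166
    n_batches: int = 5
    n_passages: int = 4
    n_treatments: int = 3
    replicates_per_cell: int = 4
    qc_interval: int = 8
    n_blanks: int = 4
    baseline_log_mean: float = float(np.log(1e4))
    baseline_log_sd: float = 1.0
    batch_effect_sd: float = 0.25
    passage_effect_sd: float = 0.10
    treatment_effect_sd: float = 0.15
    frac_treatment_responsive: float = 0.3
    drift_magnitude: float = 0.4
    drift_shape: str = "linear"
    drift_jitter: float = 0.2  # relative sd of per-feature drift magnitude
    noise_cv: float = 0.05
    blank_contamination_frac: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        for name in ("n_batches", "n_passages", "n_treatments", "replicates_per_cell"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.qc_interval < 1:
            raise ValueError("qc_interval must be >= 1")
        if self.n_blanks < 0:
            raise ValueError("n_blanks must be non-negative")
        for name in (
            "batch_effect_sd",
            "passage_effect_sd",
            "treatment_effect_sd",
            "drift_magnitude",
            "drift_jitter",
            "noise_cv",
            "baseline_log_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("frac_treatment_responsive", "blank_contamination_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.drift_shape not in _DRIFT_SHAPES:
            raise ValueError(f"drift_shape must be one of {sorted(_DRIFT_SHAPES)}")

    @property
    def n_study_samples(self) -> int:
        return self.n_batches * self.n_passages * self.n_treatments * self.replicates_per_cell

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Realised ground truth of one generated experiment.

    Effect frames are features x levels on the natural-log scale.
    ``variance_shares`` holds each design term's share of the total
    (mean-removed) log-intensity sum of squares of the study samples,
    recomputed from the generated matrix — so it reflects what drift and
    noise actually did, not just the drawn parameters.
    """

    batch_effects: pd.DataFrame
    passage_effects: pd.DataFrame
    treatment_effects: pd.DataFrame
    responsive_features: list[str]
    treatment_effect_sizes: pd.DataFrame  # responsive features x non-control levels, vs control
    drift_magnitudes: pd.Series  # per feature, fractional loss across the run
    drift_shape: str
    contamination_features: list[str]
    variance_shares: dict[str, float] = field(default_factory=dict)


def _log_variance_shares(
    logx: np.ndarray, batch: np.ndarray, passage: np.ndarray, treatment: np.ndarray
) -> dict[str, float]:
    """Share of total mean-removed SSQ captured by each design term.

    Straightforward sequential cell-mean decomposition (mains, then two-way
    interactions, then residual), summed over features.
    """
    centred = logx - logx.mean(axis=0, keepdims=True)
    total = float((centred**2).sum())
    if total == 0:
        return {t: 0.0 for t in ("batch", "passage", "treatment")}

    def level_means(labels: np.ndarray, data: np.ndarray) -> np.ndarray:
        out = np.zeros_like(data)
        for lev in np.unique(labels):
            m = labels == lev
            out[m] = data[m].mean(axis=0, keepdims=True)
        return out

    mains = {
        "batch": level_means(batch, centred),
        "passage": level_means(passage, centred),
        "treatment": level_means(treatment, centred),
    }
    labels = {"batch": batch, "passage": passage, "treatment": treatment}
    inter: dict[str, np.ndarray] = {}
    for a, b in (("treatment", "batch"), ("treatment", "passage"), ("batch", "passage")):
        joint = np.char.add(np.char.add(labels[a].astype(str), "||"), labels[b].astype(str))
        inter[f"{a}_x_{b}"] = level_means(joint, centred) - mains[a] - mains[b]
    resid = centred - sum(mains.values()) - sum(inter.values())
    shares = {k: float((v**2).sum()) / total for k, v in {**mains, **inter}.items()}
    shares["residual"] = float((resid**2).sum()) / total
    return shares


def generate_experiment(cfg: SimulationConfig) -> tuple[PeakTable, SyntheticTruth]:
    """Generate one synthetic experiment: peak table plus ground truth.

    Deterministic given ``cfg`` (including its seed). Intensities follow

    ``intensity = exp(baseline + batch + passage + treatment) * drift(order) * noise``

    with every effect on the natural-log scale, drift a smooth decreasing
    function of normalised injection order, and noise multiplicative
    log-normal with coefficient of variation ``noise_cv``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    feature_ids = [f"F{i + 1:04d}" for i in range(cfg.n_features)]
    batches = [f"B{i + 1}" for i in range(cfg.n_batches)]
    passages = list(PASSAGE_LABELS[: cfg.n_passages]) + [
        f"P{30 + 3 * i}" for i in range(max(0, cfg.n_passages - len(PASSAGE_LABELS)))
    ]
    treatments = list(TREATMENT_LABELS[: cfg.n_treatments]) + [
        f"T{i + 1}" for i in range(max(0, cfg.n_treatments - len(TREATMENT_LABELS)))
    ]

    # ----- per-feature parameters -------------------------------------- #
    baseline = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_features)

    def centred_effects(levels: list[str], sd: float) -> pd.DataFrame:
        draw = rng.normal(0.0, sd, (cfg.n_features, len(levels))) if sd > 0 else np.zeros(
            (cfg.n_features, len(levels))
        )
        draw -= draw.mean(axis=1, keepdims=True)
        return pd.DataFrame(draw, index=feature_ids, columns=levels)

    batch_eff = centred_effects(batches, cfg.batch_effect_sd)
    passage_eff = centred_effects(passages, cfg.passage_effect_sd)

    n_resp = int(round(cfg.frac_treatment_responsive * cfg.n_features))
    responsive_idx = rng.choice(cfg.n_features, size=n_resp, replace=False)
    treatment_eff = centred_effects(treatments, cfg.treatment_effect_sd)
    mask = np.zeros(cfg.n_features, dtype=bool)
    mask[responsive_idx] = True
    treatment_eff.loc[~mask] = 0.0
    responsive = [feature_ids[i] for i in sorted(responsive_idx)]
    control = treatments[0]
    effect_sizes = treatment_eff.loc[responsive, treatments[1:]].sub(
        treatment_eff.loc[responsive, control], axis=0
    )

    jitter = rng.normal(0.0, cfg.drift_jitter, cfg.n_features) if cfg.drift_jitter > 0 else np.zeros(
        cfg.n_features
    )
    drift_mag = np.clip(cfg.drift_magnitude * (1.0 + jitter), 0.0, 0.95)
    drift_mag = pd.Series(drift_mag, index=feature_ids)

    # ----- injection sequence ------------------------------------------ #
    design = [
        (b, p, t, r)
        for b in batches
        for p in passages
        for t in treatments
        for r in range(1, cfg.replicates_per_cell + 1)
    ]
    order_perm = rng.permutation(len(design))
    study_rows = [design[i] for i in order_perm]

    records = []  # (sample_id, class, batch, passage, treatment, replicate)
    for i in range(cfg.n_blanks):
        records.append((f"BLANK{i + 1:02d}", "blank", None, None, None, None))
    qc_count = 1
    records.append((f"QC{qc_count:02d}", "qc", None, None, None, None))
    for i, (b, p, t, r) in enumerate(study_rows, start=1):
        records.append((f"S{i:03d}", "sample", b, p, t, r))
        if i % cfg.qc_interval == 0 and i < len(study_rows):
            qc_count += 1
            records.append((f"QC{qc_count:02d}", "qc", None, None, None, None))
    qc_count += 1
    records.append((f"QC{qc_count:02d}", "qc", None, None, None, None))

    samples = pd.DataFrame(
        records, columns=["sample_id", "sample_class", "batch", "passage", "treatment", "replicate"]
    ).set_index("sample_id")
    samples.insert(0, "injection_order", np.arange(1, len(samples) + 1))

    # ----- expected intensities ---------------------------------------- #
    n_total = len(samples)
    log_expected = np.zeros((cfg.n_features, n_total))
    is_study = (samples["sample_class"] == "sample").to_numpy()
    is_qc = (samples["sample_class"] == "qc").to_numpy()
    is_blank = (samples["sample_class"] == "blank").to_numpy()

    b_lab = samples["batch"].to_numpy()
    p_lab = samples["passage"].to_numpy()
    t_lab = samples["treatment"].to_numpy()
    for j in np.flatnonzero(is_study):
        log_expected[:, j] = (
            baseline
            + batch_eff[b_lab[j]].to_numpy()
            + passage_eff[p_lab[j]].to_numpy()
            + treatment_eff[t_lab[j]].to_numpy()
        )
    # pooled QC: mean of the study samples' drift-free expected intensities
    qc_base = np.exp(log_expected[:, is_study]).mean(axis=1)

    # ----- drift and noise ---------------------------------------------- #
    t_norm = (samples["injection_order"].to_numpy() - 1) / max(n_total - 1, 1)
    shape = _DRIFT_SHAPES[cfg.drift_shape](t_norm)
    drift = 1.0 - drift_mag.to_numpy()[:, None] * shape[None, :]  # features x samples

    sigma = float(np.sqrt(np.log1p(cfg.noise_cv**2)))
    noise = np.exp(rng.normal(0.0, sigma, (cfg.n_features, n_total))) if sigma > 0 else np.ones(
        (cfg.n_features, n_total)
    )

    intensity = np.full((cfg.n_features, n_total), np.nan)
    intensity[:, is_study] = np.exp(log_expected[:, is_study]) * drift[:, is_study] * noise[:, is_study]
    intensity[:, is_qc] = qc_base[:, None] * drift[:, is_qc] * noise[:, is_qc]

    n_contam = int(round(cfg.blank_contamination_frac * cfg.n_features))
    contam_idx = rng.choice(cfg.n_features, size=n_contam, replace=False)
    contam = [feature_ids[i] for i in sorted(contam_idx)]
    if cfg.n_blanks > 0 and n_contam > 0:
        # contamination sits well below the pooled-sample level
        blank_level = qc_base[contam_idx] / 20.0
        intensity[np.ix_(contam_idx, np.flatnonzero(is_blank))] = (
            blank_level[:, None] * noise[np.ix_(contam_idx, np.flatnonzero(is_blank))]
        )

    features = pd.DataFrame(
        {
            "mz": np.round(rng.uniform(70.0, 1000.0, cfg.n_features), 4),
            "rt": np.round(rng.uniform(30.0, 900.0, cfg.n_features), 2),
            "ion_mode": "positive",
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )

    pt = PeakTable(
        pd.DataFrame(intensity, index=feature_ids, columns=samples.index),
        samples,
        features,
    )

    with np.errstate(divide="ignore"):
        logx = np.log(intensity[:, is_study]).T  # samples x features
    shares = _log_variance_shares(logx, b_lab[is_study], p_lab[is_study], t_lab[is_study])
    truth = SyntheticTruth(
        batch_effects=batch_eff,
        passage_effects=passage_eff,
        treatment_effects=treatment_eff,
        responsive_features=responsive,
        treatment_effect_sizes=effect_sizes,
        drift_magnitudes=drift_mag,
        drift_shape=cfg.drift_shape,
        contamination_features=contam,
        variance_shares=shares,
    )
    return pt, truth


def config_for_variance_shares(
    batch: float,
    passage: float,
    treatment: float,
    noise_cv: float = 0.2,
    **overrides,
) -> SimulationConfig:
    """Build a config whose expected log-scale variance shares match targets.

    The requested shares are of the total per-feature log-intensity variance;
    the remainder is measurement noise, whose log-scale variance follows from
    ``noise_cv``. All features are made treatment-responsive so the treatment
    share is homogeneous. Drift defaults to zero here: drift is confounded
    with nothing by design but inflates the residual.
    """
    s_noise = 1.0 - (batch + passage + treatment)
    if s_noise <= 0:
        raise ValueError("factor shares must sum to < 1; the remainder is noise")
    sigma_e2 = float(np.log1p(noise_cv**2))
    sigma_tot2 = sigma_e2 / s_noise
    defaults = dict(
        batch_effect_sd=float(np.sqrt(sigma_tot2 * batch)),
        passage_effect_sd=float(np.sqrt(sigma_tot2 * passage)),
        treatment_effect_sd=float(np.sqrt(sigma_tot2 * treatment)),
        frac_treatment_responsive=1.0,
        noise_cv=noise_cv,
        drift_magnitude=0.0,
        drift_jitter=0.0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def generate_pathway_tables(
    n_pathways: int, shared_signal: float, seed: int, labels: tuple[str, str] = ("A", "B")
) -> tuple[PathwayTable, PathwayTable]:
    """Generate a pair of pathway-analysis result tables with tunable overlap.

    Each pathway gets coordinates (-log10 p, impact). ``shared_signal``
    interpolates the second table between an independent draw (0) and an
    exact copy of the first (1), so the Mantel correlation between the two
    tables' distance structures rises smoothly with it.
    """
    if n_pathways < 3:
        raise ValueError("n_pathways must be >= 3")
    if not 0.0 <= shared_signal <= 1.0:
        raise ValueError("shared_signal must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [f"path{i + 1:03d}" for i in range(n_pathways)]

    def draw() -> tuple[np.ndarray, np.ndarray]:
        neglogp = np.abs(rng.normal(0.0, 1.5, n_pathways))
        impact = rng.beta(1.0, 3.0, n_pathways)
        return neglogp, impact

    z_a, imp_a = draw()
    z_i, imp_i = draw()
    z_b = shared_signal * z_a + (1.0 - shared_signal) * z_i
    imp_b = shared_signal * imp_a + (1.0 - shared_signal) * imp_i

    def table(z: np.ndarray, imp: np.ndarray, label: str) -> PathwayTable:
        return PathwayTable(
            pd.DataFrame(
                {"pathway_id": ids, "p_value": np.power(10.0, -z), "impact": imp}
            ),
            comparison=label,
        )

    return table(z_a, imp_a, labels[0]), table(z_b, imp_b, labels[1])
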