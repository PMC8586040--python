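"""End-to-end workflow orchestration.

Fixed stage order (each stage toggleable, all thresholds configurable):

1. read peak table (or simulate one),
2. blank filtering (ratio < 3 uninformative),
3. QC-SVRC within-run drift correction,
4. low-total-signal outlier-sample screening,
5. RSD_QC / D-ratio* feature filtering (both 20% cutoffs),
6. ASCA variance decomposition with permutation p values (500 permutations),
7. per-batch and per-batch-x-passage univariate contrasts,
8. optional Mantel meta-analysis of supplied pathway-analysis tables.

Every stage writes its outputs under the run directory and records the
surviving feature/sample counts in a JSON manifest; identical config and
seed reproduce identical numeric outputs. Every feature or sample removed
is logged with the rule that removed it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .peak_table import PeakTable, read_peak_table, write_peak_table
from .simulate import SimulationConfig, generate_experiment
from .quality import blank_filter, apply_feature_filters, detect_outlier_samples
from .drift import SvrHyperParams, fit_qc_svrc, correct_intensities, correction_report
from .asca import AscaDesign, autoscale, study_matrix, asca_decompose, asca_permutation_test
from .univariate import ttest_contrast, results_frame, intersect_significant
from .pathway import read_pathway_table, pairwise_meta, results_to_frame

log = logging.getLogger("metaboqc")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serialisable to YAML."""

    # input: either the three CSV paths, or a simulation config
    intensity_path: str | None = None
    sample_meta_path: str | None = None
    feature_meta_path: str | None = None
    simulation: SimulationConfig | None = None
    pathway_tables: list[str] = field(default_factory=list)

    # stage toggles
    do_blank_filter: bool = True
    do_correction: bool = True
    do_outlier_screen: bool = True
    do_feature_filters: bool = True
    do_asca: bool = True
    do_univariate: bool = True

    # thresholds (defaults: blank ratio 3, both quality cutoffs 20%,
    # alpha 0.05, 500 ASCA / 999 Mantel permutations)
    blank_ratio_threshold: float = 3.0
    d_ratio_max: float = 20.0
    rsd_max: float = 20.0
    outlier_k: float = 3.0
    alpha: float = 0.05
    n_perm_asca: int = 500
    n_perm_mantel: int = 999
    control_treatment: str = "CA"
    log_transform: bool = True
    autoscale: bool = True
    svr: SvrHyperParams = field(default_factory=SvrHyperParams)

    seed: int = 0
    out_dir: str = "metaboqc_run"

    def validate(self) -> None:
        have_files = all(
            p is not None
            for p in (self.intensity_path, self.sample_meta_path, self.feature_meta_path)
        )
        if not have_files and self.simulation is None:
            raise ValueError("config needs either the three input paths or a simulation block")
        for name in ("blank_ratio_threshold", "d_ratio_max", "rsd_max", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        svr = raw.pop("svr", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        if svr is not None:
            cfg.svr = SvrHyperParams(**svr)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        if self.simulation is None:
            d.pop("simulation")
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _counts(pt: PeakTable) -> dict:
    return {
        "n_features": pt.n_features,
        "n_samples": pt.n_samples,
        "n_study": len(pt.study_ids),
        "n_qc": len(pt.qc_ids),
        "n_blank": len(pt.blank_ids),
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages in order; return the manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "blank_ratio": cfg.blank_ratio_threshold,
            "d_ratio_max": cfg.d_ratio_max,
            "rsd_max": cfg.rsd_max,
            "alpha": cfg.alpha,
            "n_perm_asca": cfg.n_perm_asca,
            "n_perm_mantel": cfg.n_perm_mantel,
        },
        "stages": [],
    }

    def record(stage: str, pt: PeakTable | None = None, **extra) -> None:
        entry: dict = {"stage": stage, **extra}
        if pt is not None:
            entry.update(_counts(pt))
        manifest["stages"].append(entry)
        log.info("stage %s: %s", stage, {k: v for k, v in entry.items() if k != "stage"})

    stage = "input"
    try:
        if cfg.simulation is not None:
            sim_cfg = cfg.simulation
            pt, _truth = generate_experiment(sim_cfg)
            record("simulate", pt, config=sim_cfg.to_dict())
        else:
            pt = read_peak_table(cfg.intensity_path, cfg.sample_meta_path, cfg.feature_meta_path)
            record("read", pt)

        if cfg.do_blank_filter:
            stage = "blank_filter"
            before = pt.n_features
            pt, blank_report = blank_filter(pt, cfg.blank_ratio_threshold)
            removed = blank_report.feature_metrics.index[
                blank_report.feature_metrics["uninformative_blank"]
            ]
            for fid in removed:
                log.info("removed feature %s: blank ratio < %s", fid, cfg.blank_ratio_threshold)
            blank_report.feature_metrics.to_csv(out / "blank_filter.csv")
            record("blank_filter", pt, n_removed=before - pt.n_features)

        if cfg.do_correction:
            stage = "qc_svrc"
            models = fit_qc_svrc(pt, cfg.svr)
            corrected, flags = correct_intensities(pt, models)
            rep = correction_report(pt, corrected, threshold=cfg.d_ratio_max)
            models.summary().to_csv(out / "drift_models.csv")
            write_peak_table(corrected, out, prefix="corrected")
            record(
                "qc_svrc",
                corrected,
                frac_d_ratio_pass_before=rep.frac_pass_before,
                frac_d_ratio_pass_after=rep.frac_pass_after,
                median_rsd_before=rep.median_rsd_before,
                median_rsd_after=rep.median_rsd_after,
                n_unstable=int(flags["unstable_correction"].sum()),
            )
            pt = corrected

        if cfg.do_outlier_screen:
            stage = "outlier_samples"
            sample_metrics = detect_outlier_samples(pt, cfg.outlier_k)
            outliers = sample_metrics.index[sample_metrics["outlier_flag"]]
            for sid in outliers:
                log.info("excluded sample %s: total signal below median - k*MAD", sid)
            sample_metrics.to_csv(out / "sample_screen.csv")
            if len(outliers):
                pt = pt.subset_samples([s for s in pt.samples.index if s not in set(outliers)])
            record("outlier_samples", pt, n_excluded=len(outliers))

        if cfg.do_feature_filters:
            stage = "feature_filters"
            before = pt.n_features
            pt, qreport = apply_feature_filters(pt, cfg.d_ratio_max, cfg.rsd_max)
            fm = qreport.feature_metrics
            for fid in fm.index[fm["high_d_ratio"] | fm["high_rsd"]]:
                log.info("removed feature %s: %s", fid, "D-ratio*>max" if fm.loc[fid, "high_d_ratio"] else "RSD_QC>max")
            fm.to_csv(out / "feature_quality.csv")
            record("feature_filters", pt, n_removed=before - pt.n_features)

        write_peak_table(pt, out, prefix="final")

        if cfg.do_asca:
            stage = "asca"
            matrix = study_matrix(pt, log=cfg.log_transform)
            matrix = matrix.dropna(axis=1, how="any")
            if cfg.autoscale:
                matrix, _params = autoscale(matrix)
            design = AscaDesign.from_peak_table(pt)
            result = asca_decompose(matrix, design)
            result.permutation_p = asca_permutation_test(
                matrix, design, n_perm=cfg.n_perm_asca, seed=cfg.seed
            )
            result.n_permutations = cfg.n_perm_asca
            tbl = result.table()
            tbl.to_csv(out / "asca_effects.csv", index=False)
            for name, sca in result.sca.items():
                sca.scores.to_csv(out / f"asca_scores_{name}.csv")
            record(
                "asca",
                effect_percent={k: round(v, 3) for k, v in result.effect_percent.items()},
                residual_percent=round(result.residual_percent, 3),
                p_values=result.permutation_p,
                balanced=result.balanced,
            )

        if cfg.do_univariate:
            stage = "univariate"
            treatments = sorted(
                set(pt.samples.loc[pt.samples["sample_class"] == "sample", "treatment"])
            )
            control = cfg.control_treatment
            if control not in treatments:
                raise ValueError(f"control treatment {control!r} not present in {treatments}")
            uni_summary = {}
            for treat in [t for t in treatments if t != control]:
                res_bp, skipped = ttest_contrast(
                    pt, treat, control, strata="batch_passage", alpha=cfg.alpha
                )
                res_b, _ = ttest_contrast(pt, treat, control, strata="batch", alpha=cfg.alpha)
                results_frame(res_bp).to_csv(out / f"ttests_{treat}_vs_{control}.csv", index=False)
                annotation = (
                    pt.features["annotation"] if "annotation" in pt.features.columns else None
                )
                inter = intersect_significant(res_b, annotation=annotation)
                pd.Series(inter.exactly_k).rename_axis("k").rename("n_features").to_csv(
                    out / f"intersections_{treat}_vs_{control}.csv"
                )
                uni_summary[treat] = {
                    "n_strata_skipped": len(skipped),
                    "significant_in_all_batches": len(inter.in_all),
                    "exactly_k": inter.exactly_k,
                }
            record("univariate", contrasts=uni_summary)

        if cfg.pathway_tables:
            stage = "mantel"
            tables = [read_pathway_table(p) for p in cfg.pathway_tables]
            results, summary = pairwise_meta(
                tables, n_perm=cfg.n_perm_mantel, seed=cfg.seed
            )
            results_to_frame(results).to_csv(out / "mantel_results.csv", index=False)
            record("mantel", **summary)

    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
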