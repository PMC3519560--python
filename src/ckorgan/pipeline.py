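"""End-to-end driver: detection -> models -> ratios -> categorization ->
shift analysis -> normalization/PCA, with TSV outputs and a JSON summary.

The pipeline is deterministic given the configuration (including the
simulation seed): running it twice into two directories produces
byte-identical files.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anova, categorize, detection, io, normalize_pca, shift
from .datamodel import ExpressionMatrix, GeneAnnotation, Thresholds
from .design import StudyDesign
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Either real input paths (expression/design/annotation TSVs) or a
    simulation stanza; plus thresholds and the output directory."""

    out_dir: str = "ckorgan_results"
    thresholds: Thresholds = field(default_factory=Thresholds)
    expression_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None
    simulation: SimulationConfig | None = None
    n_boot: int = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = Thresholds(**kwargs["thresholds"])
        if "simulation" in kwargs:
            kwargs["simulation"] = SimulationConfig(**kwargs["simulation"])
        return cls(**kwargs)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(type(obj))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the machine-readable summary dict.

    Partial outputs are removed if any stage fails; the raised
    :class:`StageError` names the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    summary: dict = {}
    stage = "load"
    try:
        t0 = time.time()
        if config.simulation is not None:
            design = None
            matrix, truth, annotation = simulate_dataset(config.simulation)
            from .design import generate_design
            design = generate_design()
            truth.write_tsv(out_dir / "truth.tsv")
        else:
            design = StudyDesign.read_tsv(config.design_path)
            matrix = io.read_expression_table(config.expression_path, design)
            annotation = (GeneAnnotation.read_tsv(config.annotation_path)
                          if config.annotation_path else None)
        log.info("stage load done (%.1fs)", time.time() - t0)

        stage = "detection"
        report = detection.apply_detection_filters(matrix, design, th)
        detection.write_detection_report(report, out_dir / "detection.tsv")
        summary["n_genes"] = int(matrix.n_genes)
        summary["n_not_expressed"] = int(report["not_expressed"].sum())
        summary["n_model_eligible"] = int(report["model_eligible"].sum())
        summary["n_induction_eligible"] = int(report["induction_eligible"].sum())
        summary["n_deficiency_eligible"] = int(report["deficiency_eligible"].sum())

        stage = "models"
        fits = {}
        for subset, flag in (("induction", "induction_eligible"),
                             ("deficiency", "deficiency_eligible"),
                             ("full", "model_eligible")):
            genes = report.index[report[flag] == 1].tolist()
            stats = anova.fit_all_genes(matrix, design, subset, genes)
            anova.write_stats_table(stats, out_dir / f"stats_{subset}.tsv")
            fits[subset] = stats
        log.info("stage models done")

        stage = "ratios"
        means = categorize.condition_means(matrix, design)
        ratios = categorize.fold_change_ratios(means)

        stage = "categorization"
        counts = {}
        for analysis, classify, stats in (
                ("induction", categorize.classify_induction, fits["induction"]),
                ("deficiency", categorize.classify_deficiency, fits["deficiency"])):
            calls = classify(ratios, stats, report, th)
            calls.to_csv(out_dir / f"categories_{analysis}.tsv", sep="\t")
            analyzed = calls[calls["category"] != "not_expressed"]
            io.write_results_tables(
                analyzed["category"], ratios.ratios, _q_columns(stats),
                report["abb_total"], annotation, out_dir,
                prefix=f"results_{analysis}")
            counts[analysis] = calls["category"].value_counts().to_dict()
        summary["category_counts"] = counts

        stage = "shift"
        both = report.index[(report["induction_eligible"] == 1)
                            & (report["deficiency_eligible"] == 1)]
        full_stats = fits["full"].reindex(both).dropna(how="all")
        sub_ratios = categorize.RatioTable(ratios.ratios.reindex(both),
                                           ratios.r_base.reindex(both))
        set_root = shift.find_shift_genes(sub_ratios, full_stats, th,
                                          mode="root_under_BA1080")
        set_shoot = shift.find_shift_genes(sub_ratios, full_stats, th,
                                           mode="shoot_under_CKX1")
        overlap = shift.shift_overlap(set_root, set_shoot)
        for gene_set, name in ((set_root, "shift_root_BA1080"),
                               (set_shoot, "shift_shoot_CKX1")):
            shift.write_shift_table(gene_set, sub_ratios, full_stats,
                                    report["abb_total"], annotation,
                                    out_dir / f"{name}.tsv")
        summary["shift"] = {
            "root_under_BA1080": len(set_root),
            "shoot_under_CKX1": len(set_shoot),
            "root_up_and_shoot_down": len(overlap["root_up_and_shoot_down"]),
            "root_down_and_shoot_up": len(overlap["root_down_and_shoot_up"]),
            "overlap_total": len(overlap["total"]),
        }
        if annotation is not None:
            count, frac = shift.localization_fraction(
                overlap["root_up_and_shoot_down"], annotation, "P")
            summary["shift"]["plastid_count_root_up"] = count
            summary["shift"]["plastid_fraction_root_up"] = frac

        stage = "normalize_pca"
        pca_genes = normalize_pca.select_pca_genes(report, fits["full"], th)
        complete = means.dropna(axis=0, how="any")
        pca_genes = [g for g in pca_genes if g in complete.index]
        profiles = complete.loc[pca_genes].T   # 10 condition profiles x genes
        profiles.index = [f"{o}_{c}" for o, c in profiles.index]
        native = normalize_pca.run_pca(profiles)
        norm_means = normalize_pca.organ_normalize(complete.loc[pca_genes])
        norm_profiles = norm_means.T
        norm_profiles.index = [f"{o}_{c}" for o, c in norm_profiles.index]
        normalized = normalize_pca.run_pca(norm_profiles)
        native.scores.to_csv(out_dir / "pca_scores_native.tsv", sep="\t")
        normalized.scores.to_csv(out_dir / "pca_scores_normalized.tsv", sep="\t")
        tree = normalize_pca.support_tree(profiles, n_boot=config.n_boot,
                                          seed=getattr(config.simulation, "seed", 0))
        (out_dir / "support_tree.nwk").write_text(tree.newick() + "\n")
        summary["pca"] = {
            "n_genes": len(pca_genes),
            "eigenvalue_fractions_native":
                [round(float(v), 6) for v in native.eigenvalue_fractions[:3]],
            "eigenvalue_fractions_normalized":
                [round(float(v), 6) for v in normalized.eigenvalue_fractions[:3]],
        }

        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True,
                      default=_json_default)
            fh.write("\n")
        return summary
    except Exception as exc:
        shutil.rmtree(out_dir, ignore_errors=True)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc


def _q_columns(stats: pd.DataFrame) -> pd.DataFrame:
    return stats[[c for c in stats.columns if c.startswith("q_")]]
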