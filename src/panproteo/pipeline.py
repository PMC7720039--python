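"""End-to-end orchestration from a single config.

Stage order: (simulate | load) -> sample qualification -> quantifiability
filter -> housekeeping detection (pre-imputation) -> imputation -> tissue
enrichment -> tumor-vs-normal differential analysis -> cross-cancer
aggregation, uniqueness, protein-group clustering -> annotation joins.

Every stage writes its table to the output directory so each downstream
stage can be re-run standalone on the upstream files; the run summary JSON
records the counts at every stage together with the fully resolved config
(all thresholds and mode switches actually used). Given the same seed the
summary is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, differential, enrichment, housekeeping, qc, quantfilter
from .io_tables import (
    AnnotationTable,
    IntensityMatrix,
    SampleMetadata,
    median_normalize,
    read_annotation,
    read_intensity_matrix,
    read_metadata,
    write_intensity_matrix,
)
from .quantfilter import ImputeConfig
from .simulate import GroundTruth, SimConfig, generate_cohort, write_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage thresholds and mode switches, with study defaults."""

    out_dir: str = "results"
    # inputs: either simulate a cohort or point at existing tables
    simulate: bool = True
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    matrix_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    matrix_layout: str = "wide"
    # stages
    normalize: bool = False
    qc: qc.QCConfig = field(default_factory=qc.QCConfig)
    impute: ImputeConfig = field(default_factory=ImputeConfig)
    min_frac_quant: float = 0.4
    hk_presence: float = 0.9
    hk_per_tissue: bool = False
    fc_enrich: float = 4.0
    fc_diff: float = 2.0
    alpha: float = 0.05
    coverage: float = 0.7
    cross_cancer_frac: float = 0.4
    aggregate_strict: bool = True
    k_clusters: int = 4
    linkage_method: str = "ward"
    equal_var: bool = False

    def validate(self) -> None:
        for name in ("min_frac_quant", "hk_presence", "alpha",
                     "cross_cancer_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError(f"coverage={self.coverage} outside (0, 1]")
        if self.fc_enrich <= 1.0 or self.fc_diff <= 1.0:
            raise ValueError("fold-change thresholds must exceed 1")
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")
        if not self.simulate:
            if not (self.matrix_path and self.metadata_path):
                raise ValueError(
                    "matrix_path and metadata_path required unless simulating"
                )
        self.sim.validate()

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        obj = dict(obj)
        if "sim" in obj and isinstance(obj["sim"], dict):
            sim = dict(obj["sim"])
            if "samples_per_tissue" in sim:
                sim["samples_per_tissue"] = {
                    t: tuple(v) for t, v in sim["samples_per_tissue"].items()
                }
            obj["sim"] = SimConfig(**sim)
        if "qc" in obj and isinstance(obj["qc"], dict):
            obj["qc"] = qc.QCConfig(**obj["qc"])
        if "impute" in obj and isinstance(obj["impute"], dict):
            obj["impute"] = ImputeConfig(**obj["impute"])
        return cls(**obj)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return (and write) the machine-readable summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": _jsonable(config.to_dict()), "stages": {}}

    # -- inputs ------------------------------------------------------------
    annotation: AnnotationTable | None = None
    truth: GroundTruth | None = None
    if config.simulate:
        sim = dataclasses.replace(config.sim, rng_seed=config.seed)
        matrix, metadata, truth = generate_cohort(sim)
        write_cohort(out, matrix, metadata, truth)
    else:
        matrix = read_intensity_matrix(config.matrix_path, config.matrix_layout)
        metadata = read_metadata(config.metadata_path)
        metadata.check_against(matrix)
    if config.annotation_path:
        annotation = read_annotation(config.annotation_path)
    summary["stages"]["input"] = {
        "n_proteins": int(matrix.shape[0]),
        "n_samples": int(matrix.shape[1]),
        "n_missing": int((~matrix.observed()).to_numpy().sum()),
    }

    if config.normalize:
        matrix = median_normalize(matrix)

    # -- sample qualification ---------------------------------------------
    report = qc.assess_samples(matrix, metadata, config.qc)
    report.to_csv(out / "qc_report.tsv", sep="\t")
    matrix, metadata = qc.apply_qualification(matrix, metadata, report)
    summary["stages"]["qc"] = {
        "n_qualified": int(report["qualified"].sum()),
        "n_disqualified": int((~report["qualified"]).sum()),
        "disqualified": report.index[~report["qualified"]].tolist(),
    }

    # -- quantifiability + housekeeping (pre-imputation) -------------------
    filtered, decisions = quantfilter.quantifiability_filter(
        matrix, metadata, config.min_frac_quant
    )
    decisions.to_csv(out / "quantifiability.tsv", sep="\t")
    summary["stages"]["quant_filter"] = {
        "n_retained": int(decisions["retained"].sum()),
        "n_dropped": int((~decisions["retained"]).sum()),
    }

    hk = housekeeping.identify_housekeeping(
        filtered, metadata, config.hk_presence, per_tissue=config.hk_per_tissue
    )
    hk.to_csv(out / "housekeeping.tsv", sep="\t")
    hk_stage = {
        "n_universal_tumor": int(hk["universal_tumor"].sum()),
        "n_universal_normal": int(hk["universal_normal"].sum()),
        "n_housekeeping": int(hk["housekeeping"].sum()),
    }
    if annotation is not None:
        ref = annotation.ids_with("is_hpa_housekeeping")
        if ref:
            cmp = housekeeping.compare_reference(hk, ref)
            hk_stage["reference_overlap"] = {
                k: v for k, v in cmp.items() if k != "overlap_ids"
            }
    summary["stages"]["housekeeping"] = hk_stage

    # -- imputation --------------------------------------------------------
    imputed = quantfilter.impute_missing(filtered, metadata, config.impute)
    write_intensity_matrix(imputed, out / "imputed.tsv")
    summary["stages"]["imputation"] = {
        "n_filled": int(
            (~filtered.observed()).to_numpy().sum()
        ),
        "complete": bool(imputed.observed().to_numpy().all()),
    }

    # -- tissue enrichment -------------------------------------------------
    stats = enrichment.pairwise_tissue_stats(
        imputed, metadata, equal_var=config.equal_var
    )
    enr = enrichment.classify_enriched(
        stats, config.fc_enrich, config.alpha, config.coverage
    )
    enr.to_frame().to_csv(out / "enrichment.tsv", sep="\t")
    breakdown = enrichment.multiplicity_breakdown(enr)
    groups = enrichment.group_enrichment(
        imputed, metadata,
        fc_folds=config.fc_enrich, alpha=config.alpha,
        coverage=config.coverage, equal_var=config.equal_var,
    )
    summary["stages"]["enrichment"] = {
        "n_enriched": int((enr.multiplicity > 0).sum()),
        "multiplicity": {
            cat: int(breakdown.loc[cat, "count"]) for cat in breakdown.index
        },
        "group_enriched": {g: len(ids) for g, ids in sorted(groups.items())},
    }

    # -- differential ------------------------------------------------------
    tables = differential.differential_all_cancers(
        imputed, metadata,
        fc_folds=config.fc_diff, alpha=config.alpha, equal_var=config.equal_var,
    )
    long = []
    for cancer, table in sorted(tables.items()):
        t = table.reset_index()
        t.insert(0, "cancer", cancer)
        long.append(t)
    if long:
        pd.concat(long, ignore_index=True).to_csv(
            out / "differential.tsv", sep="\t", index=False
        )
    per_cancer = {
        c: {
            "n_up": int((t["call"] == "up").sum()),
            "n_down": int((t["call"] == "down").sum()),
        }
        for c, t in sorted(tables.items())
    }
    skipped = [
        c for c in metadata.tissues_present() if c not in tables
    ]
    common = differential.aggregate_cross_cancer(
        tables, config.cross_cancer_frac, strict=config.aggregate_strict
    )
    common.to_csv(out / "common_up.tsv", sep="\t")
    unique = differential.unique_cancer_proteins(tables)
    unique.to_frame().to_csv(out / "unique_up.tsv", sep="\t")
    associated = differential.cancer_associated_proteins(tables)

    cluster_stage: dict = {"n_cancer_associated": int(len(associated))}
    if len(associated) >= config.k_clusters:
        assignment = differential.cluster_protein_groups(
            imputed, metadata, associated,
            k=config.k_clusters, method=config.linkage_method,
        )
        assignment.to_frame().to_csv(out / "protein_groups.tsv", sep="\t")
        sizes = assignment.labels.value_counts().sort_index()
        cluster_stage["group_sizes"] = {g: int(n) for g, n in sizes.items()}
    else:
        cluster_stage["group_sizes"] = None
        logger.info("too few cancer-associated proteins to cluster")
    summary["stages"]["differential"] = {
        "per_cancer": per_cancer,
        "skipped_cancers": skipped,
        "n_common_up": int(len(common)),
        "n_unique": int(len(unique)),
    }
    summary["stages"]["clustering"] = cluster_stage

    # -- annotation joins --------------------------------------------------
    if annotation is not None and tables:
        candidates = annotate.druggable_candidates(tables, annotation)
        candidates.to_csv(out / "druggable_candidates.tsv", sep="\t", index=False)
        ct = annotate.ct_antigen_calls(
            tables, annotation, quantified_ids=imputed.protein_ids
        )
        ct.to_csv(out / "ct_antigens.tsv", sep="\t", index=False)
        drivers = annotate.driver_overlap(tables, annotation)
        drivers.to_csv(out / "driver_overlap.tsv", sep="\t", index=False)
        summary["stages"]["annotation"] = {
            "n_druggable_candidates": int(len(candidates)),
            "n_ct_detected": int(ct["detected"].sum()),
            "n_ct_elevated": int(ct["elevated"].sum()),
            "n_driver_overlap": int(len(drivers)),
        }

    with open(out / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _jsonable(obj):
    """Recursively coerce config values to JSON-stable types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
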