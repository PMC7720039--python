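"""Synthetic pan-cancer cohort generator with planted ground truth.

Emulates the statistical structure the downstream analysis assumes: 16
tissue types each with a tumor and a pooled-normal arm (cohort sizes default
to the study design this package targets), log-normally distributed protein
intensities, intensity-dependent dropout, planted housekeeping proteins
(observed everywhere), planted tissue-enriched proteins at several
multiplicities, planted per-cancer up/down-regulated proteins, and planted
low-quality outlier samples constructed to fail the sample-qualification
criteria.

Everything is driven by one integer seed; equal seeds give byte-identical
cohorts. The planted answers are returned as machine-readable
:class:`GroundTruth` and can be serialized to JSON next to the matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_tables import (
    IntensityMatrix,
    SampleMetadata,
    TISSUES,
    TISSUE_GROUPS,
    write_intensity_matrix,
    write_metadata,
)


class ConfigurationError(ValueError):
    """The simulation config is infeasible."""


#: Tumor / normal arm sizes per tissue mirroring the target study cohort
#: (normal = tumor-adjacent plus true normal tissues, pooled). The brain
#: cohort is tumor-only.
DEFAULT_SAMPLES_PER_TISSUE: dict[str, tuple[int, int]] = {
    "head_neck": (6, 6),
    "brain": (12, 0),
    "lung_adeno": (10, 10),
    "lung_squamous": (8, 8),
    "lung_small_cell": (6, 6),
    "esophagus": (7, 7),
    "stomach": (9, 9),
    "pancreas": (8, 8),
    "colon": (11, 11),
    "liver": (8, 8),
    "kidney": (10, 10),
    "bladder": (11, 11),
    "prostate": (7, 7),
    "breast": (5, 5),
    "ovary": (7, 7),
    "uterus": (4, 4),
}


@dataclass
class SimConfig:
    """Knobs of the cohort generator.

    Effects are additive on the log2 scale (multiplicative on intensities):
    ``enrichment_log2_effect`` is the planted tissue-enrichment shift (>= 2
    means > 4-fold) and ``cancer_log2_effect`` the planted tumor-vs-normal
    shift (>= 1 means > 2-fold). ``missing_intensity_slope`` controls how
    strongly dropout concentrates at low intensity (0 = missing completely
    at random at ``missing_rate``).
    """

    samples_per_tissue: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SAMPLES_PER_TISSUE)
    )
    n_proteins: int = 2000
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    noise_log2_sd: float = 0.3
    n_housekeeping: int = 200
    n_tissue_enriched: dict[str, int] = field(
        default_factory=lambda: {"1": 50, "2": 20, "3": 10, "4+": 5}
    )
    enrichment_log2_effect: float = 3.0
    n_cancer_up: int = 10
    n_cancer_down: int = 10
    cancer_log2_effect: float = 2.0
    missing_rate: float = 0.10
    missing_intensity_slope: float = 1.0
    n_outlier_samples: int = 4
    outlier_missing_rate: float = 0.6
    outlier_log2_shift: float = 2.0
    #: proteins per expression archetype (normal-high, pan-tumor-high, and
    #: two tissue-restricted tumor-high classes); 0 disables the planting
    n_archetype_per_class: int = 0
    archetype_log2_effect: float = 2.0
    rng_seed: int = 0

    def validate(self) -> None:
        unknown = sorted(set(self.samples_per_tissue) - set(TISSUES))
        if unknown:
            raise ConfigurationError(f"unknown tissues in config: {unknown}")
        for t, (nt, nn) in self.samples_per_tissue.items():
            if nt < 0 or nn < 0:
                raise ConfigurationError(f"negative sample count for {t}")
        if self.n_proteins <= 0:
            raise ConfigurationError("n_proteins must be positive")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1]")
        bad_cat = sorted(set(self.n_tissue_enriched) - {"1", "2", "3", "4+"})
        if bad_cat:
            raise ConfigurationError(f"unknown multiplicity categories: {bad_cat}")
        if any(v < 0 for v in self.n_tissue_enriched.values()):
            raise ConfigurationError("multiplicity counts must be non-negative")
        if min(self.n_housekeeping, self.n_cancer_up, self.n_cancer_down) < 0:
            raise ConfigurationError("planted counts must be non-negative")
        if self.n_archetype_per_class < 0:
            raise ConfigurationError("n_archetype_per_class must be non-negative")
        n_cancers = len(self.samples_per_tissue)
        planted = (
            self.n_housekeeping
            + sum(self.n_tissue_enriched.values())
            + n_cancers * (self.n_cancer_up + self.n_cancer_down)
            + 4 * self.n_archetype_per_class
        )
        if planted > self.n_proteins:
            raise ConfigurationError(
                f"{planted} planted proteins exceed n_proteins={self.n_proteins}"
            )
        if self.n_outlier_samples > self.n_samples():
            raise ConfigurationError("more outliers than samples")

    def n_samples(self) -> int:
        return sum(nt + nn for nt, nn in self.samples_per_tissue.values())

    def tissues(self) -> list[str]:
        return [t for t in TISSUES if t in self.samples_per_tissue]


@dataclass
class GroundTruth:
    """Machine-readable planted answers for a generated cohort."""

    housekeeping_ids: set[str]
    enriched_map: dict[str, set[str]]  # protein -> tissues it is enriched in
    cancer_up_map: dict[str, set[str]]
    cancer_down_map: dict[str, set[str]]
    outlier_sample_ids: set[str]
    archetype_map: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        obj = {
            "housekeeping_ids": sorted(self.housekeeping_ids),
            "enriched_map": {p: sorted(t) for p, t in sorted(self.enriched_map.items())},
            "cancer_up_map": {p: sorted(t) for p, t in sorted(self.cancer_up_map.items())},
            "cancer_down_map": {p: sorted(t) for p, t in sorted(self.cancer_down_map.items())},
            "outlier_sample_ids": sorted(self.outlier_sample_ids),
            "archetype_map": dict(sorted(self.archetype_map.items())),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls(
            housekeeping_ids=set(obj["housekeeping_ids"]),
            enriched_map={p: set(t) for p, t in obj["enriched_map"].items()},
            cancer_up_map={p: set(t) for p, t in obj["cancer_up_map"].items()},
            cancer_down_map={p: set(t) for p, t in obj["cancer_down_map"].items()},
            outlier_sample_ids=set(obj["outlier_sample_ids"]),
            archetype_map=dict(obj.get("archetype_map", {})),
        )


def _calibrate_dropout(latent: np.ndarray, rate: float, slope: float) -> np.ndarray:
    """Per-cell dropout probabilities, logistic in latent log2 intensity.

    The intercept is centred by bisection so that the marginal mean dropout
    probability equals ``rate``.
    """
    if rate <= 0.0:
        return np.zeros_like(latent)
    if rate >= 1.0:
        return np.ones_like(latent)
    if slope == 0.0:
        return np.full_like(latent, rate)

    def mean_prob(c: float) -> float:
        return float(expit(slope * (c - latent)).mean())

    lo, hi = latent.min() - 50.0, latent.max() + 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_prob(mid) < rate:
            lo = mid
        else:
            hi = mid
    return expit(slope * (0.5 * (lo + hi) - latent))


def generate_cohort(
    config: SimConfig,
) -> tuple[IntensityMatrix, SampleMetadata, GroundTruth]:
    """Generate one cohort: intensities, metadata, and planted truth."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    tissues = config.tissues()

    # -- samples ----------------------------------------------------------
    rows = []
    for tissue in tissues:
        n_tumor, n_normal = config.samples_per_tissue[tissue]
        for i in range(n_tumor):
            rows.append((f"{tissue}_T{i + 1:02d}", f"{tissue}_P{i + 1:02d}",
                         tissue, "tumor"))
        for i in range(n_normal):
            # matched pairs share the patient id where both arms exist
            rows.append((f"{tissue}_N{i + 1:02d}", f"{tissue}_P{i + 1:02d}",
                         tissue, "NAT"))
    meta = pd.DataFrame(rows, columns=["sample_id", "patient_id", "tissue", "state"])
    sample_ids = meta["sample_id"].to_numpy()
    n_samples = len(sample_ids)
    tissue_of = meta["tissue"].to_numpy()
    state_of = meta["state"].to_numpy()

    # -- proteins and planted roles ---------------------------------------
    n_p = config.n_proteins
    protein_ids = np.array([f"P{i + 1:05d}" for i in range(n_p)])
    order = rng.permutation(n_p)
    cursor = 0

    hk_idx = order[cursor:cursor + config.n_housekeeping]
    cursor += config.n_housekeeping

    enriched_map: dict[str, set[str]] = {}
    enriched_idx: dict[int, list[str]] = {}
    for cat, count in sorted(config.n_tissue_enriched.items()):
        mult = 4 if cat == "4+" else int(cat)
        mult = min(mult, len(tissues))
        for _ in range(count):
            p = order[cursor]
            cursor += 1
            chosen = rng.choice(len(tissues), size=mult, replace=False)
            tset = [tissues[j] for j in sorted(chosen)]
            enriched_map[protein_ids[p]] = set(tset)
            enriched_idx[p] = tset

    cancer_up_map: dict[str, set[str]] = {}
    cancer_down_map: dict[str, set[str]] = {}
    up_idx: dict[int, str] = {}
    down_idx: dict[int, str] = {}
    for tissue in tissues:
        for _ in range(config.n_cancer_up):
            p = order[cursor]
            cursor += 1
            cancer_up_map.setdefault(protein_ids[p], set()).add(tissue)
            up_idx[p] = tissue
        for _ in range(config.n_cancer_down):
            p = order[cursor]
            cursor += 1
            cancer_down_map.setdefault(protein_ids[p], set()).add(tissue)
            down_idx[p] = tissue

    # archetype classes: coherent cross-cancer patterns for clustering
    archetype_map: dict[str, str] = {}
    archetype_idx: dict[int, str] = {}
    if config.n_archetype_per_class:
        classes = [
            ("normal_high", None),
            ("tumor_high", None),
            ("digestive_tumor_high",
             [t for t in tissues if t in TISSUE_GROUPS["digestive"]]),
            ("urinary_tumor_high",
             [t for t in tissues if t in TISSUE_GROUPS["urinary"]]),
        ]
        for name, restricted in classes:
            for _ in range(config.n_archetype_per_class):
                p = order[cursor]
                cursor += 1
                archetype_map[protein_ids[p]] = name
                archetype_idx[p] = name
                targets = restricted if restricted is not None else tissues
                the_map = cancer_down_map if name == "normal_high" else cancer_up_map
                the_map.setdefault(protein_ids[p], set()).update(targets)

    # -- latent log2 intensities ------------------------------------------
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_p)
    latent = baseline[:, None] + rng.normal(
        0.0, config.noise_log2_sd, (n_p, n_samples)
    )

    col_of_tissue = {t: np.flatnonzero(tissue_of == t) for t in tissues}
    tumor_cols = {t: np.flatnonzero((tissue_of == t) & (state_of == "tumor"))
                  for t in tissues}

    for p, tset in enriched_idx.items():
        for t in tset:
            latent[p, col_of_tissue[t]] += config.enrichment_log2_effect
    for p, t in up_idx.items():
        latent[p, tumor_cols[t]] += config.cancer_log2_effect
    for p, t in down_idx.items():
        latent[p, tumor_cols[t]] -= config.cancer_log2_effect
    for p, name in archetype_idx.items():
        pid = protein_ids[p]
        sign = -1.0 if name == "normal_high" else 1.0
        targets = (cancer_down_map if name == "normal_high" else cancer_up_map)[pid]
        for t in targets:
            latent[p, tumor_cols[t]] += sign * config.archetype_log2_effect

    # -- outlier samples ---------------------------------------------------
    outlier_cols = rng.choice(n_samples, size=config.n_outlier_samples,
                              replace=False) if config.n_outlier_samples else np.array([], int)
    outlier_ids = set(sample_ids[outlier_cols])
    for s in outlier_cols:
        shift = config.outlier_log2_shift * rng.choice([-1.0, 1.0])
        latent[:, s] += shift
        # replace half the proteome with values independent of the shared
        # protein baselines -> decorrelates the sample from its tissue
        replaced = rng.choice(n_p, size=n_p // 2, replace=False)
        latent[replaced, s] = rng.normal(
            config.baseline_log2_mean + shift, config.baseline_log2_sd,
            replaced.size,
        )

    # -- dropout -----------------------------------------------------------
    p_miss = _calibrate_dropout(latent, config.missing_rate,
                                config.missing_intensity_slope)
    missing = rng.random((n_p, n_samples)) < p_miss
    if len(hk_idx):
        missing[hk_idx, :] = False  # housekeeping proteins observed everywhere
    for s in outlier_cols:
        extra = rng.random(n_p) < config.outlier_missing_rate
        missing[:, s] |= extra

    intensities = np.power(2.0, latent)
    intensities[missing] = np.nan

    matrix = IntensityMatrix(
        pd.DataFrame(intensities, index=protein_ids, columns=sample_ids)
    )
    metadata = SampleMetadata(meta)
    truth = GroundTruth(
        housekeeping_ids=set(protein_ids[hk_idx]),
        enriched_map=enriched_map,
        cancer_up_map=cancer_up_map,
        cancer_down_map=cancer_down_map,
        outlier_sample_ids=outlier_ids,
        archetype_map=archetype_map,
    )
    return matrix, metadata, truth


def write_cohort(outdir, matrix: IntensityMatrix, metadata: SampleMetadata,
                 truth: GroundTruth) -> dict[str, str]:
    """Serialize a cohort as matrix.tsv / metadata.tsv / truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": str(outdir / "matrix.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    write_intensity_matrix(matrix, paths["matrix"])
    write_metadata(metadata, paths["metadata"])
    truth.to_json(paths["truth"])
    return paths
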