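"""Tables the pipeline reads and writes, with strict validation.

The single object flowing through every stage is the :class:`IntensityMatrix`
(proteins x samples, non-negative MS intensities, missing entries explicit).
Sample metadata carries the 16-tissue vocabulary and the tumor / NAT / normal
disease state; NAT and normal tissues are pooled into one "normal" group for
every downstream comparison.

All interchange is tab-delimited UTF-8 text with a header row; no binary
formats. Zero or negative intensities are treated as not-quantified (missing)
and the coercion is counted and logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed vocabulary of the 16 tissue types (one per cancer cohort).
TISSUES: tuple[str, ...] = (
    "head_neck",
    "brain",
    "lung_adeno",
    "lung_squamous",
    "lung_small_cell",
    "esophagus",
    "stomach",
    "pancreas",
    "colon",
    "liver",
    "kidney",
    "bladder",
    "prostate",
    "breast",
    "ovary",
    "uterus",
)

#: Disease states; NAT (tumor-adjacent normal) pools with normal downstream.
STATES: tuple[str, ...] = ("tumor", "NAT", "normal")

#: Anatomic tissue groups used for group-level enrichment.
TISSUE_GROUPS: dict[str, tuple[str, ...]] = {
    "digestive": ("colon", "stomach", "esophagus", "pancreas", "liver"),
    "urinary": ("bladder", "prostate", "kidney"),
    "gynecologic": ("breast", "uterus", "ovary"),
}


class FormatError(ValueError):
    """A table violated its structural contract."""


@dataclass
class IntensityMatrix:
    """Protein quantification matrix: proteins (rows) x samples (columns).

    Observed values are strictly positive intensities in arbitrary MS units;
    missing entries are NaN and are distinguishable from zero (zeros are
    coerced to missing on construction, with a logged count).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate protein ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        df = df.astype(float)
        if (df.to_numpy() < 0).any():
            raise FormatError("negative intensities are not allowed")
        n_zero = int((df.to_numpy() == 0).sum())
        if n_zero:
            logger.info("coercing %d zero intensities to missing", n_zero)
            df = df.replace(0.0, np.nan)
        object.__setattr__(self, "data", df)

    # -- basic accessors ---------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def observed(self) -> pd.DataFrame:
        """Boolean mask of quantified cells."""
        return self.data.notna()

    def log2(self) -> pd.DataFrame:
        """Log2-transformed intensities (missing stays missing)."""
        return np.log2(self.data)

    def select_samples(self, sample_ids: Sequence[str]) -> "IntensityMatrix":
        return IntensityMatrix(self.data.loc[:, list(sample_ids)].copy())

    def select_proteins(self, protein_ids: Sequence[str]) -> "IntensityMatrix":
        return IntensityMatrix(self.data.loc[list(protein_ids)].copy())


@dataclass
class SampleMetadata:
    """Per-sample annotations: patient, tissue (16-value vocabulary), state."""

    table: pd.DataFrame  # columns: sample_id, patient_id, tissue, state

    REQUIRED = ("sample_id", "patient_id", "tissue", "state")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing required columns: {missing}")
        if df["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in metadata")
        bad_tissue = sorted(set(df["tissue"]) - set(TISSUES))
        if bad_tissue:
            raise FormatError(f"unknown tissue labels: {bad_tissue}")
        bad_state = sorted(set(df["state"]) - set(STATES))
        if bad_state:
            raise FormatError(f"unknown disease states: {bad_state}")
        df = df.copy()
        # NATs and normal tissues are analysed as a single normal group.
        df["group"] = np.where(df["state"] == "tumor", "tumor", "normal")
        object.__setattr__(self, "table", df.reset_index(drop=True))

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    def tissue_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["tissue"]

    def group_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["group"]

    def samples(
        self,
        tissue: str | None = None,
        group: str | None = None,
    ) -> list[str]:
        t = self.table
        if tissue is not None:
            t = t[t["tissue"] == tissue]
        if group is not None:
            t = t[t["group"] == group]
        return t["sample_id"].tolist()

    def tissues_present(self) -> list[str]:
        present = set(self.table["tissue"])
        return [t for t in TISSUES if t in present]

    def restrict(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        keep = set(sample_ids)
        return SampleMetadata(
            self.table[self.table["sample_id"].isin(keep)]
            .drop(columns="group")
            .copy()
        )

    def check_against(self, matrix: IntensityMatrix) -> None:
        """Raise naming the mismatch set if sample ids disagree."""
        meta = set(self.sample_ids)
        mat = set(matrix.sample_ids)
        if meta != mat:
            only_meta = sorted(meta - mat)
            only_mat = sorted(mat - meta)
            raise FormatError(
                "sample id mismatch between metadata and matrix: "
                f"metadata-only={only_meta[:10]}, matrix-only={only_mat[:10]}"
            )


ANNOTATION_FLAGS = (
    "is_drug_target",
    "is_fda_approved_target",
    "is_ct_antigen",
    "is_driver_gene",
    "is_hpa_housekeeping",
)


@dataclass
class AnnotationTable:
    """Per-protein boolean annotation flags plus optional drug names."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if "protein_id" not in df.columns:
            raise FormatError("annotation table needs a protein_id column")
        if df["protein_id"].duplicated().any():
            raise FormatError("duplicate protein ids in annotation table")
        df = df.copy()
        for flag in ANNOTATION_FLAGS:
            if flag not in df.columns:
                df[flag] = False
            col = df[flag]
            if col.dtype != bool:
                df[flag] = (
                    col.astype(str).str.strip().str.lower().map(
                        {"true": True, "1": True, "false": False, "0": False}
                    )
                )
                if df[flag].isna().any():
                    raise FormatError(f"non-boolean values in flag {flag!r}")
                df[flag] = df[flag].astype(bool)
        if "drugs" not in df.columns:
            df["drugs"] = ""
        df["drugs"] = df["drugs"].fillna("")
        object.__setattr__(self, "table", df.reset_index(drop=True))

    def ids_with(self, flag: str) -> set[str]:
        if flag not in ANNOTATION_FLAGS:
            raise KeyError(flag)
        t = self.table
        return set(t.loc[t[flag], "protein_id"])

    def drugs_of(self) -> pd.Series:
        return self.table.set_index("protein_id")["drugs"]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_intensity_matrix(path, layout: str = "wide") -> IntensityMatrix:
    """Read a quantification matrix from TSV.

    ``wide``: first column = protein id, one column per sample, blank / NA /
    zero cells parsed as missing. ``long``: columns (protein_id, sample_id,
    intensity), one row per observed cell; pivoted to wide.
    """
    if layout == "wide":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = None
        df.columns.name = None
        return IntensityMatrix(df)
    if layout == "long":
        long = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "sample_id": str})
        need = {"protein_id", "sample_id", "intensity"}
        if not need.issubset(long.columns):
            raise FormatError(f"long layout requires columns {sorted(need)}")
        if long.duplicated(["protein_id", "sample_id"]).any():
            raise FormatError("duplicate (protein, sample) pairs in long table")
        wide = long.pivot(index="protein_id", columns="sample_id", values="intensity")
        wide.index.name = None
        wide.columns.name = None
        return IntensityMatrix(wide)
    raise ValueError(f"unknown layout {layout!r}")


def write_intensity_matrix(matrix: IntensityMatrix, path) -> None:
    matrix.data.rename_axis("protein_id").to_csv(path, sep="\t", na_rep="")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.table.drop(columns="group").to_csv(path, sep="\t", index=False)


def read_annotation(path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t")
    df["protein_id"] = df["protein_id"].astype(str)
    return AnnotationTable(df)


def write_annotation(annotation: AnnotationTable, path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def median_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Cross-run normalization on the sample median.

    Each sample is scaled (a shift on the log2 scale) so that its median
    observed log2 intensity equals the global median of the pre-normalization
    sample medians. The missingness pattern is unchanged.
    """
    log2 = matrix.log2()
    medians = log2.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = medians.index[medians.isna()].tolist()
        raise ValueError(f"samples with no observed values: {bad}")
    target = float(np.median(medians.to_numpy()))
    shift = target - medians  # log2 shift per sample
    out = matrix.data.mul(np.power(2.0, shift), axis=1)
    return IntensityMatrix(out)
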