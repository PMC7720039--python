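"""Tumor-vs-normal differential analysis, aggregation and clustering.

Per cancer type, every protein is tested tumor vs normal (Welch t on log2
intensities) with BH adjustment across proteins within the cancer; calls are
"up" (log2 fc > 1, adjusted p < 0.05), "down" (symmetric), else "none" —
i.e. a fold change above 2 at 5% FDR. Cancers without at least two samples
in each arm (the tumor-only brain cohort, for instance) are skipped with a
logged notice.

Cross-cancer aggregation collects proteins called up in strictly more than
40% of the analysed cancers (7 of 16), uniqueness calls pick proteins up in
exactly one cancer, and the cancer-associated proteins are partitioned into
four protein groups by Ward hierarchical clustering of per-protein Z-scored
expression profiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .io_tables import IntensityMatrix, SampleMetadata
from .stats import bh_adjust, welch_t_test_arrays

logger = logging.getLogger(__name__)


def tumor_vs_normal(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    cancer: str,
    fc_folds: float = 2.0,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Differential table for one cancer type.

    Columns: log2_fc (tumor - normal), p, adj_p, call in {up, down, none}.
    Raises ``ValueError`` if either arm has fewer than two samples; callers
    skip the cancer.
    """
    tumor = metadata.samples(tissue=cancer, group="tumor")
    normal = metadata.samples(tissue=cancer, group="normal")
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            f"cancer {cancer}: need >=2 tumor and >=2 normal samples "
            f"(have {len(tumor)}/{len(normal)})"
        )
    log2 = matrix.log2()
    t_block = log2[tumor]
    n_block = log2[normal]
    fc, t_stat, p = welch_t_test_arrays(
        t_block.mean(axis=1).to_numpy(),
        t_block.var(axis=1, ddof=1).to_numpy(),
        len(tumor),
        n_block.mean(axis=1).to_numpy(),
        n_block.var(axis=1, ddof=1).to_numpy(),
        len(normal),
        equal_var=equal_var,
    )
    adj = bh_adjust(p)
    cut = math.log2(fc_folds)
    call = np.where(
        (fc > cut) & (adj < alpha), "up",
        np.where((fc < -cut) & (adj < alpha), "down", "none"),
    )
    return pd.DataFrame(
        {"log2_fc": fc, "t_stat": t_stat, "p": p, "adj_p": adj, "call": call},
        index=log2.index,
    ).rename_axis("protein_id")


def differential_all_cancers(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    fc_folds: float = 2.0,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> dict[str, pd.DataFrame]:
    """Per-cancer differential tables; under-powered cancers skipped."""
    tables: dict[str, pd.DataFrame] = {}
    for cancer in metadata.tissues_present():
        try:
            tables[cancer] = tumor_vs_normal(
                matrix, metadata, cancer,
                fc_folds=fc_folds, alpha=alpha, equal_var=equal_var,
            )
        except ValueError as exc:
            logger.info("skipping %s: %s", cancer, exc)
    return tables


def call_matrix(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Proteins x cancers matrix of calls ('up' / 'down' / 'none')."""
    return pd.DataFrame({c: t["call"] for c, t in sorted(tables.items())})


def cancer_associated_proteins(tables: dict[str, pd.DataFrame]) -> pd.Index:
    """Proteins called up or down in at least one analysed cancer."""
    calls = call_matrix(tables)
    return calls.index[(calls != "none").any(axis=1)]


def aggregate_cross_cancer(
    tables: dict[str, pd.DataFrame], min_frac: float = 0.4,
    strict: bool = True,
) -> pd.DataFrame:
    """Proteins up in more than ``min_frac`` of the analysed cancers.

    Strict inequality by default: with 16 analysed cancers a protein needs
    at least 7 up calls (7 > 6.4). Returns the common-up table with the up
    count and the cancer list, sorted by count descending then id.
    """
    if len(tables) < 2:
        raise ValueError("aggregation needs tables for >=2 cancers")
    calls = call_matrix(tables)
    n_cancers = calls.shape[1]
    ups = (calls == "up").sum(axis=1)
    threshold = min_frac * n_cancers
    keep = ups > threshold if strict else ups >= threshold
    out = pd.DataFrame(
        {
            "n_up": ups[keep],
            "frac_up": ups[keep] / n_cancers,
            "cancers_up": calls[keep].apply(
                lambda row: ",".join(c for c in calls.columns if row[c] == "up"),
                axis=1,
            ),
        }
    )
    out = out.sort_index(kind="stable")
    out = out.sort_values("n_up", ascending=False, kind="stable")
    return out.rename_axis("protein_id")


def unique_cancer_proteins(tables: dict[str, pd.DataFrame]) -> pd.Series:
    """Proteins up in exactly one cancer, mapped to that cancer."""
    calls = call_matrix(tables)
    up = calls == "up"
    exactly_one = up.sum(axis=1) == 1
    return up[exactly_one].idxmax(axis=1).rename("cancer").rename_axis("protein_id")


# ---------------------------------------------------------------------------
# protein-group clustering
# ---------------------------------------------------------------------------

def zscore_rows(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-protein Z score across samples (population SD)."""
    values = frame.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # constant rows stay at zero
    return pd.DataFrame((values - mean) / sd, index=frame.index,
                        columns=frame.columns)


@dataclass
class ProteinGroupAssignment:
    labels: pd.Series          # protein -> "PG-1".."PG-k"
    linkage_method: str
    k: int

    def to_frame(self) -> pd.DataFrame:
        return self.labels.rename("protein_group").rename_axis(
            "protein_id").to_frame()


def cluster_protein_groups(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    protein_ids,
    k: int = 4,
    method: str = "ward",
) -> ProteinGroupAssignment:
    """Partition cancer-associated proteins into k groups.

    Per-protein Z-scored log2 profiles are clustered agglomeratively
    (Euclidean distance, Ward linkage by default) and the tree is cut at k.
    Deterministic given the inputs: proteins enter in id order and the group
    labels PG-1..PG-k are assigned by decreasing mean tumor-minus-normal
    Z difference (most tumor-elevated group first).
    """
    ids = sorted(protein_ids)
    if len(ids) < k:
        raise ValueError(f"cannot form {k} groups from {len(ids)} proteins")
    log2 = matrix.log2().loc[ids]
    z = zscore_rows(log2)
    if k == 1:
        labels = pd.Series("PG-1", index=z.index)
        return ProteinGroupAssignment(labels=labels, linkage_method=method, k=1)
    link = linkage(z.to_numpy(), method=method, metric="euclidean")
    raw = fcluster(link, t=k, criterion="maxclust")

    # order clusters by how tumor-elevated their mean profile is
    group = metadata.group_of().reindex(z.columns)
    tumor_cols = group == "tumor"
    direction = {}
    for c in np.unique(raw):
        block = z.to_numpy()[raw == c]
        direction[c] = float(
            block[:, tumor_cols.to_numpy()].mean()
            - block[:, ~tumor_cols.to_numpy()].mean()
        )
    ordered = sorted(direction, key=lambda c: (-direction[c], c))
    rename = {c: f"PG-{i + 1}" for i, c in enumerate(ordered)}
    labels = pd.Series([rename[c] for c in raw], index=z.index)
    return ProteinGroupAssignment(labels=labels, linkage_method=method, k=k)
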