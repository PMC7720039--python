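"""Tissue-enriched and tissue-group-enriched protein classification.

Each tissue type (tumor and normal samples pooled as one entity) is compared
pairwise against every other tissue with a two-sample t test per protein on
log2 intensities; p-values are BH-adjusted within each tissue pair across
proteins. A protein is enriched in a tissue if it beats at least 70% of the
other tissues — log2 fold change above log2(4) with adjusted p < 0.05 —
which at 16 tissues means at least ceil(0.7 * 15) = 11 of the 15
comparisons. The multiplicity of a protein is the number of tissues it is
enriched in, binned as 1 / 2 / 3 / 4+.

Group enrichment pools an anatomic tissue group (digestive, urinary,
gynecologic) into one entity and applies the identical rule against each
non-member tissue.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import IntensityMatrix, SampleMetadata, TISSUE_GROUPS
from .stats import bh_adjust, welch_t_test_arrays

logger = logging.getLogger(__name__)

MULTIPLICITY_CATEGORIES = ("1", "2", "3", "4+")


def _tissue_summaries(log2: pd.DataFrame, metadata: SampleMetadata,
                      min_samples: int = 2):
    """Per-tissue per-protein mean, sample variance and n (pooled arms)."""
    means, variances, counts = {}, {}, {}
    for tissue in metadata.tissues_present():
        members = metadata.samples(tissue=tissue)
        if len(members) < min_samples:
            logger.warning(
                "tissue %s has %d sample(s); excluded from pairwise stats",
                tissue, len(members),
            )
            continue
        block = log2[members]
        means[tissue] = block.mean(axis=1).to_numpy()
        variances[tissue] = block.var(axis=1, ddof=1).to_numpy()
        counts[tissue] = len(members)
    return means, variances, counts


@dataclass
class PairwiseStats:
    """All pairwise tissue comparisons for every protein."""

    proteins: pd.Index
    tissues: list[str]
    log2_fc: dict[str, pd.DataFrame]  # tissue -> (proteins x other tissues)
    adj_p: dict[str, pd.DataFrame]


def pairwise_tissue_stats(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    equal_var: bool = False,
) -> PairwiseStats:
    """t statistics for every ordered tissue pair on the imputed log2 matrix.

    BH adjustment is applied across proteins within each unordered pair (the
    two-sided p-value is shared by both orders); fold changes are
    antisymmetric between the two orders.
    """
    metadata.check_against(matrix)
    log2 = matrix.log2()
    means, variances, counts = _tissue_summaries(log2, metadata)
    tissues = list(means)
    if len(tissues) < 2:
        raise ValueError("need at least two tissues with >=2 samples")

    fc = {t: {} for t in tissues}
    padj = {t: {} for t in tissues}
    for i, t in enumerate(tissues):
        for u in tissues[i + 1:]:
            d, _, p = welch_t_test_arrays(
                means[t], variances[t], counts[t],
                means[u], variances[u], counts[u],
                equal_var=equal_var,
            )
            adj = bh_adjust(p)
            fc[t][u] = d
            fc[u][t] = -d
            padj[t][u] = adj
            padj[u][t] = adj

    proteins = log2.index
    log2_fc = {
        t: pd.DataFrame(fc[t], index=proteins).reindex(
            columns=[u for u in tissues if u != t])
        for t in tissues
    }
    adj_p = {
        t: pd.DataFrame(padj[t], index=proteins).reindex(
            columns=[u for u in tissues if u != t])
        for t in tissues
    }
    return PairwiseStats(proteins=proteins, tissues=tissues,
                         log2_fc=log2_fc, adj_p=adj_p)


def required_wins(n_comparators: int, coverage: float) -> int:
    """Number of beaten comparators needed: ceil(coverage * n_comparators)."""
    return math.ceil(coverage * n_comparators)


@dataclass
class EnrichmentResult:
    """Per-protein x tissue enrichment calls and per-protein multiplicity."""

    n_pass: pd.DataFrame        # proteins x tissues, comparators beaten
    enriched: pd.DataFrame      # proteins x tissues, boolean
    multiplicity: pd.Series     # per protein, #tissues enriched in
    category: pd.Series         # "1" / "2" / "3" / "4+" or "" if none

    def enriched_proteins(self) -> pd.Index:
        return self.multiplicity.index[self.multiplicity > 0]

    def to_frame(self) -> pd.DataFrame:
        out = self.enriched.add_prefix("enriched_").copy()
        out["multiplicity"] = self.multiplicity
        out["category"] = self.category
        return out.rename_axis("protein_id")


def classify_enriched(
    stats: PairwiseStats,
    fc_folds: float = 4.0,
    alpha: float = 0.05,
    coverage: float = 0.7,
) -> EnrichmentResult:
    """Apply the fold-change / adjusted-p / coverage rule to pairwise stats."""
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    log2_cut = math.log2(fc_folds)
    n_pass = {}
    enriched = {}
    for t in stats.tissues:
        wins = (stats.log2_fc[t] > log2_cut) & (stats.adj_p[t] < alpha)
        k = wins.sum(axis=1)
        need = required_wins(stats.log2_fc[t].shape[1], coverage)
        n_pass[t] = k
        enriched[t] = k >= need
    n_pass = pd.DataFrame(n_pass)
    enriched = pd.DataFrame(enriched)
    multiplicity = enriched.sum(axis=1)
    category = multiplicity.map(
        lambda m: "" if m == 0 else ("4+" if m >= 4 else str(int(m)))
    )
    return EnrichmentResult(
        n_pass=n_pass, enriched=enriched,
        multiplicity=multiplicity, category=category,
    )


def multiplicity_breakdown(result: EnrichmentResult) -> pd.DataFrame:
    """Counts and percentages of enriched proteins per multiplicity bin."""
    total = int((result.multiplicity > 0).sum())
    counts = {
        cat: int((result.category == cat).sum()) for cat in MULTIPLICITY_CATEGORIES
    }
    pct = {
        cat: (100.0 * n / total if total else 0.0) for cat, n in counts.items()
    }
    return pd.DataFrame(
        {"count": pd.Series(counts), "percent": pd.Series(pct)}
    ).rename_axis("multiplicity")


def group_enrichment(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    groups: dict[str, tuple[str, ...]] | None = None,
    fc_folds: float = 4.0,
    alpha: float = 0.05,
    coverage: float = 0.7,
    equal_var: bool = False,
) -> dict[str, list[str]]:
    """Group-enriched proteins: pooled group entity vs each outside tissue."""
    groups = groups or TISSUE_GROUPS
    metadata.check_against(matrix)
    log2 = matrix.log2()
    means, variances, counts = _tissue_summaries(log2, metadata)
    log2_cut = math.log2(fc_folds)

    out: dict[str, list[str]] = {}
    for name, members in groups.items():
        member_samples = [
            s for t in members for s in metadata.samples(tissue=t)
        ]
        if not member_samples:
            raise ValueError(f"tissue group {name!r} has no samples")
        block = log2[member_samples]
        g_mean = block.mean(axis=1).to_numpy()
        g_var = block.var(axis=1, ddof=1).to_numpy()
        g_n = len(member_samples)
        comparators = [t for t in means if t not in members]
        wins = np.zeros(len(log2.index), dtype=int)
        for u in comparators:
            d, _, p = welch_t_test_arrays(
                g_mean, g_var, g_n, means[u], variances[u], counts[u],
                equal_var=equal_var,
            )
            adj = bh_adjust(p)
            wins += ((d > log2_cut) & (adj < alpha)).astype(int)
        need = required_wins(len(comparators), coverage)
        out[name] = log2.index[wins >= need].tolist()
    return out
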