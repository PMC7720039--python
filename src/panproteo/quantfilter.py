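"""Quantifiability filtering and two-branch missing-value imputation.

A protein enters the downstream analysis if it was quantified in at least
40% of the qualified samples of at least one cancer type (tumor and normal
pooled). Remaining missing cells are then filled with a left-censoring rule:

* branch A — the protein is observed in fewer than half of the same-tissue
  samples: the cell gets 5% of the smallest observed intensity above 100 in
  its own sample (a per-sample noise-floor fill);
* branch B — the protein is observed in at least half of the same-tissue
  samples: the cell gets that tissue's observed mean minus two sample
  standard deviations, floored at a small positive constant so the log2
  transform stays defined.

Observed cells are never altered and imputation is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import IntensityMatrix, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class ImputeConfig:
    min_frac_quant: float = 0.4      # per-cancer quantifiability threshold
    branch_threshold: float = 0.5    # observed fraction splitting branch A/B
    low_intensity_cutoff: float = 100.0
    low_fill_fraction: float = 0.05
    fill_floor: float = 1.0          # intensity units; keeps log2 finite


def quantifiability_filter(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    min_frac: float = 0.4,
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Keep proteins quantified in >= ``min_frac`` of some cancer cohort.

    Fractions are computed per cancer type over that cancer's (already
    qualified) tumor + normal samples. Returns the filtered matrix and a
    per-protein decision table with per-cancer observed fractions, the
    retained flag, and the list of cancers that retain the protein.
    """
    metadata.check_against(matrix)
    observed = matrix.observed()
    fractions = {}
    for tissue in metadata.tissues_present():
        members = metadata.samples(tissue=tissue)
        if not members:
            raise ValueError(f"empty cohort for cancer type {tissue}")
        fractions[tissue] = observed[members].mean(axis=1)
    frac_table = pd.DataFrame(fractions)
    retain_by = frac_table >= min_frac
    retained = retain_by.any(axis=1)

    decisions = frac_table.add_prefix("frac_").copy()
    decisions["retained"] = retained
    decisions["retaining_cancers"] = retain_by.apply(
        lambda row: ",".join(c for c in frac_table.columns if row[c]), axis=1
    )
    decisions = decisions.rename_axis("protein_id")

    kept = matrix.data.loc[retained]
    logger.info(
        "quantifiability filter: kept %d of %d proteins (min_frac=%.2f)",
        int(retained.sum()), len(retained), min_frac,
    )
    return IntensityMatrix(kept.copy()), decisions


def impute_missing(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    config: ImputeConfig | None = None,
) -> IntensityMatrix:
    """Fill every missing cell by the two-branch left-censoring rule."""
    config = config or ImputeConfig()
    metadata.check_against(matrix)
    data = matrix.data.copy()
    values = data.to_numpy()
    col_index = {s: j for j, s in enumerate(data.columns)}

    # per-sample branch-A fill: 5% of the smallest observed intensity > 100
    low_fill = np.full(values.shape[1], np.nan)
    for s, j in col_index.items():
        col = values[:, j]
        supra = col[np.isfinite(col) & (col > config.low_intensity_cutoff)]
        if supra.size:
            low_fill[j] = config.low_fill_fraction * supra.min()
        else:
            low_fill[j] = config.fill_floor
            logger.warning(
                "sample %s has no observed intensity above %.0f; "
                "branch-A fills use the floor %.2f",
                s, config.low_intensity_cutoff, config.fill_floor,
            )

    for tissue in metadata.tissues_present():
        members = metadata.samples(tissue=tissue)
        cols = np.array([col_index[s] for s in members])
        block = values[:, cols]
        obs = np.isfinite(block)
        n_obs = obs.sum(axis=1)
        frac_obs = n_obs / len(cols)

        filled0 = np.where(obs, block, 0.0)
        denom = np.maximum(n_obs, 1)
        means = filled0.sum(axis=1) / denom
        sq_dev = np.where(obs, (block - means[:, None]) ** 2, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sds = np.sqrt(sq_dev / np.maximum(n_obs - 1, 1))
        branch_b = (frac_obs >= config.branch_threshold) & (n_obs >= 2)
        degenerate = (frac_obs >= config.branch_threshold) & (n_obs < 2)
        if degenerate.any():
            logger.warning(
                "tissue %s: %d proteins at branch B with <2 observed values; "
                "falling back to the per-sample branch-A fill",
                tissue, int(degenerate.sum()),
            )
        b_fill = np.maximum(means - 2.0 * sds, config.fill_floor)

        for k, j in enumerate(cols):
            miss = ~obs[:, k]
            if not miss.any():
                continue
            fill = np.where(branch_b, b_fill, low_fill[j])
            values[miss, j] = fill[miss]

    out = pd.DataFrame(values, index=data.index, columns=data.columns)
    return IntensityMatrix(out)
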