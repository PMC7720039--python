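"""Universally expressed ("housekeeping") protein detection.

A protein is universal in the tumor arm if it is observed (pre-imputation)
in strictly more than 90% of all tumor samples pooled across cancers, and
likewise for the normal arm; housekeeping proteins are the conjunction of
the two. A per-tissue-type reading of the rule is selectable. A reference
housekeeping gene list (e.g. from a protein atlas) can be compared against
the detected set, and an across-tissue dispersion score separates stably
expressed from fluctuating housekeeping proteins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_tables import IntensityMatrix, SampleMetadata
from .stats import InsufficientData


def identify_housekeeping(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    min_frac: float = 0.9,
    per_tissue: bool = False,
) -> pd.DataFrame:
    """Presence summary per protein; strict > ``min_frac`` in both arms.

    ``per_tissue=True`` replaces the pooled-sample fractions with the
    fraction of tissue types in which the protein is observed in any tumor
    (resp. normal) sample.
    """
    metadata.check_against(matrix)
    observed = matrix.observed()
    group = metadata.group_of()
    tumor = group.index[group == "tumor"].tolist()
    normal = group.index[group == "normal"].tolist()
    if not tumor or not normal:
        raise ValueError("need both tumor and normal samples")

    if per_tissue:
        tissue_of = metadata.tissue_of()
        tumor_tissues = sorted(set(tissue_of[tumor]))
        normal_tissues = sorted(set(tissue_of[normal]))
        ft = pd.DataFrame(
            {t: observed[[s for s in tumor if tissue_of[s] == t]].any(axis=1)
             for t in tumor_tissues}
        ).mean(axis=1)
        fn = pd.DataFrame(
            {t: observed[[s for s in normal if tissue_of[s] == t]].any(axis=1)
             for t in normal_tissues}
        ).mean(axis=1)
    else:
        ft = observed[tumor].mean(axis=1)
        fn = observed[normal].mean(axis=1)

    summary = pd.DataFrame(
        {
            "frac_tumor": ft,
            "frac_normal": fn,
            "universal_tumor": ft > min_frac,
            "universal_normal": fn > min_frac,
        }
    )
    summary["housekeeping"] = summary["universal_tumor"] & summary["universal_normal"]
    return summary.rename_axis("protein_id")


def compare_reference(summary: pd.DataFrame, reference_ids) -> dict:
    """Overlap of the detected housekeeping set with a reference list."""
    reference = set(reference_ids)
    if not reference:
        raise ValueError("reference housekeeping list is empty")
    detected = set(summary.index[summary["housekeeping"]])
    overlap = detected & reference
    return {
        "n_detected": len(detected),
        "n_reference": len(reference),
        "n_overlap": len(overlap),
        "frac_of_detected": len(overlap) / len(detected) if detected else 0.0,
        "frac_of_reference": len(overlap) / len(reference),
        "overlap_ids": sorted(overlap),
    }


def expression_stability(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    protein_ids=None,
) -> pd.Series:
    """Across-tissue dispersion of tissue-mean log2 intensity per protein.

    Computed on the (post-imputation) matrix as the CV (in percent) of the
    16 tissue means on the log2 scale; low scores mean stable expression
    across tissues, high scores mean fluctuation. Requires >= 2 tissues.
    """
    metadata.check_against(matrix)
    tissues = metadata.tissues_present()
    if len(tissues) < 2:
        raise InsufficientData("dispersion needs >=2 tissues")
    log2 = matrix.log2()
    if protein_ids is not None:
        log2 = log2.loc[list(protein_ids)]
    tissue_means = pd.DataFrame(
        {t: log2[metadata.samples(tissue=t)].mean(axis=1) for t in tissues}
    )
    mean = tissue_means.mean(axis=1)
    sd = tissue_means.std(axis=1, ddof=1)
    score = 100.0 * sd / mean.abs()
    score.name = "tissue_cv_percent"
    return score
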