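"""Sample quality control.

Two layers: replicate-injection QC (per-protein CV and pairwise Pearson
across repeated injections of the same sample set) and the per-sample
qualification decision. A sample is qualified for downstream analysis if it
meets at least three of five criteria, each evaluated within its own cancer
type, independently of the other cancer types:

1. at least 50% of the proteins detected anywhere in that cancer cohort are
   quantified in the sample;
2. its median log2 intensity is similar to the other same-tissue samples
   (within k * MAD of the cohort median-of-medians, k = 3 by default);
3. its mean pairwise Pearson correlation (log2, pairwise-complete) with the
   other same-tissue samples exceeds 0.6;
4. its log2 intensity distribution is similar to the pooled same-tissue
   distribution (two-sample Kolmogorov-Smirnov statistic <= 0.3);
5. it groups with its own tissue in a principal component analysis (its
   nearest tissue centroid on the first two PCs is its own tissue).

The named criteria come without formulas; the operationalizations above are
this package's reading, every threshold is configurable, and the values
actually used are logged into the run summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp
from sklearn.decomposition import PCA

from .io_tables import IntensityMatrix, SampleMetadata, median_normalize
from .stats import InsufficientData, cv_percent

logger = logging.getLogger(__name__)


@dataclass
class QCConfig:
    min_frac_quantified: float = 0.5
    median_mad_k: float = 3.0
    median_mad_floor: float = 0.2  # log2 units; guards a degenerate zero MAD
    min_mean_correlation: float = 0.6
    max_ks_statistic: float = 0.3
    pca_min_presence: float = 0.8
    min_criteria: int = 3


# ---------------------------------------------------------------------------
# replicate QC
# ---------------------------------------------------------------------------

def replicate_qc(
    matrix: IntensityMatrix, replicate_groups: dict[str, list[str]]
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """QC of repeated injections.

    ``replicate_groups`` maps a group name (one injected sample set) to the
    sample ids of its injections. Returns (per-protein CV table in percent,
    median CV per group, pairwise Pearson matrix over all listed injections).
    Proteins observed in fewer than two injections of a group have no CV
    there (left missing, counted in the log).
    """
    for name, members in replicate_groups.items():
        if len(members) < 2:
            raise ValueError(f"replicate group {name!r} has fewer than 2 samples")

    cv_cols = {}
    for name, members in replicate_groups.items():
        sub = matrix.data[list(members)]
        n_obs = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        cv = 100.0 * sd / mean
        cv[n_obs < 2] = np.nan
        n_skipped = int((n_obs < 2).sum())
        if n_skipped:
            logger.info(
                "replicate group %s: %d proteins with <2 observations "
                "excluded from CV", name, n_skipped,
            )
        cv_cols[name] = cv
    cv_table = pd.DataFrame(cv_cols)
    median_cv = cv_table.median(axis=0, skipna=True)

    all_members = [s for members in replicate_groups.values() for s in members]
    log2 = np.log2(matrix.data[all_members])
    corr = log2.corr(method="pearson", min_periods=2)
    return cv_table, median_cv, corr


# ---------------------------------------------------------------------------
# per-sample qualification
# ---------------------------------------------------------------------------

def _pca_tissue_assignment(
    matrix: IntensityMatrix, metadata: SampleMetadata, min_presence: float
) -> pd.Series:
    """Nearest tissue centroid (leave-one-out) on the first two PCs.

    Runs on the median-normalized log2 matrix restricted to proteins observed
    in at least ``min_presence`` of all samples; remaining gaps are filled
    with the protein mean for the projection only.
    """
    norm = median_normalize(matrix)
    log2 = norm.log2()
    keep = log2.notna().mean(axis=1) >= min_presence
    sub = log2.loc[keep]
    if sub.shape[0] < 2:
        raise InsufficientData("too few well-observed proteins for PCA")
    filled = sub.apply(lambda row: row.fillna(row.mean()), axis=1)
    coords = PCA(n_components=2, random_state=0).fit_transform(filled.T.to_numpy())
    coords = pd.DataFrame(coords, index=sub.columns, columns=["pc1", "pc2"])

    tissue = metadata.tissue_of().loc[coords.index]
    xy = coords.to_numpy()
    sums = {t: xy[(tissue == t).to_numpy()].sum(axis=0)
            for t in metadata.tissues_present()}
    ns = {t: int((tissue == t).sum()) for t in metadata.tissues_present()}
    assigned = {}
    for i, s in enumerate(coords.index):
        own = tissue.iloc[i]
        best, best_d = None, np.inf
        for t, n in ns.items():
            if t == own:  # leave the sample itself out of its own centroid
                if n < 2:
                    continue
                centroid = (sums[t] - xy[i]) / (n - 1)
            else:
                centroid = sums[t] / n
            d = float(np.hypot(*(xy[i] - centroid)))
            if d < best_d:
                best, best_d = t, d
        assigned[s] = best
    return pd.Series(assigned)


def assess_samples(
    matrix: IntensityMatrix,
    metadata: SampleMetadata,
    config: QCConfig | None = None,
) -> pd.DataFrame:
    """Per-sample 5-criterion qualification report.

    Returns one row per sample: the five metric values, the five boolean
    flags, ``n_criteria_passed`` and ``qualified`` (>= 3 of 5). Tissues with
    a single sample cannot support criteria 2-5; such samples qualify on
    criterion 1 alone (logged).
    """
    config = config or QCConfig()
    metadata.check_against(matrix)
    log2 = matrix.log2()
    tissue_of = metadata.tissue_of()

    try:
        pca_assign = _pca_tissue_assignment(matrix, metadata, config.pca_min_presence)
    except InsufficientData:
        logger.warning("PCA criterion unavailable; treating as passed")
        pca_assign = None

    records = []
    for tissue in metadata.tissues_present():
        members = metadata.samples(tissue=tissue)
        cohort = log2[members]
        detected = cohort.notna().any(axis=1)
        n_detected = int(detected.sum())
        medians = cohort.median(axis=0, skipna=True)
        center = float(np.median(medians))
        mad = float(np.median(np.abs(medians - center)))
        mad_limit = max(config.median_mad_k * mad, config.median_mad_floor)
        pooled = {
            s: cohort.drop(columns=s).to_numpy().ravel() for s in members
        } if len(members) > 1 else {}
        corr_matrix = cohort.corr(method="pearson", min_periods=2) \
            if len(members) > 1 else None

        single = len(members) == 1
        if single:
            logger.warning(
                "tissue %s has a single sample; criteria 2-5 undefined", tissue
            )

        for s in members:
            vals = cohort[s]
            frac = float(vals.notna().sum() / n_detected) if n_detected else 0.0
            frac_ok = frac >= config.min_frac_quantified

            if single:
                median_ok = corr_ok = dist_ok = pca_ok = frac_ok
                med = float(medians[s])
                mean_corr = np.nan
                ks_stat = np.nan
            else:
                med = float(medians[s])
                median_ok = abs(med - center) <= mad_limit

                others = [m for m in members if m != s]
                mean_corr = float(corr_matrix.loc[others, s].mean(skipna=True))
                corr_ok = mean_corr > config.min_mean_correlation

                own = vals.dropna().to_numpy()
                pool = pooled[s]
                pool = pool[np.isfinite(pool)]
                if own.size and pool.size:
                    ks_stat = float(ks_2samp(own, pool).statistic)
                else:
                    ks_stat = 1.0
                dist_ok = ks_stat <= config.max_ks_statistic

                if pca_assign is None:
                    pca_ok = True
                else:
                    pca_ok = pca_assign.get(s) == tissue

            flags = [frac_ok, median_ok, corr_ok, dist_ok, pca_ok]
            n_passed = int(sum(flags))
            records.append(
                {
                    "sample_id": s,
                    "tissue": tissue,
                    "frac_quantified": frac,
                    "frac_ok": frac_ok,
                    "median_log2": med,
                    "median_ok": median_ok,
                    "mean_within_tissue_corr": mean_corr,
                    "corr_ok": corr_ok,
                    "ks_statistic": ks_stat,
                    "distribution_ok": dist_ok,
                    "pca_ok": pca_ok,
                    "n_criteria_passed": n_passed,
                    "qualified": n_passed >= config.min_criteria,
                }
            )
    report = pd.DataFrame(records).set_index("sample_id")
    n_fail = int((~report["qualified"]).sum())
    if n_fail:
        logger.info(
            "disqualified %d samples: %s", n_fail,
            report.index[~report["qualified"]].tolist(),
        )
    return report


def qualified_samples(report: pd.DataFrame) -> list[str]:
    return report.index[report["qualified"]].tolist()


def apply_qualification(
    matrix: IntensityMatrix, metadata: SampleMetadata, report: pd.DataFrame
) -> tuple[IntensityMatrix, SampleMetadata]:
    """Drop disqualified samples from the matrix and metadata."""
    keep = qualified_samples(report)
    return matrix.select_samples(keep), metadata.restrict(keep)
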