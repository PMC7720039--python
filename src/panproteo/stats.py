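"""Shared statistical primitives.

Every comparison in the pipeline runs on log2-transformed intensities, so a
fold change > 2 is |log2 fc| > 1 and "> 4 folds" is |log2 fc| > 2. The
default two-sample test is Welch's unequal-variance t test (two-sided);
Student's equal-variance variant is selectable. Multiple testing is
controlled with the Benjamini-Hochberg step-up adjustment, applied within
one comparison family at a time (one tissue pair, or one cancer type).

Replicate QC uses the coefficient of variation on the raw intensity scale
(100 * SD / mean, sample SD) and pairwise-complete Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class InsufficientData(ValueError):
    """A group had too few observed values for the requested statistic."""


@dataclass(frozen=True)
class TestResult:
    """Two-sample comparison on the log2 scale."""

    log2_fc: float  # mean(a) - mean(b)
    t_stat: float
    p_value: float
    df: float
    n_a: int
    n_b: int


def welch_t_test(group_a, group_b, equal_var: bool = False) -> TestResult:
    """Two-sided two-sample t test on log2 intensities.

    Welch-Satterthwaite degrees of freedom by default. Raises
    :class:`InsufficientData` if either group has fewer than two values;
    callers skip (and log) the protein rather than crash.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise InsufficientData(
            f"need >=2 observed values per group, got {a.size} and {b.size}"
        )
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    if not math.isfinite(t):  # zero variance in both groups
        t = 0.0
        p = 1.0
    return TestResult(
        log2_fc=float(a.mean() - b.mean()),
        t_stat=t,
        p_value=p,
        df=df,
        n_a=int(a.size),
        n_b=int(b.size),
    )


def welch_t_test_arrays(
    mean_a, var_a, n_a, mean_b, var_b, n_b, equal_var: bool = False
):
    """Vectorised two-sided t test from per-group summary statistics.

    Variances are sample variances (ddof=1). Returns (log2_fc, t, p) arrays;
    degenerate rows (zero variance in both groups and equal means) get
    t = 0, p = 1.
    """
    mean_a = np.asarray(mean_a, float)
    mean_b = np.asarray(mean_b, float)
    var_a = np.asarray(var_a, float)
    var_b = np.asarray(var_b, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind_from_stats(
            mean_a, np.sqrt(var_a), n_a, mean_b, np.sqrt(var_b), n_b,
            equal_var=equal_var,
        )
    t = np.asarray(t, float)
    p = np.asarray(p, float)
    bad = ~np.isfinite(t)
    t[bad] = 0.0
    p[bad] = 1.0
    return mean_a - mean_b, t, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cv_percent(values) -> float:
    """Coefficient of variation, 100 * sample SD / mean, raw intensity scale."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise InsufficientData("CV needs >=2 observed values")
    mean = v.mean()
    if mean == 0:
        raise InsufficientData("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def pearson(x, y) -> float:
    """Pearson correlation over pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        raise InsufficientData("correlation needs >=2 complete pairs")
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        raise InsufficientData("correlation undefined for constant input")
    return float(np.corrcoef(xs, ys)[0, 1])
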