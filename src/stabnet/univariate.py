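"""Univariate time-series statistics.

Per-feature one-way repeated-measures ANOVA across the storage time series
(replicate aliquot = subject), pairwise paired t-tests of every storage day
against day 0, and Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class AnovaResult:
    """Per-feature F, degrees of freedom, raw and BH-adjusted p."""

    table: pd.DataFrame  # index feature_id: F, df1, df2, p, p_adj

    def significant(self, alpha: float = 0.05) -> list[str]:
        return self.table.index[self.table["p_adj"] < alpha].tolist()


@dataclass
class PairwiseResult:
    """Paired-t results per (day, feature) plus per-day significant counts."""

    table: pd.DataFrame  # columns: day, feature_id, t, p, p_adj
    counts: pd.DataFrame  # columns: day, n_significant


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pivot(matrix: pd.DataFrame, design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Arrange values as (replicates, days, features); checks balance."""
    days = np.sort(design["storage_day"].unique())
    reps = np.sort(design["replicate"].unique())
    if len(days) < 2 or len(reps) < 2:
        raise ValueError("need >=2 days and >=2 replicates")
    counts = design.groupby(["storage_day", "replicate"]).size()
    if len(counts) != len(days) * len(reps) or (counts != 1).any():
        raise ValueError("unbalanced design: need exactly one sample per (day, replicate)")
    lookup = {
        (d, r): sid
        for sid, (d, r) in design[["storage_day", "replicate"]].iterrows()
    }
    cube = np.empty((len(reps), len(days), matrix.shape[1]))
    for i, r in enumerate(reps):
        for j, d in enumerate(days):
            cube[i, j] = matrix.loc[lookup[(d, r)]].to_numpy(dtype=float)
    return cube, days


def rm_anova(matrix: pd.DataFrame, design: pd.DataFrame) -> AnovaResult:
    """One-way within-subject ANOVA per feature, subject = replicate.

    F = MS_time / MS_error with SS_total = SS_subject + SS_time + SS_error
    and df (k-1, (k-1)(n-1)). Degenerate features with SS_time = SS_error
    = 0 are reported as F = 0, p = 1 so downstream ranking never sees NaN.
    BH adjustment is applied across features.
    """
    cube, _ = _pivot(matrix, design)
    n, k, p = cube.shape
    grand = cube.mean(axis=(0, 1))
    subj_mean = cube.mean(axis=1)  # (n, p)
    time_mean = cube.mean(axis=0)  # (k, p)
    ss_subj = k * ((subj_mean - grand) ** 2).sum(axis=0)
    ss_time = n * ((time_mean - grand) ** 2).sum(axis=0)
    ss_total = ((cube - grand) ** 2).sum(axis=(0, 1))
    ss_err = np.maximum(ss_total - ss_subj - ss_time, 0.0)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_time = ss_time / df1
    ms_err = ss_err / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ms_time / ms_err
    F = np.where(ms_time == 0, 0.0, F)  # degenerate: no time effect
    pvals = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isinf(F), 1.0, F), df1, df2))
    pvals = np.where(F == 0, 1.0, pvals)
    tab = pd.DataFrame(
        {"F": F, "df1": df1, "df2": df2, "p": pvals, "p_adj": bh_adjust(pvals)},
        index=matrix.columns,
    )
    return AnovaResult(tab)


def paired_t_vs_day0(matrix: pd.DataFrame, design: pd.DataFrame) -> PairwiseResult:
    """Paired t-test of each storage day against day 0, per feature.

    Differences are paired by replicate; two-sided p from t with n-1 df;
    BH adjustment per day across features; zero-variance differences map
    to t = +-inf (p = 0) for nonzero mean and t = 0 (p = 1) otherwise.
    The per-day count of features with adjusted p < 0.05 is also returned.
    """
    cube, days = _pivot(matrix, design)
    n = cube.shape[0]
    if days[0] != 0:
        raise ValueError("design has no day 0 baseline")
    rows, count_rows = [], []
    for j, day in enumerate(days[1:], start=1):
        diff = cube[:, j, :] - cube[:, 0, :]  # (n, p)
        mean = diff.mean(axis=0)
        sd = diff.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(n))
        zero_var = sd == 0
        t = np.where(zero_var & (mean == 0), 0.0, t)
        t = np.where(zero_var & (mean > 0), np.inf, t)
        t = np.where(zero_var & (mean < 0), -np.inf, t)
        p = np.where(np.isinf(t), 0.0,
                     2.0 * stats.t.sf(np.abs(np.where(np.isinf(t), 0.0, t)), n - 1))
        p_adj = bh_adjust(p)
        for fid, ti, pi, ai in zip(matrix.columns, t, p, p_adj):
            rows.append((int(day), fid, ti, pi, ai))
        count_rows.append((int(day), int((p_adj < 0.05).sum())))
    table = pd.DataFrame(rows, columns=["day", "feature_id", "t", "p", "p_adj"])
    counts = pd.DataFrame(count_rows, columns=["day", "n_significant"])
    return PairwiseResult(table, counts)
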