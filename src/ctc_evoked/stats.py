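"""Normality-gated statistical comparisons and trial-wise correlations.

Every two-group or repeated-measures comparison is gated on the
Shapiro-Wilk normality test (alpha 0.05 per sample; on the paired
differences for paired designs): the parametric test (t-test, repeated-
measures ANOVA) when all samples pass, otherwise its rank-based
counterpart (Mann-Whitney U, Wilcoxon signed-rank, Friedman). All tests
are two-sided. Families of post-hoc comparisons are Benjamini-Hochberg
corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p: float
    direction: str  # 'x>y', 'y>x' or 'none'
    n: tuple
    q: float | None = None
    posthoc: pd.DataFrame | None = field(repr=False, default=None)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, idempotent)."""
    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


def _normal(x: np.ndarray, alpha: float) -> bool:
    x = np.asarray(x, float)
    if np.ptp(x) == 0:
        return False  # constant sample: Shapiro undefined, use ranks
    return stats.shapiro(x)[1] > alpha


def compare_two_groups(
    x: np.ndarray,
    y: np.ndarray,
    paired: bool = False,
    alpha_normality: float = 0.05,
) -> ComparisonResult:
    """Two-group comparison with a Shapiro-Wilk gate.

    Unpaired: t-test when both samples pass normality, else
    Mann-Whitney U. Paired: paired t-test when the differences pass,
    else Wilcoxon signed-rank. Two-sided throughout. Zero variance in
    both groups yields p = 1 with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if min(x.size, y.size) < 3:
        raise ValueError("need n >= 3 per group")
    direction = "none"
    if np.ptp(x) == 0 and np.ptp(y) == 0 and (not paired or np.ptp(x - y) == 0):
        if x[0] == y[0] or (paired and np.all(x == y)):
            warnings.warn("zero variance in both groups")
            return ComparisonResult("degenerate", 0.0, 1.0, direction, (x.size, y.size))
    if paired:
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        diff = x - y
        if np.all(diff == 0):
            return ComparisonResult("wilcoxon", 0.0, 1.0, "none", (x.size, y.size))
        if _normal(diff, alpha_normality):
            stat, p = stats.ttest_rel(x, y)
            test = "paired_t"
        else:
            stat, p = stats.wilcoxon(x, y, alternative="two-sided")
            test = "wilcoxon"
    else:
        if _normal(x, alpha_normality) and _normal(y, alpha_normality):
            stat, p = stats.ttest_ind(x, y)
            test = "t"
        else:
            stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
            test = "mannwhitneyu"
    if p < 0.05:
        direction = "x>y" if x.mean() > y.mean() else "y>x"
    return ComparisonResult(test, float(stat), float(p), direction, (x.size, y.size))


def repeated_measures_compare(
    table: pd.DataFrame, alpha_normality: float = 0.05, fdr: float = 0.05
) -> ComparisonResult:
    """One-way repeated-measures comparison of a complete subject x
    condition table (subjects as rows).

    Repeated-measures ANOVA when every condition passes the normality
    gate, else the Friedman test. Post-hoc: all pairwise paired
    comparisons (gated the same way), BH-corrected. With exactly two
    conditions the result reduces to the paired two-group test.
    """
    if table.isna().any().any():
        raise ValueError("repeated-measures table has missing cells")
    conds = list(table.columns)
    if len(conds) < 2:
        raise ValueError("need at least two conditions")
    if len(conds) == 2:
        res = compare_two_groups(table[conds[0]], table[conds[1]], paired=True)
        return ComparisonResult(res.test, res.statistic, res.p, res.direction,
                                (len(table), len(conds)))
    cols = [table[c].to_numpy(float) for c in conds]
    if all(np.ptp(c - cols[0]) == 0 for c in cols):
        return ComparisonResult("degenerate", 0.0, 1.0, "none", (len(table), len(conds)))
    normal = all(_normal(c, alpha_normality) for c in cols)
    if normal:
        stat, p = _rm_anova(np.column_stack(cols))
        test = "rm_anova"
    else:
        stat, p = stats.friedmanchisquare(*cols)
        test = "friedman"
    rows = []
    for a, b in combinations(conds, 2):
        r = compare_two_groups(table[a], table[b], paired=True)
        rows.append({"pair": f"{a} vs {b}", "test": r.test, "statistic": r.statistic,
                     "p": r.p})
    posthoc = pd.DataFrame(rows)
    posthoc["q"] = bh_adjust(posthoc["p"])
    return ComparisonResult(test, float(stat), float(p), "none",
                            (len(table), len(conds)), posthoc=posthoc)


def _rm_anova(data: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA F and p for an (n_subjects x
    n_conditions) array."""
    n, k = data.shape
    grand = data.mean()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    f = (ss_cond / df_cond) / (ss_err / df_err)
    p = stats.f.sf(f, df_cond, df_err)
    return float(f), float(p)


def trialwise_correlation(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between two per-trial metrics (e.g. fraction
    of bursting thalamic units vs late-ERP peak amplitude). Returns
    (r, p); r is NaN with p = 1 when either input has zero variance."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size or a.size < 10:
        raise ValueError("need >= 10 paired trials")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("inputs must be finite")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("zero variance: correlation undefined")
        return float("nan"), 1.0
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
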