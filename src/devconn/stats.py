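"""Group statistics with the study's reporting conventions, and behavior scores.

The comparison tests mirror common electrophysiology reporting: Wilcoxon
rank-sum (reported as the rank sum of the first sample, a tie- and
continuity-corrected z value, and p), one-way ANOVA, paired t, and the
chi-square test for two proportions with Yates continuity correction (the
convention that reproduces the published chi values from the published
counts).  Behavioral scoring covers the discrimination index
DI = (novel - familiar) / (novel + familiar) and the low-exploration
exclusion rule (< 20 cm/min).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sst

from .data_model import ValidationError

__all__ = [
    "wilcoxon_ranksum", "oneway_anova", "paired_t", "chisq_2x2",
    "chisq_proportions", "discrimination_index", "exclusion_filter",
    "compare_groups",
]


def wilcoxon_ranksum(x, y) -> tuple[float, float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(ranksum, zval, p)`` where ``ranksum`` is the sum of the ranks
    of ``x`` in the pooled sample.  z uses the normal approximation with tie
    correction and a 0.5 continuity correction; for small samples
    (min(n) <= 10) without ties the p-value comes from the exact null
    distribution instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sst.rankdata(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2

    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / ((n) * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 0.0, 1.0
    diff = w - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if diff != 0 else 0.0
    p = 2.0 * sst.norm.sf(abs(z))

    no_ties = len(counts) == n
    if min(n1, n2) <= 10 and no_ties:
        p = float(sst.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact").pvalue)
    return w, float(z), float(min(p, 1.0))


def oneway_anova(*groups) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA; returns ``(F, (df_between, df_within), p)``."""
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    res = sst.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return float(res.statistic), (df1, df2), float(res.pvalue)


def paired_t(x_pre, x_post) -> tuple[float, int, float]:
    """Paired-sample t test; returns ``(t, df, p)`` with df = n - 1."""
    x_pre = np.asarray(x_pre, dtype=float)
    x_post = np.asarray(x_post, dtype=float)
    if x_pre.shape != x_post.shape:
        raise ValidationError("paired samples must have equal length")
    res = sst.ttest_rel(x_pre, x_post)
    return float(res.statistic), len(x_pre) - 1, float(res.pvalue)


def chisq_2x2(table, yates: bool = True) -> tuple[float, int, float]:
    """Chi-square test on a 2x2 contingency table.

    With ``yates=True`` (default) the Yates continuity correction
    ``chi = sum (|O - E| - 0.5)^2 / E`` (clamped at zero) is applied.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if (table < 0).any():
        raise ValidationError("counts must be non-negative")
    chi, p, df, _ = sst.chi2_contingency(table, correction=yates)
    return float(chi), int(df), float(p)


def chisq_proportions(k1: int, n1: int, k2: int, n2: int,
                      yates: bool = True) -> tuple[float, int, float]:
    """Chi-square comparison of two proportions k1/n1 vs k2/n2."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValidationError("need 0 <= k <= n for both proportions")
    return chisq_2x2([[k1, n1 - k1], [k2, n2 - k2]], yates=yates)


def discrimination_index(t_novel: float, t_familiar: float) -> float:
    """DI = (novel - familiar) / (novel + familiar); chance level 0."""
    total = t_novel + t_familiar
    if total <= 0:
        raise ValidationError("total interaction time must be positive")
    return float((t_novel - t_familiar) / total)


def exclusion_filter(trials: pd.DataFrame,
                     min_velocity: float = 20.0) -> tuple[pd.DataFrame, dict]:
    """Drop animals with low exploration (velocity strictly below threshold).

    Returns the filtered table and a report with the excluded animal ids.
    """
    trials = pd.DataFrame(trials)
    if len(trials) == 0:
        return trials, {"n_excluded": 0, "excluded_ids": []}
    keep = trials.velocity_cm_min >= min_velocity
    report = {
        "n_excluded": int((~keep).sum()),
        "excluded_ids": list(trials.loc[~keep, "animal_id"])
        if "animal_id" in trials else [],
        "threshold_cm_min": min_velocity,
    }
    return trials[keep].reset_index(drop=True), report


def compare_groups(x, y, alpha: float = 0.05) -> dict:
    """Two-group comparison with a variance-homogeneity gate.

    Mirrors the study's convention: samples are screened with Levene's test
    and compared with one-way ANOVA when the variances are homogeneous, with
    the Wilcoxon rank-sum test otherwise.  (Using a variance test as the
    normality gate is unconventional; it is kept for fidelity.)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lev_p = float(sst.levene(x, y).pvalue)
    if lev_p >= alpha:
        f, df, p = oneway_anova(x, y)
        return {"test": "oneway_anova", "statistic": f, "df": df, "p": p,
                "levene_p": lev_p, "n": (len(x), len(y))}
    w, z, p = wilcoxon_ranksum(x, y)
    return {"test": "wilcoxon_ranksum", "statistic": w, "zval": z, "p": p,
            "levene_p": lev_p, "n": (len(x), len(y))}
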