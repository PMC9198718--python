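"""Group statistics with the normality/equal-variance gate.

Groups are compared the way the electrophysiology panels are: per-group
Shapiro-Wilk normality and Levene equal-variance checks at alpha = 0.05; if
both pass, one-way ANOVA with Tukey HSD post-hoc comparisons against the
designated reference group (WT), otherwise pairwise Mann-Whitney rank-sum
tests against the reference. Significance stars: * p < 0.05, ** p < 0.01,
*** p < 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["star_label", "PairwiseResult", "GroupComparison", "compare_groups"]

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_label(p: float) -> str:
    """Significance stars for a p-value (ns above 0.05)."""
    if not np.isfinite(p):
        return "na"
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


@dataclass(frozen=True)
class PairwiseResult:
    group: str
    statistic: float
    p_value: float
    stars: str


@dataclass
class GroupComparison:
    """Outcome of the gated group comparison for one metric."""

    metric: str
    reference: str
    method: str                      # "anova_tukey" or "mannwhitney"
    shapiro_p: dict
    levene_p: float
    anova_f: Optional[float]
    anova_p: Optional[float]
    comparisons: list
    excluded: list = field(default_factory=list)
    n_per_group: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"metric": self.metric, "reference": self.reference,
             "group": c.group, "method": self.method,
             "statistic": c.statistic, "p_value": c.p_value, "stars": c.stars}
            for c in self.comparisons
        ])


def _clean_groups(groups: Mapping[str, Sequence[float]]):
    cleaned, excluded = {}, []
    for name, vals in groups.items():
        arr = np.asarray(vals, float)
        arr = arr[np.isfinite(arr)]
        if len(arr) < 3:
            excluded.append(name)
        else:
            cleaned[name] = arr
    return cleaned, excluded


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    reference: str = "WT",
    alpha: float = 0.05,
    metric: str = "",
) -> GroupComparison:
    """Compare each group against the reference with the assumption gate.

    ``groups`` maps group label to per-cell values; undefined entries (NaN)
    are dropped before testing and groups with fewer than 3 defined values are
    excluded with a warning. The gate is applied per metric: Shapiro-Wilk in
    every group and Levene across groups, both at ``alpha``.
    """
    cleaned, excluded = _clean_groups(groups)
    if excluded:
        warnings.warn(
            f"groups excluded (n < 3 defined values): {excluded}", UserWarning)
    if reference not in cleaned:
        raise ValueError(f"reference group {reference!r} missing or too small")
    if len(cleaned) < 2:
        raise ValueError("need at least 2 usable groups")

    shapiro_p = {}
    for name, arr in cleaned.items():
        if np.ptp(arr) == 0:
            shapiro_p[name] = 0.0  # degenerate: certainly non-normal
        else:
            shapiro_p[name] = float(sps.shapiro(arr).pvalue)
    levene_p = float(sps.levene(*cleaned.values()).pvalue)
    normal = all(p >= alpha for p in shapiro_p.values())
    homoscedastic = levene_p >= alpha

    others = [g for g in cleaned if g != reference]
    comparisons = []
    if normal and homoscedastic:
        method = "anova_tukey"
        f_stat, anova_p = sps.f_oneway(*cleaned.values())
        if len(cleaned) == 2:
            # Tukey's HSD with two groups reduces to the pooled t-test.
            other = others[0]
            res = sps.ttest_ind(cleaned[other], cleaned[reference],
                                equal_var=True)
            diff = float(np.mean(cleaned[other]) - np.mean(cleaned[reference]))
            p = float(res.pvalue)
            comparisons.append(PairwiseResult(
                group=other, statistic=diff, p_value=p, stars=star_label(p)))
            anova_f, anova_pv = float(f_stat), float(anova_p)
            comparisons.sort(key=lambda c: c.group)
            return GroupComparison(
                metric=metric, reference=reference, method=method,
                shapiro_p=shapiro_p, levene_p=levene_p,
                anova_f=anova_f, anova_p=anova_pv,
                comparisons=comparisons, excluded=excluded,
                n_per_group={g: len(v) for g, v in cleaned.items()},
            )

        from itertools import combinations

        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        values = np.concatenate(list(cleaned.values()))
        labels = np.concatenate([[g] * len(v) for g, v in cleaned.items()])
        tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
        names = [str(g) for g in tukey.groupsunique]
        for (i1, i2), diff, p in zip(combinations(range(len(names)), 2),
                                     tukey.meandiffs, tukey.pvalues):
            g1, g2 = names[i1], names[i2]
            if reference not in (g1, g2):
                continue
            other = g2 if g1 == reference else g1
            p = float(p)
            comparisons.append(PairwiseResult(
                group=other, statistic=float(diff), p_value=p,
                stars=star_label(p)))
        anova_f, anova_pv = float(f_stat), float(anova_p)
    else:
        method = "mannwhitney"
        anova_f = anova_pv = None
        for g in others:
            res = sps.mannwhitneyu(cleaned[g], cleaned[reference],
                                   alternative="two-sided")
            comparisons.append(PairwiseResult(
                group=g, statistic=float(res.statistic),
                p_value=float(res.pvalue), stars=star_label(res.pvalue)))

    comparisons.sort(key=lambda c: c.group)
    return GroupComparison(
        metric=metric, reference=reference, method=method,
        shapiro_p=shapiro_p, levene_p=levene_p,
        anova_f=anova_f, anova_p=anova_pv,
        comparisons=comparisons, excluded=excluded,
        n_per_group={g: len(v) for g, v in cleaned.items()},
    )
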