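"""Group-level descriptive and inferential statistics.

Descriptives are mean ± SEM (sample standard deviation over sqrt(n)).  Three
or more groups are compared with a one-way ANOVA followed by Tukey's multiple
comparisons (Tukey–Kramer for unequal n); two groups with a two-sample t-test
(pooled-variance Student by default, Welch optional).  All tests two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GroupDescriptives:
    label: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class GroupComparison:
    """A fitted group comparison: descriptives plus the omnibus test and,
    for ANOVA, Tukey-adjusted pairwise p-values keyed by label pair."""

    groups: tuple[GroupDescriptives, ...]
    test: str  # "anova_tukey" | "t_test"
    statistic: float
    df: tuple[float, ...]  # (between, within) for F; (df,) for t
    p_value: float
    pairwise: Optional[tuple[tuple[str, str, float], ...]] = None


def mean_sem(values: Sequence[float]) -> tuple[float, float, int]:
    """Arithmetic mean, standard error of the mean (n−1 denominator sd), n."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("mean_sem requires at least 2 values")
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size)), int(x.size)


def _descriptives(groups: Sequence[Sequence[float]], labels: Sequence[str]):
    out = []
    for lab, g in zip(labels, groups):
        m, s, n = mean_sem(g)
        out.append(GroupDescriptives(label=lab, n=n, mean=m, sem=s))
    return tuple(out)


def one_way_anova_tukey(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
) -> GroupComparison:
    """One-way ANOVA over k >= 2 groups with Tukey HSD pairwise comparisons.

    Unequal group sizes are handled by the Tukey–Kramer correction.  Degrees
    of freedom are (k − 1, Σn − k).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group must contain at least 2 values")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    k = len(groups)
    n_total = sum(g.size for g in groups)
    f_stat, p = sps.f_oneway(*groups)
    tukey = sps.tukey_hsd(*groups)
    pairwise = tuple(
        (labels[i], labels[j], float(tukey.pvalue[i, j]))
        for i in range(k)
        for j in range(i + 1, k)
    )
    return GroupComparison(
        groups=_descriptives(groups, labels),
        test="anova_tukey",
        statistic=float(f_stat),
        df=(float(k - 1), float(n_total - k)),
        p_value=float(p),
        pairwise=pairwise,
    )


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    welch: bool = False,
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided two-sample t-test: pooled-variance Student by default
    (df = n_a + n_b − 2), Welch with ``welch=True``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample must contain at least 2 values")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        groups=_descriptives([a, b], list(labels)),
        test="t_test",
        statistic=float(res.statistic),
        df=(float(res.df),),
        p_value=float(res.pvalue),
    )
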