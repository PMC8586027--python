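"""Group comparisons and box-plot summaries for per-cell measurements.

Each pairwise comparison is tested for normality with the
D'Agostino-Pearson omnibus test; if both groups pass at alpha the means
are compared with Welch's t-test (two-tailed, no equal-variance
assumption), otherwise with the two-tailed Mann-Whitney U test.  Groups
too small for the normality test (n < 8) fall back to the
nonparametric branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

NORMALITY_MIN_N = 8  # D'Agostino-Pearson needs at least 8 observations


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    normality_p_a: float | None
    normality_p_b: float | None
    test: str  # 'welch-t' or 'mann-whitney'
    statistic: float
    p_value: float
    stars: str


def compare_groups(
    a: np.ndarray,
    b: np.ndarray,
    alpha: float = 0.05,
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison:
    """Two-tailed comparison of two samples per the normality-gated rule."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    p_norm_a = p_norm_b = None
    both_normal = False
    if len(a) >= NORMALITY_MIN_N and len(b) >= NORMALITY_MIN_N:
        p_norm_a = float(stats.normaltest(a).pvalue)
        p_norm_b = float(stats.normaltest(b).pvalue)
        both_normal = p_norm_a > alpha and p_norm_b > alpha
    if both_normal:
        res = stats.ttest_ind(a, b, equal_var=False)
        test = "welch-t"
    else:
        method = "exact" if max(len(a), len(b)) <= NORMALITY_MIN_N else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test = "mann-whitney"
    return GroupComparison(
        label_a=label_a, label_b=label_b, n_a=len(a), n_b=len(b),
        normality_p_a=p_norm_a, normality_p_b=p_norm_b,
        test=test, statistic=float(res.statistic), p_value=float(res.pvalue),
        stars=significance_stars(float(res.pvalue)),
    )


def box_stats(values: np.ndarray) -> dict:
    """Quartiles, median and min-max whiskers (linear-interpolation quantiles)."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("empty group")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    return {
        "n": int(v.size),
        "min": float(v.min()),
        "q25": float(q25),
        "median": float(q50),
        "q75": float(q75),
        "max": float(v.max()),
        "mean": float(v.mean()),
    }


def build_report(
    per_cell: pd.DataFrame,
    value_column: str,
    group_column: str = "group",
    alpha: float = 0.05,
    plot_path: str | None = None,
) -> dict:
    """Per-group box statistics plus all pairwise comparisons.

    Empty groups are dropped with a warning.  Returns a dict with a
    ``summary`` DataFrame (one row per group) and ``comparisons`` (a
    list of GroupComparison); optionally writes a box plot.
    """
    groups = {}
    for name, sub in per_cell.groupby(group_column):
        vals = sub[value_column].dropna().to_numpy(float)
        if vals.size == 0:
            logger.warning("group %r is empty; dropped", name)
            continue
        groups[name] = vals
    if not groups:
        raise ValueError("no non-empty groups")
    summary = pd.DataFrame(
        [{"group": name, **box_stats(v)} for name, v in groups.items()]
    )
    names = list(groups)
    comparisons = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = groups[names[i]], groups[names[j]]
            if len(a) < 3 or len(b) < 3:
                logger.warning(
                    "skipping comparison %r vs %r (group too small)", names[i], names[j]
                )
                continue
            comparisons.append(
                compare_groups(a, b, alpha=alpha, label_a=str(names[i]), label_b=str(names[j]))
            )
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(names), 3.2))
        ax.boxplot([groups[n] for n in names], tick_labels=[str(n) for n in names],
                   whis=(0, 100))
        ax.set_ylabel(value_column)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return {"summary": summary, "comparisons": comparisons}
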