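"""Cohort-level statistics over the classifiers x subjects accuracy matrix.

Distribution summaries use the sample (n-1) standard deviation and Tukey's
median-of-halves quartiles (median of the lower/upper half of the sorted
data, halves excluding the overall median for odd n).  Group comparisons
are classical fixed-effects one-way ANOVA; the pairwise comparison of a
reference classifier against each other one is the two-group special case
(equivalent to the pooled-variance two-sample t-test, F = t^2).  No
multiple-comparison correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "tukey_quartiles",
    "summarize",
    "anova_oneway",
    "pairwise_vs_reference",
    "export_boxplot_data",
    "CohortSummary",
]


def tukey_quartiles(values) -> tuple[float, float]:
    """Q1/Q3 as medians of the lower and upper halves of the sorted data.

    For odd n the overall median is excluded from both halves.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values for quartiles")
    half = n // 2
    return float(np.median(x[:half])), float(np.median(x[n - half:]))


def summarize(values) -> pd.Series:
    """mu / sigma / Q1 / Q3 of one classifier's per-subject accuracies."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 accuracies to summarize")
    q1, q3 = tukey_quartiles(x)
    return pd.Series(
        {"mu": x.mean(), "sigma": x.std(ddof=1), "q1": q1, "q3": q3}
    )


def _groups(matrix: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for name, row in matrix.iterrows():
        vals = row.to_numpy(dtype=float)
        out[str(name)] = vals[np.isfinite(vals)]
    return out


def anova_oneway(matrix: pd.DataFrame) -> tuple[float, float]:
    """Fixed-effects one-way ANOVA across classifier groups: (F, p)."""
    groups = list(_groups(matrix).values())
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("zero within-group variance everywhere; F undefined")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def pairwise_vs_reference(matrix: pd.DataFrame,
                          reference: str = "NN") -> pd.Series:
    """Two-group ANOVA p-value of the reference against each other classifier.

    Missing cells are dropped pairwise (complete-case per comparison).  A
    group compared with itself yields p = 1.
    """
    groups = _groups(matrix)
    if reference not in groups:
        raise KeyError(f"reference classifier {reference!r} not in matrix")
    ref = groups[reference]
    out = {}
    for name, vals in groups.items():
        if name == reference:
            continue
        if np.array_equal(np.sort(ref), np.sort(vals)):
            out[name] = 1.0
            continue
        _, p = stats.f_oneway(ref, vals)
        out[name] = float(p)
    return pd.Series(out, name=f"p vs {reference}")


def export_boxplot_data(matrix: pd.DataFrame) -> dict[str, dict]:
    """Numeric box-plot data per classifier.

    Box edges at Tukey Q1/Q3, whiskers at the most extreme data points
    within 1.5 x IQR of the box, remaining points listed as outliers.
    """
    out = {}
    for name, vals in _groups(matrix).items():
        x = np.sort(vals)
        q1, q3 = tukey_quartiles(x)
        med = float(np.median(x))
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = x[(x >= lo_fence) & (x <= hi_fence)]
        out[name] = {
            "min": float(x.min()),
            "q1": q1,
            "median": med,
            "q3": q3,
            "max": float(x.max()),
            "whisker_low": float(inside.min()),
            "whisker_high": float(inside.max()),
            "outliers": [float(v) for v in x[(x < lo_fence) | (x > hi_fence)]],
        }
    return out


@dataclass
class CohortSummary:
    """Summary-statistics view of a cohort accuracy matrix (percent units)."""

    matrix: pd.DataFrame
    reference: str = "NN"

    @property
    def table(self) -> pd.DataFrame:
        """Per-classifier mu / sigma / Q1 / Q3 table."""
        return pd.DataFrame(
            {name: summarize(vals) for name, vals in _groups(self.matrix).items()}
        ).T

    def anova(self) -> tuple[float, float]:
        return anova_oneway(self.matrix)

    def pairwise(self) -> pd.Series:
        return pairwise_vs_reference(self.matrix, self.reference)

    def boxplot_data(self) -> dict[str, dict]:
        return export_boxplot_data(self.matrix)

    def plot_box(self, ax=None):
        """Render the per-classifier accuracy box plots (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        groups = _groups(self.matrix)
        ax.boxplot(list(groups.values()), tick_labels=list(groups))
        ax.set_ylabel("subject accuracy [%]")
        return ax

    def summary(self) -> str:
        table = self.table
        f, p = self.anova()
        lines = ["Cohort accuracy summary", "=" * 44,
                 table.round(2).to_string(),
                 "",
                 f"one-way ANOVA across classifiers: F={f:.3f}, p={p:.4f}"]
        if self.reference in self.matrix.index:
            pw = self.pairwise()
            lines.append(f"pairwise vs {self.reference}: "
                         + "  ".join(f"{k}={v:.4f}" for k, v in pw.items()))
        return "\n".join(lines)
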