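"""Thin statistical-reporting helpers.

The comparisons used when reporting pipeline outputs: a
D'Agostino-Pearson omnibus test gates each data set; Gaussian-looking
data are compared with Welch's t test (two groups) or a repeated-
measures ANOVA (paired conditions), otherwise Mann-Whitney or Friedman.
Significance is defined as P < 0.05.  These are deliberately thin
wrappers over scipy/statsmodels, not bespoke statistics.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["normality_gate", "compare_two", "compare_repeated", "ALPHA"]

ALPHA = 0.05


def normality_gate(values: Sequence[float], alpha: float = ALPHA) -> tuple[bool, float]:
    """D'Agostino-Pearson normality check; returns (looks_gaussian, p)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 8:
        # the omnibus test is undefined for tiny n; fall back to Shapiro
        stat, p = stats.shapiro(v)
    else:
        stat, p = stats.normaltest(v)
    return bool(p >= alpha), float(p)


def compare_two(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = ALPHA,
) -> dict:
    """Welch's t test when both groups pass the normality gate, else
    Mann-Whitney U; returns test name, p and significance at P < 0.05."""
    ga, _ = normality_gate(a, alpha)
    gb, _ = normality_gate(b, alpha)
    if ga and gb:
        test = "welch_t"
        _, p = stats.ttest_ind(a, b, equal_var=False)
    else:
        test = "mann_whitney"
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"test": test, "p": float(p), "significant": bool(p < alpha)}


def compare_repeated(data: np.ndarray, alpha: float = ALPHA) -> dict:
    """Paired one-way ANOVA (RM-ANOVA) or Friedman across conditions.

    ``data`` is (subjects, conditions); every condition must pass the
    normality gate for the parametric branch.
    """

    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 3:
        raise ValueError("need a (subjects, >=3 conditions) array")
    gaussian = all(normality_gate(data[:, j], alpha)[0] for j in range(data.shape[1]))
    if gaussian:
        from statsmodels.stats.anova import AnovaRM

        n_sub, n_cond = data.shape
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n_sub), n_cond),
                "condition": np.tile(np.arange(n_cond), n_sub),
                "value": data.ravel(),
            }
        )
        res = AnovaRM(long, "value", "subject", within=["condition"]).fit()
        p = float(res.anova_table["Pr > F"].iloc[0])
        test = "rm_anova"
    else:
        _, p = stats.friedmanchisquare(*[data[:, j] for j in range(data.shape[1])])
        test = "friedman"
    return {"test": test, "p": float(p), "significant": bool(p < alpha)}
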