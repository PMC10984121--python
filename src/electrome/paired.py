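"""Paired before/after comparisons with normality-based test routing.

Scalar physiology or ledger variables measured on the same plants before
and after a stimulus are compared with a paired t-test when the paired
differences look normal (Shapiro-Wilk), and with the Wilcoxon signed-rank
test otherwise — mirroring standard practice for this kind of repeated-
measures design. The coefficient of variation (CV%) summarizes dispersion
per phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .errors import ParameterError


@dataclass
class PairedComparison:
    variable: str
    n: int
    test_used: str                 # "t" | "wilcoxon" | "none"
    statistic: Optional[float]
    p_value: Optional[float]
    mean_before: float
    mean_after: float
    sd_before: float
    sd_after: float
    median_before: float
    median_after: float
    cv_before: float
    cv_after: float
    normal_differences: Optional[bool] = None
    no_difference: bool = False

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value is not None and self.p_value <= alpha


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV% = 100 * sample SD / |mean|; NaN when the mean is zero."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ParameterError("empty input")
    mean = x.mean()
    if mean == 0:
        return float("nan")
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    return float(100.0 * sd / abs(mean))


def paired_compare(before: Sequence[float], after: Sequence[float],
                   alpha: float = 0.05, normality_alpha: float = 0.05,
                   variable: str = "") -> PairedComparison:
    """Compare paired before/after values with automatic test routing.

    The paired differences are screened with Shapiro-Wilk at
    ``normality_alpha``: if compatible with normality a two-sided paired
    t-test runs, otherwise the two-sided Wilcoxon signed-rank test. All
    differences equal to zero is reported as ``no_difference`` (neither
    test is defined), not as a p-value.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape or b.ndim != 1:
        raise ParameterError(
            f"before/after must be 1-D and equal length, got {b.shape} vs {a.shape}")
    if b.size < 3:
        raise ParameterError("need at least 3 paired observations")

    summary = dict(
        variable=variable, n=int(b.size),
        mean_before=float(b.mean()), mean_after=float(a.mean()),
        sd_before=float(b.std(ddof=1)), sd_after=float(a.std(ddof=1)),
        median_before=float(np.median(b)), median_after=float(np.median(a)),
        cv_before=coefficient_of_variation(b) if b.mean() != 0 else float("nan"),
        cv_after=coefficient_of_variation(a) if a.mean() != 0 else float("nan"),
    )

    d = a - b
    if np.all(d == 0):
        return PairedComparison(test_used="none", statistic=None, p_value=None,
                                no_difference=True, **summary)
    if np.std(d) == 0:
        # constant nonzero shift: direction certain, no within-pair variance
        return PairedComparison(test_used="none", statistic=None,
                                p_value=None, no_difference=False, **summary)

    _, shapiro_p = sp_stats.shapiro(d)
    normal = bool(shapiro_p > normality_alpha)
    if normal:
        stat, p = sp_stats.ttest_rel(b, a)
        test = "t"
    else:
        stat, p = sp_stats.wilcoxon(b, a, zero_method="wilcox",
                                    alternative="two-sided")
        test = "wilcoxon"
    return PairedComparison(test_used=test, statistic=float(stat),
                            p_value=float(p), normal_differences=normal,
                            **summary)


def comparison_table(ledger: pd.DataFrame, variables: Sequence[str],
                     group_col: str = "experiment", phase_col: str = "phase",
                     id_col: str = "plant_id", alpha: float = 0.05
                     ) -> pd.DataFrame:
    """Before/after comparison table across experiments and ledger variables.

    ``ledger`` has one row per series with phase labels; values are paired
    by plant within each experiment. Rows missing either phase are dropped.
    """
    records = []
    for group, sub in ledger.groupby(group_col):
        wide = sub.pivot_table(index=id_col, columns=phase_col,
                               values=list(variables))
        for var in variables:
            if (var, "before") not in wide.columns or \
                    (var, "after") not in wide.columns:
                continue
            pair = wide[var][["before", "after"]].dropna()
            if len(pair) < 3:
                continue
            cmp_ = paired_compare(pair["before"], pair["after"], alpha=alpha,
                                  variable=var)
            records.append({
                group_col: group, "variable": var, "n": cmp_.n,
                "before": cmp_.mean_before, "after": cmp_.mean_after,
                "sd_before": cmp_.sd_before, "sd_after": cmp_.sd_after,
                "cv_before": cmp_.cv_before, "cv_after": cmp_.cv_after,
                "test": cmp_.test_used, "p_value": cmp_.p_value,
                "significant": cmp_.significant(alpha),
            })
    return pd.DataFrame.from_records(records)
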