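"""Distribution tests used by the comparison reports.

Normality is screened with Shapiro-Wilk; when it is rejected, group
comparisons fall back to the Fligner-Killeen test, mirroring the
normality-first decision rule used throughout the analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class StatTestResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def shapiro_wilk(sample) -> StatTestResult:
    """Shapiro-Wilk normality test."""
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got {len(x)}")
    res = sps.shapiro(x)
    return StatTestResult(
        test_name="shapiro-wilk",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=(len(x),),
    )


def fligner_killeen(*samples) -> StatTestResult:
    """Fligner-Killeen test for homogeneity of variances across groups."""
    if len(samples) < 2:
        raise ValueError("Fligner-Killeen needs at least 2 groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    for a in arrays:
        if len(a) < 3:
            raise ValueError(f"each group needs n >= 3, got {len(a)}")
    res = sps.fligner(*arrays)
    return StatTestResult(
        test_name="fligner-killeen",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=tuple(len(a) for a in arrays),
    )


def compare_distributions(a, b, alpha: float = 0.05) -> dict:
    """Normality-gated two-group comparison.

    Shapiro-Wilk on each group; if either rejects normality at ``alpha``,
    the groups are compared with Fligner-Killeen, else with Welch's t-test.
    """
    sw_a = shapiro_wilk(a)
    sw_b = shapiro_wilk(b)
    normal = sw_a.p_value >= alpha and sw_b.p_value >= alpha
    if normal:
        res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
        chosen = StatTestResult(
            test_name="welch-t",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n_per_group=(len(a), len(b)),
        )
    else:
        chosen = fligner_killeen(a, b)
    return {
        "shapiro_a": sw_a,
        "shapiro_b": sw_b,
        "normal": normal,
        "comparison": chosen,
    }
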