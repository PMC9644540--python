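"""Validation metrics: IoU, absolute-error summaries, and the two-sided t-test.

IoU scores pixel-set agreement between two masks (1 means identical sets).
Angle accuracy is summarized as the mean of absolute errors and its sample
standard deviation, per junction and pooled.  Group comparisons use a
two-sided t-test at the 5% significance level; Welch's unequal-variance
form is the default, with a pooled-variance flag for strict replication of
spreadsheet-style analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        """True at the 5% level (p <= 0.05)."""
        return self.p_value <= 0.05


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two binary masks; in [0, 1].

    Raises when the masks differ in shape, or when both are empty (the
    ratio is undefined rather than 0).
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        raise ValidationError("IoU undefined: both masks are empty")
    inter = int(np.logical_and(a, b).sum())
    return inter / union


def error_summary(
    measured: pd.DataFrame,
    truth: pd.DataFrame,
    value: str = "rom_raw_deg",
    on: tuple[str, ...] = ("junction",),
) -> pd.DataFrame:
    """Mean absolute error and its sample SD, per junction and pooled.

    ``measured`` and ``truth`` are aligned on the ``on`` key columns
    (include ``subject_id`` there for multi-subject tables); rows where
    either value is missing are excluded pairwise.  The output has one row
    per junction and a final ``overall`` row pooling all aligned pairs,
    with columns ``mean_abs_error``, ``sd`` (ddof=1, NaN for n=1) and ``n``.
    """
    keys = list(on)
    m = measured[keys + [value]].rename(columns={value: "measured"})
    t = truth[keys + [value]].rename(columns={value: "truth"})
    merged = m.merge(t, on=keys, how="inner").dropna(subset=["measured", "truth"])
    if merged.empty:
        return pd.DataFrame(columns=["junction", "mean_abs_error", "sd", "n"])
    merged["abs_err"] = (merged["measured"] - merged["truth"]).abs()
    rows = []
    for j, grp in merged.groupby("junction", sort=True):
        rows.append(
            {
                "junction": j,
                "mean_abs_error": grp["abs_err"].mean(),
                "sd": grp["abs_err"].std(ddof=1),
                "n": len(grp),
            }
        )
    rows.append(
        {
            "junction": "overall",
            "mean_abs_error": merged["abs_err"].mean(),
            "sd": merged["abs_err"].std(ddof=1),
            "n": len(merged),
        }
    )
    return pd.DataFrame(rows)


def t_test_two_sided(sample1, sample2, equal_var: bool = False) -> TTestResult:
    """Two-sided t-test between two error samples (Welch by default).

    Degenerate inputs (zero variance in both samples) return p = 1 for
    equal means and p = 0 otherwise, by convention.
    """
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    if len(s1) < 2 or len(s2) < 2:
        raise ValidationError("each sample needs at least 2 observations")
    if s1.var(ddof=1) == 0 and s2.var(ddof=1) == 0:
        same = np.isclose(s1.mean(), s2.mean())
        return TTestResult(statistic=0.0 if same else np.inf, p_value=1.0 if same else 0.0)
    res = stats.ttest_ind(s1, s2, equal_var=equal_var)
    return TTestResult(statistic=float(res.statistic), p_value=float(res.pvalue))
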