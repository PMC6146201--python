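"""Self-contained statistical primitives.

Paired and two-sample t tests, a one-way repeated-measures ANOVA, and the
behavioral reaction-time filter.  The test statistics and degrees of freedom
are computed from first principles; p-values come from the t / F
distribution survival functions evaluated through the regularized
incomplete beta function.  All t p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "TestResult",
    "DegenerateDataError",
    "paired_t",
    "two_sample_t",
    "rm_anova_oneway",
    "rt_filter",
]


class DegenerateDataError(ValueError):
    """Zero-variance or otherwise degenerate input to a test."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float

    def __iter__(self):
        return iter((self.statistic, self.df, self.p_value))


def _t_p_two_sided(t: float, df: float) -> float:
    """Two-sided Student-t p-value via the regularized incomplete beta."""
    return float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))


def _f_sf(f: float, df1: float, df2: float) -> float:
    """P(F > f) via the regularized incomplete beta."""
    if f <= 0:
        return 1.0
    return float(special.betainc(df2 / 2.0, df1 / 2.0, df2 / (df2 + df1 * f)))


def paired_t(x, y) -> TestResult:
    """Two-sided paired t test.

    t = mean(d) / (sd(d)/sqrt(n)) with d = x - y and sample SD (n-1
    denominator); df = n - 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("differences have zero variance")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    return TestResult(float(t), float(df), _t_p_two_sided(t, df))


def two_sample_t(x, y, equal_var: bool = False) -> TestResult:
    """Two-sided independent-samples t test.

    Welch statistic with Welch-Satterthwaite df by default; classical
    pooled-variance statistic when ``equal_var`` is true.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise DegenerateDataError("zero variance in both groups")
    if equal_var:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
        df = nx + ny - 2.0
    else:
        se = np.sqrt(vx / nx + vy / ny)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    t = (x.mean() - y.mean()) / se
    return TestResult(float(t), float(df), _t_p_two_sided(t, df))


def rm_anova_oneway(table) -> TestResult:
    """One-way repeated-measures ANOVA (within-subject factor).

    ``table`` is subjects x conditions (2-D array or DataFrame with one row
    per subject, one column per condition; complete, no missing cells).
    F = MS_condition / MS_error with df (k-1, (k-1)(n-1)), the error term
    being the subject-by-condition interaction.
    """
    values = np.asarray(table, dtype=float)
    if values.ndim != 2:
        raise ValueError("table must be subjects x conditions")
    if np.isnan(values).any():
        raise ValueError("missing cells in repeated-measures table")
    n, k = values.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    grand = values.mean()
    ss_cond = n * np.sum((values.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((values.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((values - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1.0, (k - 1.0) * (n - 1.0)
    ms_err = ss_err / df2
    if ms_err == 0:
        raise DegenerateDataError("zero error variance in RM-ANOVA")
    f = (ss_cond / df1) / ms_err
    return TestResult(float(f), (df1, df2), _f_sf(f, df1, df2))


def rt_filter(behavior: pd.DataFrame) -> pd.DataFrame:
    """Behavioral trial filter: drop incorrect responses, then per-emotion
    reaction-time outliers.

    Incorrect-response rows are removed first.  Then, within each emotion
    (per subject if a ``subject`` column is present), rows whose RT lies
    outside [mean - 2 SD, mean + 2 SD] — mean and sample SD computed on that
    group's correct-response RTs — are removed.  Bounds are inclusive and
    the filter is a single pass (bounds are not recomputed after removal).
    """
    required = {"emotion", "rt_ms", "correct"}
    if not required.issubset(behavior.columns):
        raise ValueError(f"behavior table needs columns {sorted(required)}")
    correct = behavior[behavior["correct"].astype(bool)]
    group_cols = ["subject", "emotion"] if "subject" in behavior.columns else ["emotion"]
    kept = []
    for _, grp in correct.groupby(group_cols, sort=False):
        if len(grp) < 2:
            import warnings
            warnings.warn("emotion group with < 2 correct trials excluded")
            continue
        m = grp["rt_ms"].mean()
        sd = grp["rt_ms"].std(ddof=1)
        mask = (grp["rt_ms"] >= m - 2 * sd) & (grp["rt_ms"] <= m + 2 * sd)
        kept.append(grp[mask])
    if not kept:
        return correct.iloc[0:0]
    return pd.concat(kept).sort_index()
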