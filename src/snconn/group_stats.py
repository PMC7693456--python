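"""Demographic/behavioral group comparison: pooled t, Cohen's d, chi-square.

The pooled-variance (equal-variance) two-sample t is the default because the
effect-size relation d = t * sqrt(1/n1 + 1/n2) then holds exactly, which is
the convention used in the reference tables this package reproduces.  Welch's
t is available via ``equal_var=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupComparison:
    """One variable's two-group comparison, shaped like a demographics table row."""

    variable: str
    mean_sd_group1: Tuple[float, float]
    mean_sd_group2: Tuple[float, float]
    t_value: float
    df: float
    p_value: float
    cohens_d: float
    d_ci95: Tuple[float, float]


def two_sample_t(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> Tuple[float, float, float]:
    """Two-sample t-test; returns (t, df, two-sided p).

    Pooled-variance Student t by default; Welch with ``equal_var=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    sp2 = (
        (x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)
    ) / (x.size + y.size - 2)
    if equal_var and sp2 == 0:
        raise ValueError("zero pooled variance")
    df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def cohens_d_from_t(t: float, n1: int, n2: int) -> float:
    """Cohen's d from a pooled two-sample t: d = t * sqrt(1/n1 + 1/n2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("n1, n2 must be >= 2")
    return t * math.sqrt(1.0 / n1 + 1.0 / n2)


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d from raw samples: mean difference over pooled SD.

    Agrees exactly with :func:`cohens_d_from_t` applied to the pooled t.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    sp2 = (
        (x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)
    ) / (x.size + y.size - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    return float((x.mean() - y.mean()) / math.sqrt(sp2))


def cohens_d_ci(
    d: float, n1: int, n2: int, level: float = 0.95
) -> Tuple[float, float]:
    """Normal-approximation confidence interval for Cohen's d.

    SE = sqrt((n1+n2)/(n1*n2) + d^2 / (2 (n1+n2))).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    se = math.sqrt((n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2)))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (d - z * se, d + z * se)


def chi_square_counts(
    table: Sequence[Sequence[float]], correction: bool = False
) -> Tuple[float, float]:
    """Pearson chi-square on a contingency table of counts; returns (chi2, p).

    No continuity correction by default; pass ``correction=True`` for Yates.
    """
    tab = np.asarray(table, dtype=float)
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(tab, correction=correction)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    x: Sequence[float], y: Sequence[float], variable: str = "", level: float = 0.95
) -> GroupComparison:
    """Full per-variable comparison row: t, p, d and its CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, df, p = two_sample_t(x, y)
    d = cohens_d(x, y)
    return GroupComparison(
        variable=variable,
        mean_sd_group1=(float(x.mean()), float(x.std(ddof=1))),
        mean_sd_group2=(float(y.mean()), float(y.std(ddof=1))),
        t_value=t,
        df=df,
        p_value=p,
        cohens_d=d,
        d_ci95=cohens_d_ci(d, x.size, y.size, level),
    )


def demographics_table(
    subjects: pd.DataFrame,
    variables: Optional[Sequence[str]] = None,
    group_col: str = "group",
    gender_col: str = "gender",
) -> pd.DataFrame:
    """Demographics-report table: one row per continuous variable plus gender.

    Continuous variables get the pooled t / Cohen's d / 95% CI columns;
    gender gets a chi-square on the 2x2 group-by-gender counts.  All raw
    p-values are emitted; ``significant`` flags p <= 0.001.
    """
    groups = sorted(subjects[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    g1 = subjects[subjects[group_col] == groups[0]]
    g2 = subjects[subjects[group_col] == groups[1]]
    if variables is None:
        variables = [
            c
            for c in subjects.columns
            if c not in (group_col, gender_col, "subject_id")
            and pd.api.types.is_numeric_dtype(subjects[c])
        ]
    rows = []
    for var in variables:
        x = g1[var].dropna().to_numpy()
        y = g2[var].dropna().to_numpy()
        c = compare_groups(x, y, variable=var)
        rows.append(
            {
                "variable": var,
                f"mean_{groups[0]}": c.mean_sd_group1[0],
                f"sd_{groups[0]}": c.mean_sd_group1[1],
                f"mean_{groups[1]}": c.mean_sd_group2[0],
                f"sd_{groups[1]}": c.mean_sd_group2[1],
                "t_value": c.t_value,
                "cohens_d": c.cohens_d,
                "d_ci95_low": c.d_ci95[0],
                "d_ci95_high": c.d_ci95[1],
                "p_value": c.p_value,
                "test": "pooled_t",
            }
        )
    if gender_col in subjects.columns:
        counts = pd.crosstab(subjects[group_col], subjects[gender_col])
        chi2, p = chi_square_counts(counts.to_numpy())
        rows.append(
            {"variable": gender_col, "t_value": chi2, "p_value": p, "test": "chi_square"}
        )
    out = pd.DataFrame(rows)
    out["significant"] = out["p_value"] <= 0.001
    return out
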