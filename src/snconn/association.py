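"""Normality-gated correlation between edge connectivity and clinical scores.

The method-assignment rule mirrors common practice in clinical imaging
reports: each variable pair is first screened with Shapiro-Wilk; Pearson's
correlation is used only when both variables pass (p > alpha), otherwise
Spearman's rank-order correlation.  All pairwise tests are emitted with
their uncorrected p-values alongside Benjamini-Hochberg q-values so readers
can apply either convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PEARSON = "pearson"
SPEARMAN = "spearman"


@dataclass
class CorrelationResult:
    edge: str
    variable: str
    method: str
    r: float
    p: float
    n: int
    normality_p: Tuple[float, float]  # Shapiro p of (x, y)


def _check_sample(v: np.ndarray, name: str) -> None:
    if v.size < 4:
        raise ValueError(f"{name}: need n >= 4, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name}: non-finite values")
    if np.ptp(v) == 0:
        raise ValueError(f"{name}: constant sample")


def shapiro_normal(x: Sequence[float], alpha: float = 0.05) -> Tuple[bool, float]:
    """Shapiro-Wilk normality screen; returns (passes, p)."""
    x = np.asarray(x, dtype=float)
    _check_sample(x, "sample")
    p = float(stats.shapiro(x).pvalue)
    return p > alpha, p


def choose_method(
    x: Sequence[float], y: Sequence[float], normality_alpha: float = 0.05
) -> str:
    """Pearson iff both variables pass Shapiro-Wilk, else Spearman."""
    ok_x, _ = shapiro_normal(x, normality_alpha)
    ok_y, _ = shapiro_normal(y, normality_alpha)
    return PEARSON if (ok_x and ok_y) else SPEARMAN


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: Optional[str] = None,
    normality_alpha: float = 0.05,
    edge: str = "",
    variable: str = "",
) -> CorrelationResult:
    """Correlation with two-sided p; the method is normality-gated if unset.

    Spearman is computed on average ranks (ties shared).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    _check_sample(x, "x")
    _check_sample(y, "y")
    px = float(stats.shapiro(x).pvalue)
    py = float(stats.shapiro(y).pvalue)
    if method is None:
        method = (
            PEARSON if (px > normality_alpha and py > normality_alpha) else SPEARMAN
        )
    if method == PEARSON:
        r, p = stats.pearsonr(x, y)
    elif method == SPEARMAN:
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(
        edge=edge,
        variable=variable,
        method=method,
        r=float(r),
        p=float(p),
        n=int(x.size),
        normality_p=(px, py),
    )


def association_table(
    features: pd.DataFrame,
    variables: pd.DataFrame,
    normality_alpha: float = 0.05,
    report_alpha: float = 0.01,
) -> pd.DataFrame:
    """All edge-by-variable correlations, with BH q-values.

    ``features`` holds one column per edge (rows = subjects, aligned with
    ``variables`` on the index).  The ``flagged`` column marks uncorrected
    p below ``report_alpha``.
    """
    features, variables = features.align(variables, join="inner", axis=0)
    if len(features) < 4:
        raise ValueError("fewer than 4 aligned subjects")
    rows = []
    for edge in features.columns:
        for var in variables.columns:
            res = correlate(
                features[edge].to_numpy(),
                variables[var].to_numpy(),
                normality_alpha=normality_alpha,
                edge=str(edge),
                variable=str(var),
            )
            rows.append(
                {
                    "edge": res.edge,
                    "variable": res.variable,
                    "method": res.method,
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_bh"] = multipletests(out["p"], method="fdr_bh")[1]
        out["flagged"] = out["p"] < report_alpha
    return out
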