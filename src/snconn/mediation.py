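"""Simple (single-mediator) mediation with percentile-bootstrap inference.

The model decomposes the effect of an exposure X (e.g. hemoglobin) on an
outcome Y (e.g. a digit-span score) through a mediator M (an edge's
Fisher-z connectivity) using three OLS regressions sharing the same
covariates (default age, gender, education):

    Y = i   + c  X + covariates + e        (total effect)
    M = i_M + a  X + covariates + e_M      (exposure -> mediator)
    Y = i_Y + c' X + b M + covariates + e_Y  (direct + mediator paths)

The indirect effect is a*b and, on any complete-case sample, the OLS
identity c = c' + a*b holds to machine precision.  Inference on a*b uses a
percentile bootstrap over subjects (default 5000 resamples); the effect is
classified as suppression when the indirect CI excludes zero while both
the total and direct effects are non-significant — the pattern reported
for hemoglobin -> connectivity -> working-memory scores in anemic
patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

NO_EFFECT = "no_effect"
FULL_MEDIATION = "full_mediation"
PARTIAL_MEDIATION = "partial_mediation"
SUPPRESSION = "suppression"

_MAX_REDRAWS = 100


@dataclass
class MediationSpec:
    x: str
    m: str
    y: str
    covariates: Sequence[str] = ("age", "gender", "education")
    n_bootstrap: int = 5000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if len({self.x, self.m, self.y}) != 3:
            raise ValueError("X, M, Y must be distinct columns")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class PathEstimate:
    coef: float
    se: float
    p: float


@dataclass
class MediationFit:
    a: PathEstimate
    b: PathEstimate
    c: PathEstimate
    c_prime: PathEstimate
    indirect: float
    i_M: float
    i_Y: float
    resid_sd_M: float
    resid_sd_Y: float
    n_used: int
    n_dropped: int
    boot_ci_indirect: Optional[Tuple[float, float]] = None
    boot_indirect: Optional[np.ndarray] = None
    effect_class: Optional[str] = None

    def to_dict(self) -> dict:
        d = {
            "a": self.a.coef, "se_a": self.a.se, "p_a": self.a.p,
            "b": self.b.coef, "se_b": self.b.se, "p_b": self.b.p,
            "c": self.c.coef, "se_c": self.c.se, "p_c": self.c.p,
            "c_prime": self.c_prime.coef, "se_c_prime": self.c_prime.se,
            "p_c_prime": self.c_prime.p,
            "indirect_ab": self.indirect,
            "i_M": self.i_M, "i_Y": self.i_Y,
            "resid_sd_M": self.resid_sd_M, "resid_sd_Y": self.resid_sd_Y,
            "n_used": self.n_used, "n_dropped": self.n_dropped,
            "effect_class": self.effect_class,
        }
        if self.boot_ci_indirect is not None:
            d["boot_llci"] = self.boot_ci_indirect[0]
            d["boot_ulci"] = self.boot_ci_indirect[1]
        return d


def _design(data: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    return np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in cols]
    )


def _check_rank(design: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = []
        keep: List[int] = []
        for j in range(design.shape[1]):
            if np.linalg.matrix_rank(design[:, keep + [j]]) > len(keep):
                keep.append(j)
            else:
                bad.append(names[j] if j > 0 else "intercept")
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")


def fit_model4(data: pd.DataFrame, spec: MediationSpec) -> MediationFit:
    """Point estimates of a, b, c, c' from three OLS fits on complete cases."""
    cols = [spec.x, spec.m, spec.y, *spec.covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    full = data[cols].apply(pd.to_numeric, errors="coerce")
    cc = full.dropna()
    n_dropped = len(full) - len(cc)
    if len(cc) < len(spec.covariates) + 3:
        raise ValueError(
            f"only {len(cc)} complete cases; need >= {len(spec.covariates) + 3}"
        )

    cov = list(spec.covariates)
    d_total = _design(cc, [spec.x, *cov])
    d_med = d_total
    d_out = _design(cc, [spec.x, spec.m, *cov])
    _check_rank(d_out, ["intercept", spec.x, spec.m, *cov])

    fit_c = sm.OLS(cc[spec.y].to_numpy(), d_total).fit()
    fit_a = sm.OLS(cc[spec.m].to_numpy(), d_med).fit()
    fit_by = sm.OLS(cc[spec.y].to_numpy(), d_out).fit()

    def path(fit, idx) -> PathEstimate:
        return PathEstimate(
            coef=float(fit.params[idx]),
            se=float(fit.bse[idx]),
            p=float(fit.pvalues[idx]),
        )

    a = path(fit_a, 1)
    c = path(fit_c, 1)
    c_prime = path(fit_by, 1)
    b = path(fit_by, 2)
    return MediationFit(
        a=a,
        b=b,
        c=c,
        c_prime=c_prime,
        indirect=a.coef * b.coef,
        i_M=float(fit_a.params[0]),
        i_Y=float(fit_by.params[0]),
        resid_sd_M=float(np.sqrt(fit_a.mse_resid)),
        resid_sd_Y=float(np.sqrt(fit_by.mse_resid)),
        n_used=len(cc),
        n_dropped=n_dropped,
    )


def _batched_indirect(
    d_med: np.ndarray,
    d_out: np.ndarray,
    m_vec: np.ndarray,
    y_vec: np.ndarray,
    idx: np.ndarray,
) -> np.ndarray:
    """a*b for a batch of bootstrap index sets (rows of ``idx``)."""
    dm = d_med[idx]                     # (B, n, p1)
    do = d_out[idx]                     # (B, n, p2)
    mm = m_vec[idx]
    yy = y_vec[idx]
    g_m = np.einsum("bnp,bnq->bpq", dm, dm)
    g_o = np.einsum("bnp,bnq->bpq", do, do)
    r_m = np.einsum("bnp,bn->bp", dm, mm)
    r_o = np.einsum("bnp,bn->bp", do, yy)
    beta_m = np.linalg.solve(g_m, r_m[..., None])[..., 0]
    beta_o = np.linalg.solve(g_o, r_o[..., None])[..., 0]
    return beta_m[:, 1] * beta_o[:, 2]


def bootstrap_indirect(
    data: pd.DataFrame, spec: MediationSpec
) -> Tuple[Tuple[float, float], np.ndarray]:
    """Percentile-bootstrap CI for the indirect effect a*b.

    Subjects are resampled with replacement ``n_bootstrap`` times; each
    resample's a*b is collected and the CI is the (alpha/2, 1-alpha/2)
    percentile pair.  Rank-deficient resamples are redrawn (bounded
    retries).  Seed-deterministic.
    """
    cols = [spec.x, spec.m, spec.y, *spec.covariates]
    cc = data[cols].apply(pd.to_numeric, errors="coerce").dropna()
    if len(cc) < len(spec.covariates) + 3:
        raise ValueError("too few complete cases for bootstrap")
    cov = list(spec.covariates)
    d_med = _design(cc, [spec.x, *cov])
    d_out = _design(cc, [spec.x, spec.m, *cov])
    m_vec = cc[spec.m].to_numpy(dtype=float)
    y_vec = cc[spec.y].to_numpy(dtype=float)

    rng = np.random.default_rng(spec.seed)
    n = len(cc)
    boot = np.empty(spec.n_bootstrap)
    filled = 0
    chunk = 2000
    redraws = 0
    while filled < spec.n_bootstrap:
        want = min(chunk, spec.n_bootstrap - filled)
        idx = rng.integers(0, n, size=(want, n))
        try:
            vals = _batched_indirect(d_med, d_out, m_vec, y_vec, idx)
        except np.linalg.LinAlgError:
            vals = np.full(want, np.nan)
            for r in range(want):
                try:
                    vals[r] = _batched_indirect(
                        d_med, d_out, m_vec, y_vec, idx[r][None, :]
                    )[0]
                except np.linalg.LinAlgError:
                    pass
        good = np.isfinite(vals)
        bad = int(want - good.sum())
        if bad:
            redraws += bad
            if redraws > _MAX_REDRAWS:
                raise ValueError(
                    "too many rank-deficient bootstrap resamples; "
                    "check for near-constant columns"
                )
        take = vals[good]
        boot[filled : filled + take.size] = take
        filled += take.size

    alpha = 1.0 - spec.ci_level
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return (float(lo), float(hi)), boot


def classify_effect(
    fit: MediationFit, alpha: float = 0.05
) -> str:
    """Effect taxonomy from the bootstrap CI and the total/direct p-values.

    * ``no_effect`` — indirect CI contains 0;
    * ``suppression`` — indirect CI excludes 0, total and direct both
      non-significant;
    * ``full_mediation`` — indirect CI excludes 0, total significant,
      direct non-significant;
    * ``partial_mediation`` — any other CI-excluding-zero pattern.
    """
    if fit.boot_ci_indirect is None:
        raise ValueError("fit has no bootstrap CI; run bootstrap_indirect first")
    lo, hi = fit.boot_ci_indirect
    if lo <= 0.0 <= hi:
        return NO_EFFECT
    total_sig = fit.c.p < alpha
    direct_sig = fit.c_prime.p < alpha
    if not total_sig and not direct_sig:
        return SUPPRESSION
    if total_sig and not direct_sig:
        return FULL_MEDIATION
    return PARTIAL_MEDIATION


def run_mediation(
    data: pd.DataFrame, spec: MediationSpec, alpha: float = 0.05
) -> MediationFit:
    """Fit, bootstrap, and classify in one call."""
    fit = fit_model4(data, spec)
    ci, boot = bootstrap_indirect(data, spec)
    fit.boot_ci_indirect = ci
    fit.boot_indirect = boot
    fit.effect_class = classify_effect(fit, alpha=alpha)
    return fit
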