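"""Mediation: OLS decomposition, percentile bootstrap, effect taxonomy."""

import numpy as np
import pandas as pd
import pytest

from snconn import (
    MediationFit,
    MediationSpec,
    SyntheticConfig,
    bootstrap_indirect,
    classify_effect,
    fit_model4,
    generate_cohort,
    run_mediation,
)
from snconn.mediation import PathEstimate
from snconn.synthetic import MediationGroundTruth, mediation_table


def _structural_data(rng, n=150, a=0.5, b=0.4, c_prime=0.1):
    x = rng.normal(0, 1, n)
    m = 0.2 + a * x + rng.normal(0, 0.5, n)
    y = 1.0 + c_prime * x + b * m + rng.normal(0, 1.0, n)
    return pd.DataFrame(
        {
            "X": x,
            "M": m,
            "Y": y,
            "age": rng.normal(46, 10, n),
            "gender": rng.integers(0, 2, n),
            "education": rng.normal(10, 3, n),
        }
    )


SPEC = MediationSpec(x="X", m="M", y="Y", n_bootstrap=400, seed=0)


class TestFitModel4:
    def test_effect_decomposition_identity(self, rng):
        fit = fit_model4(_structural_data(rng), SPEC)
        assert abs(fit.c.coef - (fit.c_prime.coef + fit.indirect)) < 1e-10

    def test_b_zero_limit(self, rng):
        fit = fit_model4(_structural_data(rng, b=0.0), SPEC)
        se_ab = abs(fit.a.coef) * fit.b.se + abs(fit.b.coef) * fit.a.se
        assert abs(fit.indirect) < 3 * se_ab + 1e-9

    def test_recovers_planted_paths_from_cohort(self):
        cfg = SyntheticConfig(n_per_group=100, n_timepoints=230, seed=21)
        tab = mediation_table(generate_cohort(cfg), standardize_x=True)
        fit = fit_model4(tab, SPEC)
        gt = cfg.mediation
        assert fit.a.coef == pytest.approx(gt.a, abs=3 * fit.a.se)
        assert fit.b.coef == pytest.approx(gt.b, abs=3 * fit.b.se)
        assert fit.c_prime.coef == pytest.approx(gt.c_prime, abs=3 * fit.c_prime.se)

    def test_collinear_design_refused_with_names(self, rng):
        data = _structural_data(rng)
        data["age2"] = 2 * data["age"]
        spec = MediationSpec(
            x="X", m="M", y="Y", covariates=("age", "age2"), n_bootstrap=10
        )
        with pytest.raises(ValueError, match="age2"):
            fit_model4(data, spec)

    def test_complete_case_deletion_counted(self, rng):
        data = _structural_data(rng, n=60)
        data.loc[3, "M"] = np.nan
        data.loc[7, "Y"] = np.nan
        fit = fit_model4(data, SPEC)
        assert fit.n_used == 58 and fit.n_dropped == 2

    def test_noise_covariates_leave_paths_nearly_unchanged(self, rng):
        data = _structural_data(rng, n=400)
        with_cov = fit_model4(data, SPEC)
        without = fit_model4(
            data, MediationSpec(x="X", m="M", y="Y", covariates=(), n_bootstrap=10)
        )
        assert with_cov.a.coef == pytest.approx(without.a.coef, abs=2 * without.a.se)
        assert with_cov.b.coef == pytest.approx(without.b.coef, abs=2 * without.b.se)


class TestBootstrapIndirect:
    def test_seed_deterministic(self, rng):
        data = _structural_data(rng)
        ci1, boot1 = bootstrap_indirect(data, SPEC)
        ci2, boot2 = bootstrap_indirect(data, SPEC)
        assert ci1 == ci2 and np.array_equal(boot1, boot2)

    def test_strong_mediation_excludes_zero(self):
        rejections = 0
        for rep in range(10):
            g = np.random.default_rng(3000 + rep)
            data = _structural_data(g, n=200, a=0.8, b=0.8)
            ci, _ = bootstrap_indirect(
                data, MediationSpec(x="X", m="M", y="Y", n_bootstrap=400, seed=rep)
            )
            rejections += not (ci[0] <= 0.0 <= ci[1])
        assert rejections >= 10 * 0.95

    def test_null_ci_never_undercovers(self):
        # double-null (a = b = 0): the percentile CI for a*b is conservative,
        # so rejections must stay at or below the nominal binomial bound
        from scipy.stats import binom

        n_rep, reject = 60, 0
        for rep in range(n_rep):
            g = np.random.default_rng(9000 + rep)
            data = _structural_data(g, n=100, a=0.0, b=0.0, c_prime=0.0)
            ci, _ = bootstrap_indirect(
                data, MediationSpec(x="X", m="M", y="Y", n_bootstrap=300, seed=rep)
            )
            reject += not (ci[0] <= 0.0 <= ci[1])
        assert reject <= binom.ppf(0.975, n_rep, 0.05)

    def test_ci_width_shrinks_like_root_n(self):
        # mean CI width over replicate datasets scales roughly as n^(-1/2)
        widths = []
        for n in (50, 100, 200, 400):
            reps = []
            for r in range(5):
                g = np.random.default_rng(1000 * n + r)
                data = _structural_data(g, n=n)
                ci, _ = bootstrap_indirect(
                    data,
                    MediationSpec(x="X", m="M", y="Y", n_bootstrap=600, seed=r),
                )
                reps.append(ci[1] - ci[0])
            widths.append(np.mean(reps))
        assert widths == sorted(widths, reverse=True)
        assert 1.8 < widths[0] / widths[-1] < 4.5  # ~sqrt(8) expected


class TestClassifyEffect:
    def _fit(self, ci, p_total, p_direct):
        path = lambda p: PathEstimate(coef=0.1, se=0.05, p=p)
        return MediationFit(
            a=path(0.01), b=path(0.01), c=path(p_total), c_prime=path(p_direct),
            indirect=(ci[0] + ci[1]) / 2, i_M=0, i_Y=0, resid_sd_M=1,
            resid_sd_Y=1, n_used=43, n_dropped=0, boot_ci_indirect=ci,
        )

    def test_reported_suppression_pattern(self):
        # indirect CI (0.0006, 0.015) with non-significant total (p=0.9048)
        # and direct (p=0.3613) effects is a suppression effect
        fit = self._fit((0.0006, 0.015), p_total=0.9048, p_direct=0.3613)
        assert classify_effect(fit) == "suppression"

    def test_ci_containing_zero_is_no_effect(self):
        fit = self._fit((-0.01, 0.02), p_total=0.01, p_direct=0.01)
        assert classify_effect(fit) == "no_effect"

    def test_full_mediation_definition(self):
        fit = self._fit((0.1, 0.3), p_total=0.001, p_direct=0.4)
        assert classify_effect(fit) == "full_mediation"

    def test_partial_mediation_otherwise(self):
        fit = self._fit((0.1, 0.3), p_total=0.001, p_direct=0.001)
        assert classify_effect(fit) == "partial_mediation"


def test_run_mediation_end_to_end_on_cohort():
    cfg = SyntheticConfig(
        n_per_group=150,
        n_timepoints=230,
        mediation=MediationGroundTruth(a=0.8, b=0.8, c_prime=0.1,
                                       noise_sd_Y=0.8),
        seed=33,
    )
    tab = mediation_table(generate_cohort(cfg), standardize_x=True)
    fit = run_mediation(tab, MediationSpec(x="X", m="M", y="Y",
                                           n_bootstrap=500, seed=2))
    assert fit.effect_class in {"partial_mediation", "full_mediation",
                                "suppression"}
    assert fit.boot_ci_indirect[0] > 0.0
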