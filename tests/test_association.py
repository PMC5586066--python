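"""Logistic models, likelihood-ratio tests, AUC/DeLong, bootstrap validation."""

import numpy as np
import pandas as pd
import pytest

from mammospat import association as assoc
from mammospat.errors import (
    DesignError,
    InvalidComparisonError,
    SeparationError,
    UndefinedAUCError,
)
from mammospat.phantom import DEFAULT_BETA, CohortSpec, generate_cohort

FPC13 = [
    "fpc12_1", "fpc12_2", "fpc13_1", "fpc13_2", "fpc14_1", "fpc14_2",
    "fpc23_1", "fpc23_2", "fpc24_1", "fpc24_2", "fpc24_3", "fpc34_1", "fpc34_2",
]


def null_cohort(n_cases, n_controls, seed, n_fpcs=13, fpc_beta=None):
    """Cohort with zero covariate effects plus standard-normal fPC columns.

    ``fpc_beta`` optionally adds a direct effect of the first fPC column on
    the case log-odds (by resampling status).
    """
    beta = {k: 0.0 for k in DEFAULT_BETA}
    cohort, _ = generate_cohort(
        CohortSpec(n_cases=n_cases, n_controls=n_controls, seed=seed, beta=beta)
    )
    rng = np.random.default_rng(seed + 1)
    for name in FPC13[:n_fpcs]:
        cohort[name] = rng.normal(size=len(cohort))
    if fpc_beta:
        from scipy.special import expit

        logit = fpc_beta * cohort[FPC13[0]].to_numpy()
        cohort["status"] = (rng.random(len(cohort)) < expit(logit)).astype(int)
    return cohort


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        # the printed case/control counts of the main study
        y = np.r_[np.ones(1170), np.zeros(1283)]
        X = pd.DataFrame({"const": np.ones(y.size)})
        fit = assoc.fit_logistic(y, X)
        assert fit.params["const"] == pytest.approx(np.log(1170 / 1283), abs=1e-8)

    def test_two_by_two_log_odds_ratio(self):
        a, b, c, d = 30, 70, 55, 45  # exposed cases/controls, unexposed
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        X = pd.DataFrame({"const": np.ones(y.size), "exposed": x})
        fit = assoc.fit_logistic(y, X)
        assert fit.params["exposed"] == pytest.approx(np.log(a * d / (b * c)), abs=1e-8)

    def test_perfect_separation_raises(self):
        y = np.r_[np.zeros(20), np.ones(20)]
        x = np.r_[np.arange(20), np.arange(100, 120)].astype(float)
        X = pd.DataFrame({"const": np.ones(40), "x": x})
        with pytest.raises(SeparationError):
            assoc.fit_logistic(y, X)

    def test_rank_deficiency_raises(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        x = np.arange(20, dtype=float)
        X = pd.DataFrame({"const": np.ones(20), "x": x, "x2": 2 * x})
        with pytest.raises(DesignError):
            assoc.fit_logistic(y, X)


class TestLikelihoodRatio:
    def test_identical_models_give_p_one(self):
        y = np.r_[np.zeros(30), np.ones(30)]
        X = pd.DataFrame({"const": np.ones(60)})
        fit = assoc.fit_logistic(y, X)
        stat, df, p = assoc.likelihood_ratio_test(fit, fit)
        assert (stat, df, p) == (0.0, 0, 1.0)

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 60).astype(float)
        Xa = pd.DataFrame({"const": np.ones(60), "a": rng.normal(size=60)})
        Xb = pd.DataFrame({"const": np.ones(60), "b": rng.normal(size=60)})
        fa, fb = assoc.fit_logistic(y, Xa), assoc.fit_logistic(y, Xb)
        with pytest.raises(InvalidComparisonError):
            assoc.likelihood_ratio_test(fa, fb)

    @pytest.mark.parametrize("seed", range(6))
    def test_categorical_lrt_equals_g_statistic(self, seed):
        # the logistic LRT on expanded counts is the contingency G-test
        rng = np.random.default_rng(seed)
        cases = rng.integers(15, 120, size=4)
        controls = rng.integers(15, 120, size=4)
        stat, df, p = assoc.categorical_lrt_from_counts(cases, controls)
        g, gdf, gp = assoc.contingency_g_statistic(np.stack([cases, controls]))
        assert df == gdf == 3
        assert stat == pytest.approx(g, rel=1e-6)
        assert p == pytest.approx(gp, rel=1e-4)

    def test_parity_afb_counts_from_main_study(self):
        stat, df, p = assoc.categorical_lrt_from_counts(
            [157, 349, 372, 214, 78], [129, 354, 351, 351, 98]
        )
        assert df == 4
        assert p == pytest.approx(7.4e-7, rel=0.05)


class TestGlobalSpatialTest:
    def test_no_fpc_columns_rejected(self):
        cohort = null_cohort(50, 50, 0, n_fpcs=0)
        with pytest.raises(InvalidComparisonError):
            assoc.global_spatial_test(cohort, fpc_cols=())

    def test_type_one_error_calibrated(self):
        # null cohorts: rejection rate at 0.05 stays within binomial bounds
        rejections = 0
        n_rep = 60
        for s in range(n_rep):
            cohort = null_cohort(120, 120, 1000 + s, n_fpcs=4)
            _, _, p = assoc.global_spatial_test(cohort)
            rejections += p < 0.05
        # binomial(60, 0.05): central 99.7% range is 0..9
        assert rejections <= 9

    def test_power_against_a_real_fpc_effect(self):
        cohort = null_cohort(500, 500, 7, n_fpcs=6, fpc_beta=0.5)
        _, df, p = assoc.global_spatial_test(cohort)
        assert df == 6
        assert p < 0.01

    def test_pd_codings_all_run(self):
        cohort = null_cohort(100, 100, 3, n_fpcs=2)
        for scale in ("sqrt", "raw", "categorical"):
            _, _, p = assoc.global_spatial_test(cohort, pd_scale=scale)
            assert 0 <= p <= 1


class TestScore:
    def test_single_fpc_weighting(self):
        cohort = null_cohort(40, 40, 2, n_fpcs=1)
        cohort["fpc12_1"] = 1.0
        fit = assoc.LogisticFit(
            params=pd.Series({"const": 0.0, "fpc12_1": -0.395}),
            bse=pd.Series({"const": 1.0, "fpc12_1": 0.1}),
            pvalues=pd.Series({"const": 1.0, "fpc12_1": 0.01}),
            llf=0.0,
            n=80,
            design_cols=("const", "fpc12_1"),
        )
        score = assoc.build_score(fit, cohort, ["fpc12_1"])
        assert np.allclose(score, -0.395)

    def test_missing_term_raises(self):
        cohort = null_cohort(20, 20, 4, n_fpcs=2)
        fit = assoc.LogisticFit(
            params=pd.Series({"const": 0.0}),
            bse=pd.Series({"const": 1.0}),
            pvalues=pd.Series({"const": 1.0}),
            llf=0.0,
            n=40,
            design_cols=("const",),
        )
        with pytest.raises(KeyError):
            assoc.build_score(fit, cohort, ["fpc12_1"])

    def test_score_variance_is_quadratic_form(self):
        rng = np.random.default_rng(5)
        n = 4000
        cov = np.array([[1.0, 0.3], [0.3, 2.0]])
        vals = rng.multivariate_normal([0, 0], cov, size=n)
        df = pd.DataFrame(vals, columns=["fpc12_1", "fpc12_2"])
        beta = np.array([0.5, -0.2])
        fit = assoc.LogisticFit(
            params=pd.Series({"fpc12_1": beta[0], "fpc12_2": beta[1]}),
            bse=pd.Series(dtype=float),
            pvalues=pd.Series(dtype=float),
            llf=0.0,
            n=n,
            design_cols=("fpc12_1", "fpc12_2"),
        )
        score = assoc.build_score(fit, df, ["fpc12_1", "fpc12_2"])
        sample_cov = np.cov(vals, rowvar=False)
        assert np.var(score, ddof=1) == pytest.approx(beta @ sample_cov @ beta, rel=1e-6)

    def test_per_sd_odds_ratio_closed_forms(self):
        fit = assoc.LogisticFit(
            params=pd.Series({"score": 0.0, "other": 0.2}),
            bse=pd.Series(dtype=float),
            pvalues=pd.Series(dtype=float),
            llf=0.0,
            n=10,
            design_cols=("score", "other"),
        )
        assert assoc.per_sd_odds_ratio(fit, "score", 1.0) == 1.0
        assert assoc.per_sd_odds_ratio(fit, "other", 2.0) == pytest.approx(np.exp(0.4))
        # the per-SD effect size scale: effect 0.33 corresponds to OR 1.39
        assert np.exp(0.33) == pytest.approx(1.39, abs=0.005)


class TestAUCAndDeLong:
    def test_perfect_separation_gives_auc_one(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.zeros(10), np.ones(10)]
        assert assoc.auc(scores, labels) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 2000
        labels = rng.integers(0, 2, n)
        scores = rng.normal(size=n)
        n1, n0 = labels.sum(), n - labels.sum()
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(assoc.auc(scores, labels) - 0.5) < 3 * se

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            assoc.auc([0.1, 0.2], [1, 1])

    def test_delong_variance_close_to_bootstrap(self):
        rng = np.random.default_rng(1)
        n = 400
        labels = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        scores = rng.normal(size=n) + 0.8 * labels
        v_delong = assoc.delong_variance(scores, labels)
        boot = []
        for _ in range(800):
            idx1 = rng.integers(0, n // 2, n // 2)
            idx0 = rng.integers(n // 2, n, n // 2)
            idx = np.r_[idx1, idx0]
            boot.append(assoc.auc(scores[idx], labels[idx]))
        v_boot = np.var(boot, ddof=1)
        assert abs(v_delong - v_boot) / v_boot < 0.15

    def test_delong_identical_models(self):
        rng = np.random.default_rng(2)
        labels = np.r_[np.ones(50), np.zeros(50)]
        scores = rng.normal(size=100) + labels
        z, p = assoc.delong_test(scores, scores, labels)
        assert z == 0.0 and p == 1.0

    def test_delong_detects_better_model(self):
        rng = np.random.default_rng(3)
        n = 1000
        labels = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        good = rng.normal(size=n) + 1.5 * labels
        bad = rng.normal(size=n)
        z, p = assoc.delong_test(good, bad, labels)
        assert z > 0 and p < 1e-6


class TestOptimismBootstrap:
    def test_identity_resample_gives_zero_optimism(self):
        cohort = null_cohort(80, 80, 6, n_fpcs=3)
        rep = assoc.optimism_bootstrap(
            cohort, B=1, seed=0, resample=lambda rng, n: np.arange(n)
        )
        assert all(abs(v) < 1e-12 for v in rep.optimism.values())
        assert rep.honest == pytest.approx(rep.apparent)

    def test_honest_effect_not_above_apparent_under_null(self):
        for seed in (0, 1, 2):
            cohort = null_cohort(300, 300, 20 + seed, n_fpcs=5)
            rep = assoc.optimism_bootstrap(cohort, B=40, seed=seed)
            assert rep.honest["per_sd_effect"] <= rep.apparent["per_sd_effect"] + 1e-12
            assert rep.honest["auc_full"] <= rep.apparent["auc_full"] + 1e-12


class TestStepwise:
    def test_true_signal_selected_among_noise(self):
        hits = 0
        for seed in range(10):
            cohort = null_cohort(400, 400, 300 + seed, n_fpcs=8, fpc_beta=0.35)
            selected = assoc.stepwise_select(cohort, FPC13[:8])
            hits += FPC13[0] in selected
        assert hits >= 8

    def test_all_noise_selects_little(self):
        sizes = []
        for seed in range(10):
            cohort = null_cohort(200, 200, 400 + seed, n_fpcs=8)
            sizes.append(len(assoc.stepwise_select(cohort, FPC13[:8])))
        assert np.median(sizes) <= 2

    def test_empty_candidates(self):
        cohort = null_cohort(100, 100, 5, n_fpcs=0)
        assert assoc.stepwise_select(cohort, []) == []


class TestDeterminantRegression:
    def test_recovers_bmi_effect(self):
        cohort = null_cohort(400, 400, 8, n_fpcs=1)
        rng = np.random.default_rng(9)
        cohort["fpc12_1"] = 2.0 * cohort["bmi"] + rng.normal(0, 1.0, len(cohort))
        table, corr = assoc.fpc_determinant_regression(cohort, "fpc12_1")
        est, se = table.loc["bmi", "coef"], table.loc["bmi", "se"]
        assert abs(est - 2.0) < 3 * se
        assert corr["bmi"][0] > 0.9

    def test_null_response_uncorrelated(self):
        cohort = null_cohort(300, 300, 10, n_fpcs=1)
        table, corr = assoc.fpc_determinant_regression(cohort, "fpc12_1")
        for var in ("age", "bmi", "pd"):
            assert abs(corr[var][0]) < 3.0 / np.sqrt(len(cohort))

    def test_intercept_only_on_centred_response(self):
        cohort = null_cohort(100, 100, 11, n_fpcs=1)
        cohort["fpc12_1"] -= cohort["fpc12_1"].mean()
        table, _ = assoc.fpc_determinant_regression(
            cohort, "fpc12_1", include_adjustments=False
        )
        assert table.loc["const", "coef"] == pytest.approx(0.0, abs=1e-12)
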