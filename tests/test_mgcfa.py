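"""Multi-group CFA: oracle equivalence, df bookkeeping, invariance cascade."""

import dataclasses

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import approx_fprime

from neuroallometry import (compute_derived, default_config, fit_cfa,
                            generate_cohort, inject_group_difference,
                            invariance_cascade, latent_group_difference,
                            regional_metric_tests)
from neuroallometry.mgcfa import (CFASpec, IdentificationError, _discrepancy,
                                  _Layout, chisq_diff_test, fit_cfa_moments,
                                  fit_indices)
from neuroallometry.simulate import delta_alpha_for_standardized_gap

from conftest import PAIRED8, PAIRED8_PAIRS, UNPAIRED5


def _one_factor_population(rng, p=3):
    lam = rng.uniform(0.4, 0.9, p)
    th = rng.uniform(0.2, 0.8, p)
    mu = rng.normal(0, 0.5, p)
    return mu, np.outer(lam, lam) + np.diag(th), lam


class TestTriadOracle:
    def test_100_random_instances_match_closed_form(self):
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(100):
            mu, S, lam = _one_factor_population(rng)
            spec = CFASpec(indicators=("x1", "x2", "x3"), groups=("g",))
            fit = fit_cfa_moments(spec, [mu], [S], [500])
            lam1 = abs(fit.parameters.loadings["g"][0])
            closed = np.sqrt(S[0, 1] * S[0, 2] / S[1, 2])
            worst = max(worst, abs(lam1 - closed))
            assert fit.chisq < 1e-6   # just-identified: zero discrepancy
        assert worst < 1e-5

    def test_saturated_implied_moments_match_sample(self):
        rng = np.random.default_rng(7)
        mu, S, _ = _one_factor_population(rng)
        spec = CFASpec(indicators=("x1", "x2", "x3"), groups=("g",))
        fit = fit_cfa_moments(spec, [mu], [S], [300])
        par = fit.parameters
        lam = par.loadings["g"]
        implied = np.outer(lam, lam) + np.diag(par.residual_var["g"])
        np.testing.assert_allclose(implied, S, atol=1e-8)
        np.testing.assert_allclose(par.intercepts["g"], mu, atol=1e-8)
        cfi, tli, rmsea = fit.fit_indices
        assert cfi == 1.0 and rmsea == 0.0


def test_analytic_gradient_matches_numeric():
    rng = np.random.default_rng(0)
    spec = CFASpec(indicators=("a", "b", "c", "d"),
                   residual_pairs=(("a", "b"),), intercepts_equal=True,
                   latent_mean_free=True, latent_var_free=True)
    lay = _Layout(spec)
    means = [rng.normal(0, 1, 4) for _ in range(2)]
    covs = []
    for _ in range(2):
        A = rng.normal(0, 1, (60, 4))
        covs.append(A.T @ A / 60 + 0.5 * np.eye(4))
    w = [0.45, 0.55]
    lds = [np.linalg.slogdet(S)[1] for S in covs]
    x0 = rng.normal(0, 0.3, lay.n_free)
    f = lambda x: _discrepancy(x, lay, means, covs, w, lds)[0]
    g = _discrepancy(x0, lay, means, covs, w, lds)[1]
    num = approx_fprime(x0, f, 1e-7)
    assert np.max(np.abs(num - g)) < 1e-5


class TestDegreesOfFreedom:
    @pytest.mark.parametrize("p, n_pairs", [(5, 0), (8, 3), (22, 10)])
    def test_delta_df_equals_newly_constrained_count(self, p, n_pairs):
        inds = tuple(f"x{i}" for i in range(p))
        pairs = tuple((f"x{2*i}", f"x{2*i+1}") for i in range(n_pairs))
        conf = _Layout(CFASpec(indicators=inds, residual_pairs=pairs))
        metric = _Layout(CFASpec(indicators=inds, residual_pairs=pairs,
                                 loadings_equal=True))
        scalar = _Layout(CFASpec(indicators=inds, residual_pairs=pairs,
                                 loadings_equal=True, intercepts_equal=True))
        assert conf.n_free - metric.n_free == p
        assert metric.n_free - scalar.n_free == p
        # regional metric test frees exactly one parameter
        freed = _Layout(CFASpec(indicators=inds, residual_pairs=pairs,
                                loadings_equal=True,
                                free_loadings=frozenset({inds[0]})))
        assert freed.n_free - metric.n_free == 1

    def test_configural_df_value(self):
        # two groups, p indicators, K pairs: df = p(p+3) - 2(3p + K)
        spec = CFASpec(indicators=tuple(f"x{i}" for i in range(6)),
                       residual_pairs=(("x0", "x1"),))
        lay = _Layout(spec)
        assert 6 * 9 - lay.n_free == 6 * 9 - 2 * (3 * 6 + 1)


class TestFitIndices:
    def test_arithmetic_example(self):
        # chisq 150 / df 100 vs baseline 1100 / 110, N=500, two groups
        spec = CFASpec(indicators=("a", "b", "c"))
        from neuroallometry.mgcfa import CFAFitResult
        fit = CFAFitResult(spec=spec, parameters=None, chisq=150.0, df=100,
                           fit_indices=(0, 0, 0), converged=True,
                           n_per_group={"control": 250, "asd": 250},
                           loglik=0.0, baseline_chisq=1100.0, baseline_df=110)
        cfi, tli, rmsea = fit_indices(fit)
        assert np.isclose(cfi, 1 - 50 / 990)
        assert np.isclose(rmsea, np.sqrt(2) * np.sqrt(50 / (100 * 500)))
        assert tli <= 1.0

    def test_chisq_equal_df_limit(self):
        from neuroallometry.mgcfa import CFAFitResult
        spec = CFASpec(indicators=("a", "b", "c"))
        fit = CFAFitResult(spec=spec, parameters=None, chisq=100.0, df=100,
                           fit_indices=(0, 0, 0), converged=True,
                           n_per_group={"control": 200, "asd": 200},
                           loglik=0.0, baseline_chisq=900.0, baseline_df=110)
        cfi, tli, rmsea = fit_indices(fit)
        assert cfi == 1.0 and rmsea == 0.0

    def test_true_one_factor_model_fits_well(self, clean_config):
        import copy
        cfg = copy.deepcopy(clean_config)
        cfg.seed = 31
        c, _ = generate_cohort(cfg)
        c = compute_derived(c)
        fit = fit_cfa(CFASpec(indicators=UNPAIRED5), c)
        cfi, tli, rmsea = fit.fit_indices
        assert cfi > 0.95 and tli > 0.95 and rmsea < 0.06


class TestChisqDiff:
    def test_identical_models(self, clean_config):
        import copy
        cfg = copy.deepcopy(clean_config)
        cfg.seed = 32
        cfg.n_per_group = (150, 150)
        c, _ = generate_cohort(cfg)
        c = compute_derived(c)
        fit = fit_cfa(CFASpec(indicators=UNPAIRED5), c)
        t = chisq_diff_test(fit, fit)
        assert t.delta_chisq == 0.0 and t.p_value == 1.0

    def test_non_nested_specs_error(self, clean_config):
        import copy
        cfg = copy.deepcopy(clean_config)
        cfg.seed = 33
        cfg.n_per_group = (150, 150)
        c, _ = generate_cohort(cfg)
        c = compute_derived(c)
        a = fit_cfa(CFASpec(indicators=UNPAIRED5, loadings_equal=True), c)
        b = fit_cfa(CFASpec(indicators=UNPAIRED5, intercepts_equal=True), c)
        with pytest.raises(ValueError, match="nested"):
            chisq_diff_test(a, b)

    def test_monotone_chisq_under_constraints(self, null_cohort):
        c, _ = null_cohort
        spec = CFASpec(indicators=PAIRED8, residual_pairs=PAIRED8_PAIRS)
        conf = fit_cfa(spec, c)
        metric = fit_cfa(dataclasses.replace(spec, loadings_equal=True), c)
        scalar = fit_cfa(dataclasses.replace(spec, loadings_equal=True,
                                             intercepts_equal=True), c)
        assert metric.chisq >= conf.chisq - 1e-4
        assert scalar.chisq >= metric.chisq - 1e-4


class TestCascade:
    def test_global_metric_df_is_indicator_count(self, null_cohort):
        c, _ = null_cohort
        spec = CFASpec(indicators=PAIRED8, residual_pairs=PAIRED8_PAIRS)
        casc = invariance_cascade(c, spec)
        g = casc.tests[0]
        assert g.level == "global_metric"
        assert g.delta_df == len(PAIRED8)

    def test_gating_no_regional_without_global(self, null_cohort):
        c, _ = null_cohort
        spec = CFASpec(indicators=UNPAIRED5)
        casc = invariance_cascade(c, spec)
        levels = [t.level for t in casc.tests]
        if not casc.tests[0].significant:
            assert "regional_metric" not in levels

    def test_injected_gap_localized(self):
        cfg = default_config(seed=77)
        cfg.sex_ratio = (1.0, 1.0)
        cfg.site_sd = 0.0
        cfg.n_per_group = (300, 300)
        da = delta_alpha_for_standardized_gap(cfg, "right_hippocampus", -0.4)
        cfg = inject_group_difference(cfg, "right_hippocampus", da,
                                      anchor_log10_tbv=cfg.tbv_log10_mean[
                                          "male"])
        c, _ = generate_cohort(cfg)
        c = compute_derived(c)
        spec = CFASpec(indicators=PAIRED8, residual_pairs=PAIRED8_PAIRS)
        tests = regional_metric_tests(c, spec)
        best = max(tests, key=lambda t: t.delta_chisq)
        assert best.target == "right_hippocampus"
        assert best.significant
        # reference-group loading exceeds the ASD loading by ~ the gap
        assert 0.2 < best.standardized_group_difference < 0.6

    def test_parameter_recovery_bias(self, clean_config):
        import copy
        cfg = copy.deepcopy(clean_config)
        cfg.seed = 34
        cfg.n_per_group = (1000, 1000)
        c, truth = generate_cohort(cfg)
        c = compute_derived(c)
        fit = fit_cfa(CFASpec(indicators=UNPAIRED5), c)
        sd_t = c.df["log10_tbv"].std(ddof=1)
        for gi, g in enumerate(("control", "asd")):
            for i, region in enumerate(UNPAIRED5):
                sd_v = c.df[f"log10_{region}"].std(ddof=1)
                expected = truth.alphas[g][region] * sd_t / sd_v
                got = abs(fit.parameters.loadings[g][i])
                assert abs(got - expected) < 0.05, (g, region)


class TestLatentMean:
    def test_identification_error_without_intercept_constraints(self):
        with pytest.raises(IdentificationError):
            CFASpec(indicators=UNPAIRED5, latent_mean_free=True)

    def test_null_shift_recovered_as_zero(self, clean_config):
        import copy
        cfg = copy.deepcopy(clean_config)
        cfg.seed = 35
        c, _ = generate_cohort(cfg)
        c = compute_derived(c)
        spec = CFASpec(indicators=UNPAIRED5, loadings_equal=True,
                       intercepts_equal=True, latent_mean_free=True)
        eff, se, p = latent_group_difference(fit_cfa(spec, c))
        assert abs(eff) < 2 * se

    def test_injected_shift_recovered(self, clean_config):
        import copy
        cfg = copy.deepcopy(clean_config)
        cfg.seed = 36
        cfg.tbv_group_shift = 0.23 * cfg.tbv_log10_sd   # 0.23 latent SD
        c, _ = generate_cohort(cfg)
        c = compute_derived(c)
        spec = CFASpec(indicators=PAIRED8, residual_pairs=PAIRED8_PAIRS,
                       loadings_equal=True, intercepts_equal=True,
                       latent_mean_free=True)
        eff, se, p = latent_group_difference(fit_cfa(spec, c))
        assert abs(eff - 0.23) < 0.08

    def test_se_shrinks_with_sample_size(self, clean_config):
        import copy
        ses = []
        for n in (300, 1200):
            cfg = copy.deepcopy(clean_config)
            cfg.seed = 37
            cfg.n_per_group = (n, n)
            c, _ = generate_cohort(cfg)
            c = compute_derived(c)
            spec = CFASpec(indicators=UNPAIRED5, loadings_equal=True,
                           intercepts_equal=True, latent_mean_free=True)
            _, se, _ = latent_group_difference(fit_cfa(spec, c))
            ses.append(se)
        # quadrupling N halves the SE
        assert 0.4 < ses[1] / ses[0] < 0.65


def test_null_delta_chisq_distribution_small():
    # under the null the metric test statistic follows chi2(p)
    ds = []
    for seed in range(120):
        cfg = default_config(seed=60000 + seed)
        cfg.sex_ratio = (1.0, 1.0)
        cfg.site_sd = 0.0
        cfg.n_per_group = (250, 250)
        c, _ = generate_cohort(cfg)
        c = compute_derived(c)
        spec = CFASpec(indicators=UNPAIRED5)
        conf = fit_cfa(spec, c)
        metric = fit_cfa(dataclasses.replace(spec, loadings_equal=True), c)
        ds.append(metric.chisq - conf.chisq)
    ks = stats.kstest(ds, stats.chi2(len(UNPAIRED5)).cdf)
    assert ks.pvalue > 0.01
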