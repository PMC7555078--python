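"""Mixed-effects group models, FDR, sensitivity variants, elimination."""

import copy

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroallometry import (backward_eliminate, cohens_d_from_fit,
                            compute_derived, default_config, fdr_adjust,
                            fit_lmem, flag_outliers, generate_cohort,
                            inject_group_difference, sensitivity_suite,
                            severity_model)
from neuroallometry.cohort import CohortTable
from neuroallometry.lmem import LMEMResult, LMEMSpec, build_model_frame
from neuroallometry.simulate import delta_alpha_for_standardized_gap

SLOPE_SPEC = LMEMSpec(response="right_hippocampus",
                      fixed_terms=("group", "log_tbv", "group:log_tbv"))


class TestFDR:
    def test_single_p_identity(self):
        assert fdr_adjust([0.04]) == [0.04]

    def test_hand_computed_example(self):
        # p(i) * m / i with step-up monotonicity: all become 0.04
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_empty(self):
        assert fdr_adjust([]) == []

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_dominates_and_rank_preserving(self, ps):
        out = np.asarray(fdr_adjust(ps))
        ps = np.asarray(ps)
        assert (out >= ps - 1e-12).all()
        assert (out <= 1.0).all()
        order = np.argsort(ps, kind="stable")
        assert (np.diff(out[order]) >= -1e-12).all()

    def test_empirical_fdr_controlled(self):
        # 5% true effects at p ~ 0 among uniforms: FDR <= 0.05 + 0.02
        rng = np.random.default_rng(5)
        rates = []
        for _ in range(50):
            p = rng.uniform(size=1000)
            truth = np.zeros(1000, dtype=bool)
            truth[:50] = True
            p[:50] = 1e-12
            q = np.asarray(fdr_adjust(p.tolist()))
            sig = q < 0.05
            if sig.any():
                rates.append((sig & ~truth).sum() / sig.sum())
        assert np.mean(rates) <= 0.07


class TestLMEMFit:
    def test_single_site_matches_plain_ols(self):
        cfg = default_config(seed=41)
        cfg.n_sites = 1
        cfg.site_sd = 0.0
        c, _ = generate_cohort(cfg)
        c = compute_derived(c)
        with pytest.warns(UserWarning, match="single site"):
            res = fit_lmem(SLOPE_SPEC, c)
        frame = build_model_frame(SLOPE_SPEC, c)
        X = np.column_stack([np.ones(len(frame)), frame["group"],
                             frame["log_tbv"],
                             frame["group"] * frame["log_tbv"]])
        beta, *_ = np.linalg.lstsq(X, frame["y"].to_numpy(), rcond=None)
        got = [res.term("group")["beta"], res.term("log_tbv")["beta"],
               res.term("group:log_tbv")["beta"]]
        np.testing.assert_allclose(got, beta[1:], atol=1e-6)

    def test_zero_site_variance_matches_ols(self):
        cfg = default_config(seed=42)
        cfg.site_sd = 0.0
        c, _ = generate_cohort(cfg)
        c = compute_derived(c)
        res = fit_lmem(SLOPE_SPEC, c)
        frame = build_model_frame(SLOPE_SPEC, c)
        X = np.column_stack([np.ones(len(frame)), frame["group"],
                             frame["log_tbv"],
                             frame["group"] * frame["log_tbv"]])
        beta, *_ = np.linalg.lstsq(X, frame["y"].to_numpy(), rcond=None)
        got = [res.term("group")["beta"], res.term("log_tbv")["beta"],
               res.term("group:log_tbv")["beta"]]
        np.testing.assert_allclose(got, beta[1:], atol=5e-3)
        if res.meta["method"] == "mixedlm":
            assert res.meta["site_var"] < 1e-3

    def test_null_group_effects_near_zero(self):
        ok = 0
        for seed in range(20):
            c, _ = generate_cohort(default_config(seed=80000 + seed))
            c = compute_derived(c)
            res = fit_lmem(SLOPE_SPEC, c)
            g = res.term("group")
            gi = res.term("group:log_tbv")
            ok += (abs(g["beta"]) < 2 * g["se"]
                   and abs(gi["beta"]) < 2 * gi["se"])
        assert ok >= 16

    def test_affine_unit_invariance(self):
        c, _ = generate_cohort(default_config(seed=43))
        res1 = fit_lmem(SLOPE_SPEC, compute_derived(c))
        c2 = c.copy()
        for r in c2.regions:
            c2.df[r] = c2.df[r] / 1000.0   # mm^3 -> cm^3
        res2 = fit_lmem(SLOPE_SPEC, compute_derived(
            CohortTable(c2.df, c2.regions)))
        np.testing.assert_allclose(res1.table["beta"], res2.table["beta"],
                                   atol=1e-8)

    def test_slope_gap_recovery(self):
        cfg = default_config(seed=44)
        cfg.sex_ratio = (1.0, 1.0)
        cfg.n_per_group = (137, 123)
        da = delta_alpha_for_standardized_gap(cfg, "right_hippocampus",
                                              -0.25)
        cfg = inject_group_difference(cfg, "right_hippocampus", da,
                                      anchor_log10_tbv=cfg.tbv_log10_mean[
                                          "male"])
        c, _ = generate_cohort(cfg)
        res = fit_lmem(SLOPE_SPEC, compute_derived(c))
        row = res.term("group:log_tbv")
        assert abs(row["beta"] - (-0.25)) <= 0.16   # within ~2 SE

    def test_hemisphere_requires_subject_intercept(self):
        with pytest.raises(ValueError, match="subject random intercept"):
            LMEMSpec(response="hippocampus",
                     fixed_terms=("group", "hemisphere"))
        spec = LMEMSpec(response="hippocampus",
                        fixed_terms=("group", "hemisphere",
                                     "group:hemisphere"),
                        random_intercepts=("site", "subject"))
        c, _ = generate_cohort(default_config(seed=45))
        res = fit_lmem(spec, compute_derived(c))
        assert res.meta["n"] == 2 * 654   # stacked hemispheres
        assert np.isfinite(res.term("group:hemisphere")["beta"])


class TestSensitivity:
    def test_no_removal_identity(self):
        cfg = default_config(seed=46)
        cfg.comorbidity_rate = (0.0, 0.0)
        c, _ = generate_cohort(cfg)
        c = compute_derived(c)   # no outlier flags computed -> none removed
        suite = sensitivity_suite(SLOPE_SPEC, c)
        a, b = suite["full"], suite["no_outliers_comorbid"]
        np.testing.assert_allclose(a.table["beta"], b.table["beta"],
                                   atol=1e-12)

    def test_outlier_attenuation(self):
        cfg = default_config(seed=47)
        cfg.sex_ratio = (1.0, 1.0)
        cfg.n_per_group = (80, 80)
        c, _ = generate_cohort(cfg)
        # a massive outlier in one ASD subject inflates the group effect
        df = c.df.copy()
        asd_ix = df.index[df["group"] == "asd"][0]
        df.loc[asd_ix, "right_hippocampus"] *= 10.0
        c = flag_outliers(compute_derived(CohortTable(df, c.regions)))
        suite = sensitivity_suite(
            LMEMSpec(response="right_hippocampus",
                     fixed_terms=("group", "log_tbv")), c)
        full = abs(suite["full"].term("group")["beta"])
        robust = abs(suite["no_outliers_comorbid"].term("group")["beta"])
        assert robust < full

    def test_medication_null_coefficient(self):
        ok = 0
        for seed in range(10):
            c, _ = generate_cohort(default_config(seed=90000 + seed))
            c = compute_derived(c)
            suite = sensitivity_suite(SLOPE_SPEC, c)
            med = suite["medication_covariate"].term("medication")
            ok += abs(med["beta"]) < 2 * med["se"]
        assert ok >= 8


class TestSeverity:
    def test_null_ados_effect(self):
        c, _ = generate_cohort(default_config(seed=48))
        c = compute_derived(c)
        res = severity_model(SLOPE_SPEC, c)
        row = res.term("ados")
        assert abs(row["beta"]) < 2.5 * row["se"]
        assert "group" not in res.table.index

    def test_insufficient_n_errors(self):
        cfg = default_config(seed=49)
        cfg.ados_missing_rate = 0.95
        c, _ = generate_cohort(cfg)
        with pytest.raises(ValueError, match="ADOS"):
            severity_model(SLOPE_SPEC, compute_derived(c))

    def test_group_term_error_on_asd_only(self):
        c, _ = generate_cohort(default_config(seed=50))
        c = compute_derived(c)
        asd = c.subset(c.df["group"] == "asd")
        with pytest.raises(ValueError, match="constant"):
            fit_lmem(SLOPE_SPEC, asd)


def _handmade_age_interaction_cohort(seed, n=400, effect=0.03):
    """Volumes with a genuine group-by-age slope difference."""
    rng = np.random.default_rng(seed)
    group = np.repeat(["control", "asd"], n // 2)
    gcode = (group == "asd").astype(float) - 0.5
    age = rng.uniform(6, 27, n)
    log_tbv = rng.normal(6.08, 0.04, n)
    log_v = (1.2 + 0.75 * log_tbv + effect * gcode * (age - age.mean()) / 5.0
             + rng.normal(0, 0.03, n))
    tbv = 10.0 ** log_tbv
    wm = 0.4 * tbv
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "site": np.repeat([f"site{j}" for j in range(4)], n // 4),
        "group": group,
        "sex": rng.permutation(np.repeat(["male", "female"], n // 2)),
        "age": age, "fsiq": rng.normal(105, 10, n),
        "medication": False, "comorbidity": False, "ados_total": np.nan,
        "right_hippocampus": 10.0 ** log_v,
        "cerebral_white_matter": wm, "total_gray_matter": tbv - wm,
    })
    return compute_derived(CohortTable(
        df, ["right_hippocampus", "cerebral_white_matter",
             "total_gray_matter"]))


class TestBackwardElimination:
    TERMS = ("group", "age", "sex", "group:age", "group:sex", "age:sex",
             "group:age:sex")

    def test_marginality_and_main_effects(self):
        c = _handmade_age_interaction_cohort(1)
        spec = LMEMSpec(response="right_hippocampus", fixed_terms=self.TERMS)
        final, fit = backward_eliminate(spec, c)
        kept = set(final.fixed_terms)
        assert {"group", "age", "sex"} <= kept
        # marginality: any retained 2-way under a retained 3-way
        if "group:age:sex" in kept:
            assert {"group:age", "group:sex", "age:sex"} <= kept

    def test_true_interaction_retained(self):
        hits = 0
        for seed in range(15):
            c = _handmade_age_interaction_cohort(seed, effect=0.04)
            spec = LMEMSpec(response="right_hippocampus",
                            fixed_terms=self.TERMS)
            final, _ = backward_eliminate(spec, c)
            hits += "group:age" in final.fixed_terms
        assert hits >= 12

    def test_all_significant_is_fixed_point(self):
        c = _handmade_age_interaction_cohort(3)
        spec = LMEMSpec(response="right_hippocampus",
                        fixed_terms=("group", "age", "group:age"))
        # with a strong true interaction nothing is removable
        final, fit = backward_eliminate(spec, c, threshold=0.999999)
        assert final.fixed_terms == spec.fixed_terms or \
            len(final.fixed_terms) >= 3


def test_cohens_d_conversion():
    table = pd.DataFrame({"beta": [0.1], "se": [0.04], "p": [0.01],
                          "p_fdr": [0.01], "d": [np.nan]},
                         index=["group"])
    res = LMEMResult(spec=SLOPE_SPEC, table=table, meta={"resid_df": 625})
    # t = 2.5, nu = 625 -> d = 2 * 2.5 / 25 = 0.2
    assert np.isclose(cohens_d_from_fit(res, "group"), 0.2)
    res.table.loc["group", "beta"] = -0.1
    assert cohens_d_from_fit(res, "group") < 0


def test_full_factorial_null_rate():
    # all group-involving terms of the five-way model stay near-null
    sig = total = 0
    for seed in range(5):
        c, _ = generate_cohort(default_config(seed=95000 + seed))
        c = compute_derived(c)
        base = ["group", "log_tbv", "age", "sex", "fsiq"]
        terms = []
        import itertools
        for k in range(1, 6):
            for combo in itertools.combinations(base, k):
                terms.append(":".join(combo))
        spec = LMEMSpec(response="left_putamen", fixed_terms=tuple(terms))
        res = fit_lmem(spec, c)
        for t in terms:
            if "group" in t.split(":"):
                total += 1
                sig += res.table.loc[res.table.index[
                    res.table.index == t], "p"].iloc[0] < 0.05
    assert sig / total < 0.15
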