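import numpy as np
import pandas as pd
import pytest

from tdcsdose import inference
from tdcsdose.inference import (bayes_factor_01, graded_dose, h2_model,
                                h3_mixed_model, pearson_with_df,
                                sensation_model, staged_h1)

GROUPS = np.repeat([0.0, 4.0, 6.0], 40)


def draw_cohort(rng, means, n=40, rho=0.62, noise=1.0):
    wpm = rng.standard_normal(3 * n)
    eps = rho * wpm + np.sqrt(1 - rho**2) * rng.standard_normal(3 * n)
    g = np.repeat([0.0, 4.0, 6.0], n)
    y = np.asarray(means)[np.repeat([0, 1, 2], n)] + noise * eps
    return y, wpm, g


class TestStagedH1:
    def test_strong_linear_gradient_labeled_monotonic(self, rng):
        y, wpm, g = draw_cohort(rng, (0.0, 1.5, 3.0), noise=0.1)
        res = staged_h1(y, wpm, g)
        assert res.label == "monotonic"
        assert res.stage2 is None and res.stage3 is None
        assert res.stage1.p < 0.05

    def test_null_cohorts_mostly_labeled_no_effect(self):
        """Under the null the staged tree keeps ~95% of cohorts at no_effect
        (stage-1 at alpha plus Bonferroni-corrected stage-2)."""
        labels = []
        for rep in range(300):
            rng = np.random.default_rng(5000 + rep)
            y, wpm, g = draw_cohort(rng, (0.0, 0.0, 0.0))
            labels.append(staged_h1(y, wpm, g).label)
        rate = np.mean([lb == "no_effect" for lb in labels])
        # expected ~ 0.95 * 0.975 ~ 0.926; allow 3 binomial SEs (~0.045)
        assert 0.88 <= rate <= 0.98

    def test_middle_arm_bump_labeled_reversing_in_majority(self):
        """Means (0, 1.2, 0) null the graded slope but light up the
        categorical stage and the 4-vs-6 Tukey contrast."""
        labels = []
        for rep in range(40):
            rng = np.random.default_rng(7000 + rep)
            y, wpm, g = draw_cohort(rng, (0.0, 1.2, 0.0))
            labels.append(staged_h1(y, wpm, g).label)
        assert np.mean([lb == "reversing" for lb in labels]) > 0.5

    def test_saturating_profile_can_be_labeled_saturating(self):
        labels = []
        for rep in range(40):
            rng = np.random.default_rng(9000 + rep)
            y, wpm, g = draw_cohort(rng, (0.0, 1.0, 1.0))
            labels.append(staged_h1(y, wpm, g).label)
        # a flat 4-vs-6 contrast should essentially never read as reversing
        assert np.mean([lb == "reversing" for lb in labels]) < 0.1
        assert set(labels) <= {"monotonic", "saturating", "no_effect"}

    def test_exactly_one_label_and_stage_population_consistent(self, rng):
        for means in [(0, 0, 0), (0, 1, 2), (0, 1.2, 0), (0, 1, 1)]:
            y, wpm, g = draw_cohort(rng, means, n=25)
            res = staged_h1(y, wpm, g)
            assert res.label in {"monotonic", "reversing", "saturating",
                                 "no_effect"}
            if res.label == "monotonic":
                assert res.stage2 is None
            else:
                assert res.stage2 is not None
            assert (res.stage3 is not None) == (res.label in
                                                {"reversing", "saturating"})

    def test_monotone_recoding_of_dose_levels_is_irrelevant(self, rng):
        y, wpm, g = draw_cohort(rng, (0.0, 0.4, 0.8))
        res_ma = staged_h1(y, wpm, g)
        res_rank = staged_h1(y, wpm, graded_dose(g))
        assert res_ma.label == res_rank.label
        assert res_ma.stage1.p == pytest.approx(res_rank.stage1.p)

    def test_small_group_rejected(self, rng):
        with pytest.raises(inference.ModelError):
            staged_h1([1, 2, 3, 4], [1, 2, 3, 4], [0, 0, 4, 6])


class TestH2Model:
    def test_identical_unit_ratios_are_a_clean_null(self):
        res = h2_model(np.ones(120), GROUPS)
        assert res.tests["dose_slope"].p == pytest.approx(1.0)
        assert res.tests["intercept_vs_1"].p == pytest.approx(1.0)

    def test_planted_intercept_offset_recovered_with_ci_coverage(self):
        """Cohorts with post/pre drift 1.19 and no dose effect: the fitted
        intercept's 95% CI covers 1.19 in most replicates."""
        cover, estimates = 0, []
        n_rep = 40
        for rep in range(n_rep):
            rng = np.random.default_rng(3000 + rep)
            ratios = 1.19 * np.exp(0.15 * rng.standard_normal(120))
            res = h2_model(ratios, GROUPS)
            se = res.se["intercept"]
            est = res.params["intercept"]
            estimates.append(est)
            cover += abs(est - 1.19) < 1.96 * se
        assert cover / n_rep >= 0.85
        assert np.mean(estimates) == pytest.approx(1.19, abs=0.03)

    def test_dose_proportional_ratios_give_significant_slope(self, rng):
        x = graded_dose(GROUPS)
        ratios = 1.0 + 0.2 * x + 0.1 * rng.standard_normal(120)
        res = h2_model(ratios, GROUPS)
        assert res.tests["dose_slope"].p < 1e-6
        assert res.params["dose_slope"] == pytest.approx(0.2, abs=0.05)

    def test_too_few_ratios_per_group_rejected(self):
        with pytest.raises(inference.ModelError):
            h2_model(np.ones(6), [0, 0, 0, 4, 4, 6])


class TestH3Model:
    def test_null_rejection_rate_near_alpha(self):
        rej = 0
        n_rep = 400
        for rep in range(n_rep):
            rng = np.random.default_rng(11000 + rep)
            res = h3_mixed_model(rng.standard_normal(120),
                                 rng.standard_normal(120))
            rej += res.tests["mep_slope"].p < 0.05
        assert rej / n_rep == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n_rep))

    def test_collinear_outcomes_give_p_near_zero(self):
        m = np.linspace(0.5, 2.0, 120)
        res = h3_mixed_model(3.0 + 2.0 * m, m)
        assert res.tests["mep_slope"].p < 1e-12

    def test_single_observation_per_subject_degrades_to_ols_with_note(self):
        rng = np.random.default_rng(0)
        res = h3_mixed_model(rng.standard_normal(50), rng.standard_normal(50),
                             subject=np.arange(50))
        assert any("OLS" in n for n in res.notes)
        assert res.params["re_var"] == 0.0

    def test_repeated_measures_fit_uses_random_intercept(self):
        rng = np.random.default_rng(1)
        subj = np.repeat(np.arange(30), 2)
        offs = np.repeat(rng.standard_normal(30), 2)
        m = rng.standard_normal(60)
        y = 0.5 * m + offs + 0.3 * rng.standard_normal(60)
        res = h3_mixed_model(y, m, subject=subj)
        assert "mixed" in res.notes
        assert res.params["mep_slope"] == pytest.approx(0.5, abs=0.2)
        assert res.params["re_var"] > 0.1


class TestBayesFactor:
    def test_identical_models_give_bf_of_one(self, rng):
        y = rng.standard_normal(40)
        assert bayes_factor_01(y, np.zeros(40)) == 1.0

    def test_strong_effect_large_n_drives_bf01_to_zero(self, rng):
        x = rng.standard_normal(500)
        y = x + 0.3 * rng.standard_normal(500)
        assert bayes_factor_01(y, x) < 1e-10

    def test_null_data_favor_the_null(self, rng):
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        assert bayes_factor_01(y, x) > 1.0

    def test_quadrature_matches_independent_jzs_implementation(self):
        """At unit prior scale the quadrature reproduces the classic JZS
        correlation Bayes factor from an independent implementation."""
        import pingouin as pg
        rng = np.random.default_rng(17)
        for beta in (0.0, 0.3, 0.8):
            x = rng.standard_normal(35)
            y = beta * x + rng.standard_normal(35)
            r = np.corrcoef(x, y)[0, 1]
            bf10_ref = float(pg.bayesfactor_pearson(r, 35, method="wetzels"))
            bf01 = bayes_factor_01(y, x, prior_scale=1.0)
            assert 1.0 / bf01 == pytest.approx(bf10_ref, rel=1e-4)

    def test_covariate_residualization_changes_the_evidence(self, rng):
        w = rng.standard_normal(150)
        x = w + 0.3 * rng.standard_normal(150)
        y = 2.0 * w + 0.5 * rng.standard_normal(150)
        # x predicts y only through w; conditioning on w should weaken it
        bf01_raw = bayes_factor_01(y, x)
        bf01_adj = bayes_factor_01(y, x, covariates=w)
        assert bf01_adj > bf01_raw


class TestSensationModel:
    def make_frame(self, rng, beta_sens=0.0, n=120):
        current = np.repeat([0.0, 4.0, 6.0], n // 3)
        sens = np.clip(np.round(0.5 * current +
                                rng.normal(2, 1.5, n)), 0, 10)
        y = beta_sens * sens + rng.standard_normal(n)
        return pd.DataFrame({"subject_id": [f"S{i}" for i in range(n)],
                             "mean_ncs": y, "sensation": sens,
                             "current_mA": current})

    def test_null_sensation_rejection_rate_near_alpha(self):
        rej_sens, rej_int = 0, 0
        n_rep = 250
        for rep in range(n_rep):
            rng = np.random.default_rng(21000 + rep)
            res = sensation_model(self.make_frame(rng))
            rej_sens += res.tests["sensation"].p < 0.05
            rej_int += res.tests["sens_x_cur"].p < 0.05
        band = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert rej_sens / n_rep == pytest.approx(0.05, abs=band)
        assert rej_int / n_rep == pytest.approx(0.05, abs=band)

    def test_negative_sensation_effect_estimated_negative(self):
        rng = np.random.default_rng(5)
        res = sensation_model(self.make_frame(rng, beta_sens=-0.1, n=600),
                              interaction=False)
        assert res.params["sensation"] == pytest.approx(-0.1, abs=0.05)
        assert res.tests["sensation"].p < 0.05

    def test_active_only_variant_drops_sham_arm(self, rng):
        df = self.make_frame(rng)
        res = sensation_model(df, active_only=True, interaction=False)
        assert res.params is not None  # fits on 4/6 mA arms only
        with pytest.raises(inference.ModelError):
            sensation_model(df.assign(sensation=df["sensation"] + 20))


class TestPearson:
    def test_perfect_line_gives_r_one(self):
        x = np.arange(10.0)
        r, df, p = pearson_with_df(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and df == 8

    def test_null_r_rarely_exceeds_point3_at_n120(self):
        big = 0
        for rep in range(200):
            rng = np.random.default_rng(31000 + rep)
            r, _, _ = pearson_with_df(rng.standard_normal(120),
                                      rng.standard_normal(120))
            big += abs(r) >= 0.3
        assert big / 200 <= 0.01

    def test_bivariate_normal_recovers_rho(self):
        rng = np.random.default_rng(6)
        z = rng.multivariate_normal([0, 0], [[1, 0.62], [0.62, 1]],
                                    size=10_000)
        r, df, p = pearson_with_df(z[:, 0], z[:, 1])
        assert r == pytest.approx(0.62, abs=0.02)
        assert df == 9998 and p < 1e-10

    def test_too_small_sample_rejected(self):
        with pytest.raises(inference.ModelError):
            pearson_with_df([1.0, 2.0], [3.0, 4.0])
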