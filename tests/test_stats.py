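"""Tests of effect sizes, ANOVA/Tukey, mixed models and Bayes factors."""

import numpy as np
import pytest
from scipy import stats as sps

from neurolz import (
    SyntheticConfig,
    anova_tukey,
    baseline_cortex_model,
    bayes_factor,
    cohens_d,
    fit_poly_mixed,
    gen_dose_dataset,
    select_shape,
    stim_dose_model,
)
from neurolz.stats import STATE_CODES
from neurolz.synthetic import DOSE_CENTER
from oracles import cohens_d_formula, polyfit_ols


def dose_table(shape="inverted_u", **kwargs):
    cfg = SyntheticConfig(**{"n_cats": 5, "seed": 1234, **kwargs})
    tab = gen_dose_dataset(shape, cfg)
    return tab.assign(x=tab["dose"].astype(float) - DOSE_CENTER)


class TestCohensD:
    def test_identical_samples_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert cohens_d(a, a) == 0.0

    def test_hand_computed_example(self):
        d = cohens_d([0, 0, 1, 1], [1, 1, 2, 2])
        assert d == pytest.approx(-np.sqrt(3), abs=1e-12)  # -1.732

    def test_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(1, 2, 40)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_matches_longhand_formula(self, rng):
        a, b = rng.normal(0, 1, 25), rng.normal(0.5, 1.5, 35)
        assert cohens_d(a, b) == pytest.approx(cohens_d_formula(a, b))

    def test_location_scale_invariance(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
        assert cohens_d(3 + 2 * a, 3 + 2 * b) == pytest.approx(cohens_d(a, b))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestAnovaTukey:
    def test_two_groups_matches_t_test(self, rng):
        groups = {"a": rng.normal(0, 1, 30), "b": rng.normal(0.4, 1, 25)}
        _, _, effects = anova_tukey(groups)
        t_p = sps.ttest_ind(groups["a"], groups["b"]).pvalue
        assert effects[0].p_adj == pytest.approx(t_p, abs=1e-6)

    def test_separated_groups_detected(self, rng):
        groups = {"lo": rng.normal(0, 1, 50), "hi": rng.normal(5, 1, 50)}
        F, p, effects = anova_tukey(groups)
        assert effects[0].p_adj < 1e-6
        assert abs(effects[0].d) > 3

    def test_all_pairs_reported(self, rng):
        groups = {k: rng.normal(i, 1, 10) for i, k in enumerate("abcd")}
        _, _, effects = anova_tukey(groups)
        assert len(effects) == 6
        for eff in effects:
            assert np.sign(eff.d) == np.sign(eff.mean_diff)

    def test_degenerate_constant_groups_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            anova_tukey({"a": np.ones(5), "b": np.ones(5)})

    def test_small_group_named_in_error(self):
        with pytest.raises(ValueError, match="'tiny'"):
            anova_tukey({"tiny": np.array([1.0]), "b": np.array([1.0, 2.0])})


class TestFitPolyMixed:
    def test_zero_variance_components_match_ols(self):
        tab = dose_table(sigma_cat=0.0, sigma_session=0.0, seed=7)
        mixed = fit_poly_mixed(tab, 2, "cat+session")
        ols = polyfit_ols(tab["x"].to_numpy(), tab["C"].to_numpy(), 2)
        np.testing.assert_allclose(mixed.coefficients, ols, rtol=1e-4)

    def test_degree_zero_balanced_gives_grand_mean(self):
        tab = dose_table("flat", seed=5)
        fit = fit_poly_mixed(tab, 0, "none")
        assert fit.coefficients[0] == pytest.approx(tab["C"].mean())

    def test_beta2_recovered_within_interval(self):
        tab = dose_table("inverted_u", seed=1234)
        fit = fit_poly_mixed(tab, 2, "cat+session")
        lo = fit.coefficients[2] - 1.96 * fit.coef_se[2]
        hi = fit.coefficients[2] + 1.96 * fit.coef_se[2]
        assert lo <= -0.0008 <= hi

    def test_bic_identity_holds(self):
        tab = dose_table(seed=3)
        fit = fit_poly_mixed(tab, 1, "cat")
        assert fit.BIC == pytest.approx(
            -2 * fit.loglik + fit.k_params * np.log(fit.n_obs)
        )

    def test_nested_fits_loglik_monotone(self):
        tab = dose_table("flat", seed=11)
        fits = [fit_poly_mixed(tab, d, "cat+session") for d in (1, 2, 3)]
        assert fits[0].loglik <= fits[1].loglik + 1e-6 <= fits[2].loglik + 2e-6
        # BIC may still prefer the smaller model on flat truth
        assert fits[0].BIC < fits[1].BIC

    def test_unknown_random_spec_rejected(self):
        with pytest.raises(ValueError):
            fit_poly_mixed(dose_table(), 1, "clinic")


class TestBayesFactor:
    def test_identical_bic_gives_unit_bf(self):
        tab = dose_table(seed=2)
        fit = fit_poly_mixed(tab, 1, "cat")
        comp = bayes_factor(fit, fit)
        assert comp.BF_ab == 1.0 and not comp.substantial

    def test_bf_five_at_twice_log_five(self):
        tab = dose_table(seed=2)
        a = fit_poly_mixed(tab, 1, "cat")
        from dataclasses import replace

        b = replace(a, BIC=a.BIC + 2 * np.log(5.0))
        assert bayes_factor(a, b).BF_ab == pytest.approx(5.0)

    def test_antisymmetry(self):
        tab = dose_table(seed=4)
        a = fit_poly_mixed(tab, 1, "cat+session")
        b = fit_poly_mixed(tab, 2, "cat+session")
        assert bayes_factor(a, b).BF_ab * bayes_factor(b, a).BF_ab == pytest.approx(
            1.0, abs=1e-12
        )

    def test_mismatched_n_obs_rejected(self):
        t1, t2 = dose_table(seed=2), dose_table(seed=2).iloc[:-10]
        a = fit_poly_mixed(t1, 1, "cat")
        b = fit_poly_mixed(t2, 1, "cat")
        with pytest.raises(ValueError, match="n_obs"):
            bayes_factor(a, b)

    def test_linear_truth_disfavours_quadratic(self):
        wins = 0
        for seed in range(8):
            tab = dose_table("linear", seed=seed, epochs_per_condition=20)
            comps, _, _ = select_shape(tab, degrees=(1, 2), random_spec="cat+session")
            if comps["quadratic_vs_linear"].BF_ab < 1:
                wins += 1
        assert wins >= 6  # BIC penalty dominates in the clear majority


class TestSelectShape:
    def test_inverted_u_detected(self):
        comps, label, fits = select_shape(dose_table("inverted_u"),
                                          random_spec="cat+session")
        assert label == "inverted-U"
        assert comps["quadratic_vs_linear"].BF_ab > 5
        assert fits[2].beta2 < 0

    def test_u_shape_detected(self):
        _, label, fits = select_shape(dose_table("u"), random_spec="cat+session")
        assert label == "U" and fits[2].beta2 > 0

    def test_linear_truth_labelled_linear(self):
        _, label, _ = select_shape(dose_table("linear"), random_spec="cat+session")
        assert label == "linear"

    def test_sleep_state_coding_order(self):
        assert [STATE_CODES[s] for s in ("W", "LS", "SWS", "REM")] == [0, 1, 2, 3]


class TestStimDoseModel:
    def test_null_stim_effect_not_substantial(self):
        cfg = SyntheticConfig(n_cats=3, seed=21, stim_effect=0.0,
                              epochs_per_condition=30)
        tab = gen_dose_dataset("inverted_u", cfg, include_stim=True)
        rep = stim_dose_model(tab)
        assert rep["interaction"]["BF"] < 1
        assert rep["interaction"]["eta_sq"] < 0.01
        assert not rep["stim"]["reliable"]

    def test_additive_stim_effect_found_without_interaction(self):
        cfg = SyntheticConfig(n_cats=3, seed=22, stim_effect=0.04,
                              epochs_per_condition=30)
        tab = gen_dose_dataset("inverted_u", cfg, include_stim=True)
        rep = stim_dose_model(tab)
        assert rep["stim"]["BF"] > 5 and rep["stim"]["reliable"]
        assert rep["interaction"]["BF"] < 1

    def test_single_dose_missing_cells_error(self):
        cfg = SyntheticConfig(n_cats=2, seed=1, epochs_per_condition=4)
        tab = gen_dose_dataset("flat", cfg, doses=(5,), include_stim=True)
        with pytest.raises(ValueError, match="doses"):
            stim_dose_model(tab)


class TestBaselineCortexModel:
    def test_distinct_cortex_offsets_preferred(self):
        cfg = SyntheticConfig(n_cats=3, seed=31, epochs_per_condition=20)
        tab = gen_dose_dataset("flat", cfg, cortex_offsets={"rPp": 0.0, "lPp": -0.06})
        comp = baseline_cortex_model(tab)
        assert comp.preferred == "cortex" and comp.BF_ab > 5

    def test_identical_cortices_favour_null(self):
        cfg = SyntheticConfig(n_cats=3, seed=32, epochs_per_condition=20)
        tab = gen_dose_dataset("flat", cfg, cortex_offsets={"rPp": 0.0, "lPp": 0.0})
        comp = baseline_cortex_model(tab)
        assert comp.BF_ab < 5

    def test_overwhelming_evidence_stays_finite(self):
        cfg = SyntheticConfig(n_cats=3, seed=33, sigma_cat=0.0, sigma_session=0.0,
                              sigma_eps=1e-6, epochs_per_condition=10)
        tab = gen_dose_dataset("flat", cfg, cortex_offsets={"a": 0.0, "b": 1.0})
        comp = baseline_cortex_model(tab)
        assert np.isfinite(comp.BF_ab) and comp.BF_ab > 5

    def test_single_cortex_rejected(self):
        cfg = SyntheticConfig(n_cats=2, seed=1, epochs_per_condition=4)
        tab = gen_dose_dataset("flat", cfg, cortex_offsets={"only": 0.0})
        with pytest.raises(ValueError, match="2 cortices"):
            baseline_cortex_model(tab)
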