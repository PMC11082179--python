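import math

import numpy as np
import pandas as pd
import pytest

from elegreet.models import (
    ModelSpec,
    bootstrap_ci,
    build_combination_frame,
    combination_spec,
    dummy_centre,
    fit_binomial_glmm,
    fit_multinomial,
    fit_multinomial_attention,
    lrt,
    marginal_r2,
    reduced_spec,
    stability,
    vif,
    z_transform,
)
from elegreet.simulate import (
    combination_fixture,
    generate_binary_panel,
    generate_modality_data,
    reference_fixture,
)


def binary_spec(**kw):
    base = dict(response="y", fixed=("x",), random=(("group", ("Intercept",)),))
    base.update(kw)
    return ModelSpec(**base)


class TestMultinomialOracle:
    def test_fixed_fit_reproduces_contingency_log_odds(self):
        """A saturated fixed-effects fit equals the closed-form log-odds of
        the aggregated 2x3 table."""
        fit = fit_multinomial_attention(reference_fixture(), random_effects=False)
        # attending=1 cell counts: sv 344, aud 209, tac 11; attending=0: 54, 44, 8
        assert fit.params["silent_visual~attending"] == pytest.approx(
            math.log((344 / 11) / (54 / 8)), abs=1e-6
        )
        assert fit.params["audible~attending"] == pytest.approx(
            math.log((209 / 11) / (44 / 8)), abs=1e-6
        )
        assert fit.params["audible~Intercept"] == pytest.approx(
            math.log(44 / 8), abs=1e-6
        )

    def test_attending_odds_ratio_magnitude(self):
        fit = fit_multinomial_attention(reference_fixture(), random_effects=False)
        assert math.exp(fit.params["silent_visual~attending"]) == pytest.approx(
            (344 / 11) / (54 / 8), rel=1e-6
        )

    def test_null_attention_data_covers_zero(self):
        d = generate_modality_data(
            4000, attention_effects=(0.0, 0.0), re_sd=0.3, n_signallers=8, seed=21
        )
        spec = ModelSpec(
            response="modality", fixed=("attending",),
            random=(("signaller_id", ("Intercept",)),),
            family="multinomial_logit", reference="tactile",
        )
        ci = fit_multinomial(d, spec).wald_ci()
        assert ci.loc["silent_visual~attending", "lower"] < 0
        assert ci.loc["silent_visual~attending", "upper"] > 0

    def test_few_level_factor_falls_back_to_fixed(self):
        d = generate_modality_data(500, n_signallers=2, seed=1)
        fit = fit_multinomial_attention(
            d.rename(columns={"attending": "attending"}).assign(
                category="body_act",
                recipient_attending=np.where(d["attending"] > 0, "yes", "no"),
            ),
            random_effects=True,
        )
        assert fit.method == "fixed"
        assert any("<3 levels" in n for n in fit.notes)


class TestBinomialGLMM:
    def test_zero_variance_reduces_to_glm(self):
        import statsmodels.api as sm

        d = generate_binary_panel(1500, beta=(-0.4, 0.9), re_sd=0.0, seed=5)
        mixed = fit_binomial_glmm(d, binary_spec(method="laplace"))
        X = np.column_stack([np.ones(len(d)), d["x"]])
        glm = sm.GLM(d["y"], X, family=sm.families.Binomial()).fit()
        assert mixed.params["x"] == pytest.approx(glm.params.iloc[1], abs=5e-3)
        assert mixed.params["Intercept"] == pytest.approx(glm.params.iloc[0], abs=5e-3)
        assert any("boundary" in n for n in mixed.notes)

    def test_laplace_and_agq_agree(self):
        d = generate_binary_panel(1200, beta=(-0.5, 1.0), re_sd=0.8,
                                  n_groups=10, seed=6)
        lap = fit_binomial_glmm(d, binary_spec(method="laplace"))
        agq = fit_binomial_glmm(d, binary_spec(method="agq"))
        assert lap.params["x"] == pytest.approx(agq.params["x"], abs=0.02)
        assert lap.loglik == pytest.approx(agq.loglik, abs=0.5)

    def test_recovers_negative_tail_effect(self):
        d = generate_binary_panel(3000, beta=(0.2, -1.0), re_sd=0.5,
                                  n_groups=12, seed=7)
        fit = fit_binomial_glmm(d, binary_spec())
        ci = fit.wald_ci()
        assert ci.loc["x", "lower"] < -1.0 < ci.loc["x", "upper"]

    def test_random_slope_covariance_estimated(self):
        d = generate_binary_panel(4000, beta=(0.0, 1.0), re_sd=0.8,
                                  n_groups=25, slope_sd=0.6, seed=8)
        fit = fit_binomial_glmm(
            d, binary_spec(random=(("group", ("Intercept", "x")),))
        )
        terms, Sigma = fit.random_cov["group"]
        assert terms == ("Intercept", "x")
        assert Sigma.shape == (2, 2)
        assert Sigma[0, 0] > 0.1  # intercept variance clearly non-zero

    def test_non_binary_response_rejected(self):
        d = pd.DataFrame({"y": [0, 1, 2], "x": [0.0, 1.0, 0.0], "group": list("aab")})
        with pytest.raises(ValueError, match="0/1"):
            fit_binomial_glmm(d, binary_spec())


class TestLRT:
    def test_identical_models_give_zero(self):
        d = generate_binary_panel(400, seed=9)
        fit = fit_binomial_glmm(d, binary_spec())
        chi2, df, p = lrt(fit, fit)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_df_counts_parameter_difference(self):
        d = generate_binary_panel(400, seed=10)
        full = fit_binomial_glmm(d, binary_spec())
        red = fit_binomial_glmm(d, reduced_spec(binary_spec(), ["x"]))
        chi2, df, p = lrt(full, red)
        assert df == 1
        assert chi2 >= 0

    def test_statistic_grows_with_n(self):
        chis = []
        for n in (300, 1200, 4800):
            d = generate_binary_panel(n, beta=(0.0, 0.8), re_sd=0.4, seed=11)
            full = fit_binomial_glmm(d, binary_spec())
            red = fit_binomial_glmm(d, reduced_spec(binary_spec(), ["x"]))
            chis.append(lrt(full, red)[0])
        assert chis[0] < chis[1] < chis[2]

    def test_non_nested_rejected(self):
        d = generate_binary_panel(300, seed=12)
        full = fit_binomial_glmm(d, binary_spec())
        red = fit_binomial_glmm(d.iloc[:200], reduced_spec(binary_spec(), ["x"]))
        with pytest.raises(ValueError):
            lrt(full, red)


class TestVIF:
    def test_orthogonal_predictors(self):
        rng = np.random.default_rng(0)
        d = pd.DataFrame({"a": [1, 1, -1, -1] * 10, "b": [1, -1, 1, -1] * 10})
        assert np.allclose(vif(d, ["a", "b"]), 1.0)

    def test_duplicated_predictor_flagged_infinite(self):
        d = pd.DataFrame({"a": np.arange(10.0)})
        d["b"] = d["a"]
        assert np.isinf(vif(d, ["a", "b"])).all()

    def test_correlated_pair_closed_form(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=4000)
        b = 0.8 * a + math.sqrt(1 - 0.64) * rng.normal(size=4000)
        d = pd.DataFrame({"a": a, "b": b})
        r2 = np.corrcoef(a, b)[0, 1] ** 2
        expected = 1.0 / (1.0 - r2)
        got = vif(d, ["a", "b"])
        assert got["a"] == pytest.approx(expected, rel=1e-9)
        assert got["a"] == pytest.approx(1 / (1 - 0.64), rel=0.05)

    def test_single_term_rejected(self):
        with pytest.raises(ValueError):
            vif(pd.DataFrame({"a": [1.0, 2.0]}), ["a"])


class TestBootstrapAndStability:
    def test_bootstrap_deterministic_under_seed(self):
        d = generate_binary_panel(400, beta=(0.0, 1.2), re_sd=0.4,
                                  n_groups=8, seed=13)
        fit = fit_binomial_glmm(d, binary_spec())
        ci1 = bootstrap_ci(fit, n_boot=30, seed=4)
        ci2 = bootstrap_ci(fit, n_boot=30, seed=4)
        pd.testing.assert_frame_equal(ci1, ci2)

    def test_bootstrap_excludes_zero_for_strong_effect(self):
        d = generate_binary_panel(2000, beta=(0.0, 1.5), re_sd=0.3,
                                  n_groups=10, seed=14)
        fit = fit_binomial_glmm(d, binary_spec())
        ci = bootstrap_ci(fit, n_boot=60, seed=5)
        assert ci.loc["x", "lower"] > 0

    def test_stability_tight_for_homogeneous_levels(self):
        d = generate_binary_panel(3000, beta=(0.0, 1.0), re_sd=0.1,
                                  n_groups=10, seed=15)
        fit = fit_binomial_glmm(d, binary_spec())
        tab = stability(fit)
        assert tab.loc["x", "min"] <= fit.params["x"] <= tab.loc["x", "max"]
        assert tab.loc["x", "max"] - tab.loc["x", "min"] < 0.5

    def test_planted_outlier_widens_range(self):
        d = generate_binary_panel(2000, beta=(0.0, 0.8), re_sd=0.2,
                                  n_groups=8, seed=16)
        # one aberrant group with the effect reversed
        bad = d[d["group"] == "G1"].copy()
        bad["y"] = 1.0 - bad["y"]
        d2 = pd.concat([d[d["group"] != "G1"], bad], ignore_index=True)
        clean = stability(fit_binomial_glmm(d, binary_spec()))
        dirty = stability(fit_binomial_glmm(d2, binary_spec()))
        width = lambda t: t.loc["x", "max"] - t.loc["x", "min"]
        assert width(dirty) > width(clean)

    def test_stability_requires_random_factor(self):
        d = generate_binary_panel(200, seed=17)
        fit = fit_binomial_glmm(d, binary_spec(random=()))
        with pytest.raises(ValueError):
            stability(fit)


class TestMarginalR2:
    def test_zero_fixed_effects_give_zero(self):
        d = generate_binary_panel(800, beta=(0.0, 0.0), re_sd=0.5, seed=18)
        fit = fit_binomial_glmm(d, binary_spec())
        assert marginal_r2(fit) == pytest.approx(0.0, abs=0.02)

    def test_closed_form_without_random_variance(self):
        d = generate_binary_panel(6000, beta=(0.0, 2.0), re_sd=0.0, seed=19)
        fit = fit_binomial_glmm(d, binary_spec(random=()))
        X = np.column_stack([np.ones(len(d)), d["x"]])
        v = float(np.var(X @ fit.params.to_numpy()))
        assert marginal_r2(fit) == pytest.approx(v / (v + math.pi**2 / 3), abs=1e-9)

    def test_monotone_in_effect_size(self):
        vals = []
        for b in (0.3, 0.8, 1.6):
            d = generate_binary_panel(3000, beta=(0.0, b), re_sd=0.3,
                                      n_groups=10, seed=20)
            vals.append(marginal_r2(fit_binomial_glmm(d, binary_spec())))
        assert vals[0] < vals[1] < vals[2]


class TestCombinationFrame:
    def test_frame_construction_and_fit(self, synthetic_dataset):
        from elegreet.collocation import extract_bigrams
        from elegreet.simulate import generate_scans
        from elegreet.sociality import nn_matrix

        records, truth, params = synthetic_dataset
        bigrams = extract_bigrams(records, "ordered_first_overlap")
        nn = nn_matrix(generate_scans(params))
        frame = build_combination_frame(bigrams, records, dict(params.individuals), nn)
        assert {"vocal_first", "is_rumble_earflap", "sex_male", "nn_z"} <= set(
            frame.columns
        )
        assert abs(frame["nn_z"].mean()) < 1e-9
        assert frame["nn_z"].std(ddof=1) == pytest.approx(1.0)
        assert abs(frame["sex_male"].mean()) < 1e-9
        spec = combination_spec("is_rumble_earflap")
        fit = fit_binomial_glmm(frame, spec)
        assert np.isfinite(fit.loglik)
        red = fit_binomial_glmm(frame, reduced_spec(spec, spec.fixed))
        chi2, df, p = lrt(fit, red)
        assert df == 4 and 0 <= p <= 1

    def test_dummy_centre_and_z_transform(self):
        d = pd.DataFrame({"sex": ["male", "male", "female", "female"]})
        c = dummy_centre(d, "sex", "male")
        assert list(c) == [0.5, 0.5, -0.5, -0.5]
        z = z_transform(pd.Series([1.0, 2.0, 3.0]))
        assert z.mean() == pytest.approx(0.0)
        assert z.std(ddof=1) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            z_transform(pd.Series([2.0, 2.0]))
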