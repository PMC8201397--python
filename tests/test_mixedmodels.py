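"""Mixed-model inference: nested random effects, LRTs, contrasts, surfaces."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from uavfield.mixedmodels import (
    cultivar_analysis,
    fit_lmm,
    lrt_fixed_effect,
    marginal_effects,
    trait_analysis,
    trait_terms,
)
from uavfield.synthetic import simulate_cell_observations


@pytest.fixture(scope="module")
def null_data():
    return simulate_cell_observations(np.random.default_rng(11))


@pytest.fixture(scope="module")
def zero_variance_data():
    """Row and plot random effects switched off: the LMM should match OLS."""
    return simulate_cell_observations(
        np.random.default_rng(5), row_sd=0.0, plot_sd=0.0,
        cultivar_effects={"v2": 40.0},
    )


class TestFitLmm:
    def test_zero_variance_matches_ols_oracle(self, zero_variance_data):
        import statsmodels.formula.api as smf

        fit = fit_lmm(zero_variance_data, ["C(sowing_date)", "C(cultivar)"], "ML")
        ols = smf.ols("y_hat ~ C(sowing_date) + C(cultivar)",
                      zero_variance_data).fit()
        np.testing.assert_allclose(fit.fe_params.to_numpy(),
                                   ols.params.to_numpy(), atol=1e-4)
        assert fit.var_row == pytest.approx(0.0, abs=2.0)
        assert fit.var_plot == pytest.approx(0.0, abs=2.0)

    def test_intercept_only_zero_variance_is_arithmetic_mean(self, zero_variance_data):
        fit = fit_lmm(zero_variance_data, [], "ML")
        assert fit.fe_params.iloc[0] == pytest.approx(
            zero_variance_data["y_hat"].mean(), abs=1e-3
        )

    def test_reml_and_ml_fixed_effects_agree_on_balanced_data(self):
        # exactly balanced: every cultivar appears twice in every row, so the
        # GLS fixed-effect estimate is invariant to the variance estimates
        data = simulate_cell_observations(np.random.default_rng(8), n_rows=8,
                                          plots_per_row=8, cells_per_plot=8)
        plot_pos = data["plot_id"].str.slice(1).astype(int) - 1
        data = data.assign(cultivar="v" + ((plot_pos % 4) + 1).astype(str))
        ml = fit_lmm(data, ["C(cultivar)"], "ML")
        reml = fit_lmm(data, ["C(cultivar)"], "REML")
        np.testing.assert_allclose(ml.fe_params.to_numpy(),
                                   reml.fe_params.to_numpy(), atol=1e-3)

    def test_collinear_fixed_effects_rejected(self, null_data):
        data = null_data.assign(dup=lambda d: d["y_hat"] * 0 + 1.0)
        with pytest.raises(np.linalg.LinAlgError):
            fit_lmm(data, ["dup"], "ML")

    def test_matches_direct_likelihood_oracle(self):
        """Profile-free oracle: maximize the exact multivariate-normal
        log-likelihood with scipy on a tiny balanced design."""
        rng = np.random.default_rng(21)
        data = simulate_cell_observations(rng, n_rows=4, plots_per_row=3,
                                          cells_per_plot=6)
        fit = fit_lmm(data, [], "ML")

        n = len(data)
        Zr = pd.get_dummies(data["row_id"]).to_numpy(float)
        Zp = pd.get_dummies(data["plot_id"]).to_numpy(float)

        def negll(theta):
            vr, vp, ve, mu = np.exp(theta[0]), np.exp(theta[1]), np.exp(theta[2]), theta[3]
            V = vr * Zr @ Zr.T + vp * Zp @ Zp.T + ve * np.eye(n)
            sign, logdet = np.linalg.slogdet(V)
            r = data["y_hat"].to_numpy() - mu
            return 0.5 * (logdet + r @ np.linalg.solve(V, r)
                          + n * np.log(2 * np.pi))

        x0 = np.array([np.log(600.0), np.log(200.0), np.log(900.0), 500.0])
        res = minimize(negll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
        assert -res.fun == pytest.approx(fit.loglik, abs=1e-3)
        assert fit.fe_params.iloc[0] == pytest.approx(res.x[3], abs=1e-2)


class TestLrt:
    def test_identical_models_give_zero_statistic(self, null_data):
        terms = ["C(cultivar)"]
        res = lrt_fixed_effect(null_data, terms, terms)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_non_nested_terms_rejected(self, null_data):
        with pytest.raises(ValueError):
            lrt_fixed_effect(null_data, ["C(cultivar)"], ["C(sowing_date)"])

    def test_categorical_term_df_is_levels_minus_one(self, null_data):
        res = lrt_fixed_effect(null_data, ["C(sowing_date)", "C(cultivar)"],
                               ["C(sowing_date)"])
        assert res.df == null_data["cultivar"].nunique() - 1

    def test_invariant_to_affine_rescaling_of_covariate(self):
        data = simulate_cell_observations(
            np.random.default_rng(4), trait_effect_spec={("stem_dw",): 0.3}
        )
        r1 = lrt_fixed_effect(data, ["stem_dw"], [])
        scaled = data.assign(stem_dw=data["stem_dw"] * 3.7 - 120.0)
        r2 = lrt_fixed_effect(scaled, ["stem_dw"], [])
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-6)


class TestCultivarAnalysis:
    def test_contrast_count_and_reference(self):
        data = simulate_cell_observations(
            np.random.default_rng(14), n_rows=7, plots_per_row=8,
            n_cultivars=14, cells_per_plot=6,
        )
        res = cultivar_analysis(data)
        assert len(res.contrasts) == 13  # k - 1 contrasts vs. reference
        assert res.reference == res.emm.idxmin()
        assert res.reference not in set(res.contrasts["cultivar"])

    def test_dominant_cultivar_flagged_highly_significant(self):
        data = simulate_cell_observations(
            np.random.default_rng(15), n_rows=8, plots_per_row=8,
            cultivar_effects={"v3": 90.0},  # 3 residual SDs
        )
        res = cultivar_analysis(data)
        row = res.contrasts.set_index("cultivar").loc["v3"]
        assert row["mark"] == "**"
        assert res.lrt_cultivar.p_value < 0.01

    def test_holm_adjustment_available(self):
        data = simulate_cell_observations(np.random.default_rng(16))
        res = cultivar_analysis(data, p_adjust="holm")
        assert "p_adjusted" in res.contrasts
        assert (res.contrasts["p_adjusted"] >= res.contrasts["p"] - 1e-12).all()


class TestTraitAnalysis:
    def test_design_has_eleven_fixed_coefficients(self):
        data = simulate_cell_observations(
            np.random.default_rng(17), trait_effect_spec={("stem_dw",): 0.0}
        )
        assert len(trait_terms()) == 10  # 4 mains + 6 pairwise interactions
        res = trait_analysis(data)
        assert res.fit.n_fixed == 11  # + intercept

    def test_planted_interaction_recovered(self):
        data = simulate_cell_observations(
            np.random.default_rng(18), n_rows=8, plots_per_row=8,
            trait_effect_spec={("stem_dw", "agb_dw"): 0.004},
        )
        res = trait_analysis(data)
        lrts = res.lrts.set_index("term")
        assert lrts.loc["stem_dw:agb_dw", "p"] < 0.05

    def test_constant_trait_rejected(self):
        data = simulate_cell_observations(
            np.random.default_rng(19), trait_effect_spec={("stem_dw",): 0.0}
        )
        data["seed100_w"] = 20.0
        with pytest.raises(np.linalg.LinAlgError):
            trait_analysis(data)


@pytest.fixture(scope="module")
def fitted():
    data = simulate_cell_observations(
        np.random.default_rng(20), n_rows=8, plots_per_row=8,
        trait_effect_spec={("stem_dw", "agb_dw"): 0.004},
    )
    return trait_analysis(data)


class TestMarginalEffects:
    def test_no_interaction_gives_parallel_lines(self):
        data = simulate_cell_observations(
            np.random.default_rng(22), trait_effect_spec={("stem_dw",): 0.2}
        )
        work = data.copy()
        fit = fit_lmm(work, ["stem_dw", "agb_dw"], "REML")
        surf = marginal_effects(fit, "stem_dw", "agb_dw",
                                [-10.0, 0.0, 10.0], [300.0, 400.0])
        wide = surf.pivot(index="stem_dw", columns="agb_dw", values="prediction")
        slopes = wide.diff().iloc[1:]
        assert np.allclose(slopes[300.0], slopes[400.0], atol=1e-10)

    def test_interaction_slope_changes_sign_at_closed_form_point(self, fitted):
        fit = fitted.fit
        b = fit.fe_params
        b_focal = b["stem_dw"]
        b_int = b["stem_dw:agb_dw"]
        flip = -b_focal / b_int  # moderator value where the focal slope flips
        surf = marginal_effects(fit, "stem_dw", "agb_dw", [-1.0, 1.0],
                                [flip - 50.0, flip + 50.0])
        wide = surf.pivot(index="agb_dw", columns="stem_dw", values="prediction")
        slope_lo = wide.loc[flip - 50.0, 1.0] - wide.loc[flip - 50.0, -1.0]
        slope_hi = wide.loc[flip + 50.0, 1.0] - wide.loc[flip + 50.0, -1.0]
        assert np.sign(slope_lo) != np.sign(slope_hi)
        np.testing.assert_allclose(slope_lo / 2.0, b_focal + b_int * (flip - 50.0),
                                   atol=1e-10)

    def test_prediction_at_means_is_population_mean(self):
        # main-effects-only model: the design is linear in the covariates,
        # so predicting at covariate means equals the mean fixed prediction
        data = simulate_cell_observations(
            np.random.default_rng(23), trait_effect_spec={("stem_dw",): 0.2}
        )
        fit = fit_lmm(data, ["stem_dw", "agb_dw"], "REML")
        mf, mm = data["stem_dw"].mean(), data["agb_dw"].mean()
        surf = marginal_effects(fit, "stem_dw", "agb_dw", [mf], [mm])
        X = fit.result.model.exog
        pop = float(X.mean(axis=0) @ fit.fe_params.to_numpy())
        assert surf["prediction"].iloc[0] == pytest.approx(pop, abs=1e-6)
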