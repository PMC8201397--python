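"""All-subsets Gaussian model search: fits, AIC, ranking, Akaike weights."""

import numpy as np
import pandas as pd
import pytest

from uavfield.selection import (
    DegenerateFitError,
    FitResult,
    SingularityError,
    aic,
    best_model,
    enumerate_models,
    fit_all_subsets,
    fit_gaussian_glm,
    load_best_model,
    rank_models,
    save_best_model,
)


def normal_equations_oracle(X, y):
    """Independent OLS oracle: explicit normal-equations solve."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
    resid = y - Xd @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    return beta, rss, 1.0 - rss / tss


def fit_with_aic(spec, aic_value, n=143):
    """Construct a FitResult whose AIC equals ``aic_value`` exactly."""
    k = len(spec) + 2
    loglik = (2 * k - aic_value) / 2.0
    rss = n * np.exp(-2.0 * loglik / n - np.log(2 * np.pi) - 1.0)
    return FitResult(spec=spec, params=np.zeros(len(spec) + 1), rss=rss,
                     tss=rss * 10, n=n, degenerate=False)


class TestFit:
    def test_exact_line_is_degenerate(self):
        design = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        fit = fit_gaussian_glm(design, [1.0, 3.0, 5.0, 7.0])
        assert fit.params == pytest.approx([1.0, 2.0])
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.degenerate
        with pytest.raises(DegenerateFitError):
            aic(fit)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 3))
        y = 2.0 + X @ np.array([1.0, -0.5, 0.25]) + rng.normal(0, 0.3, 20)
        fit = fit_gaussian_glm(pd.DataFrame(X, columns=list("abc")), y)
        beta, rss, r2 = normal_equations_oracle(X, y)
        np.testing.assert_allclose(fit.params, beta, atol=1e-8)
        assert fit.rss == pytest.approx(rss, abs=1e-8)
        assert fit.r_squared == pytest.approx(r2, abs=1e-8)

    def test_duplicated_predictor_is_singular(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        design = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(SingularityError):
            fit_gaussian_glm(design, rng.normal(size=12))


class TestAic:
    def test_parameter_count_includes_intercept_and_variance(self):
        rng = np.random.default_rng(1)
        design = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        fit = fit_gaussian_glm(design, rng.normal(size=30))
        assert fit.k == 6  # 4 slopes + intercept + residual variance

    def test_hand_computed_value(self):
        # n = 20, RSS = 20, one predictor: logLik = -10(ln 2pi + 1)
        fit = FitResult(spec=("x",), params=np.zeros(2), rss=20.0, tss=200.0,
                        n=20, degenerate=False)
        assert fit.loglik == pytest.approx(-10 * (np.log(2 * np.pi) + 1), abs=1e-6)
        assert aic(fit) == pytest.approx(62.7576, abs=1e-3)

    def test_same_spec_same_data_same_aic(self):
        rng = np.random.default_rng(2)
        design = pd.DataFrame({"x": rng.normal(size=15)})
        y = rng.normal(size=15)
        assert aic(fit_gaussian_glm(design, y)) == aic(fit_gaussian_glm(design, y))


class TestEnumeration:
    def test_counts(self):
        assert len(enumerate_models([f"x{i}" for i in range(7)])) == 128
        assert enumerate_models([]) == [()]

    def test_all_specs_unique_and_guarded(self):
        specs = enumerate_models(list("abcde"))
        assert len(set(specs)) == len(specs) == 32
        with pytest.raises(ValueError):
            enumerate_models([f"x{i}" for i in range(21)])
        assert len(enumerate_models(list("ab"), max_candidates=1, force=True)) == 4


class TestRanking:
    def test_equal_aic_gives_equal_weights(self):
        fits = [fit_with_aic(("a",), 100.0), fit_with_aic(("b",), 100.0)]
        table = rank_models(fits).table
        np.testing.assert_allclose(table["weight"], [0.5, 0.5])

    def test_printed_weight_identity(self):
        """Relative Akaike weights reproduce the published ranking table.

        With the best model's weight 0.082, models at dAIC 1.66 / 3.21 /
        4.74 must print 0.036 / 0.016 / 0.008 at three decimals.
        """
        deltas = {("m16",): 1.66, ("m17",): 3.21, ("m20",): 4.74}
        fits = [fit_with_aic(("m1",), 2375.4)]
        fits += [fit_with_aic(s, 2375.4 + d) for s, d in deltas.items()]
        table = rank_models(fits).table.set_index("spec")
        w_best = 0.082
        ratio = table["weight"] / table.loc["m1", "weight"]
        assert round(w_best * ratio["m16"], 3) == 0.036
        assert round(w_best * ratio["m17"], 3) == 0.016
        assert round(w_best * ratio["m20"], 3) == 0.008

    def test_weights_normalized_and_decreasing(self):
        rng = np.random.default_rng(3)
        fits = [fit_with_aic((f"x{i}",), 100 + 10 * rng.random()) for i in range(12)]
        table = rank_models(fits).table
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(table["weight"]) <= 1e-15).all()
        assert table["delta_aic"].iloc[0] == 0.0
        # exact relative-weight identity
        np.testing.assert_allclose(
            table["weight"] / table["weight"].iloc[0],
            np.exp(-table["delta_aic"] / 2.0),
        )

    def test_aic_tie_broken_by_smaller_k(self):
        fits = [fit_with_aic(("a", "b"), 50.0), fit_with_aic(("c",), 50.0)]
        table = rank_models(fits)
        assert best_model(table).spec == ("c",)


class TestBestModel:
    def test_single_fit_table(self):
        fit = fit_with_aic(("a",), 10.0)
        assert best_model(rank_models([fit])) is fit

    def test_noiseless_recovery_of_true_subset(self, noiseless_experiment):
        from uavfield.geometry import extract_point_covariates, join_samples
        from uavfield.synthetic import sample_points_from_table

        layout, stack, samples, truth = noiseless_experiment
        cov = extract_point_covariates(stack, sample_points_from_table(samples))
        joined, _ = join_samples(cov, samples.drop(columns=["x", "y", "plot_id"]))
        table = fit_all_subsets(joined, list(stack.names), "ear_dry_weight_g")
        assert set(best_model(table).spec) == set(truth.true_model_subset)


def test_oracle_equivalence_on_random_instances():
    """Coefficients/RSS/R^2 match the normal-equations oracle to 1e-8."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        n = rng.integers(10, 51)
        m = rng.integers(1, 6)
        X = rng.normal(size=(n, m))
        beta_true = rng.normal(size=m)
        y = rng.normal() + X @ beta_true + rng.normal(0, 0.5, n)
        design = pd.DataFrame(X, columns=[f"x{j}" for j in range(m)])
        fit = fit_gaussian_glm(design, y)
        beta, rss, r2 = normal_equations_oracle(X, y)
        np.testing.assert_allclose(fit.params, beta, atol=1e-8)
        assert fit.rss == pytest.approx(rss, abs=1e-8)
        assert fit.r_squared == pytest.approx(r2, abs=1e-8)


def test_best_model_roundtrip(tmp_path):
    rng = np.random.default_rng(5)
    design = pd.DataFrame(rng.normal(size=(25, 2)), columns=["u", "v"])
    y = 1.0 + design["u"] * 2 - design["v"] + rng.normal(0, 0.1, 25)
    fit = fit_gaussian_glm(design, y)
    path = tmp_path / "model.txt"
    save_best_model(fit, path)
    back = load_best_model(path)
    assert back.spec == fit.spec
    np.testing.assert_allclose(back.params, fit.params)
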