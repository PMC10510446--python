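import numpy as np
import pandas as pd
import pytest

import arviz as az

from plastsel.mcmc import PosteriorFit, SamplerConfig, nb_loglik
from plastsel.reaction_norms import extract_blups, fit_rrmm
from plastsel.simulate import SimulationTruth, StudyDesign, ZIParams, simulate_dataset
from plastsel.yearly import (
    censoring_sensitivity,
    coefficient_table,
    fit_zinb_selection,
    predict_any_seed_prob,
    residual_plasticity,
    temperature_quartiles,
    zinb_loglik,
    zinb_zero_prob,
)


def plasticity_table(intercepts, slopes):
    return pd.DataFrame({
        "individual_id": [f"i{k}" for k in range(len(intercepts))],
        "blup_intercept": intercepts,
        "blup_slope": slopes,
    })


class TestResidualPlasticity:
    def test_uncorrelated_slopes_are_just_centred(self, rng):
        ints = rng.standard_normal(200)
        slopes = rng.standard_normal(200)
        slopes -= np.polyval(np.polyfit(ints, slopes, 1), ints) - slopes.mean()
        out = residual_plasticity(plasticity_table(ints, slopes))
        assert np.allclose(out["residual_slope"], slopes - slopes.mean(), atol=1e-9)

    def test_perfect_fit_gives_zero_residuals(self):
        out = residual_plasticity(plasticity_table([0, 1, 2], [0, 1, 2]))
        assert np.allclose(out["residual_slope"], 0, atol=1e-12)

    def test_hand_computed_ols_residuals(self):
        # (0,0), (1,0), (2,3): OLS slope 1.5, intercept -0.5 -> residuals (0.5, -1, 0.5)
        out = residual_plasticity(plasticity_table([0, 1, 2], [0, 0, 3]))
        assert np.allclose(out["residual_slope"], [0.5, -1.0, 0.5], atol=1e-12)

    def test_residuals_exactly_orthogonal_to_intercepts(self, rng):
        ints = rng.standard_normal(500)
        slopes = 0.4 * ints + 0.3 * rng.standard_normal(500)
        out = residual_plasticity(plasticity_table(ints, slopes))
        assert abs(np.dot(out["residual_slope"], ints - ints.mean())) < 1e-8
        assert abs(out["residual_slope"].mean()) < 1e-10

    def test_zero_intercept_variance_warns_and_centres(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = residual_plasticity(plasticity_table([1, 1, 1, 1], [0, 1, 2, 3]))
        assert np.allclose(out["residual_slope"], [-1.5, -0.5, 0.5, 1.5])

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError):
            residual_plasticity(plasticity_table([0, 1], [0, 1]))


class TestZinbDensity:
    def test_reduces_to_plain_nb_without_zero_inflation(self, rng):
        y = rng.integers(0, 20, 300).astype(float)
        eta_c = rng.normal(1.0, 0.5, 300)
        ll_zinb = zinb_loglik(y, eta_c, np.full(300, -40.0), phi=1.7)
        ll_nb = nb_loglik(y, np.exp(eta_c), 1.7)
        assert np.allclose(ll_zinb, ll_nb, atol=1e-8)

    def test_zero_mass_closed_form(self):
        # P(0) = pi + (1 - pi) (phi/(phi+mu))^phi; mu=2, phi=1, pi=0.5 -> 2/3
        assert zinb_zero_prob(np.array([2.0]), 1.0, np.array([0.5]))[0] == \
            pytest.approx(2 / 3)
        ll0 = zinb_loglik(np.array([0.0]), np.array([np.log(2.0)]),
                          np.array([0.0]), 1.0)
        assert np.exp(ll0[0]) == pytest.approx(2 / 3)


def constant_zinb_fit(beta_zero, p_range=(-1.0, 1.0)) -> PosteriorFit:
    """A PosteriorFit whose zero-part coefficients are fixed at given values."""
    n_draws = 200
    post = {
        "beta_zero": np.tile(np.asarray(beta_zero, dtype=float), (1, n_draws, 1)),
        "beta_count": np.zeros((1, n_draws, 5)),
        "nb_dispersion": np.full((1, n_draws), 2.0),
    }
    idata = az.from_dict(posterior=post, dims={"beta_zero": ["zc"], "beta_count": ["cc"]},
                         coords={"zc": list("abcde"), "cc": list("abcde")})
    return PosteriorFit(idata=idata, model="zinb_const",
                        data={"plasticity_range": p_range,
                              "X_means": np.zeros(5), "n_obs": 0})


class TestPredictions:
    def test_all_zero_coefficients_give_half_everywhere(self):
        fit = constant_zinb_fit([0, 0, 0, 0, 0])
        pred = predict_any_seed_prob(fit, temps=np.array([-1.0, 0.0, 1.0]),
                                     plasticity_grid=np.array([-0.5, 0.0, 0.5]))
        assert np.allclose(pred["p_any_seeds"], 0.5)

    def test_plug_in_logistic_value(self):
        # zero part (1.010, -1.197, 0.083, 0.804, 0) at T = 0, plasticity = 0:
        # p(any) = 1 - logistic(1.010) ~ 0.267
        fit = constant_zinb_fit([1.010, -1.197, 0.083, 0.804, 0.0])
        pred = predict_any_seed_prob(fit, temps=np.array([0.0]),
                                     plasticity_grid=np.array([0.0]))
        assert pred["p_any_seeds"].iloc[0] == pytest.approx(0.267, abs=0.001)

    def test_positive_interaction_steepens_gradient_in_cold_springs(self):
        fit = constant_zinb_fit([1.0, -1.2, 0.08, 0.8, 0.0])
        grid = np.array([-0.5, 0.5])
        pred = predict_any_seed_prob(fit, temps=np.array([-2.0, 2.0]),
                                     plasticity_grid=grid)
        by_temp = {t: g.sort_values("plasticity")["p_any_seeds"].to_numpy()
                   for t, g in pred.groupby("april_temp")}
        slope_cold = by_temp[-2.0][1] - by_temp[-2.0][0]
        slope_warm = by_temp[2.0][1] - by_temp[2.0][0]
        assert slope_cold > slope_warm

    def test_prediction_identity(self):
        fit = constant_zinb_fit([0.7, -1.0, 0.1, 0.5, -0.04])
        pred = predict_any_seed_prob(fit, temps=np.array([0.3]),
                                     plasticity_grid=np.array([-0.2, 0.2]))
        assert np.allclose(pred["p_any_seeds"] + pred["zero_prob"], 1.0)

    def test_extrapolation_warns(self):
        fit = constant_zinb_fit([0, 0, 0, 0, 0], p_range=(-0.3, 0.3))
        with pytest.warns(UserWarning, match="extrapolation"):
            predict_any_seed_prob(fit, temps=np.array([0.0]),
                                  plasticity_grid=np.array([-2.0, 2.0]))


def test_temperature_quartiles_partition_years(small_dataset):
    q = temperature_quartiles(small_dataset.climate, 4)
    assert len(q) == 4
    assert q["temp_mean"].is_monotonic_increasing
    tv = small_dataset.climate["april_mean_centred"]
    assert q["temp_low"].iloc[0] == pytest.approx(tv.min())
    assert q["temp_high"].iloc[-1] == pytest.approx(tv.max())


@pytest.fixture(scope="module")
def zinb_fit(small_dataset, reduced_config):
    m2 = fit_rrmm(small_dataset.events, small_dataset.climate, "m2",
                  config=reduced_config)
    plast = residual_plasticity(extract_blups(m2))
    return fit_zinb_selection(small_dataset.events, small_dataset.climate, plast,
                              "residual", reduced_config)


class TestZinbFit:
    def test_zero_part_coefficients_near_truth(self, zinb_fit):
        tab = coefficient_table(zinb_fit).set_index("coefficient")
        # strongly identified zero-part terms (not mediated by shrunken BLUPs)
        for coef, true_val in (("zi_intercept", 1.010), ("zi_size", -0.042)):
            mean = tab.loc[coef, "posterior_mean"]
            sd = tab.loc[coef, "posterior_sd"]
            assert abs(mean - true_val) < 3 * sd, coef

    def test_interaction_sign_positive(self, zinb_fit):
        tab = coefficient_table(zinb_fit).set_index("coefficient")
        assert tab.loc["zi_plasticity_x_temp", "posterior_mean"] > 0

    def test_table_layout_covers_both_parts(self, zinb_fit):
        tab = coefficient_table(zinb_fit)
        names = set(tab["coefficient"])
        assert {"intercept", "zi_intercept", "plasticity", "zi_plasticity",
                "nb_dispersion", "sd_ind_count", "sd_ind_zero"} <= names

    def test_null_zero_inflation_covers_zero(self, reduced_config):
        truth = SimulationTruth(
            zi_params=ZIParams(zi_intercept=-20.0, zi_slope_effect=0,
                               zi_temp_effect=0, zi_size_effect=0,
                               zi_interaction=0, zi_sigma_ind=1e-9),
            design=StudyDesign(n_individuals=150, n_years=15),
        )
        ds = simulate_dataset(truth, seed=55)
        m2 = fit_rrmm(ds.events, ds.climate, "m2", config=reduced_config)
        plast = residual_plasticity(extract_blups(m2))
        fit = fit_zinb_selection(ds.events, ds.climate, plast, "residual",
                                 reduced_config)
        tab = coefficient_table(fit).set_index("coefficient")
        for coef in ("zi_plasticity", "zi_april_temp", "zi_plasticity_x_temp"):
            assert tab.loc[coef, "ci_low"] <= 0 <= tab.loc[coef, "ci_high"], coef


class TestCensoring:
    def test_thresholds_filter_individuals(self, small_dataset, reduced_config):
        counts = small_dataset.events.groupby("individual_id").size()
        cfg = SamplerConfig(chains=2, iterations=300, burn_in=150, thin=1, seed=1)
        res = censoring_sensitivity(small_dataset.events, small_dataset.individuals,
                                    small_dataset.climate, min_events=(1, 3), config=cfg)
        assert res[1]["n_individuals"] == counts.size
        assert res[3]["n_individuals"] == int((counts >= 3).sum())
        assert res[3]["n_individuals"] < res[1]["n_individuals"]

    def test_threshold_leaving_too_few_individuals_is_skipped(self, small_dataset,
                                                              reduced_config):
        res = censoring_sensitivity(small_dataset.events, small_dataset.individuals,
                                    small_dataset.climate, min_events=(30,),
                                    config=reduced_config)
        assert "note" in res[30] and "fit" not in res[30]
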