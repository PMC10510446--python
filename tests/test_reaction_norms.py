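from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from plastsel.mcmc import SamplerConfig, check_convergence
from plastsel.reaction_norms import (
    bayes_r2,
    compare_looic,
    extract_blups,
    fit_model_set,
    fit_rrmm,
)
from plastsel.simulate import SimulationTruth, StudyDesign, simulate_dataset

TRUTH = {"beta": -2.375, "sd_ind_intercept": 1.555, "sd_ind_slope": 0.783,
         "corr_int_slope": 0.800, "sd_year": 5.160}


class TestRecovery:
    def test_posterior_means_near_generating_values(self, m2_fit):
        for name, true_val in TRUTH.items():
            mean = m2_fit.posterior_mean(name)
            sd = m2_fit.posterior_sd(name)
            assert abs(mean - true_val) < 2.5 * sd, f"{name}: {mean} vs {true_val}"

    def test_convergence_diagnostics_pass(self, m2_fit):
        rep = check_convergence(m2_fit)
        assert rep.passed, str(rep)

    def test_null_slope_variance_concentrates_near_zero(self, reduced_config):
        # full-scale design: ~2600 events carry enough information to pull the
        # slope sd towards zero when individuals are truly identical
        truth = SimulationTruth(sigma_int=1e-6, sigma_slope=1e-6, rho_int_slope=0.0)
        ds = simulate_dataset(truth, seed=21)
        fit = fit_rrmm(ds.events, ds.climate, "m2", config=reduced_config)
        draws = fit.stacked("sd_ind_slope")
        assert draws.mean() < 0.2
        assert np.quantile(draws, 0.975) < 0.45


class TestCentringInvariance:
    def test_shifting_raw_temperatures_leaves_slope_unchanged(self, small_dataset,
                                                              reduced_config):
        climate2 = small_dataset.climate.copy()
        climate2["april_mean_centred"] = climate2["april_mean_centred"] + 7.0
        fit1 = fit_rrmm(small_dataset.events, small_dataset.climate, "m2",
                        config=reduced_config)
        fit2 = fit_rrmm(small_dataset.events, climate2, "m2", config=reduced_config)
        # predictor is re-centred internally, so the posterior is identical
        assert fit1.posterior_mean("beta") == pytest.approx(
            fit2.posterior_mean("beta"), abs=1e-12)


class TestModelComparison:
    def test_identical_fits_have_zero_delta(self, m2_fit):
        table = compare_looic({"x": m2_fit, "y": m2_fit})
        assert table["delta_looic"].abs().max() < 1e-9

    def test_mismatched_observations_rejected(self, m2_fit, reduced_config):
        ds2 = simulate_dataset(SimulationTruth(design=StudyDesign(40, 8)), seed=9)
        other = fit_rrmm(ds2.events, ds2.climate, "m0", config=reduced_config)
        with pytest.raises(ValueError, match="identical observation"):
            compare_looic({"a": m2_fit, "b": other})

    def test_strong_slope_variance_prefers_m2(self, reduced_config):
        truth = SimulationTruth(sigma_slope=1.5,
                                design=StudyDesign(n_individuals=200, n_years=15))
        ds = simulate_dataset(truth, seed=31)
        fits = fit_model_set(ds.events, ds.climate, config=reduced_config)
        table = compare_looic(fits)
        assert table.loc[0, "model"] == "m2"


class TestBlups:
    def test_shrinkage_contracts_extreme_individuals(self, m2_fit, small_dataset,
                                                     blups):
        # raw per-individual OLS intercept deviations vs posterior-mean BLUPs
        ev = small_dataset.events.merge(
            small_dataset.climate[["year", "april_mean_centred"]], on="year")
        raw_dev = (
            ev.groupby("individual_id")["ffd"].mean() - ev["ffd"].mean()
        ).reindex(blups["individual_id"]).to_numpy()
        assert np.std(blups["blup_intercept"]) < np.std(raw_dev)
        extreme = np.argsort(np.abs(raw_dev))[-10:]
        assert np.all(np.abs(blups["blup_intercept"].to_numpy()[extreme])
                      <= np.abs(raw_dev[extreme]))

    def test_blups_track_generating_deviations(self, blups, small_dataset):
        # with ~3.3 events per individual and residual sd ~4.7 days the
        # per-individual reliability caps this correlation near 0.6; the check
        # is that shrinkage estimates track the truth, not that they equal it
        lat = small_dataset.latents.set_index("individual_id")
        joined = blups.set_index("individual_id").join(lat)
        assert np.corrcoef(joined["blup_intercept"], joined["a"])[0, 1] > 0.5

    def test_deviations_are_shrinkage_centred(self, blups):
        dev = blups["blup_intercept"]
        assert abs(dev.mean()) < 0.1 * dev.std()

    def test_reported_values_add_population_mean(self, blups, m2_fit):
        diff = blups["reported_intercept"] - blups["blup_intercept"]
        assert np.allclose(diff, m2_fit.posterior_mean("intercept"))

    def test_m0_has_no_blups(self, small_dataset, reduced_config):
        fit = fit_rrmm(small_dataset.events, small_dataset.climate, "m0",
                       config=reduced_config)
        with pytest.raises(ValueError, match="individual effects"):
            extract_blups(fit)


class TestBayesR2:
    def test_near_noiseless_data_gives_r2_near_one(self, reduced_config):
        truth = SimulationTruth(sigma_resid=0.05,
                                design=StudyDesign(n_individuals=100, n_years=12))
        ds = simulate_dataset(truth, seed=13)
        fit = fit_rrmm(ds.events, ds.climate, "m2", config=reduced_config)
        assert bayes_r2(fit)["mean"] > 0.95

    def test_pure_noise_gives_r2_near_zero(self, reduced_config, rng):
        ds = simulate_dataset(SimulationTruth(design=StudyDesign(100, 12)), seed=14)
        ev = ds.events.copy()
        ev["ffd"] = 58.0 + 4.0 * rng.standard_normal(len(ev))  # no structure at all
        fit = fit_rrmm(ev, ds.climate, "m2", config=reduced_config)
        assert bayes_r2(fit)["mean"] < 0.1


def test_invalid_model_and_predictor_rejected(small_dataset, reduced_config):
    with pytest.raises(ValueError, match="model"):
        fit_rrmm(small_dataset.events, small_dataset.climate, "m7",
                 config=reduced_config)
    with pytest.raises(ValueError, match="predictor"):
        fit_rrmm(small_dataset.events, small_dataset.climate, "m0",
                 predictor="humidity", config=reduced_config)


def test_single_year_rejected(reduced_config):
    ds = simulate_dataset(SimulationTruth(design=StudyDesign(30, 2)), seed=15)
    climate1 = ds.climate.iloc[:1]
    events1 = ds.events[ds.events["year"] == climate1["year"].iloc[0]]
    with pytest.raises(ValueError, match="2 years"):
        fit_rrmm(events1, climate1, "m0", config=reduced_config)


def test_alternative_predictors_share_the_code_path(small_dataset, reduced_config):
    for predictor in ("april_variance", "frost_days"):
        fit = fit_rrmm(small_dataset.events, small_dataset.climate, "m1",
                       predictor=predictor, config=reduced_config)
        assert fit.data["predictor"] == predictor
        assert np.isfinite(fit.posterior_mean("beta"))
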