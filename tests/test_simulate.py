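from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from plastsel.ingest import events_from_visits
from plastsel.simulate import (
    ClimateParams,
    FitnessLatent,
    SimulationTruth,
    StudyDesign,
    ZIParams,
    simulate_climate,
    simulate_dataset,
    simulate_survey,
)


def test_same_seed_is_byte_identical():
    a = simulate_dataset(seed=11, include_visits=True)
    b = simulate_dataset(seed=11, include_visits=True)
    for name in ("climate", "events", "individuals", "latents", "visits"):
        pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))


def test_default_study_design_dimensions():
    ds = simulate_dataset(seed=0)
    assert len(ds.climate) == 22
    assert ds.individuals["individual_id"].nunique() == 800
    mean_events = ds.individuals["n_flowering_years"].mean()
    assert 2.8 < mean_events < 3.8  # geometric schedule, mean ~3.3


def test_climate_moments_and_frost_correlation():
    truth = SimulationTruth(climate=ClimateParams(temp_mean=5, temp_sd=2),
                            design=StudyDesign(n_individuals=2, n_years=5000))
    cl = simulate_climate(truth, np.random.default_rng(3))
    # MC tolerance: 3 standard errors of a sample sd at n = 5000
    se = 2 / np.sqrt(2 * (5000 - 1))
    assert abs(cl["april_mean"].std() - 2.0) < 3 * se
    assert np.corrcoef(cl["april_mean"], cl["frost_days"])[0, 1] < -0.5
    assert abs(cl["april_mean_centred"].mean()) < 1e-9


def test_zero_temperature_variance_gives_identical_years():
    truth = SimulationTruth(climate=ClimateParams(temp_sd=0.0),
                            design=StudyDesign(n_individuals=2, n_years=6))
    cl = simulate_climate(truth, np.random.default_rng(0))
    assert np.allclose(cl["april_mean_centred"], 0.0)
    assert cl["april_mean"].nunique() == 1


def test_latent_moments_match_truth_at_large_n():
    truth = SimulationTruth(design=StudyDesign(n_individuals=5000, n_years=22))
    ds = simulate_dataset(truth, seed=8)
    lat = ds.latents
    n = len(lat)
    for col, sd_true in (("a", 1.555), ("b", 0.783), ("w", 1.240)):
        se = sd_true / np.sqrt(2 * (n - 1))
        assert abs(lat[col].std() - sd_true) < 3 * se
    for cols, r_true in ((("a", "b"), 0.800), (("a", "w"), -0.448), (("b", "w"), 0.162)):
        r = np.corrcoef(lat[cols[0]], lat[cols[1]])[0, 1]
        se = (1 - r_true**2) / np.sqrt(n - 3)
        assert abs(r - r_true) < 3 * se
    # residualized plasticity is orthogonal to the intercept deviation
    assert abs(np.corrcoef(lat["p"], lat["a"])[0, 1]) < 0.05


def test_no_individual_variation_collapses_to_population_line():
    truth = SimulationTruth(
        sigma_int=1e-9, sigma_slope=1e-9, sigma_year=1e-9, sigma_resid=1e-9,
        rho_int_slope=0.0,
        fitness_latent=FitnessLatent(corr_wint_a=0.0, corr_wint_b=0.0),
        design=StudyDesign(n_individuals=50, n_years=10),
    )
    ds = simulate_dataset(truth, seed=1)
    ev = ds.events.merge(ds.climate[["year", "april_mean_centred"]], on="year")
    predicted = truth.mu_ffd + truth.beta_T * ev["april_mean_centred"]
    assert np.allclose(ev["ffd"], predicted, atol=1e-6)


def test_zinb_zero_fraction_matches_closed_form():
    # mu = 2, phi = 1, pi = 0.5: P(0) = 0.5 + 0.5 * (1/3) = 2/3
    truth = SimulationTruth(
        w_intercept=np.log(2.0), size_effect=0.0, nb_dispersion=1.0,
        fitness_latent=FitnessLatent(sigma_wint=1e-9, corr_wint_a=0, corr_wint_b=0),
        zi_params=ZIParams(zi_intercept=0.0, zi_slope_effect=0, zi_temp_effect=0,
                           zi_size_effect=0, zi_interaction=0, zi_sigma_ind=1e-9),
        design=StudyDesign(n_individuals=5000, n_years=22),
    )
    ds = simulate_dataset(truth, seed=4)
    frac = (ds.events["seeds_intact"] == 0).mean()
    n = len(ds.events)
    p_true = 2 / 3
    se = np.sqrt(p_true * (1 - p_true) / n)
    assert abs(frac - p_true) < 3 * se


def test_extreme_zero_inflation_gives_all_zeros():
    truth = SimulationTruth(
        zi_params=ZIParams(zi_intercept=20.0, zi_slope_effect=0, zi_temp_effect=0,
                           zi_size_effect=0, zi_interaction=0, zi_sigma_ind=1e-9),
        design=StudyDesign(n_individuals=200, n_years=10),
    )
    ds = simulate_dataset(truth, seed=2)
    assert (ds.events["seeds_intact"] == 0).all()


def test_nonpositive_definite_covariance_rejected():
    truth = SimulationTruth(rho_int_slope=0.99,
                            fitness_latent=FitnessLatent(corr_wint_a=-0.9,
                                                         corr_wint_b=0.9))
    with pytest.raises(ValueError, match="positive definite"):
        truth.validate()


def test_invalid_dispersion_rejected():
    with pytest.raises(ValueError, match="dispersion"):
        SimulationTruth(nb_dispersion=0.0).validate()


class TestSurvey:
    def test_noise_free_survey_recovers_ffd_exactly_on_grid(self):
        truth = SimulationTruth(design=StudyDesign(n_individuals=60, n_years=8))
        ds = simulate_dataset(truth, seed=5, include_visits=True)
        rec = events_from_visits(ds.visits)
        merged = rec.merge(ds.events, on=["individual_id", "year"],
                           suffixes=("_rec", "_true"))
        err = (merged["ffd_rec"] - merged["ffd_true"]).abs()
        assert len(merged) == len(ds.events)
        # exact up to rounding of the real-valued generating FFD
        assert err.max() <= 0.5 + 1e-9
        assert err.mean() <= 2.0

    def test_noisy_counts_stay_within_two_days(self):
        truth = SimulationTruth(design=StudyDesign(n_individuals=80, n_years=8))
        ds = simulate_dataset(truth, seed=6)
        vis = simulate_survey(ds.events, np.random.default_rng(1), count_noise=1.0)
        rec = events_from_visits(vis)
        merged = rec.merge(ds.events, on=["individual_id", "year"],
                           suffixes=("_rec", "_true"))
        assert (merged["ffd_rec"] - merged["ffd_true"]).abs().mean() <= 2.0

    def test_full_grazing_flags_every_event_expected(self):
        truth = SimulationTruth(design=StudyDesign(n_individuals=40, n_years=6))
        ds = simulate_dataset(truth, seed=7)
        vis = simulate_survey(ds.events, np.random.default_rng(2), grazing_rate=1.0)
        rec = events_from_visits(vis)
        assert len(rec) == len(ds.events)
        assert rec["ffd_is_expected"].all()


def test_fitness_measures_consistent_with_study_span():
    ds = simulate_dataset(SimulationTruth(design=StudyDesign(150, 15)), seed=3)
    iv = ds.individuals
    lhs = iv["mean_fitness_per_year"] * iv["n_study_years"]
    rhs = iv["mean_fitness_per_event"] * iv["n_flowering_years"]
    assert np.allclose(lhs, rhs, atol=1e-9)
    assert (iv["n_study_years"] >= iv["n_flowering_years"]).all()
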