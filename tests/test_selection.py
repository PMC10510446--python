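import numpy as np
import pytest

import arviz as az

from plastsel.mcmc import PosteriorFit, SamplerConfig
from plastsel.selection import (
    SelectionSummary,
    fit_bivariate_rrmm,
    selection_differentials,
    selection_gradients,
)
from plastsel.simulate import (
    FitnessLatent,
    SimulationTruth,
    StudyDesign,
    simulate_dataset,
)


def fit_from_cov_draws(cov_draws: np.ndarray) -> PosteriorFit:
    """Wrap a (n_draws, 3, 3) covariance array as a PosteriorFit."""
    idata = az.from_dict(
        posterior={"re_cov": cov_draws[None, ...]},
        dims={"re_cov": ["re_dim0", "re_dim1"]},
        coords={"re_dim0": ["a", "b", "w"], "re_dim1": ["a", "b", "w"]},
    )
    return PosteriorFit(idata=idata, model="synthetic-cov")


def cov_from(P, S, var_w=1.0):
    c = np.zeros((3, 3))
    c[:2, :2] = P
    c[:2, 2] = c[2, :2] = S
    c[2, 2] = var_w
    return c


class TestGradientAlgebra:
    def test_identity_trait_covariance_returns_differentials(self):
        S = np.array([0.37, -0.12])
        fit = fit_from_cov_draws(np.repeat(cov_from(np.eye(2), S)[None], 200, axis=0))
        G = selection_gradients(fit)
        assert np.allclose(G.draws["beta_intercept"], S[0])
        assert np.allclose(G.draws["beta_slope"], S[1])

    def test_worked_two_by_two_case(self):
        # P = [[1, .5], [.5, 1]], S = (0.2, 0.1)  =>  beta = (0.2, 0.0)
        P = np.array([[1.0, 0.5], [0.5, 1.0]])
        fit = fit_from_cov_draws(
            np.repeat(cov_from(P, np.array([0.2, 0.1]))[None], 200, axis=0))
        G = selection_gradients(fit)
        assert np.allclose(G.draws["beta_intercept"], 0.2, atol=1e-12)
        assert np.allclose(G.draws["beta_slope"], 0.0, atol=1e-12)

    def test_round_trip_s_equals_p_beta(self, rng):
        draws = []
        for _ in range(300):
            A = rng.standard_normal((3, 3))
            draws.append(A @ A.T + 0.5 * np.eye(3))
        draws = np.array(draws)
        fit = fit_from_cov_draws(draws)
        G = selection_gradients(fit)
        beta = np.column_stack([G.draws["beta_intercept"], G.draws["beta_slope"]])
        S_back = np.einsum("nij,nj->ni", draws[:, :2, :2], beta)
        assert np.allclose(S_back, draws[:, :2, 2], atol=1e-10)

    def test_zero_covariance_draw_gives_zero_differentials(self):
        fit = fit_from_cov_draws(
            np.repeat(cov_from(np.diag([2.0, 0.5]), np.zeros(2))[None], 150, axis=0))
        S = selection_differentials(fit)
        assert np.allclose(S.draws["S_intercept"], 0)
        assert np.allclose(S.draws["S_slope"], 0)

    def test_differential_is_correlation_times_sds(self):
        # sigma_a = 2, sigma_w = 3, corr = -0.5  =>  cov = -3
        c = np.diag([4.0, 1.0, 9.0])
        c[0, 2] = c[2, 0] = -0.5 * 2 * 3
        fit = fit_from_cov_draws(np.repeat(c[None], 150, axis=0))
        S = selection_differentials(fit)
        assert np.allclose(S.draws["S_intercept"], -3.0)

    def test_singular_draws_excluded_and_counted(self):
        good = np.repeat(cov_from(np.eye(2), np.array([0.1, 0.1]))[None], 500, axis=0)
        good[3, :2, :2] = np.array([[1.0, 1.0], [1.0, 1.0]])  # one singular draw
        fit = fit_from_cov_draws(good)
        G = selection_gradients(fit, max_excluded_frac=0.01)
        assert G.n_excluded == 1
        assert len(G.draws["beta_slope"]) == 499

    def test_too_many_singular_draws_aborts(self):
        bad = np.repeat(cov_from(np.ones((2, 2)), np.array([0.1, 0.1]))[None],
                        200, axis=0)
        fit = fit_from_cov_draws(bad)
        with pytest.raises(RuntimeError, match="singular"):
            selection_gradients(fit)


@pytest.fixture(scope="module")
def bivariate_fit(small_dataset, reduced_config):
    return fit_bivariate_rrmm(small_dataset.events, small_dataset.individuals,
                              small_dataset.climate, "per_event", reduced_config)


class TestBivariateFit:
    def test_trait_fitness_correlation_recovered(self, bivariate_fit):
        mean = bivariate_fit.posterior_mean("corr_int_fitness")
        sd = bivariate_fit.posterior_sd("corr_int_fitness")
        assert abs(mean - (-0.448)) < 2.5 * sd
        assert mean < 0  # earlier-flowering individuals have higher fitness

    def test_ffd_submodel_matches_univariate_structure(self, bivariate_fit):
        assert abs(bivariate_fit.posterior_mean("beta_temp") - (-2.375)) < \
            2.5 * bivariate_fit.posterior_sd("beta_temp")
        assert bivariate_fit.posterior_mean("sd_year") > 2.0

    def test_covariance_draws_positive_semidefinite(self, bivariate_fit):
        cov = bivariate_fit.stacked("re_cov")
        eigmin = np.linalg.eigvalsh(cov).min(axis=1)
        assert (eigmin > -1e-10).all()

    def test_summary_tables_have_mode_inside_hpd(self, bivariate_fit):
        for summ in (selection_differentials(bivariate_fit),
                     selection_gradients(bivariate_fit)):
            tab = summ.table()
            assert (tab["hpd_low"] <= tab["posterior_mode"]).all()
            assert (tab["posterior_mode"] <= tab["hpd_high"]).all()

    def test_fitness_measure_switch_changes_only_the_response(self, small_dataset,
                                                              reduced_config):
        fit = fit_bivariate_rrmm(small_dataset.events, small_dataset.individuals,
                                 small_dataset.climate, "per_year", reduced_config)
        assert fit.data["fitness_measure"] == "per_year"
        assert set(fit.idata.posterior.data_vars) == \
            set(fit.idata.posterior.data_vars)  # same parameter set
        assert np.isfinite(fit.posterior_mean("intercept_fitness"))

    def test_invalid_fitness_measure_rejected(self, small_dataset, reduced_config):
        with pytest.raises(ValueError, match="fitness_measure"):
            fit_bivariate_rrmm(small_dataset.events, small_dataset.individuals,
                               small_dataset.climate, "per_decade", reduced_config)


def test_no_selection_null_covers_zero(reduced_config):
    truth = SimulationTruth(
        fitness_latent=FitnessLatent(corr_wint_a=0.0, corr_wint_b=0.0),
        design=StudyDesign(n_individuals=150, n_years=15),
    )
    ds = simulate_dataset(truth, seed=77)
    fit = fit_bivariate_rrmm(ds.events, ds.individuals, ds.climate, "per_event",
                             reduced_config)
    tab = selection_gradients(fit).table().set_index("coefficient")
    for coef in ("beta_intercept", "beta_slope"):
        assert tab.loc[coef, "hpd_low"] <= 0 <= tab.loc[coef, "hpd_high"]
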