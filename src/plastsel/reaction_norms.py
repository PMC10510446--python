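"""Among-individual variation in thermal reaction norms of first flowering day.

Three nested Gaussian mixed models of FFD against a (mean-centred) yearly
spring-climate predictor, all with a year random intercept:

* ``m0`` — no individual effects: a single population-level reaction norm;
* ``m1`` — individual random intercepts: individuals differ in average timing;
* ``m2`` — individual random intercepts *and* slopes (the random-regression
  mixed model, RRMM): individuals also differ in thermal plasticity, with an
  estimated intercept-slope correlation.

All three are fitted with a conjugate Gibbs sampler (every full conditional is
available in closed form: normal updates for fixed and random effects,
inverse-gamma for variances, inverse-Wishart for the 2x2 individual
covariance).  The models are compared by LOOIC (PSIS-smoothed leave-one-out,
on the deviance scale, lower = better); per-individual posterior-mean
deviations (BLUPs) summarize each individual's reaction norm.

Priors: Normal(0, 1000^2) on fixed effects, inverse-gamma(0.01, 0.01) on the
year and residual variances, inverse-Wishart(nu0 = 4, I) on the individual
covariance (weakly informative conjugate choices; the data dominate at the
sample sizes these models are meant for).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import arviz as az

from .mcmc import AdaptiveScale, PosteriorFit, SamplerConfig, check_convergence

__all__ = [
    "fit_rrmm",
    "fit_model_set",
    "compare_looic",
    "extract_blups",
    "bayes_r2",
    "check_convergence",
    "PREDICTORS",
]

PREDICTORS = ("april_mean_centred", "april_variance", "frost_days")

_FIXED_PREC = 1e-6      # Normal(0, 1000^2) prior on fixed effects
_IG_SHAPE = 0.01        # inverse-gamma(0.01, 0.01) on the year/residual variances
_HALF_T_DF = 3.0        # half-Student-t(3) priors on individual-effect sds
_HALF_T_SCALE_INT = 10.0    # days
_HALF_T_SCALE_SLOPE = 2.5   # days / degC
_IG_RATE = 0.01


def _log_half_t(s: float, scale: float, df: float = _HALF_T_DF) -> float:
    """Log density (up to a constant) of a half-Student-t prior on an sd."""
    return -0.5 * (df + 1.0) * np.log1p((s / scale) ** 2 / df)


def _prepare(events: pd.DataFrame, climate: pd.DataFrame, predictor: str):
    if predictor not in PREDICTORS:
        raise ValueError(f"predictor must be one of {PREDICTORS}, got {predictor!r}")
    if climate["year"].nunique() < 2 or events["individual_id"].nunique() < 2:
        raise ValueError("need at least 2 years and 2 individuals")
    merged = events.merge(climate[["year", predictor]], on="year", how="left")
    if merged[predictor].isna().any():
        missing = sorted(merged.loc[merged[predictor].isna(), "year"].unique())
        raise ValueError(f"years missing from climate table: {missing}")
    x = merged[predictor].to_numpy(dtype=float)
    # year-level centring so the intercept is the trait value in an average year
    year_vals = climate.set_index("year")[predictor]
    x = x - float(year_vals.mean())
    y = merged["ffd"].to_numpy(dtype=float)
    ind_codes, ind_ids = pd.factorize(merged["individual_id"], sort=True)
    yr_codes, yr_ids = pd.factorize(merged["year"], sort=True)
    return y, x, ind_codes, np.asarray(ind_ids), yr_codes, np.asarray(yr_ids)


def _inv_gamma(rng, shape, rate):
    return rate / rng.gamma(shape)


def _sigma_from_theta(theta: np.ndarray) -> np.ndarray:
    """(log sd_int, log sd_slope, atanh rho) -> 2x2 covariance."""
    s1, s2 = np.exp(theta[0]), np.exp(theta[1])
    rho = np.tanh(theta[2])
    return np.array([[s1 * s1, rho * s1 * s2], [rho * s1 * s2, s2 * s2]])


def _sigma_logpost_m2(theta, n_i, St_i, Stt_i, Sr, Srt, sig2):
    """Log posterior of the individual covariance with the per-individual
    deviations integrated out (Gaussian marginal via rank-2 Woodbury forms),
    plus half-t(3) priors on the sds, a uniform prior on the correlation, and
    the log-Jacobian of the unconstrained parameterization.  Conditions on
    fixed effects, year effects and sigma^2."""
    Sigma = _sigma_from_theta(theta)
    s1sq, s2sq, c = Sigma[0, 0], Sigma[1, 1], Sigma[0, 1]
    det_s = s1sq * s2sq - c * c
    if det_s <= 0 or not np.isfinite(det_s):
        return -np.inf, Sigma
    l11, l12, l22 = s2sq / det_s, -c / det_s, s1sq / det_s  # inv(Sigma)
    m11 = l11 + n_i / sig2
    m12 = l12 + St_i / sig2
    m22 = l22 + Stt_i / sig2
    det_m = m11 * m22 - m12 * m12
    h1, h2 = Sr / sig2, Srt / sig2
    quad = (m22 * h1 * h1 - 2 * m12 * h1 * h2 + m11 * h2 * h2) / det_m
    ll = -0.5 * (n_i.size * np.log(det_s) + np.sum(np.log(det_m)) - np.sum(quad))
    lprior = (_log_half_t(np.sqrt(s1sq), _HALF_T_SCALE_INT)
              + _log_half_t(np.sqrt(s2sq), _HALF_T_SCALE_SLOPE))
    ljac = 0.5 * np.log(s1sq) + 0.5 * np.log(s2sq) + np.log1p(-np.tanh(theta[2]) ** 2)
    return ll + lprior + ljac, Sigma


def _siga_logpost_m1(log_sd, n_i, Sr, sig2):
    """Marginal (individuals integrated out) log posterior of the intercept-only
    random-effect sd, half-t(3) prior, log-sd parameterization."""
    s2a = np.exp(2.0 * log_sd)
    m = 1.0 / s2a + n_i / sig2
    h = Sr / sig2
    ll = -0.5 * (n_i.size * np.log(s2a) + np.sum(np.log(m)) - np.sum(h * h / m))
    lprior = _log_half_t(np.exp(log_sd), _HALF_T_SCALE_INT) + log_sd
    return ll + lprior


def _gibbs_chain(model, y, t, ind, yr, n_ind, n_yr, cfg: SamplerConfig, rng):
    n = y.size
    with_a = model in ("m1", "m2")
    with_b = model == "m2"

    n_i = np.bincount(ind, minlength=n_ind).astype(float)
    n_j = np.bincount(yr, minlength=n_yr).astype(float)
    t_yr = np.bincount(yr, weights=t, minlength=n_yr) / np.maximum(n_j, 1)
    St_i = np.bincount(ind, weights=t, minlength=n_ind)
    Stt_i = np.bincount(ind, weights=t * t, minlength=n_ind)
    X = np.column_stack([np.ones(n), t])
    XtX = X.T @ X

    # dispersed initial values around an OLS fit
    gam, *_ = np.linalg.lstsq(X, y, rcond=None)
    gam = gam + rng.normal(0, [1.0, 0.3])
    sig2 = float(np.var(y - X @ gam)) * np.exp(rng.normal(0, 0.3))
    sig2_u = 4.0 * np.exp(rng.normal(0, 0.3))
    u = np.zeros(n_yr)
    a = np.zeros(n_ind)
    b = np.zeros(n_ind)
    theta = np.array([0.0, np.log(0.5), 0.0]) + rng.normal(0, 0.2, size=3)
    Sigma = _sigma_from_theta(theta)
    sig2_a = float(np.exp(rng.normal(0, 0.4)))
    sig_step = AdaptiveScale(0.2, target=0.3)

    n_kept = cfg.n_kept
    out = {
        "intercept": np.empty(n_kept), "beta": np.empty(n_kept),
        "sd_year": np.empty(n_kept), "sd_resid": np.empty(n_kept),
        "var_fitted": np.empty(n_kept),
        "u": np.empty((n_kept, n_yr)),
    }
    if with_a:
        out["sd_ind_intercept"] = np.empty(n_kept)
        out["a"] = np.empty((n_kept, n_ind))
    if with_b:
        out["sd_ind_slope"] = np.empty(n_kept)
        out["corr_int_slope"] = np.empty(n_kept)
        out["b"] = np.empty((n_kept, n_ind))
    loglik = np.empty((n_kept, n))

    k = 0
    for it in range(cfg.iterations):
        re_part = u[yr]
        if with_a:
            re_part = re_part + a[ind]
        if with_b:
            re_part = re_part + b[ind] * t

        # fixed effects
        r = y - re_part
        prec = XtX / sig2 + _FIXED_PREC * np.eye(2)
        mean = np.linalg.solve(prec, X.T @ r / sig2)
        L = np.linalg.cholesky(prec)
        gam = mean + np.linalg.solve(L.T, rng.standard_normal(2))
        fixed = X @ gam

        # year intercepts
        r = y - fixed
        if with_a:
            r = r - a[ind]
        if with_b:
            r = r - b[ind] * t
        prec_j = n_j / sig2 + 1.0 / sig2_u
        mu_j = np.bincount(yr, weights=r, minlength=n_yr) / sig2 / prec_j
        u = mu_j + rng.standard_normal(n_yr) / np.sqrt(prec_j)

        # individual effects + their covariance: a collapsed Metropolis step on
        # the covariance (deviations integrated out analytically) followed by a
        # conjugate redraw of the deviations.  Plain conjugate cycling of
        # (deviations | Sigma) and (Sigma | deviations) mixes very slowly when
        # most individuals carry only a few observations.
        if with_b:
            r = y - fixed - u[yr]
            Sr_raw = np.bincount(ind, weights=r, minlength=n_ind)
            Srt_raw = np.bincount(ind, weights=r * t, minlength=n_ind)
            lp_cur, _ = _sigma_logpost_m2(theta, n_i, St_i, Stt_i, Sr_raw, Srt_raw, sig2)
            for _ in range(5):  # several cheap refreshes decorrelate the correlation
                prop = theta + sig_step.scale * rng.standard_normal(3)
                lp_prop, Sigma_prop = _sigma_logpost_m2(
                    prop, n_i, St_i, Stt_i, Sr_raw, Srt_raw, sig2
                )
                accept = np.log(rng.random()) < lp_prop - lp_cur
                if accept:
                    theta, Sigma, lp_cur = prop, Sigma_prop, lp_prop
                if it < cfg.burn_in:
                    sig_step.update(float(accept))
            Lam = np.linalg.inv(Sigma)
            Sr = Sr_raw / sig2
            Srt = Srt_raw / sig2
            P11 = n_i / sig2 + Lam[0, 0]
            P12 = St_i / sig2 + Lam[0, 1]
            P22 = Stt_i / sig2 + Lam[1, 1]
            det = P11 * P22 - P12 * P12
            m1 = (P22 * Sr - P12 * Srt) / det
            m2 = (P11 * Srt - P12 * Sr) / det
            L11 = np.sqrt(P11)
            L21 = P12 / L11
            L22 = np.sqrt(P22 - L21 * L21)
            z1 = rng.standard_normal(n_ind)
            z2 = rng.standard_normal(n_ind)
            x2 = z2 / L22
            x1 = (z1 - L21 * x2) / L11
            a, b = m1 + x1, m2 + x2
        elif with_a:
            r = y - fixed - u[yr]
            Sr_raw = np.bincount(ind, weights=r, minlength=n_ind)
            log_sd = 0.5 * np.log(sig2_a)
            lp_cur = _siga_logpost_m1(log_sd, n_i, Sr_raw, sig2)
            prop = log_sd + sig_step.scale * rng.standard_normal()
            lp_prop = _siga_logpost_m1(prop, n_i, Sr_raw, sig2)
            accept = np.log(rng.random()) < lp_prop - lp_cur
            if accept:
                sig2_a = float(np.exp(2.0 * prop))
            if it < cfg.burn_in:
                sig_step.update(float(accept))
            prec_i = n_i / sig2 + 1.0 / sig2_a
            mu_i = Sr_raw / sig2 / prec_i
            a = mu_i + rng.standard_normal(n_ind) / np.sqrt(prec_i)

        # recentring (interweaving) moves: the likelihood is flat along
        # (intercept + d, u - d) and (fixed effects + d, individual effects - d),
        # so Gibbs on those directions' exact conditionals removes the slow
        # random walk between fixed effects and random-effect means.
        prec_d = n_yr / sig2_u + _FIXED_PREC
        mean_d = (u.sum() / sig2_u - _FIXED_PREC * gam[0]) / prec_d
        d = mean_d + rng.standard_normal() / np.sqrt(prec_d)
        u -= d
        gam[0] += d
        # slope vs year effects: likelihood flat along (beta + d, u_j - d * t_j)
        prec_d = t_yr @ t_yr / sig2_u + _FIXED_PREC
        mean_d = (u @ t_yr / sig2_u - _FIXED_PREC * gam[1]) / prec_d
        d = mean_d + rng.standard_normal() / np.sqrt(prec_d)
        u -= d * t_yr
        gam[1] += d
        if with_b:
            Lam = np.linalg.inv(Sigma)
            prec2 = n_ind * Lam + _FIXED_PREC * np.eye(2)
            rhs = Lam @ np.array([a.sum(), b.sum()]) - _FIXED_PREC * gam
            mean2 = np.linalg.solve(prec2, rhs)
            Lc = np.linalg.cholesky(prec2)
            d2 = mean2 + np.linalg.solve(Lc.T, rng.standard_normal(2))
            a -= d2[0]
            b -= d2[1]
            gam += d2
        elif with_a:
            prec_d = n_ind / sig2_a + _FIXED_PREC
            mean_d = (a.sum() / sig2_a - _FIXED_PREC * gam[0]) / prec_d
            d = mean_d + rng.standard_normal() / np.sqrt(prec_d)
            a -= d
            gam[0] += d
        fixed = X @ gam

        # variances
        fitted = fixed + u[yr]
        if with_a:
            fitted = fitted + a[ind]
        if with_b:
            fitted = fitted + b[ind] * t
        resid = y - fitted
        sig2 = _inv_gamma(rng, _IG_SHAPE + n / 2, _IG_RATE + resid @ resid / 2)
        sig2_u = _inv_gamma(rng, _IG_SHAPE + n_yr / 2, _IG_RATE + u @ u / 2)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and k < n_kept:
            out["intercept"][k] = gam[0]
            out["beta"][k] = gam[1]
            out["sd_year"][k] = np.sqrt(sig2_u)
            out["sd_resid"][k] = np.sqrt(sig2)
            out["var_fitted"][k] = np.var(fitted)
            out["u"][k] = u
            if with_a:
                out["a"][k] = a
                out["sd_ind_intercept"][k] = (
                    np.sqrt(Sigma[0, 0]) if with_b else np.sqrt(sig2_a)
                )
            if with_b:
                out["b"][k] = b
                out["sd_ind_slope"][k] = np.sqrt(Sigma[1, 1])
                out["corr_int_slope"][k] = Sigma[0, 1] / np.sqrt(Sigma[0, 0] * Sigma[1, 1])
            loglik[k] = -0.5 * np.log(2 * np.pi * sig2) - resid**2 / (2 * sig2)
            k += 1
    return out, loglik


def fit_rrmm(
    events: pd.DataFrame,
    climate: pd.DataFrame,
    model: str = "m2",
    predictor: str = "april_mean_centred",
    config: SamplerConfig | None = None,
) -> PosteriorFit:
    """Fit one of the nested FFD models (``m0``/``m1``/``m2``) by Gibbs sampling."""
    if model not in ("m0", "m1", "m2"):
        raise ValueError(f"model must be m0, m1 or m2, got {model!r}")
    cfg = config or SamplerConfig()
    y, x, ind, ind_ids, yr, yr_ids = _prepare(events, climate, predictor)

    chains_out, chains_ll = [], []
    for rng in cfg.chain_rngs():
        out, ll = _gibbs_chain(model, y, x, ind, yr, len(ind_ids), len(yr_ids), cfg, rng)
        chains_out.append(out)
        chains_ll.append(ll)

    posterior = {
        name: np.stack([c[name] for c in chains_out])
        for name in chains_out[0]
    }
    dims = {"u": ["year"], "a": ["individual"], "b": ["individual"]}
    coords = {"year": yr_ids, "individual": ind_ids}
    idata = az.from_dict(
        posterior=posterior,
        log_likelihood={"ffd": np.stack(chains_ll)},
        dims={k: v for k, v in dims.items() if k in posterior},
        coords=coords,
    )
    fit = PosteriorFit(
        idata=idata,
        model=model,
        data={
            "y": y, "x": x, "ind": ind, "yr": yr,
            "individual_ids": ind_ids, "year_ids": yr_ids,
            "predictor": predictor, "n_obs": y.size,
        },
        meta={"sampler": "gibbs", "config": cfg},
    )
    if cfg.chains >= 2:
        report = check_convergence(fit)
        if not report.passed:
            fit.warnings.append(str(report))
    else:
        fit.warnings.append("single chain: R-hat diagnostics unavailable")
    return fit


def fit_model_set(
    events: pd.DataFrame,
    climate: pd.DataFrame,
    predictor: str = "april_mean_centred",
    config: SamplerConfig | None = None,
    models: tuple[str, ...] = ("m0", "m1", "m2"),
) -> dict[str, PosteriorFit]:
    """Fit the nested model set on identical observations (for LOOIC comparison)."""
    cfg = config or SamplerConfig()
    seeds = np.random.SeedSequence(cfg.seed).generate_state(len(models)) % (2**31)
    fits = {}
    for model, seed in zip(models, seeds):
        from dataclasses import replace

        fits[model] = fit_rrmm(events, climate, model, predictor,
                               replace(cfg, seed=int(seed)))
    return fits


def compare_looic(fits: dict[str, PosteriorFit]) -> pd.DataFrame:
    """PSIS-LOO comparison table: LOOIC (deviance scale, lower = better),
    standard errors, ranking, differences to the best model with their
    standard errors, and the worst Pareto-k diagnostic per model."""
    sizes = {name: f.data.get("n_obs") for name, f in fits.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"fits are not on identical observation sets: {sizes}")
    loos = {name: az.loo(f.idata, pointwise=True, scale="deviance")
            for name, f in fits.items()}
    rows = []
    for name, loo in loos.items():
        rows.append(
            {
                "model": name,
                "looic": float(loo.elpd_loo),
                "se": float(loo.se),
                "p_loo": float(loo.p_loo),
                "pareto_k_max": float(np.max(loo.pareto_k.values)),
            }
        )
    table = pd.DataFrame(rows).sort_values("looic").reset_index(drop=True)
    table["rank"] = np.arange(len(table))
    best = table.loc[0, "model"]
    deltas, dses = [], []
    best_ll = loos[best].loo_i.values
    for name in table["model"]:
        diff_i = loos[name].loo_i.values - best_ll
        deltas.append(float(diff_i.sum()))
        dses.append(float(np.sqrt(len(diff_i) * np.var(diff_i))))
    table["delta_looic"] = deltas
    table["delta_se"] = dses
    return table


def extract_blups(fit: PosteriorFit) -> pd.DataFrame:
    """Per-individual posterior-mean deviations (BLUPs) from an m1/m2 fit.

    Reported intercepts/slopes add the population-level fixed effect, i.e.
    they are each individual's own reaction norm rather than its deviation.
    """
    if "a" not in fit.idata.posterior:
        raise ValueError("fit has no individual effects (model m0)")
    out = pd.DataFrame({"individual_id": fit.data["individual_ids"]})
    a = fit.stacked("a")
    out["blup_intercept"] = a.mean(axis=0)
    out["blup_intercept_sd"] = a.std(axis=0)
    out["reported_intercept"] = out["blup_intercept"] + fit.posterior_mean("intercept")
    if "b" in fit.idata.posterior:
        b = fit.stacked("b")
        out["blup_slope"] = b.mean(axis=0)
        out["blup_slope_sd"] = b.std(axis=0)
        out["reported_slope"] = out["blup_slope"] + fit.posterior_mean("beta")
    return out


def bayes_r2(fit: PosteriorFit) -> dict:
    """Bayesian R^2: per draw, var(fitted) / (var(fitted) + residual variance)."""
    var_fit = fit.stacked("var_fitted")
    sig2 = fit.stacked("sd_resid") ** 2
    draws = var_fit / (var_fit + sig2)
    return {
        "mean": float(draws.mean()),
        "sd": float(draws.std()),
        "draws": draws,
    }
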