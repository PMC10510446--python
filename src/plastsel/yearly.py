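"""Yearly selection on plasticity: does spring temperature change which level
of plasticity is favoured?

Yearly intact-seed counts are modelled with a zero-inflated negative binomial
GLMM.  Both parts carry the same fixed effects — plasticity (the BLUP slope,
by default residualized on the BLUP intercept so it is orthogonal to average
flowering time), mean-centred April temperature, their interaction, and plant
size — plus an individual random intercept:

    count part:  log mu    = Xc beta_c + e_i        (NB, dispersion phi)
    zero part:   logit pi  = Xz beta_z + f_i
    P(Y = 0)   = pi + (1 - pi) * (phi / (phi + mu))^phi

A credible zero-part interaction between plasticity and temperature means the
*probability of producing any seeds* for more vs less plastic individuals
shifts with spring temperature — the signature of temperature-dependent
selection on plasticity.  BLUPs enter as fixed known covariates (point
estimates), the approach shown to give less biased selection estimates than
propagating BLUP uncertainty; a draws-propagating variant can be emulated by
refitting over posterior BLUP samples.

The module also houses the censoring sensitivity analysis: refitting the
selection models after excluding individuals with few flowering events.
"""

from __future__ import annotations

import warnings as _warnings
import arviz as az
import numpy as np
import pandas as pd

from .mcmc import (
    AdaptiveCov,
    AdaptiveScale,
    PosteriorFit,
    SamplerConfig,
    check_convergence,
    nb_loglik,
    slice_update_1d,
)

__all__ = [
    "residual_plasticity",
    "fit_zinb_selection",
    "predict_any_seed_prob",
    "censoring_sensitivity",
    "zinb_loglik",
    "zinb_zero_prob",
]

_FIXED_PREC = 1e-6
_IG_SHAPE = 0.01
_IG_RATE = 0.01
_LOGPHI_PRIOR_SD = 2.0

COUNT_COEFS = ("intercept", "plasticity", "april_temp", "plasticity_x_temp", "size")
ZERO_COEFS = tuple("zi_" + c for c in COUNT_COEFS)


def residual_plasticity(estimates: pd.DataFrame) -> pd.DataFrame:
    """Plasticity adjusted for average flowering time.

    Ordinary least squares of the BLUP slope on the BLUP intercept; the
    residuals are a plasticity measure exactly orthogonal to (and therefore
    not confounded with) individual mean flowering time.  With (numerically)
    zero variance in the intercepts the residuals degenerate to mean-centred
    slopes, with a warning.
    """
    if len(estimates) < 3:
        raise ValueError("need at least 3 individuals to residualize")
    x = estimates["blup_intercept"].to_numpy(dtype=float)
    yv = estimates["blup_slope"].to_numpy(dtype=float)
    out = estimates[["individual_id", "blup_intercept", "blup_slope"]].copy()
    if np.var(x) < 1e-12 * max(1.0, np.var(yv)):
        _warnings.warn("zero variance in BLUP intercepts; residual plasticity "
                       "equals mean-centred slopes")
        out["residual_slope"] = yv - yv.mean()
        return out
    slope = np.cov(x, yv, ddof=0)[0, 1] / np.var(x)
    out["residual_slope"] = yv - (yv.mean() + slope * (x - x.mean()))
    return out


def zinb_zero_prob(mu: np.ndarray, phi: float, pi: np.ndarray) -> np.ndarray:
    """P(Y = 0) of the zero-inflated negative binomial: pi + (1-pi) (phi/(phi+mu))^phi."""
    return pi + (1.0 - pi) * (phi / (phi + mu)) ** phi


def zinb_loglik(y: np.ndarray, eta_count: np.ndarray, eta_zero: np.ndarray,
                phi: float) -> np.ndarray:
    """Pointwise ZINB log likelihood on the linear-predictor scale.

    At ``eta_zero -> -inf`` (pi = 0) this reduces exactly to the plain
    negative-binomial log likelihood.
    """
    y = np.asarray(y, dtype=float)
    mu = np.exp(np.clip(eta_count, -30, 30))
    ez = np.clip(eta_zero, -30, 30)
    log_pi = -np.log1p(np.exp(-ez))
    log_1mpi = -np.log1p(np.exp(ez))
    log_nb0 = phi * (np.log(phi) - np.log(phi + mu))
    ll_zero = np.logaddexp(log_pi, log_1mpi + log_nb0)
    ll_pos = log_1mpi + nb_loglik(y, mu, phi)
    return np.where(y == 0, ll_zero, ll_pos)


def _design(events, climate, plasticity, measure):
    if measure not in ("residual", "raw"):
        raise ValueError("measure must be 'residual' or 'raw'")
    pcol = "residual_slope" if measure == "residual" else "blup_slope"
    df = events.merge(climate[["year", "april_mean_centred"]], on="year", how="left")
    df = df.merge(plasticity[["individual_id", pcol]], on="individual_id", how="inner")
    if df["april_mean_centred"].isna().any():
        raise ValueError("events reference years missing from the climate table")
    p = df[pcol].to_numpy(dtype=float)
    tt = df["april_mean_centred"].to_numpy(dtype=float)
    size = df["size_sqrt_centred"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), p, tt, p * tt, size])
    y = df["seeds_intact"].to_numpy(dtype=float)
    ind, ind_ids = pd.factorize(df["individual_id"], sort=True)
    return y, X, ind, np.asarray(ind_ids), df


def _chain_zinb(y, X, ind, n_ind, cfg, rng):
    n, p = X.shape
    is_zero = y == 0
    zero_frac = float(is_zero.mean())

    bc = np.zeros(p)
    bz = np.zeros(p)
    bc[0] = np.log(y[~is_zero].mean() + 0.5) if (~is_zero).any() else 0.0
    bz[0] = np.log(max(zero_frac, 0.02) / max(1 - zero_frac, 0.02))
    bc += rng.normal(0, 0.1, p)
    bz += rng.normal(0, 0.1, p)
    e = np.zeros(n_ind)
    f = np.zeros(n_ind)
    sig2_e = 0.1 * np.exp(rng.normal(0, 0.3))
    sig2_f = 0.1 * np.exp(rng.normal(0, 0.3))
    lphi = np.log(2.0) + rng.normal(0, 0.3)

    step_c = AdaptiveCov(p + 1, init_scale=0.05)  # count coefs + log phi
    step_z = AdaptiveCov(p, init_scale=0.05)
    step_e = AdaptiveScale(0.3, target=0.44)
    step_f = AdaptiveScale(0.5, target=0.44)

    def ll_obs(bc_, bz_, e_, f_, lphi_):
        return zinb_loglik(y, X @ bc_ + e_[ind], X @ bz_ + f_[ind], np.exp(lphi_))

    n_kept = cfg.n_kept
    out = {
        "beta_count": np.empty((n_kept, p)),
        "beta_zero": np.empty((n_kept, p)),
        "nb_dispersion": np.empty(n_kept),
        "sd_ind_count": np.empty(n_kept),
        "sd_ind_zero": np.empty(n_kept),
    }
    loglik = np.empty((n_kept, n))
    k = 0

    for it in range(cfg.iterations):
        adapt = it < cfg.burn_in

        # --- count-part coefficients and dispersion: slice along learned axes
        psi = np.concatenate([bc, [lphi]])
        evals, evecs = step_c.principal_axes()

        def lp_count(pv):
            return (
                float(np.sum(ll_obs(pv[:p], bz, e, f, pv[p])))
                - 0.5 * _FIXED_PREC * pv[:p] @ pv[:p]
                - 0.5 * pv[p] ** 2 / _LOGPHI_PRIOR_SD**2
            )

        for kk in range(p + 1):
            v = evecs[:, kk]
            width = 2.0 * float(np.sqrt(evals[kk]))
            s = slice_update_1d(lambda s_: lp_count(psi + s_ * v), 0.0, width, rng)
            psi = psi + s * v
        bc, lphi = psi[:p].copy(), float(psi[p])
        if adapt:
            step_c.update(psi)

        # --- zero-part coefficients
        psi = bz.copy()
        evals, evecs = step_z.principal_axes()

        def lp_zero(pv):
            return (float(np.sum(ll_obs(bc, pv, e, f, lphi)))
                    - 0.5 * _FIXED_PREC * pv @ pv)

        for kk in range(p):
            v = evecs[:, kk]
            width = 2.0 * float(np.sqrt(evals[kk]))
            s = slice_update_1d(lambda s_: lp_zero(psi + s_ * v), 0.0, width, rng)
            psi = psi + s * v
        bz = psi.copy()
        if adapt:
            step_z.update(psi)

        # --- individual random intercepts, both parts (vectorized Metropolis)
        eta_z = X @ bz + f[ind]
        eta_c_fix = X @ bc
        ll_i = np.bincount(ind, weights=zinb_loglik(y, eta_c_fix + e[ind], eta_z,
                                                    np.exp(lphi)), minlength=n_ind)
        acc_sum = 0.0
        for _ in range(3):
            ep = e + step_e.scale * rng.standard_normal(n_ind)
            ll_p = np.bincount(ind, weights=zinb_loglik(y, eta_c_fix + ep[ind], eta_z,
                                                        np.exp(lphi)), minlength=n_ind)
            lr = (ll_p - ll_i) - 0.5 * (ep**2 - e**2) / sig2_e
            acc = np.log(rng.random(n_ind)) < lr
            e = np.where(acc, ep, e)
            ll_i = np.where(acc, ll_p, ll_i)
            acc_sum += acc.mean()
        if adapt:
            step_e.update(acc_sum / 3)

        eta_c = eta_c_fix + e[ind]
        eta_z_fix = X @ bz
        ll_i = np.bincount(ind, weights=zinb_loglik(y, eta_c, eta_z_fix + f[ind],
                                                    np.exp(lphi)), minlength=n_ind)
        acc_sum = 0.0
        for _ in range(3):
            fp = f + step_f.scale * rng.standard_normal(n_ind)
            ll_p = np.bincount(ind, weights=zinb_loglik(y, eta_c, eta_z_fix + fp[ind],
                                                        np.exp(lphi)), minlength=n_ind)
            lr = (ll_p - ll_i) - 0.5 * (fp**2 - f**2) / sig2_f
            acc = np.log(rng.random(n_ind)) < lr
            f = np.where(acc, fp, f)
            ll_i = np.where(acc, ll_p, ll_i)
            acc_sum += acc.mean()
        if adapt:
            step_f.update(acc_sum / 3)

        # --- random-intercept variances: conjugate refresh + non-centred
        # (scale) slice so small variances cannot trap the chain
        sig2_e = (_IG_RATE + e @ e / 2) / rng.gamma(_IG_SHAPE + n_ind / 2)
        sig2_f = (_IG_RATE + f @ f / 2) / rng.gamma(_IG_SHAPE + n_ind / 2)

        for which in ("e", "f"):
            sig2 = sig2_e if which == "e" else sig2_f
            lat = e if which == "e" else f
            s0 = 0.5 * np.log(sig2)
            h = lat / np.exp(s0)

            def lp_scale(s_):
                lat_ = np.exp(s_) * h
                if which == "e":
                    ll = np.sum(ll_obs(bc, bz, lat_, f, lphi))
                else:
                    ll = np.sum(ll_obs(bc, bz, e, lat_, lphi))
                return float(ll) - 2.0 * _IG_SHAPE * s_ - _IG_RATE * np.exp(-2.0 * s_)

            s_new = s0 + slice_update_1d(lambda d: lp_scale(s0 + d), 0.0, 0.3, rng)
            if which == "e":
                sig2_e, e = float(np.exp(2 * s_new)), np.exp(s_new) * h
            else:
                sig2_f, f = float(np.exp(2 * s_new)), np.exp(s_new) * h

        # --- recentring: intercepts vs random-effect means
        for which in ("e", "f"):
            sig2 = sig2_e if which == "e" else sig2_f
            lat = e if which == "e" else f
            b0 = bc[0] if which == "e" else bz[0]
            prec_d = n_ind / sig2 + _FIXED_PREC
            mean_d = (lat.sum() / sig2 - _FIXED_PREC * b0) / prec_d
            d = mean_d + rng.standard_normal() / np.sqrt(prec_d)
            if which == "e":
                e, bc[0] = lat - d, b0 + d
            else:
                f, bz[0] = lat - d, b0 + d

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and k < n_kept:
            out["beta_count"][k] = bc
            out["beta_zero"][k] = bz
            out["nb_dispersion"][k] = np.exp(lphi)
            out["sd_ind_count"][k] = np.sqrt(sig2_e)
            out["sd_ind_zero"][k] = np.sqrt(sig2_f)
            loglik[k] = ll_obs(bc, bz, e, f, lphi)
            k += 1
    return out, loglik


def fit_zinb_selection(
    events: pd.DataFrame,
    climate: pd.DataFrame,
    plasticity: pd.DataFrame,
    measure: str = "residual",
    config: SamplerConfig | None = None,
) -> PosteriorFit:
    """Fit the yearly ZINB selection model.

    ``plasticity`` is the table from :func:`residual_plasticity` (or any table
    with ``blup_slope``/``residual_slope``); ``measure`` picks which column
    enters the model.  Count and zero part share the covariate set; "zi\\_"
    prefixes label the zero part in the output.
    """
    cfg = config or SamplerConfig()
    y, X, ind, ind_ids, df = _design(events, climate, plasticity, measure)
    chains, lls = [], []
    for rng in cfg.chain_rngs():
        outc, ll = _chain_zinb(y, X, ind, len(ind_ids), cfg, rng)
        chains.append(outc)
        lls.append(ll)
    posterior = {nm: np.stack([c[nm] for c in chains]) for nm in chains[0]}
    idata = az.from_dict(
        posterior=posterior,
        log_likelihood={"seeds": np.stack(lls)},
        dims={"beta_count": ["count_coef"], "beta_zero": ["zero_coef"]},
        coords={"count_coef": list(COUNT_COEFS), "zero_coef": list(ZERO_COEFS)},
    )
    fit = PosteriorFit(
        idata=idata,
        model=f"zinb_{measure}",
        data={
            "individual_ids": ind_ids, "n_obs": len(y), "measure": measure,
            "X_means": X.mean(axis=0), "plasticity_range": (X[:, 1].min(), X[:, 1].max()),
            "X": X, "y": y, "ind": ind,
        },
        meta={"sampler": "metropolis-within-gibbs", "config": cfg},
    )
    if cfg.chains >= 2:
        report = check_convergence(fit)
        if not report.passed:
            fit.warnings.append(str(report))
    return fit


def coefficient_table(fit: PosteriorFit) -> pd.DataFrame:
    """Posterior mean/sd/CI table in the layout of a two-part ZINB model."""
    rows = []
    bc = fit.stacked("beta_count")
    bz = fit.stacked("beta_zero")
    extras = {
        "nb_dispersion": fit.stacked("nb_dispersion"),
        "sd_ind_count": fit.stacked("sd_ind_count"),
        "sd_ind_zero": fit.stacked("sd_ind_zero"),
    }
    for names, mat in ((COUNT_COEFS, bc), (ZERO_COEFS, bz)):
        for j, nm in enumerate(names):
            d = mat[:, j]
            lo, hi = np.quantile(d, [0.025, 0.975])
            rows.append({"coefficient": nm, "posterior_mean": d.mean(),
                         "posterior_sd": d.std(), "ci_low": lo, "ci_high": hi})
    for nm, d in extras.items():
        lo, hi = np.quantile(d, [0.025, 0.975])
        rows.append({"coefficient": nm, "posterior_mean": d.mean(),
                     "posterior_sd": d.std(), "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def temperature_quartiles(climate: pd.DataFrame, n_quartiles: int = 4) -> pd.DataFrame:
    """Empirical quantile bins of year-level April temperature and each bin's mean."""
    tvals = climate["april_mean_centred"].to_numpy(dtype=float)
    edges = np.quantile(tvals, np.linspace(0, 1, n_quartiles + 1))
    bins = np.clip(np.searchsorted(edges, tvals, side="right") - 1, 0, n_quartiles - 1)
    rows = []
    for q in range(n_quartiles):
        sel = tvals[bins == q]
        rows.append({"quartile": q + 1, "temp_low": edges[q], "temp_high": edges[q + 1],
                     "temp_mean": float(sel.mean()) if sel.size else np.nan})
    return pd.DataFrame(rows)


def predict_any_seed_prob(
    fit: PosteriorFit,
    temps: np.ndarray | None = None,
    plasticity_grid: np.ndarray | None = None,
    climate: pd.DataFrame | None = None,
    n_quartiles: int = 4,
    prob: float = 0.95,
) -> pd.DataFrame:
    """Marginal predicted probability of producing any seeds.

    For each temperature (by default the mean April temperature of each
    empirical quartile of study years) and each plasticity value, the zero
    part's linear predictor is evaluated with non-focal covariates at their
    means and random effects at zero; p(any seeds) = 1 - logistic(eta_zero),
    averaged over posterior draws with an HPD band.
    """
    if temps is None:
        if climate is None:
            raise ValueError("provide temps or a climate table")
        temps = temperature_quartiles(climate, n_quartiles)["temp_mean"].to_numpy()
    if plasticity_grid is None:
        lo, hi = fit.data["plasticity_range"]
        plasticity_grid = np.linspace(lo, hi, 25)
    else:
        lo, hi = fit.data["plasticity_range"]
        if np.min(plasticity_grid) < lo - 1e-9 or np.max(plasticity_grid) > hi + 1e-9:
            _warnings.warn("plasticity grid extends beyond the observed range; "
                           "predictions there are extrapolations")
    bz = fit.stacked("beta_zero")
    size_mean = fit.data["X_means"][4]
    rows = []
    from .mcmc import hpd_interval

    for tv in np.atleast_1d(temps):
        for pv in plasticity_grid:
            x = np.array([1.0, pv, tv, pv * tv, size_mean])
            eta = np.clip(bz @ x, -30, 30)
            p_any = 1.0 - 1.0 / (1.0 + np.exp(-eta))
            lo_h, hi_h = hpd_interval(p_any, prob)
            rows.append({"april_temp": tv, "plasticity": pv,
                         "p_any_seeds": float(p_any.mean()),
                         "hpd_low": lo_h, "hpd_high": hi_h,
                         "zero_prob": float(1.0 - p_any.mean())})
    return pd.DataFrame(rows)


def censoring_sensitivity(
    events: pd.DataFrame,
    individuals: pd.DataFrame,
    climate: pd.DataFrame,
    min_events: tuple[int, ...] = (1, 2, 3, 4),
    fitness_measure: str = "per_event",
    config: SamplerConfig | None = None,
    min_individuals: int = 10,
):
    """Refit the bivariate selection model keeping only individuals with at
    least ``k`` flowering events, for each threshold ``k``.

    Returns ``{k: {"n_individuals", "fit", "differentials", "gradients"}}``;
    thresholds leaving fewer than ``min_individuals`` individuals are reported
    with a note instead of a fit.
    """
    from .selection import fit_bivariate_rrmm, selection_differentials, selection_gradients

    cfg = config or SamplerConfig()
    counts = events.groupby("individual_id").size()
    results = {}
    for k in sorted(min_events):
        keep = counts.index[counts >= k]
        ev = events[events["individual_id"].isin(keep)]
        iv = individuals[individuals["individual_id"].isin(keep)]
        if len(keep) < min_individuals:
            results[k] = {"n_individuals": len(keep),
                          "note": f"only {len(keep)} individuals left; threshold skipped"}
            continue
        fit = fit_bivariate_rrmm(ev, iv, climate, fitness_measure, cfg)
        results[k] = {
            "n_individuals": int(len(keep)),
            "fit": fit,
            "differentials": selection_differentials(fit),
            "gradients": selection_gradients(fit),
        }
    return results
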