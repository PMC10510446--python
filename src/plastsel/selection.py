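"""Selection on reaction-norm intercepts and slopes from a bivariate
trait-fitness random-regression model.

The model couples two likelihoods through one latent trivariate-normal
individual effect v_i = (a_i, b_i, w_i):

* first flowering day (Gaussian):  FFD_ij = mu + a_i + (beta_T + b_i) T_j + u_j + eps_ij
* mean fitness across years (negative binomial, log link, one observation per
  individual):  E[W_i] = exp(w0 + gamma_s * size_i + w_i)

The 3x3 covariance of v_i carries all the selection information, following
the Lande-Arnold framework transplanted to reaction-norm traits: selection
*differentials* are the covariances of the latent fitness intercept with the
trait intercept and slope, S = (cov(w, a), cov(w, b)), and selection
*gradients* correct for the intercept-slope covariance, beta = P^-1 S with P
the 2x2 trait covariance.  Both are computed per posterior draw and then
summarized by posterior mode and HPD interval, so the full posterior
uncertainty of the covariance propagates into the selection estimates.

Because reaction-norm slopes are negative here (warmer springs -> earlier
flowering), a *positive* gradient on the slope means selection for a
*shallower* slope, i.e. decreased plasticity.

Sampling: Gibbs for all Gaussian conditionals (fixed effects, year effects,
variances, (a_i, b_i) given w_i); an independence Metropolis step at the
conditional mode for the latent fitness intercepts; slice sampling of the
marginal posterior (latents integrated out by Gauss-Hermite quadrature) for
the fitness-side globals; a collapsed Metropolis/slice update for the 3x3
covariance; and exact recentring moves between fixed effects and
random-effect means (see docs/methods.md).  Mean fitness values are
real-valued averages, scored with the continuous (gamma-function)
negative-binomial density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .mcmc import (
    AdaptiveCov,
    PosteriorFit,
    SamplerConfig,
    check_convergence,
    nb_loglik,
    slice_update_1d,
    summarize_mode_hpd,
)

__all__ = [
    "fit_bivariate_rrmm",
    "selection_differentials",
    "selection_gradients",
    "SelectionSummary",
    "summarize_mode_hpd",
]

_FIXED_PREC = 1e-6
_IG_SHAPE = 0.01
_IG_RATE = 0.01
_IW_DF = 5.0  # d + 2 for d = 3
_IW_SCALE = np.eye(3)
_LOGPHI_PRIOR_SD = 2.0  # log-normal prior on the NB dispersion


@dataclass
class SelectionSummary:
    """Posterior draws and mode/HPD summaries of selection coefficients."""

    draws: dict[str, np.ndarray]
    prob: float = 0.95
    n_excluded: int = 0
    notes: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = []
        for name, d in self.draws.items():
            mode, lo, hi = summarize_mode_hpd(d, self.prob)
            rows.append(
                {
                    "coefficient": name,
                    "posterior_mode": mode,
                    "hpd_low": lo,
                    "hpd_high": hi,
                    "posterior_mean": float(np.mean(d)),
                    "excludes_zero": bool(lo > 0 or hi < 0),
                }
            )
        return pd.DataFrame(rows)


def _prepare_bivariate(events, individuals, climate, fitness_measure, include_size):
    if fitness_measure not in ("per_event", "per_year"):
        raise ValueError("fitness_measure must be 'per_event' or 'per_year'")
    merged = events.merge(climate[["year", "april_mean_centred"]], on="year", how="left")
    if merged["april_mean_centred"].isna().any():
        raise ValueError("events reference years missing from the climate table")
    ind_codes, ind_ids = pd.factorize(merged["individual_id"], sort=True)
    yr_codes, yr_ids = pd.factorize(merged["year"], sort=True)
    indiv = individuals.set_index("individual_id").loc[np.asarray(ind_ids)]
    fit_col = f"mean_fitness_{fitness_measure}"
    fvals = indiv[fit_col].to_numpy(dtype=float)
    if np.any(fvals < 0):
        raise ValueError("negative fitness values")
    size = (
        indiv["mean_size_sqrt_centred"].to_numpy(dtype=float)
        if include_size
        else np.zeros(len(ind_ids))
    )
    return (
        merged["ffd"].to_numpy(dtype=float),
        merged["april_mean_centred"].to_numpy(dtype=float),
        ind_codes,
        np.asarray(ind_ids),
        yr_codes,
        np.asarray(yr_ids),
        fvals,
        size,
    )


def _cond_ab_given_w(Sigma):
    """Mean coefficient and 2x2 conditional covariance of (a,b) | w."""
    coef = Sigma[:2, 2] / Sigma[2, 2]
    cov = Sigma[:2, :2] - np.outer(Sigma[:2, 2], Sigma[:2, 2]) / Sigma[2, 2]
    return coef, cov


def _chol_from_theta(theta: np.ndarray) -> np.ndarray:
    """6-vector (log l11, l21, log l22, l31, l32, log l33) -> lower Cholesky."""
    L = np.zeros((3, 3))
    L[0, 0] = np.exp(theta[0])
    L[1, 0] = theta[1]
    L[1, 1] = np.exp(theta[2])
    L[2, 0] = theta[3]
    L[2, 1] = theta[4]
    L[2, 2] = np.exp(theta[5])
    return L


def _theta_from_chol(L: np.ndarray) -> np.ndarray:
    return np.array(
        [np.log(L[0, 0]), L[1, 0], np.log(L[1, 1]), L[2, 0], L[2, 1], np.log(L[2, 2])]
    )


def _iw_logprior_jac(theta: np.ndarray, L: np.ndarray) -> float:
    """Inverse-Wishart(_IW_DF, I) log prior on Sigma = L L' plus the log-Jacobian
    of the Cholesky-with-log-diagonal parameterization."""
    log_diag_sum = theta[0] + theta[2] + theta[5]
    Linv = np.linalg.inv(L)
    lprior = -(_IW_DF + 4.0) * log_diag_sum - 0.5 * np.sum(Linv * Linv)
    ljac = 5.0 * theta[0] + 4.0 * theta[2] + 3.0 * theta[5]
    return lprior + ljac


def _collapsed_sigma_logpost(theta, w, n_i, St_i, Stt_i, Zr1, Zr2, sig2):
    """Log posterior of the 3x3 covariance with the FFD deviations (a_i, b_i)
    integrated out analytically (their prior given w_i is Gaussian and the FFD
    likelihood Gaussian, so the marginal is a rank-2 Woodbury form) and the
    w_i conditioned on.  Zr1/Zr2 are per-individual sums of residuals and
    residuals*t with fixed and year effects removed."""
    L = _chol_from_theta(theta)
    Sigma = L @ L.T
    sww = Sigma[2, 2]
    coef, C = _cond_ab_given_w(Sigma)
    det_c = C[0, 0] * C[1, 1] - C[0, 1] ** 2
    if det_c <= 0 or sww <= 0 or not np.isfinite(det_c):
        return -np.inf, None
    l11, l12, l22 = C[1, 1] / det_c, -C[0, 1] / det_c, C[0, 0] / det_c
    m1, m2 = coef[0] * w, coef[1] * w
    m11 = l11 + n_i / sig2
    m12 = l12 + St_i / sig2
    m22 = l22 + Stt_i / sig2
    det_m = m11 * m22 - m12 * m12
    # quadratic terms of N(r; Z m, sig2 I + Z C Z') via Woodbury
    h1 = (Zr1 - (n_i * m1 + St_i * m2)) / sig2
    h2 = (Zr2 - (St_i * m1 + Stt_i * m2)) / sig2
    quad_w = (m22 * h1 * h1 - 2 * m12 * h1 * h2 + m11 * h2 * h2) / det_m
    cross = (-2 * (Zr1 * m1 + Zr2 * m2)
             + n_i * m1 * m1 + 2 * St_i * m1 * m2 + Stt_i * m2 * m2) / sig2
    n_ind = n_i.size
    ll_ffd = -0.5 * (
        n_ind * np.log(det_c) + np.sum(np.log(det_m)) + np.sum(cross) - np.sum(quad_w)
    )
    ll_w = -0.5 * (n_ind * np.log(sww) + np.sum(w * w) / sww)
    return ll_ffd + ll_w + _iw_logprior_jac(theta, L), Sigma


def _chain_bivariate(y, t, ind, yr, n_ind, n_yr, F, size, cfg, rng):
    n = y.size
    n_i = np.bincount(ind, minlength=n_ind).astype(float)
    n_j = np.bincount(yr, minlength=n_yr).astype(float)
    t_yr = np.bincount(yr, weights=t, minlength=n_yr) / np.maximum(n_j, 1)
    St_i = np.bincount(ind, weights=t, minlength=n_ind)
    Stt_i = np.bincount(ind, weights=t * t, minlength=n_ind)
    X = np.column_stack([np.ones(n), t])
    XtX = X.T @ X
    gh_x, gh_w = np.polynomial.hermite.hermgauss(9)
    log_gh_w = np.log(gh_w) - 0.5 * np.log(np.pi)

    # initial values, jittered between chains
    gam, *_ = np.linalg.lstsq(X, y, rcond=None)
    gam = gam + rng.normal(0, [1.0, 0.3])
    sig2 = float(np.var(y - X @ gam)) * np.exp(rng.normal(0, 0.3))
    sig2_u = 4.0 * np.exp(rng.normal(0, 0.3))
    u = np.zeros(n_yr)
    a = np.zeros(n_ind)
    b = np.zeros(n_ind)
    w0 = float(np.log(F.mean() + 0.1)) + rng.normal(0, 0.2)
    gs = rng.normal(0, 0.01)
    w = np.clip(np.log(F + 0.5) - w0, -3, 3) + rng.normal(0, 0.1, n_ind)
    phi = 2.0 * np.exp(rng.normal(0, 0.3))
    Sigma = np.diag([1.0, 0.25, 1.0])

    step_cov = AdaptiveCov(6, init_scale=0.05)
    step_fitside = AdaptiveCov(6, init_scale=0.05)

    def _fitside_logpost(pv):
        """Marginal log posterior of the fitness-side globals
        (w0, gamma_s, log phi, fitness row of the Cholesky factor) with the
        latent fitness intercepts integrated out by Gauss-Hermite quadrature.
        Conditions on (a_i, b_i); the trait block of the covariance is fixed."""
        Lp = Lch.copy()
        Lp[2, 0], Lp[2, 1], Lp[2, 2] = pv[3], pv[4], np.exp(pv[5])
        Sp = Lp @ Lp.T
        coef = np.linalg.solve(Sp[:2, :2], Sp[:2, 2])
        var_w = Sp[2, 2] - coef @ Sp[:2, 2]
        if var_w <= 1e-10 or not np.isfinite(var_w):
            return -np.inf, Lp
        phi_ = np.exp(pv[2])
        mw = a * coef[0] + b * coef[1]
        eta = (pv[0] + pv[1] * size + mw)[:, None] + np.sqrt(2.0 * var_w) * gh_x[None, :]
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        base = gammaln(F + phi_) - gammaln(phi_) - gammaln(F + 1.0)
        node_ll = (phi_ * (np.log(phi_) - np.log(phi_ + mu))
                   + F[:, None] * (eta - np.log(phi_ + mu)) + log_gh_w[None, :])
        mx = node_ll.max(axis=1)
        ll = float(np.sum(base + mx + np.log(np.sum(np.exp(node_ll - mx[:, None]), axis=1))))
        lp = (ll - 0.5 * _FIXED_PREC * (pv[0] ** 2 + pv[1] ** 2)
              - 0.5 * pv[2] ** 2 / _LOGPHI_PRIOR_SD**2
              + _iw_logprior_jac(_theta_from_chol(Lp), Lp))
        return lp, Lp

    n_kept = cfg.n_kept
    scalars = [
        "intercept_ffd", "beta_temp", "sd_year", "sd_resid",
        "intercept_fitness", "size_effect", "nb_dispersion",
    ]
    out = {nm: np.empty(n_kept) for nm in scalars}
    out["re_cov"] = np.empty((n_kept, 3, 3))
    out["u"] = np.empty((n_kept, n_yr))
    k = 0

    for it in range(cfg.iterations):
        adapt = it < cfg.burn_in

        # --- FFD fixed effects
        r = y - u[yr] - a[ind] - b[ind] * t
        prec = XtX / sig2 + _FIXED_PREC * np.eye(2)
        mean = np.linalg.solve(prec, X.T @ r / sig2)
        L = np.linalg.cholesky(prec)
        gam = mean + np.linalg.solve(L.T, rng.standard_normal(2))
        fixed = X @ gam

        # --- year intercepts
        r = y - fixed - a[ind] - b[ind] * t
        prec_j = n_j / sig2 + 1.0 / sig2_u
        mu_j = np.bincount(yr, weights=r, minlength=n_yr) / sig2 / prec_j
        u = mu_j + rng.standard_normal(n_yr) / np.sqrt(prec_j)

        # --- 3x3 covariance: conditional inverse-Wishart refresh, a collapsed
        # Metropolis update with (a_i, b_i) integrated out, then a conjugate
        # redraw of (a_i, b_i) given the new covariance.
        V = np.column_stack([a, b, w])
        S = _IW_SCALE + V.T @ V
        Sigma = stats.invwishart.rvs(df=_IW_DF + n_ind, scale=S, random_state=rng)

        r = y - fixed - u[yr]
        Zr1 = np.bincount(ind, weights=r, minlength=n_ind)
        Zr2 = np.bincount(ind, weights=r * t, minlength=n_ind)
        theta = _theta_from_chol(np.linalg.cholesky(Sigma))
        evals_c, evecs_c = step_cov.principal_axes()
        for kk in range(6):
            v = evecs_c[:, kk]
            width = 2.0 * float(np.sqrt(evals_c[kk]))
            s = slice_update_1d(
                lambda s_: _collapsed_sigma_logpost(
                    theta + s_ * v, w, n_i, St_i, Stt_i, Zr1, Zr2, sig2
                )[0],
                0.0, width, rng,
            )
            theta = theta + s * v
        Sigma = _collapsed_sigma_logpost(theta, w, n_i, St_i, Stt_i, Zr1, Zr2, sig2)[1]
        if adapt:
            step_cov.update(theta)

        # --- (a_i, b_i) | w_i, Sigma : conjugate bivariate normal
        coef, Cab = _cond_ab_given_w(Sigma)
        Lam = np.linalg.inv(Cab)
        prior_mean = np.outer(w, coef)
        h1 = Zr1 / sig2 + Lam[0, 0] * prior_mean[:, 0] + Lam[0, 1] * prior_mean[:, 1]
        h2 = Zr2 / sig2 + Lam[0, 1] * prior_mean[:, 0] + Lam[1, 1] * prior_mean[:, 1]
        P11 = n_i / sig2 + Lam[0, 0]
        P12 = St_i / sig2 + Lam[0, 1]
        P22 = Stt_i / sig2 + Lam[1, 1]
        det = P11 * P22 - P12 * P12
        m1 = (P22 * h1 - P12 * h2) / det
        m2 = (P11 * h2 - P12 * h1) / det
        L11 = np.sqrt(P11)
        L21 = P12 / L11
        L22 = np.sqrt(P22 - L21 * L21)
        z2 = rng.standard_normal(n_ind) / L22
        z1 = (rng.standard_normal(n_ind) - L21 * z2) / L11
        a, b = m1 + z1, m2 + z2

        # --- fitness-side globals: slice sampling of the marginal posterior
        # (latent fitness intercepts integrated out) along the principal axes
        # of their learned covariance.  With one fitness observation per
        # individual, the dispersion and the latent scale are only weakly
        # separable; marginalizing the latents lets the chain move freely
        # along that ridge.
        Lch = np.linalg.cholesky(Sigma)
        psi = np.array([w0, gs, np.log(phi), Lch[2, 0], Lch[2, 1], np.log(Lch[2, 2])])
        evals, evecs = step_fitside.principal_axes()
        for kk in range(6):
            v = evecs[:, kk]
            width = 2.0 * float(np.sqrt(evals[kk]))
            s = slice_update_1d(lambda s_: _fitside_logpost(psi + s_ * v)[0],
                                0.0, width, rng)
            psi = psi + s * v
        _, Lp = _fitside_logpost(psi)
        w0, gs, phi = float(psi[0]), float(psi[1]), float(np.exp(psi[2]))
        Sigma = Lp @ Lp.T
        if adapt:
            step_fitside.update(psi)

        # --- latent fitness intercepts w_i: independence Metropolis at the
        # conditional mode (the conditional is globally log-concave), so w_i
        # relocates globally after the marginal move above.
        coef_w = np.linalg.solve(Sigma[:2, :2], Sigma[:2, 2])
        var_w = Sigma[2, 2] - coef_w @ Sigma[:2, 2]
        mw = a * coef_w[0] + b * coef_w[1]
        eta0 = w0 + gs * size
        wstar = w.copy()
        for _ in range(4):
            mu = np.exp(np.clip(eta0 + wstar, -30, 30))
            g = F - (F + phi) * mu / (phi + mu) - (wstar - mw) / var_w
            hh = -(F + phi) * phi * mu / (phi + mu) ** 2 - 1.0 / var_w
            wstar = wstar + np.clip(-g / hh, -4.0, 4.0)
        sd_prop = np.sqrt(-1.3 / hh)
        wp = wstar + sd_prop * rng.standard_normal(n_ind)

        def _w_logtarget(wv):
            return (nb_loglik(F, np.exp(np.clip(eta0 + wv, -30, 30)), phi)
                    - 0.5 * (wv - mw) ** 2 / var_w)

        lr = (_w_logtarget(wp) - _w_logtarget(w)
              + 0.5 * ((wp - wstar) ** 2 - (w - wstar) ** 2) / sd_prop**2)
        acc = np.log(rng.random(n_ind)) < lr
        w = np.where(acc, wp, w)

        # --- recentring: FFD fixed effects vs individual-effect means
        coef, Cab2 = _cond_ab_given_w(Sigma)
        Lam2 = np.linalg.inv(Cab2)
        prec2 = n_ind * Lam2 + _FIXED_PREC * np.eye(2)
        dev = np.array([np.sum(a - coef[0] * w), np.sum(b - coef[1] * w)])
        rhs = Lam2 @ dev - _FIXED_PREC * gam
        mean2 = np.linalg.solve(prec2, rhs)
        Lc = np.linalg.cholesky(prec2)
        d2 = mean2 + np.linalg.solve(Lc.T, rng.standard_normal(2))
        a -= d2[0]
        b -= d2[1]
        gam += d2

        # --- recentring moves for the FFD part
        prec_d = n_yr / sig2_u + _FIXED_PREC
        mean_d = (u.sum() / sig2_u - _FIXED_PREC * gam[0]) / prec_d
        d = mean_d + rng.standard_normal() / np.sqrt(prec_d)
        u -= d
        gam[0] += d
        prec_d = t_yr @ t_yr / sig2_u + _FIXED_PREC
        mean_d = (u @ t_yr / sig2_u - _FIXED_PREC * gam[1]) / prec_d
        d = mean_d + rng.standard_normal() / np.sqrt(prec_d)
        u -= d * t_yr
        gam[1] += d
        fixed = X @ gam

        # --- variances of the FFD part
        resid = y - fixed - u[yr] - a[ind] - b[ind] * t
        sig2 = (_IG_RATE + resid @ resid / 2) / rng.gamma(_IG_SHAPE + n / 2)
        sig2_u = (_IG_RATE + u @ u / 2) / rng.gamma(_IG_SHAPE + n_yr / 2)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and k < n_kept:
            out["intercept_ffd"][k] = gam[0]
            out["beta_temp"][k] = gam[1]
            out["sd_year"][k] = np.sqrt(sig2_u)
            out["sd_resid"][k] = np.sqrt(sig2)
            out["intercept_fitness"][k] = w0
            out["size_effect"][k] = gs
            out["nb_dispersion"][k] = phi
            out["re_cov"][k] = Sigma
            out["u"][k] = u
            k += 1
    return out


def fit_bivariate_rrmm(
    events: pd.DataFrame,
    individuals: pd.DataFrame,
    climate: pd.DataFrame,
    fitness_measure: str = "per_event",
    config: SamplerConfig | None = None,
    include_size: bool = True,
) -> PosteriorFit:
    """Fit the bivariate FFD + mean-fitness random-regression model.

    ``fitness_measure`` selects mean fitness per flowering event or per year
    of study as the fitness response; nothing else in the model changes.
    ``include_size=False`` drops the plant-size fixed effect from the fitness
    submodel (a robustness switch).
    """
    cfg = config or SamplerConfig()
    y, t, ind, ind_ids, yr, yr_ids, F, size = _prepare_bivariate(
        events, individuals, climate, fitness_measure, include_size
    )
    chains = []
    for rng in cfg.chain_rngs():
        chains.append(
            _chain_bivariate(y, t, ind, yr, len(ind_ids), len(yr_ids), F, size, cfg, rng)
        )
    posterior = {nm: np.stack([c[nm] for c in chains]) for nm in chains[0]}

    # derived labelled summaries of the covariance
    cov = posterior["re_cov"]
    sds = np.sqrt(np.stack([cov[..., i, i] for i in range(3)], axis=-1))
    posterior["sd_ind_intercept"] = sds[..., 0]
    posterior["sd_ind_slope"] = sds[..., 1]
    posterior["sd_ind_fitness"] = sds[..., 2]
    posterior["corr_int_slope"] = cov[..., 0, 1] / (sds[..., 0] * sds[..., 1])
    posterior["corr_int_fitness"] = cov[..., 0, 2] / (sds[..., 0] * sds[..., 2])
    posterior["corr_slope_fitness"] = cov[..., 1, 2] / (sds[..., 1] * sds[..., 2])

    idata = az.from_dict(
        posterior=posterior,
        dims={"re_cov": ["re_dim0", "re_dim1"], "u": ["year"]},
        coords={"re_dim0": ["a", "b", "w"], "re_dim1": ["a", "b", "w"], "year": yr_ids},
    )
    fit = PosteriorFit(
        idata=idata,
        model=f"bivariate_{fitness_measure}",
        data={
            "individual_ids": ind_ids, "year_ids": yr_ids, "n_obs": y.size,
            "fitness_measure": fitness_measure, "include_size": include_size,
            "fitness_scoring": "continuous negative binomial (real-valued means)",
        },
        meta={"sampler": "metropolis-within-gibbs", "config": cfg},
    )
    if cfg.chains >= 2:
        report = check_convergence(fit)
        if not report.passed:
            fit.warnings.append(str(report))
    else:
        fit.warnings.append("single chain: R-hat diagnostics unavailable")
    return fit


def _cov_draws(fit: PosteriorFit) -> np.ndarray:
    return fit.stacked("re_cov")


def _mean_fitness_scale(fit: PosteriorFit) -> np.ndarray:
    """Per-draw model-implied mean fitness at average size with the latent
    intercept integrated out: exp(w0 + sigma_w^2 / 2)."""
    w0 = fit.stacked("intercept_fitness")
    sw2 = fit.stacked("re_cov")[:, 2, 2]
    return np.exp(w0 + sw2 / 2.0)


def selection_differentials(fit: PosteriorFit, prob: float = 0.95,
                            mean_standardize: bool = False) -> SelectionSummary:
    """Total selection on reaction-norm intercept and slope.

    Per posterior draw, S = (cov(w, a), cov(w, b)) read off the 3x3 latent
    covariance (latent log-fitness scale), then summarized by mode and HPD.
    ``mean_standardize=True`` multiplies each draw by its model-implied mean
    fitness, moving the coefficients from the latent log scale to the
    absolute-fitness scale; the default reports the latent scale.
    """
    cov = _cov_draws(fit)
    scale = _mean_fitness_scale(fit) if mean_standardize else 1.0
    return SelectionSummary(
        draws={"S_intercept": cov[:, 0, 2] * scale, "S_slope": cov[:, 1, 2] * scale},
        prob=prob,
        notes=(["mean-standardized"] if mean_standardize else []),
    )


def selection_gradients(fit: PosteriorFit, prob: float = 0.95,
                        max_excluded_frac: float = 0.01,
                        mean_standardize: bool = False) -> SelectionSummary:
    """Direct selection on intercept and slope: per draw, beta = P^-1 S.

    P is the draw's 2x2 trait covariance and S its differential vector.
    Numerically singular draws are excluded and counted; more than
    ``max_excluded_frac`` of them aborts the computation.  With negative
    reaction-norm slopes, a positive slope gradient means selection for
    decreased plasticity.  ``mean_standardize`` as in
    :func:`selection_differentials`.
    """
    cov = _cov_draws(fit)
    P = cov[:, :2, :2]
    S = cov[:, :2, 2]
    det = P[:, 0, 0] * P[:, 1, 1] - P[:, 0, 1] ** 2
    ok = det > 1e-12 * np.maximum(P[:, 0, 0] * P[:, 1, 1], 1e-300)
    n_excluded = int((~ok).sum())
    if n_excluded > max_excluded_frac * len(det):
        raise RuntimeError(
            f"{n_excluded}/{len(det)} posterior draws have a singular trait "
            "covariance; gradients are not identifiable"
        )
    beta = np.full((len(det), 2), np.nan)
    beta[ok, 0] = (P[ok, 1, 1] * S[ok, 0] - P[ok, 0, 1] * S[ok, 1]) / det[ok]
    beta[ok, 1] = (P[ok, 0, 0] * S[ok, 1] - P[ok, 0, 1] * S[ok, 0]) / det[ok]
    notes = [] if n_excluded == 0 else [f"excluded {n_excluded} singular draws"]
    if mean_standardize:
        scale = _mean_fitness_scale(fit)[ok]
        beta[ok] *= scale[:, None]
        notes.append("mean-standardized")
    return SelectionSummary(
        draws={"beta_intercept": beta[ok, 0], "beta_slope": beta[ok, 1]},
        prob=prob,
        n_excluded=n_excluded,
        notes=notes,
    )
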