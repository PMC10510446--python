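"""Shared MCMC machinery: sampler configuration, adaptive Metropolis steps,
posterior containers and posterior summaries.

The model-specific samplers (conjugate Gibbs for the Gaussian random-regression
models, Metropolis-within-Gibbs for the bivariate trait-fitness model and the
zero-inflated seed-count model) live next to their models; this module holds
the pieces they share.  Posterior draws are stored as
:class:`arviz.InferenceData`, so that convergence diagnostics (split R-hat,
effective sample size), PSIS-LOO and HDI intervals all come from arviz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import arviz as az
import numpy as np
from scipy import stats

__all__ = [
    "SamplerConfig",
    "PosteriorFit",
    "ConvergenceReport",
    "check_convergence",
    "summarize_mode_hpd",
    "hpd_interval",
    "posterior_mode",
    "nb_loglik",
    "AdaptiveScale",
]

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run lengths.  Defaults follow common practice for these models:
    4 chains, 4000 iterations with the first 1000 discarded as burn-in and a
    thinning rate of 2, giving 6000 retained draws."""

    chains: int = 4
    iterations: int = 4000
    burn_in: int = 1000
    thin: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1 or self.chains < 1:
            raise ValueError("thin and chains must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    def chain_rngs(self) -> list[np.random.Generator]:
        return [np.random.default_rng(s) for s in
                np.random.SeedSequence(self.seed).spawn(self.chains)]

    def reduced(self, chains: int = 2, iterations: int = 1000,
                burn_in: int = 500, thin: int = 1) -> "SamplerConfig":
        return replace(self, chains=chains, iterations=iterations,
                       burn_in=burn_in, thin=thin)


class AdaptiveScale:
    """Robbins-Monro adaptation of a random-walk proposal scale (scalar or a
    vector of per-coordinate scales) toward a target acceptance rate.
    Adaptation must only be driven during burn-in to keep the chain valid."""

    def __init__(self, init: float | np.ndarray, target: float = 0.3):
        self.log_scale = np.log(np.asarray(init, dtype=float))
        self.target = target
        self._t = 0

    @property
    def scale(self):
        return np.exp(self.log_scale)

    def update(self, accept_rate: float | np.ndarray) -> None:
        self._t += 1
        gain = min(0.5, 2.0 / np.sqrt(self._t))
        self.log_scale = self.log_scale + gain * (np.asarray(accept_rate) - self.target)


class AdaptiveCov:
    """Haario-style adaptive multivariate random-walk proposal: after a
    warm-up of isotropic steps, proposals use 2.38^2/d times the running
    empirical covariance of the visited states (plus a small nugget).
    Adaptation is driven only during burn-in."""

    def __init__(self, dim: int, init_scale: float = 0.1, start: int = 200):
        self.dim = dim
        self.scale = init_scale
        self.start = start
        self._n = 0
        self._mean = np.zeros(dim)
        self._m2 = np.zeros((dim, dim))
        self._chol = init_scale * np.eye(dim)

    def propose(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return x + self._chol @ rng.standard_normal(self.dim)

    def update(self, x: np.ndarray) -> None:
        self._n += 1
        delta = x - self._mean
        self._mean += delta / self._n
        self._m2 += np.outer(delta, x - self._mean)
        if self._n > self.start and self._n % 50 == 0:
            cov = self._m2 / (self._n - 1)
            cov = (2.38**2 / self.dim) * cov + 1e-8 * np.eye(self.dim)
            try:
                self._chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass

    def principal_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues and eigenvectors of the current covariance estimate."""
        if self._n > self.start:
            cov = self._m2 / (self._n - 1) + 1e-10 * np.eye(self.dim)
        else:
            cov = self.scale**2 * np.eye(self.dim)
        evals, evecs = np.linalg.eigh(cov)
        return np.maximum(evals, 1e-12), evecs


def slice_update_1d(logf: Callable[[float], float], x0: float, width: float,
                    rng: np.random.Generator, max_out: int = 10) -> float:
    """One univariate slice-sampling update (stepping-out then shrinkage).

    Rejection-free, so it traverses long flat ridges that defeat random-walk
    Metropolis; ``width`` only affects efficiency, not correctness.
    """
    f0 = logf(x0)
    y = f0 + np.log(rng.random())
    left = x0 - width * rng.random()
    right = left + width
    for _ in range(max_out):
        if logf(left) <= y:
            break
        left -= width
    for _ in range(max_out):
        if logf(right) <= y:
            break
        right += width
    for _ in range(100):
        x1 = left + (right - left) * rng.random()
        if logf(x1) > y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


@dataclass
class PosteriorFit:
    """Labelled posterior draws plus the data the model was fitted to.

    ``idata`` holds a ``posterior`` group (and, when the sampler computes it,
    a ``log_likelihood`` group used for PSIS-LOO).  ``data`` keeps the design
    arrays so derived quantities (fitted values, posterior predictive draws)
    can be reconstructed without refitting.
    """

    idata: az.InferenceData
    model: str
    data: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one variable with chain/draw flattened into the first axis."""
        da = self.idata.posterior[name]
        return da.stack(sample=("chain", "draw")).transpose("sample", ...).to_numpy()

    def posterior_mean(self, name: str) -> np.ndarray | float:
        val = self.idata.posterior[name].mean(("chain", "draw")).to_numpy()
        return float(val) if val.ndim == 0 else val

    def posterior_sd(self, name: str) -> np.ndarray | float:
        val = self.idata.posterior[name].std(("chain", "draw")).to_numpy()
        return float(val) if val.ndim == 0 else val

    def summary(self, var_names: list[str] | None = None):
        return az.summary(self.idata, var_names=var_names, kind="stats")

    @property
    def n_draws(self) -> int:
        post = self.idata.posterior
        return post.sizes["chain"] * post.sizes["draw"]


@dataclass
class ConvergenceReport:
    rhat: Mapping[str, float]
    neff_ratio: Mapping[str, float]
    rhat_max: float
    neff_ratio_min: float
    passed: bool

    def __str__(self) -> str:
        worst_r = max(self.rhat.values())
        worst_n = min(self.neff_ratio.values())
        status = "PASS" if self.passed else "FAIL"
        return (f"convergence {status}: max R-hat {worst_r:.4f} "
                f"(limit {self.rhat_max}), min N_eff/N {worst_n:.3f} "
                f"(limit {self.neff_ratio_min})")


def check_convergence(fit: PosteriorFit, rhat_max: float = 1.05,
                      neff_ratio_min: float = 0.1) -> ConvergenceReport:
    """Split R-hat and relative effective sample size for every parameter.

    The fit passes if all R-hat values are below ``rhat_max`` and all
    N_eff/N ratios above ``neff_ratio_min``.  R-hat needs >= 2 chains.
    """
    post = fit.idata.posterior
    if post.sizes["chain"] < 2:
        raise ValueError("R-hat requires at least 2 chains")
    n_total = post.sizes["chain"] * post.sizes["draw"]
    rhat_ds = az.rhat(fit.idata)
    ess_ds = az.ess(fit.idata)
    rhat, neff = {}, {}
    for name in rhat_ds.data_vars:
        rhat[name] = float(np.nanmax(rhat_ds[name].to_numpy()))
        neff[name] = float(np.nanmin(ess_ds[name].to_numpy())) / n_total
    passed = max(rhat.values()) < rhat_max and min(neff.values()) > neff_ratio_min
    return ConvergenceReport(rhat, neff, rhat_max, neff_ratio_min, passed)


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` posterior mass (empirical HPD)."""
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    m = int(np.ceil(prob * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m - 1])


def posterior_mode(draws: np.ndarray) -> float:
    """Mode of a kernel density estimate over the draws (Silverman bandwidth)."""
    draws = np.asarray(draws, dtype=float)
    if np.ptp(draws) == 0:
        return float(draws[0])
    kde = stats.gaussian_kde(draws, bw_method="silverman")
    grid = np.linspace(draws.min(), draws.max(), 1024)
    return float(grid[np.argmax(kde(grid))])


def summarize_mode_hpd(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float, float]:
    """(posterior mode, HPD low, HPD high) of a vector of posterior draws."""
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 100:
        raise ValueError(f"need at least 100 draws to summarize, got {draws.size}")
    if np.ptp(draws) == 0:
        c = float(draws[0])
        return c, c, c
    lo, hi = hpd_interval(draws, prob)
    return posterior_mode(draws), lo, hi


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Pointwise negative-binomial log density, mean-dispersion form
    (variance mu + mu^2/phi), valid for real-valued non-negative y so that
    mean fitness values (averages of counts) can be scored directly."""
    from scipy.special import gammaln

    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    return (
        gammaln(y + phi) - gammaln(phi) - gammaln(y + 1.0)
        + phi * (np.log(phi) - np.log(phi + mu))
        + y * (np.log(mu) - np.log(phi + mu))
    )
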