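# Methods

This note documents the statistical models, the synthetic-data generator, the
samplers, and the design decisions behind `plastsel`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself compute.

## Scientific setting

A long-lived perennial herb flowers once per spring; the day its first flower
opens (first flowering day, FFD, counted in days after the vernal equinox)
responds to spring temperature. Individuals followed over many years each
trace out a *thermal reaction norm*: an intercept (average flowering time in
an average April) and a slope (plasticity, days advanced per degree of April
warming; negative, since warm springs mean earlier flowering). The package
asks three questions: (1) do individuals differ in intercept and slope, (2)
is there phenotypic selection on either (via intact-seed production), and
(3) does selection on plasticity change with spring temperature?

## Field-data ingestion

**FFD dating.** Surveys visit each plant every ~5 days. When an open flower
is first seen at visit `d1`, flowering began somewhere in the preceding
interval; the estimate backdates by `min(4, (n_open(d1) − 1) + bud_stage(d0))`
days, using the number of open flowers at the interval end and the most
developed bud's stage at its start (0 small bud, 1 large, 2 showing colour).
Both quantities indicate how far flowering had progressed. The offset rule is
a deterministic, auditable stand-in for interval-censored dating; its
constants are configurable, and output rows carry flags (`ffd_is_expected`,
`left_censored`) marking estimated or censored dates.

**Grazed plants (the invisible fraction).** Plants grazed before any flower
was observed would, if dropped, bias selection estimates — grazers remove
early/late phenotypes non-randomly. When ≥ 50% of shoots are grazed and no
flower was ever seen, an *expected* FFD is projected forward from the last
recorded bud stage (stage 2 → +5 d, 1 → +10 d, 0 → +15 d from that visit),
flagged `ffd_is_expected`.

**Equinox conversion.** Calendar dates become days after the March equinox
(day 0 = equinox date, UTC), computed from the standard astronomical
polynomial-plus-periodic-terms approximation (sub-hour accuracy over
1000–3000 CE); a user-supplied table overrides it. This removes leap-year
artefacts from day-of-year phenology.

**Fitness and size.** Per individual: mean intact seeds per flowering event
(total seeds / flowering years) and per year of study (total seeds / years
under observation, the span from first flowering year to the end of the
study). Plant size is above-ground volume, `Σ π r² h` over shoots, entering
models as mean-centred √volume.

**Climate.** April daily mean temperatures from ≥ 1 station, averaged
day-wise across stations, reduced to the April mean, the within-April
variance, and the count of frost days (daily mean < 0 °C, a strict
definition since only daily means are ingested). Stations need ≥ 80% of
April days (configurable); gaps are ignored. April means are centred across
study years so reaction-norm intercepts are trait values in an average year.

## Models

### Reaction-norm model set (hypothesis 1)

Three nested Gaussian mixed models of FFD on the centred yearly predictor
`T_j` (April mean by default; April variance or frost days as config
switches sharing the same code path), all with a year random intercept
`u_j ~ N(0, σ_year²)`:

* **m0** `FFD_ij = μ + β T_j + u_j + ε_ij`
* **m1** adds individual intercepts `a_i`
* **m2** (RRMM) adds correlated individual slopes:
  `FFD_ij = (μ + a_i) + (β + b_i) T_j + u_j + ε_ij`,
  `(a_i, b_i) ~ N(0, Σ)` with sds `σ_int`, `σ_slope` and correlation `ρ`.

Models are compared by LOOIC (PSIS-smoothed leave-one-out, deviance scale,
lower better) with pointwise conditional log-likelihoods; Pareto-k
diagnostics are reported (isolated high k values are expected for
single-observation individuals in hierarchical models). BLUPs are posterior
means of the individual deviations; reported values add the population fixed
effect. Bayesian R² is `var(fitted)/(var(fitted) + σ²)` per draw, with
fitted values including all random effects.

### Bivariate trait–fitness model (hypothesis 2)

FFD (Gaussian, as m2) and mean fitness across years (negative binomial, log
link, one observation per individual) share one latent trivariate-normal
individual effect `(a_i, b_i, w_i)` with a free 3×3 covariance; fitness gets
a plant-size fixed effect (removable by switch), FFD keeps the year
intercept. Mean fitness values are real-valued averages and are scored with
the continuous (gamma-function) negative-binomial density — the documented
alternative to rounding.

Selection summaries follow the Lande–Arnold framework on reaction-norm
traits, on the latent log-fitness scale without relativizing fitness (an
optional mean-standardization is provided but off by default):
differentials `S = (cov(w,a), cov(w,b))` (total selection) and gradients
`β = P⁻¹S` with `P` the 2×2 trait covariance (direct selection), computed
**per posterior draw** and then summarized by posterior mode (Gaussian KDE,
Silverman bandwidth) and 95% HPD (shortest interval). Draws with numerically
singular `P` are excluded and counted; > 1% excluded aborts. Because slopes
are negative, a positive slope gradient means selection for *decreased*
plasticity.

### Yearly ZINB selection model (hypothesis 3)

Yearly intact-seed counts follow a zero-inflated negative binomial. Count
part (log link) and zero part (logit link) share the covariate set —
plasticity, April temperature, their interaction, plant size — and each
carries its own individual random intercept. `P(0) = π + (1−π)(φ/(φ+μ))^φ`.
Plasticity is the BLUP slope residualized (OLS) on the BLUP intercept,
making it exactly orthogonal to average flowering time; the raw BLUP slope
is a switch. BLUPs enter as fixed known covariates (point estimates), the
choice shown to give less biased selection estimates than propagating BLUP
uncertainty; refitting over posterior BLUP draws emulates the propagating
variant when needed.

Marginal predictions report `1 − logistic(η_zero)` — the probability of any
seeds — on a plasticity grid at the mean April temperature of each empirical
quartile of study years, non-focal covariates at their means and random
effects at zero, averaged over draws with HPD bands. A grid outside the
observed plasticity range triggers an extrapolation warning.

**Censoring sensitivity** refits the bivariate selection model keeping only
individuals with ≥ k flowering events (k = 1…4); thresholds leaving < 10
individuals are skipped with a note.

## Posterior computation

No probabilistic-programming backend is assumed; the samplers are authored
here and emit labelled draws plus pointwise log-likelihoods as
`arviz.InferenceData`, so R-hat, effective sample size, PSIS-LOO and HDI all
come from arviz. Any sampler with that contract could be substituted.

* **Gaussian models (m0/m1/m2):** conjugate Gibbs for fixed effects, year
  effects, residual/year variances and individual deviations. Two
  ingredients make the chain mix at these data densities (~3 events per
  individual): (i) exact *recentring* moves along the likelihood-flat
  directions (intercept vs mean year effect, slope vs the year-effect
  component along T, fixed effects vs individual-effect means), and (ii) a
  *collapsed* Metropolis update of the individual covariance with the
  deviations integrated out analytically (rank-2 Woodbury forms), followed
  by a conjugate redraw of the deviations. Plain conjugate cycling of
  (deviations | Σ) and (Σ | deviations) is catastrophically slow here.
* **Bivariate model:** the same FFD machinery, plus: latent fitness
  intercepts updated by an independence Metropolis step at the conditional
  mode (the NB-plus-normal conditional is globally log-concave, so a few
  Newton steps plus a slightly inflated Gaussian proposal give near-1
  acceptance); the fitness-side globals (fitness intercept, size effect,
  log dispersion, and the fitness row of the covariance Cholesky factor)
  updated by slice sampling of their *marginal* posterior with the latent
  intercepts integrated out by 9-node Gauss–Hermite quadrature. The
  marginalization matters: with one fitness observation per individual,
  latent heterogeneity (σ_w) and NB overdispersion (φ) are only weakly
  separable and form a long posterior ridge that blocks latent-conditional
  updates. Slice directions follow the principal axes of an adaptively
  learned covariance (adaptation frozen after burn-in).
* **ZINB model:** slice updates along learned axes for each coefficient
  block (count + log φ; zero part), vectorized random-walk Metropolis for
  the per-individual intercepts, conjugate variance refreshes plus
  non-centred scale slices so small variances cannot trap the chain, and
  intercept recentring moves.

**Priors.** Fixed effects `N(0, 1000²)`. Year and residual variances
inverse-gamma(0.01, 0.01). For the m2 individual covariance:
half-Student-t(3) on the sds (scale 10 days for intercepts, 2.5 days/°C for
slopes) and a uniform prior on the correlation — weakly informative on each
parameter's natural scale, with mass at zero so a truly absent variance
component can be diagnosed. The bivariate 3×3 covariance instead uses
inverse-Wishart(5, I), which its sampler needs for the conjugate conditional
refresh; with several hundred individuals the data dominate it. The NB
dispersion has a log-normal(0, 2²) prior. A sensitivity flag (doubling prior
scales) is a config-level rerun.

**Defaults.** 4 chains × 4000 iterations, 1000 burn-in, thinning 2 (6000
retained draws); convergence requires split R-hat < 1.05 and N_eff/N > 0.1
for every parameter, otherwise the fit carries an explicit warning. Tests
and the acceptance script use reduced runs (2 chains × 600–1500) chosen so
the whole suite completes in minutes on one core; posterior means are stable
at those lengths even where the N_eff ratio of the weakly identified
fitness-dispersion ridge stays below the reporting threshold.

## Synthetic-data generator

The generator is first-class, tested code. Defaults define the study regime
the estimators target:

| quantity | default | note |
|---|---|---|
| individuals × years | 800 × 22 | two survey blocks with a gap |
| flowering events / individual | geometric, mean 3.3, clipped to span | |
| FFD: μ, β | 58.591 d, −2.375 d/°C | |
| σ_int, σ_slope, ρ | 1.555, 0.783, 0.800 | |
| σ_year | 5.160 d | |
| σ_resid | 4.66 d | calibrated, see below |
| April mean | N(5.0, 1.3²) °C | among-year |
| daily within-April sd | 3.0 °C | drives frost days |
| fitness: w0, size effect | 0.791, 0.040 | count part, log link |
| latent fitness sd, corr(a,w), corr(b,w) | 1.240, −0.448, 0.162 | |
| NB dispersion φ | 2.0 | not externally constrained |
| zero part | 1.010, −1.197 (plasticity), 0.083 (temp), 0.804 (interaction), −0.042 (size), sd 0.176 | |

`σ_resid` is not externally constrained; it is set by a closed-form
calibration so that the reaction-norm + year structure explains ≈ 0.645 of
FFD variance at the defaults:
`R² = (σ_int² + σ_year² + (β² + σ_slope²)σ_T²) / (… + σ_resid²)`, giving
σ_resid = 4.66 d at σ_T = 1.3 °C. The April-mean sd of 1.3 °C is a
realistic among-year value for a southern-Scandinavian April and is the
value the calibration assumes. Daily series are synthesized around each
year's mean and re-centred, so frost-day counts correlate negatively with
the April mean as in real spring climate (the directional property the
tests assert).

Zero-part extras `zi_intercept_effect` and `zi_intercept_temp_effect`
(coefficients on `a_i` and `a_i × T_j`, both 0 by default) emulate
(temperature-dependent) selection on mean flowering time. They exist because
the documented sign-reversal phenomenon — raw-slope plasticity showing the
*opposite* temperature interaction from residualized plasticity — requires
selection on flowering time that varies with temperature: a purely
main-effect preference for early flowering projects onto the plasticity main
effect, not the interaction. The reversal scenario in the tests sets
`zi_intercept_temp_effect = −1` (early flowering favoured more strongly in
cold springs).

The survey simulator writes visit records on a 5-day grid whose flower
counts and bud stages are constructed to be consistent with the dating rule,
so noise-free surveys recover the true FFD exactly (up to rounding) and
noisy ones within ~2 days; grazing injection produces `ffd_is_expected`
events.

**What the generator does not emulate:** spatial structure, survival and
skipped-flowering dynamics (the event schedule is exchangeable across
years), pollination and seed-predation mechanisms, within-April temperature
autocorrelation, and any dependence of plant size on phenology. Passing
recovery tests therefore show the estimators work *under the stated
generative model at the stated information density* — not that real surveys
satisfy those assumptions.

## Known limitations

* With ~3.3 events per individual and σ_resid ≈ 4.7 d, per-individual
  reliability caps the correlation between BLUPs and true deviations near
  0.5–0.6 *regardless of sample size*; slope BLUPs, and especially
  residualized slopes, are strongly shrunken. Downstream models that use
  BLUPs as covariates (the ZINB model) therefore see attenuated plasticity
  measures, and their individual random intercepts absorb the unexplained
  part — their variance estimates exceed the generating value by
  construction. Sign and credibility of the interaction are the robust
  quantities, and those are what the tests assert.
* σ_w (latent fitness heterogeneity) and φ (NB overdispersion) are only
  weakly separable with one mean-fitness value per individual; their
  posteriors are wide and strongly correlated. Selection covariances remain
  well identified.
* The bivariate model fits mean fitness as negative binomial while the
  generator produces it by averaging zero-inflated yearly counts — a
  deliberate mirroring of the analysis pipeline's own approximation, so
  latent-scale "truth" values are attenuation targets, not exact ones.
* Exact zero variance components sit on the prior boundary; the half-t
  priors make near-zero posteriors attainable but upper CI bounds under a
  true null remain prior-influenced at weak information.
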