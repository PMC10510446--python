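# plastsel

**Phenotypic selection on thermal reaction norms of flowering phenology.**

Long-term phenology surveys follow marked plants across decades: each spring
an individual flowers on some day (its *first flowering day*, FFD, counted in
days after the vernal equinox), and each individual's FFD responds to spring
temperature along its own *reaction norm* — an intercept (average timing) and
a slope (thermal plasticity, days advanced per °C; negative, since warm
springs mean earlier flowering). `plastsel` is a toolkit for asking, with
such data, the three questions evolutionary ecologists ask of plasticity:

1. **Do individuals differ** in average flowering time and in plasticity?
   A set of nested random-regression mixed models (RRMM) of FFD on
   mean-centred April temperature `T_j`, with a year random intercept:

   `FFD_ij = (μ + a_i) + (β_T + b_i) T_j + u_j + ε_ij`,
   `(a_i, b_i) ~ N(0, Σ)`,

   compared by LOOIC (PSIS leave-one-out), with per-individual BLUPs.
2. **Is there selection** on intercepts and slopes? A bivariate
   trait–fitness model couples the Gaussian FFD submodel with a
   negative-binomial model of mean intact-seed production through one latent
   trivariate individual effect `(a_i, b_i, w_i)`. In the Lande–Arnold
   framework, selection differentials are `S = (cov(w,a), cov(w,b))` and
   gradients `β = P⁻¹S` (with `P` the trait covariance), computed per
   posterior draw and summarized by posterior mode and 95% HPD interval.
3. **Does spring temperature shape selection on plasticity?** Yearly seed
   counts follow a zero-inflated negative binomial whose zero part contains
   a plasticity × April-temperature interaction (plasticity = the BLUP
   slope residualized on the BLUP intercept, so it is orthogonal to average
   timing); marginal predictions give the probability of producing any
   seeds across plasticity and temperature.

The package also ingests raw survey records (interval-censored FFD dating
from 5-day visits, expected FFD for plants grazed before flowering, plant
volume, April climate summaries from station data) and ships a
synthetic-data generator that reproduces the statistical structure of a
22-year, ~800-individual field study — so every stage is testable without
any field data. MCMC samplers (conjugate Gibbs plus collapsed/slice
Metropolis-within-Gibbs) are built in; diagnostics, LOO and HPD intervals
come from arviz. See `docs/methods.md` for the models, priors and samplers.

## Worked example

Simulate a study at the default regime, fit the model set, and quantify
selection:

```python
from plastsel import (SimulationTruth, simulate_dataset, fit_model_set,
                      compare_looic, bayes_r2, extract_blups,
                      fit_bivariate_rrmm, selection_gradients, SamplerConfig)
from plastsel.simulate import StudyDesign

truth = SimulationTruth(design=StudyDesign(n_individuals=300, n_years=22))
ds = simulate_dataset(truth, seed=7)
cfg = SamplerConfig(chains=2, iterations=1000, burn_in=500, thin=1, seed=11)

fits = fit_model_set(ds.events, ds.climate, config=cfg)
print(compare_looic(fits)[["model", "looic", "delta_looic", "delta_se"]])
m2 = fits["m2"]
print(f"slope: {m2.posterior_mean('beta'):.2f} days/degC, "
      f"sd(slope): {m2.posterior_mean('sd_ind_slope'):.2f}, "
      f"R2 = {bayes_r2(m2)['mean']:.3f}")

bfit = fit_bivariate_rrmm(ds.events, ds.individuals, ds.climate,
                          "per_event", cfg)
print(selection_gradients(bfit).table()[
    ["coefficient", "posterior_mode", "hpd_low", "hpd_high"]])
```

Output (seeds as above):

```
  model        looic  delta_looic   delta_se
0    m2  6255.755254     0.000000   0.000000
1    m1  6259.889232     4.133978   5.243436
2    m0  6293.485623    37.730368  13.329234
slope: -3.19 days/degC, sd(slope): 0.82, R2 = 0.628
      coefficient  posterior_mode   hpd_low  hpd_high
0  beta_intercept       -0.702065 -1.364947 -0.257751
1      beta_slope        0.831400 -0.104603  2.017783
```

Reading it: the full RRMM (`m2`) wins the LOOIC comparison — individuals
differ in both intercept and slope; the population flowers ~3 days earlier
per °C of April warming. The negative intercept gradient is direct selection
for earlier average flowering; the positive slope gradient (slopes being
negative) points toward selection for *decreased* plasticity, here with an
HPD that still brushes zero at 300 individuals.

The same pipeline runs from the shell:

```bash
plastsel simulate --out data/ --seed 1
plastsel run config.yaml      # simulate/ingest -> models -> selection -> yearly
plastsel report output_dir/   # markdown report with figures
```

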