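# paleobear

Spatially explicit Bayesian reconstruction of Holocene brown bear
(*Ursus arctos*) extinction and colonization dynamics in Europe from
imperfect archaeofaunal detection data, with an embedded path analysis
separating the direct and human-mediated effects of climate on
extinction risk, and a comparative meta-analysis of reproductive rate
across extant bear populations.

## Who this is for

Quantitative ecologists and archaeozoologists working with
detection/non-detection data over deep time: dated excavation records
tell you where a species *was found*, not where it *was* — detection
depends on how much bone a site preserved (calibrated here by ubiquitous
prey species as negative controls) and on the kind of site.  The package
provides the full pipeline — covariate derivation, state-space
metapopulation model, Bayesian variable selection, MCMC engine,
diagnostics, and a synthetic-data generator with known ground truth — so
every stage is testable without access to the original compiled
databases.

## The model

Latent occupancy `z[s,t]` of 100-km grid cell `s` in period `t` follows
a two-state Markov process.  Per-year extinction and colonization rates
are mapped onto per-interval probabilities through the Kolmogorov
forward equations, because the seven analysis periods are unequal
(interval lengths Δt = 3500, 3500, 2250, 900, 310, 52.5 years between
period midpoints):

    p_γ = 1 − (r_φ + r_γ·e^{−(r_φ+r_γ)Δt})/(r_φ + r_γ),   p_φ analogous
    log r_φ[s,t] = β_0 + β_LU·LU + β_NPP·NPP + β_WT·WT + β_ELE·ELE
    log r_γ[s,t] = Σ_{s′≠s} e^{−α·d(s,s′)} z[s′,t]            (λ ≡ 1)

with least-cost-path distances `d`, mean dispersal distance `1/α`
(Gamma(3,1) prior, mode 2 ⇒ 50 km on the 100-km grid).  Observations
are Bernoulli: `y_i ~ Bern(z·p_i)` with
`logit p_i = β_p,0 + β_p,NSP·ln NSP_i + β_p,TYP`, and perfect detection
(range maps) in the last two periods.  Covariates are linked by three
Gaussian regressions (WT←ELE; NPP←WT,ELE; LU←NPP,WT,ELE) with cell
random effects; the ten path slopes carry spike-and-slab priors
(spike precision 3600, shared slab sd ~ U(0,20), prior inclusion 0.5),
giving 2¹⁰ = 1,024 candidate models searched by MCMC, summarized by
inclusion probabilities and Bayes factors, and decomposed per posterior
draw into direct and mediated (indirect) effects.  NPP comes from the
Miami model `NPP = min(3000(1+e^{1.315−0.119T})⁻¹, 3000(1−e^{−0.000664P}))`.
The meta-analysis models reproductive rate RR = LS/LI across bear
populations with a gamma identity-link mixed model in body mass, NPP
and wintering-season temperature, weighted by sample sizes.

See `docs/methods.md` for assumptions, priors, sampler composition and
limitations.

## Worked example

Generate a synthetic study (12×12 grid, the seven Holocene periods,
~1,500 excavation records with the observed site-type mix), fit it, and
decompose effects:

```sh
paleobear simulate --seed 7 --out study
paleobear fit --data study --out fit --seed 7 --chains 2 \
    --iterations 400 --burn-in 150 --thinning 5
paleobear decompose --fit fit --out effects
head -5 effects/effects.csv
```

prints (this short demo run, values rounded here for display; generating truth
β_LU=0.8, β_WT=0.9, β_NPP=−0.4, β_ELE=−0.3):

```
INFO paleobear: wrote synthetic study (1509 records) to study
INFO paleobear: fit complete: 100 pooled draws -> fit
INFO paleobear: effect decomposition written to effects/effects.csv
effect_name,kind,mean,ci_low,ci_high,inclusion_prob,bayes_factor
direct_lu,direct,1.052,0.575,1.607,1.0,199.0
direct_wt,direct,1.020,0.613,1.597,1.0,199.0
direct_npp,direct,-0.629,-0.993,-0.267,0.99,99.0
direct_ele,direct,-0.277,-0.600,0.021,0.83,4.88
```

Each row is one effect on the extinction rate: the posterior mean and
95% interval of the standardized slope, the SSVS posterior inclusion
probability of that path, and its Bayes factor (posterior odds /
prior odds).  Here the land-use and winter-temperature paths are
selected with certainty and the credible intervals bracket the
generating truth; longer chains (the study configuration is 10 chains ×
4,500 iterations) tighten the intervals.  `fit/` also contains the
posterior draws (long and wide CSV), the occurrence-probability surface
`P(z[s,t]=1)` and the median net trend `log10(r_φ/r_γ)` per cell-period
(positive = net range loss); `paleobear diagnose` tabulates
rank-normalized split R-hat and effective sample sizes, and
`paleobear report` pools surfaces across the 2×2 scenario factorial
(land-use intensity × Asian colonization).

The same pipeline is available as a library:

```python
from paleobear import (SyntheticTruth, generate_study, FitData,
                       MCMCConfig, run_mcmc, decompose_effects)
study = generate_study(SyntheticTruth(seed=7))
data = FitData(cov=study["covariates"], distances=study["distances"],
               records=study["records"], scheme=study["scheme"],
               grid_shape=(12, 12))
draws = run_mcmc(data, MCMCConfig(n_chains=4, n_iter=3000, burn_in=1200,
                                  thinning=18, seed=0))
print(decompose_effects(draws.slope_draws()).summary)
```

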