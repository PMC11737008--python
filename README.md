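# grassipm

Demographic analysis for factorial climate × land-management grassland
experiments: size-structured vital-rate regressions, a two-stage integral
projection model (IPM), bootstrap and plot-level permutation inference,
parameter sensitivities, and life-table-response-experiment (LTRE)
decomposition — plus a synthetic census generator with known ground truth
so every stage of the pipeline is testable without field data.

It is aimed at plant population ecologists working with longitudinal
individual censuses from replicated field experiments (here: climate ∈
{ambient, future} × management ∈ {grazing, mowing}, five replicate plots
per combination, subplots nested in plots, annual April-to-April
transitions plus an autumn seedling count).

## The model

Individuals are structured by log size z on [L, U], with a discrete class
M of overwintering spring seedlings:

    n(z′, t+1) = M(t)·B·η(z′) + ∫_L^U [ S(z)·G(z′|z) + P(z)·F(z)·θ_f·B·η(z′) ] n(z, t) dz
    M(t+1)     = ∫_L^U P(z)·F(z)·θ_s · n(z, t) dz

with logistic survival S(z) and flowering P(z), Gaussian growth G(z′|z)
(SD σ_G), log-link Poisson seed output F(z), per-seed fall and spring
recruitment rates θ_f and θ_s, establishment probability B (used for both
seedling pathways, since April recruits cannot be assigned to a cohort),
and a Gaussian recruit-size density η. Midpoint-rule discretisation on 200
bins gives a 201×201 nonnegative matrix whose dominant eigenvalue is the
asymptotic population growth rate λ; log λ > 0 means projected growth.

On top of the fitted IPMs the package computes bootstrap distributions of
λ (default 1000 replicates, resampling individuals and subplot-years),
permutation tests that reassign treatment labels across whole plots
(default 1000 permutations, exhaustive when possible), finite-difference
sensitivities ∂λ/∂α_i for all 14 parameters (forward step 0.001), and the
LTRE decomposition δ_i = (α_i,1 − α_i,2)·∂λ/∂α_i grouped into five
demographic processes and scaled to proportional influence. See
`docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

```python
from grassipm import PlantDemographyModel, default_truth

model = PlantDemographyModel.from_truth(default_truth(seed=1))
res = model.fit()
print(res.summary())
```

```
Plant demography IPM fit: species='synthetic'
log-size domain [-2.617, 6.089], 200 bins, eviction='renorm'

stratum                    lambda    log lambda
ambient_grazing             0.8741      -0.1346
ambient_mowing              0.8708      -0.1384
future_grazing              0.8661      -0.1438
future_mowing               0.8784      -0.1297
ambient                     0.8723      -0.1366
future                      0.8720      -0.1369
grazing                     0.8701      -0.1391
mowing                      0.8745      -0.1341

parameter            ambient_graz  ambient_mowi  future_grazi  future_mowin  ...
surv_int                  0.2002        0.1500        0.1927        0.1637  ...
surv_slope                0.7163        0.7369        0.6936        0.6944  ...
...
```

The four combination strata are fitted jointly with full
size × climate × management interactions; the main-effect rows (ambient,
future, grazing, mowing) average the two relevant combinations' parameters
before the kernel is rebuilt. Here the simulated population is slightly
declining in every stratum (log λ ≈ −0.13 to −0.14), and the fitted
survival intercept/slope for ambient grazing (0.20, 0.72) recover the
generating truth (0.2, 0.7).

Downstream analyses hang off the results object:

```python
res.bootstrap_lambda("ambient_grazing", n_boot=1000, seed=1)   # sd of log lambda
res.permutation_test("management", within={"climate": "ambient"})
res.sensitivity("ambient_grazing")                             # 14 derivatives
r = res.ltre("ambient_grazing", "ambient_mowing")
r.scaled_process_contributions
# {'survival': +0.064, 'growth': -0.038, 'reproduction': +0.053,
#  'recruitment': +0.013, 'establishment': +0.018}   (delta lambda = 0.0033)
```

A one-command pipeline is available as a CLI:

```sh
grassipm simulate --seed 3 --out census/          # synthetic census + truth YAML
grassipm all --config config.yaml --out run/      # fit -> IPM -> inference -> report
```

producing tidy CSVs (parameters, λ table with bootstrap summaries, the six
treatment contrasts' permutation p-values, sensitivities, all pairwise
LTREs), figures, and a manifest sufficient to reproduce the run.

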