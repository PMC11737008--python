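# Methods

## Scope and model

`grassipm` implements the demographic analysis pipeline for a 2×2 factorial
grassland experiment crossing climate (ambient vs. a hotter/drier "future"
treatment) with land management (extensive sheep grazing vs. mowing), with
five replicate plots per treatment combination and census subplots nested in
plots. The annual life cycle runs April to April with one additional autumn
seedling count; the species modelled are perennials without a persistent
seed bank, so there is no seed-bank stage.

The population model is a two-stage integral projection model (IPM): a
discrete class M of overwintering spring seedlings and a continuous class
n(z) of established plants structured by z, the natural log of plant size
(cm² basal area or leaf count, depending on species). Seven vital-rate
components drive the model, 14 parameters in all:

| component | model | parameters |
|---|---|---|
| survival S(z) | Bernoulli, logit link | α_S, β_S |
| growth G(z′\|z) | Normal in z′ given z | α_G, β_G, σ_G |
| flowering probability P(z) | Bernoulli, logit link | α_P, β_P |
| seed number F(z) | Poisson, log link | α_F, β_F |
| fall / spring recruitment | per-subplot seedlings-per-seed ratio | θ_f, θ_s |
| establishment | per-subplot new-plants-per-seedling ratio | B |
| recruit size η(z′) | Normal | η̄, σ_η |

The projection equations are

    n(z′, t+1) = M(t)·B·η(z′) + ∫_L^U [ S(z)·G(z′|z) + P(z)·F(z)·θ_f·B·η(z′) ] n(z, t) dz
    M(t+1)     = ∫_L^U P(z)·F(z)·θ_s · n(z, t) dz

B multiplies both seedling pathways because the April census cannot tell
fall-derived from spring-derived recruits. The continuous integral is
discretised with the midpoint rule on 200 equal bins by default, giving a
201×201 nonnegative iteration matrix whose dominant eigenvalue is the
asymptotic growth rate λ; log λ (natural log) is the reported scale.

Note the spring-seedling production integral is weighted by the current
size distribution n(z, t): this is the only reading that leaves the model a
linear operator, and it is what the implementation uses.

## Estimation

All regressions operate on log size. Under the default factorial
stratification each regression is fitted once, jointly, with full
size × climate × management interactions (a saturated treatment coding), and
per-combination (intercept, slope) pairs are read off as coefficient
contrasts; this is numerically identical to independent per-combination
fits but yields one covariance per component. Main-effect parameter sets
(ambient, future, grazing, mowing) are the arithmetic means of the two
combination parameter vectors sharing the level, applied identically to all
14 parameters; main-effect λ comes from the averaged parameters, never from
averaging λ.

Fits use statsmodels GLMs (Binomial and Poisson) and OLS. Design choices
that the data force:

* **Separation.** Small strata can have all-or-none outcomes; Bernoulli
  fits then fall back to a ridge-penalised GLM (penalty 1e-4) with a
  warning, which keeps fitted probabilities finite and near the boundary.
* **Seed counts.** Per-individual seed output is estimated as
  seed heads × mean seeds-per-head among lab samples from the same plot
  (species-wide mean when a plot has no samples). Because that plot mean is
  itself estimated from a handful of heads, its error is shared by every
  individual in the plot; the Poisson seed model therefore reports
  plot-clustered robust standard errors rather than classical Poisson SEs.
* **Grouping term.** The experiment nests plots in climate units. The
  Gaussian growth model can carry a random plot intercept
  (`plot_random_effect=True`, statsmodels MixedLM), with population-level
  coefficients extracted and an OLS fallback when the variance component is
  degenerate. Bernoulli/Poisson analogues of that random term are not
  fitted; the IPM consumes one fixed parameter vector per stratum either
  way, and the treatment-coded fixed effects are what enter the kernel.
* **Discrete rates.** θ_f, θ_s and B are means of per-subplot-year ratios
  over subplots with nonzero denominators (zero-denominator subplot-years
  are excluded and logged); a pooled ratio-of-totals estimator is available
  via `aggregation="pooled"`. B is a proportion; estimates above 1 (more
  new plants than counted seedlings, which field data can produce) are
  clipped to 1 with a warning.
* **Quasi-extinction.** A treatment combination with fewer than 25
  individuals and fewer than 10 flowering individuals in the reference
  census year (default: the latest) is excluded from fitting and reported.
  Both inequalities are strict: exactly 25 or exactly 10 keeps the stratum.
  If a combination is excluded, main effects that need it are unavailable.
* **Pooling.** Years are pooled by default; `by_year=True` fits one IPM per
  annual transition, taking each transition's recruit sizes from the next
  spring's first-recorded plants (so the final transition, which has no
  following census, is skipped).

## Kernel numerics

* **Integration limits.** L and U default to the species' observed log-size
  range padded by 0.5·σ_G on each side, shared across strata so λ values
  are comparable on a common domain.
* **Eviction.** The growth and recruit-size densities are renormalised to
  unit mass on [L, U] (`eviction="renorm"`, the default), so no survival
  probability is silently lost over the boundaries; with renormalisation the
  survival–growth block's column sums equal S(z_j) to machine precision.
  `eviction="none"` keeps the raw truncated densities. A density narrower
  than the mesh can resolve (σ far below the bin width, e.g. from a
  degenerate fit on zero-variance data) renormalises to a point mass in the
  bin containing its mean — the correct σ→0 limit.
* **Eigenvalues.** λ is the spectral radius from a dense nonsymmetric
  eigendecomposition; for these nonnegative matrices the dominant
  eigenvalue is real (asserted). A normalised power iteration cross-checks
  it to relative 1e-8, warning instead of failing when a reducible matrix
  stalls the iteration.
* **Sensitivities.** ∂λ/∂α_i is a forward finite difference with absolute
  step 0.001 on every parameter (the production setting; step and a central
  scheme are configurable). A perturbation that violates a parameter
  constraint (e.g. a negative SD) is reported as NaN with a warning, never
  silently skipped.

## Inference

* **Bootstrap** (default 1000 replicates): individual records are resampled
  with replacement (the sampling unit of the regression rates) and
  subplot-years with replacement (the unit of the discrete rates); all
  vital rates are refitted and the kernel rebuilt on the stratum's fixed
  [L, U]. Main-effect strata resample and refit each of their two
  combinations and average parameters. Replicates whose refit fails are
  dropped and logged; more than 10% failures is a hard error.
* **Permutation tests** (default 1000 permutations): treatments are applied
  at the plot scale, so whole plots are the exchangeable units. The null is
  built by reassigning the tested factor's labels across plots (keeping
  plot membership intact), refitting both groups and recomputing
  T = λ_A − λ_B. For equal group sizes the two-sided statistic |T| is
  invariant under swapping the groups, so complementary assignments form
  one equivalence class and the effective space is C(n, k)/2 classes (126
  for two groups of five plots); when that count is at most n_perm the
  classes are enumerated exhaustively and the p-value is exact, with level
  ⌊α·N⌋/N (0.0476 at α = 0.05, N = 126). Otherwise random reassignments
  are sampled and the two-sided p-value uses the add-one estimator
  (1 + #{|T*| ≥ |T|}) / (1 + n_perm), which cannot return 0. At least two
  plots per group are required; assignments whose groups cannot be fitted
  are dropped and reported, with a hard error above 10%.
* **LTRE.** For a pair of strata, Δλ = λ_A − λ_B is decomposed as
  δ_i = (α_i,A − α_i,B)·∂λ/∂α_i with sensitivities evaluated at the
  elementwise midpoint parameter set (configurable to either endpoint).
  Contributions are grouped into five processes — survival, growth,
  reproduction (flowering + seed number), recruitment (θ_f, θ_s) and
  establishment (B, η) — and scaled by Σ|δ_i|, which preserves sign while
  making absolute contributions sum to 1.
* **Effect sizes.** Management effect = λ_grazing − λ_mowing; climate
  effect = λ_ambient − λ_future; positive values mean a grazing / ambient
  preference. The cross-species phenology regressions are simple OLS of
  effect sizes on flowering duration (end − start + 1 months, inclusive)
  and mean flowering start month, refusing to fit fewer than 3 species.

## The synthetic census generator

The generator is first-class, tested code: it produces censuses with
exactly the statistical structure the estimators assume, plus the
ground-truth parameter set, so every stage has a known answer. Defaults
describe one realistic study: initial cohorts of 1141/1079/1075/1353
individuals for the four combinations (patterned on the most abundant
study species), 5 plots × 8 subplots per combination, 4 annual transitions,
initial log sizes N(1, 1), and a shared vital-rate truth (survival
logit 0.2 + 0.7z; growth 0.4 + 0.8z, σ = 0.6; flowering logit −2 + z;
seeds exp(2 + 0.5z); θ_f = 0.03, θ_s = 0.015, B = 0.3; recruits
N(−0.5, 0.4²)) chosen once to give a mildly sub-replacement to stable
population in the simulated size range, matching the order of magnitude of
λ in managed grassland perennials.

Generation per year: Bernoulli survival and flowering at the individual's
current z; survivors grow Normally; expected seed output exp(α_F + β_F z)
is realised as seed heads × per-head seed counts. Head number is the
stochastically rounded expected head load μ/m (keeping E[heads] = μ/m and
hence E[seeds] = μ exactly), and per-head seed counts are negative binomial
(mean 15, size 40, CV ≈ 0.3). This puts the seed-count noise where the lab
protocol can see it — in the per-head draws — rather than in head-count
clustering, so the heads × plot-mean estimation path is informative at
field sample sizes; it is the one place where the generator is deliberately
tamer than the most pessimistic reading of real data, and coarser
individual-level overdispersion can be restored by lowering the per-head
dispersion. The lab table carries 2 sampled heads per plot at each of two
reproductive-season visits per transition year, pooled. Subplot seed totals
are thinned binomially into fall and spring seedlings (Poisson when a rate
exceeds 1, which real seedling/seed ratios can), seedlings become new
plants binomially with probability B, and recruits enter the next census
with Normal log sizes. A single integer seed drives per-combination,
per-year substreams, so regeneration is bit-identical.

What the generator does **not** emulate: plot-level random effects on the
vital rates (plots differ only by sampling noise), spatially explicit
individuals, drought years, within-year management events, a seed bank, and
density dependence. Passing recovery tests therefore demonstrate estimator
correctness under the model's own assumptions, not robustness to
misspecification.

## Problem sizes used in the checks

The recovery check fits 5000 individuals per combination on 5 plots
(≈58k individual-transitions over 4 years) and requires every parameter
within 0.1 (or 2 SE) of truth and |Δ log λ| < 0.05 against the
ground-truth kernel on the same domain. The permutation calibration runs
200 null censuses (150 individuals per group, 5 plots per group, 2
transitions) at 200 permutations each with 30-bin kernels — the test's
level is a property of label exchangeability, not of census size or mesh
resolution, so a small design measures it cleanly. The bootstrap
degeneracy check uses a census whose rows are all identical, for which any
resample reproduces the data and sd(λ) must be exactly 0.

## Known limitations

* Bernoulli/Poisson mixed models (random plot intercepts) are not fitted;
  only the Gaussian growth component offers the random term.
* The Poisson seed model is a working model under overdispersion: point
  estimates are consistent, and clustered SEs absorb plot-level
  seeds-per-head error, but individual-level overdispersion beyond that is
  not modelled (no negative-binomial regression or zero inflation).
* Eviction correction is renormalisation only; no size-ceiling or
  boundary-absorption alternatives.
* No stochastic-environment λ_s, transient dynamics, density dependence, or
  multiple-testing correction across species.
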