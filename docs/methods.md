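# Methods

## The model

The quantity of interest is the Weber fraction `w` of each species: the
proportional difference between two quantities needed for reliable
discrimination. `w` is never observed directly. What is observed is a table
of binary trials — an animal compared two quantities `n1` and `n2` and was
right or wrong — pooled over species, studies, subjects and task paradigms.

The psychophysical link is the linear-scale scalar-variability model: a
quantity `n` is represented as a Gaussian with mean `n` and standard
deviation `w·n`. Ordering two independent representations gives the probit
closed form

    P(correct) = Φ( |n1 − n2| / (w · sqrt(n1² + n2²)) ),

which depends on the pair only through its ratio (Weber's law), equals 1/2
for equal pairs, and approaches 1 for easy ratios. No lapse or guessing
parameter is included; paradigm-level shifts in difficulty are absorbed by
the task effect below.

Each trial carries a latent log Weber fraction assembled additively:

    log w_trial = β0 + β1·x[species]
                + σ_species·u[species]
                + σ_study·z_study + σ_subject·z_subject + σ_task·z_task

with one species-level predictor `x` per run (z-scored, so coefficients for
different predictors are on a common per-SD scale). The species-effect
vector `u` is multivariate normal with correlation

    M = λ·V + (1 − λ)·I,

where `V` is the phylogenetic correlation matrix (shared root-to-MRCA path
length divided by total tree depth, unit diagonal) and Pagel's λ ∈ [0, 1]
is fitted jointly with everything else. λ = 0 makes species exchangeable;
λ = 1 imposes the full Brownian-expected correlation. Study, subject and
task effects are independent normals scaled by half-normal scale
parameters; subjects are nested in species by the labelling convention
`species/subject_id`. Trial outcomes are Bernoulli with the probit accuracy
above. Equal-quantity trials are retained and contribute a constant
log(1/2).

`V` is normalized to a correlation matrix rather than left in time units:
the λ-mixture interpolates toward the identity, which only makes sense on
the unit-diagonal scale, and total tree depth would otherwise act as an
arbitrary multiplier absorbed by σ_species.

## Priors

All unstated by design elsewhere, chosen weakly informative and centred on
the plausible animal range (`w` roughly 0.1–1):

| parameter | prior | rationale |
|---|---|---|
| β0 | Normal(log 0.5, 1) | grand log-w centred on w = 0.5 |
| β1 | Normal(0, 1) | per-SD effect of a standardized predictor |
| σ_species, σ_study, σ_subject, σ_task | HalfNormal(1) | scales on log-w, order ≤ 1 |
| λ | Uniform(0, 1) | uninformative over the admissible range |

## Sampling

The posterior is explored with a No-U-turn sampler written for this
package: recursive tree doubling with slice sampling of trajectory states,
dual-averaging step-size adaptation (target acceptance 0.8), and windowed
diagonal mass-matrix estimation during warmup. The parameter vector is
unconstrained (logit λ, log scales, with the uniform/half-normal Jacobians
in the density); gradients are analytic, including the λ gradient through
the inverse and log-determinant of `M`. Species effects use a centered
parameterization `v ~ MVN(0, M)` scaled by σ_species — with thousands of
trials per fit the data dominate and centered geometry samples well;
study/subject/task effects are non-centered (`σ·z`). The
incorrect-response hazard φ(q)/Φ(−q) is computed via `erfcx` to avoid
catastrophic cancellation at extreme log-w.

Trials sharing (species, study, subject, task, ratio) are collapsed to
binomial counts before sampling; this is an exact likelihood rewrite that
cuts the per-gradient cost several-fold.

Convergence is assessed with split-chain rank-normalized Rhat (arviz); the
working convergence contract is max Rhat < 1.05 over all scalar
parameters, checked on every fitted run in the test suite. Chains run
sequentially with seeds spawned deterministically from the single
`ModelSpec.seed`; two runs with identical spec and data produce identical
draws. Fits warn when more than 10% of post-warmup transitions diverge.

## Synthetic data

The generator runs the same model forwards, so recovery tests are exact
self-consistency checks. The default structural scale mirrors the compiled
comparative literature — 33 species, 49 studies, 672 subjects — and the
`desk8` preset is the reduced scale used throughout testing: 8 species, 6
studies, 40 subjects, 50 trials per subject (~2000 trials), true
β0 = log 0.4, β1 = −0.3, λ = 0.8, σ_species = 0.5, and 0.25 for the other
three scales. Quantity pairs are drawn from a pool of twelve pairs used
widely in the animal literature (1v2 … 10v15), spanning ratios 1.1–3, the
range over which `w` in [0.1, 1] is identifiable from binary outcomes.
Studies are single-species when studies outnumber species (the literature
situation) and span species otherwise; each study carries one task
paradigm drawn from a 0.4/0.3/0.3 mix of controlled-array, sequential and
simultaneous paradigms.

Random trees come from a unit-depth coalescent (msprime) — exchangeable,
ultrametric, and reproducible under seed. The fixed 33-species tree in
`trees.py` is a synthetic stand-in assembled from rounded literature node
ages, with the two recent splits (robins at 3 Myr, dog/wolf at 0.015 Myr)
added by grafting.

What the generator does *not* emulate: species-specific procedural quirks
of individual studies, unbalanced designs beyond the cycling allocation,
task-specific Weber fractions (the model assumes one task shift shared
across species), ceiling/floor artefacts from non-binary scoring, and any
real predictor covariance structure (the synthetic predictor is
standard-normal, independent of the tree). Passing recovery tests
therefore demonstrate internal consistency of model + sampler, not
robustness to real-data misspecification.

## Recovery behaviour and problem sizes

All heavy checks run at `desk8` scale to keep the default test run in
minutes. At that scale the per-replicate probability that the β1 posterior
mean has the true sign is about 0.9 — with 8 species, a residual species
scale of 0.5 and phylogenetic correlation 0.8, a single draw of species
effects can tilt the realized species-level slope substantially, and the
posterior faithfully tracks the realized slope rather than the generating
coefficient. The recovery suite therefore runs 3 seeded replicates and
asserts at least 2/3 correct signs and 2/3 coverage of the truth by the
90% interval; the full 20-replicate experiment (thresholds 18/20 and
16/20) is the same code with a larger range. Because the fitted β1 acts on
the z-scored predictor, truth is compared on that scale
(β1_true · sd(x_sample)).

λ is weakly identified from 8 species: posteriors are pulled toward the
uniform prior mean, and the λ=0 vs λ=0.9 check asserts only the *ordering*
of posterior means on a shared tree, which is stable.

Simulation-based calibration runs 12 prior-draw replicates at a tiny scale
(8 species, 16 subjects, 320 trials) and checks coarse uniformity of the
rank statistics of β0 and β1 (χ², α = 0.01): a deliberately low-power but
honest screen for systematic posterior miscalibration.

## Numerical choices and edge cases

- Ultrametricity: tip-depth spread beyond relative 1e-6 warns and terminal
  branches are stretched to the mean depth (published supertrees carry
  rounding slack); it is never an error.
- `V` from any ultrametric tree is positive semidefinite; Cholesky
  factorizations add a 1e-10 jitter.
- PGLS for residual brain volume fixes λ = 1 (pure Brownian correlation):
  RBV is a precomputed predictor, not part of the joint fit, and the
  Brownian default keeps it free of circularity with the fitted λ.
- The log transform list (ECV, group size, home range, day journey, four
  neuron count/density columns) uses natural logs; % fruit and the two
  cognition scores stay on their native scales. The general-cognition
  score is negated so high = good.
- Neuron *count* imputation from brain mass applies only to primates and
  never overwrites a measured value; neuron *density* imputation is
  refused outright (density and number are decoupled in primates).
- `discrimination_bound` adds a 1e-9 fuzz before the ceiling so binary
  float representations of thresholds like 0.2 × 10 land on the intended
  integer.
- Species present in trial data but absent from the tree abort with an
  explicit KeyError; species missing the predictor of the current run are
  dropped for that run only.
- η = log w_trial is clipped to ±40 inside the sampler density; the prior
  keeps all posterior mass far inside the clip.

## Known limitations

- One predictor per run, by design; no joint multi-predictor model.
- λ applies to species effects only; no phylogenetic structure on study or
  subject effects.
- The three-level task factor assumes each paradigm shifts log-w equally
  across species.
- Desk-scale λ inference is prior-dominated; sharp λ statements need more
  species than the reduced test configurations use.
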