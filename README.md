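# phyloweber

Phylogenetic hierarchical Bayesian estimation of species Weber fractions
from binary quantity-discrimination trials.

## The problem

Many birds and mammals can tell 10 items from 15, but species differ in
how fine a contrast they resolve. That precision is summarized by the
Weber fraction `w`: the proportional difference between two quantities
needed for reliable discrimination (`w = 0.2` → 10 vs 12 is resolvable;
`w = 0.5` → only 10 vs 15). Comparative datasets compiled from the
literature are awkward for standard phylogenetic regression because `w` is
never observed — only binary trial outcomes are, pooled across studies,
subjects and task paradigms, and species are not independent data points.

This package fits the joint model that solves both problems at once. Under
the linear-scale scalar-variability model, a quantity `n` is represented
as a Gaussian with standard deviation `w·n`, giving the probit likelihood

    P(correct) = Φ( |n1 − n2| / (w · √(n1² + n2²)) ).

Each trial's latent log Weber fraction is

    log w = β0 + β1·x[species] + σ_sp·u[species]
          + σ_study·z_study + σ_subj·z_subj + σ_task·z_task,

where `x` is one standardized species-level predictor (neuron density,
brain volume, group size, ...) and the species effects `u` are
multivariate normal with correlation `M = λ·V + (1 − λ)·I` — `V` the
tree-implied correlation matrix and `λ` Pagel's phylogenetic-signal
parameter, fitted jointly. Everything is sampled with a No-U-turn sampler
(analytic gradients) and diagnosed with split-chain rank-normalized Rhat.

For whom: comparative cognition researchers who want species-level
psychophysical parameters (and their predictors) from pooled binary trial
data while controlling phylogeny, plus a fully synthetic test bed for the
method itself.

## Worked example

```python
import phyloweber as pw
from phyloweber.model import ModelSpec, fit, rhat, species_weber_summary
from phyloweber.reporting import coefficient_summary

# desk-scale synthetic study: 8 species, 6 studies, 40 subjects,
# 2000 trials; true beta1 = -0.3, lambda = 0.8
config = pw.desk8(seed=1)
tree = pw.simulate_tree(config.n_species, 1)
trials, predictors, truth = pw.simulate_dataset(tree, config)
cov = pw.tree_to_correlation(tree)

spec = ModelSpec(predictor_name="x", chains=2, warmup=500, draws=500, seed=11)
draws = fit(trials, predictors, cov, spec)
print(f"max Rhat {max(rhat(draws).values()):.4f}")
print(coefficient_summary(draws).round(3).to_string())
```

prints

```
max Rhat 1.0102
    mean   q2.5    q25    q75  q97.5  sign_consistent
x -0.424 -0.954 -0.576 -0.262  0.054            False
```

The coefficient posterior is centred near the generating effect on the
standardized scale (here −0.33 after multiplying β1 = −0.3 by the sample
SD of `x`): the model recovers a negative predictor effect on log `w`,
with an interval honestly wide for 8 species. The `sign_consistent` flag
marks whether the whole central 95% interval lies on one side of zero. A
no-predictor run of the same model yields per-species Weber fractions:

```python
spec0 = ModelSpec(chains=2, warmup=500, draws=500, seed=11)
weber = species_weber_summary(fit(trials, None, cov, spec0))
print(weber["q50"].round(3).head(3).to_string())
```

```
sp00    0.568
sp01    0.648
sp02    0.461
```

medians on the `w` scale (columns q2.5–q97.5 give the posterior
intervals). The same pipeline is available from the shell:

```sh
phyloweber simulate --preset desk8 --seed 3 --out sim/
phyloweber fit --trials sim/trials.csv --tree sim/tree.nwk \
    --predictors sim/predictors.csv --predictor x \
    --chains 4 --draws 1000 --warmup 1000 --seed 1 --out run1/
```

The numbered drivers under `analysis/` run the same steps as a narrative
pipeline (simulate → fit → recovery → report), writing tables under
`results/`.

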