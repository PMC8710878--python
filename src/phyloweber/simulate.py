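"""Synthetic trees, predictor tables and trial data with the model's structure.

The generator runs the hierarchical model forwards: species effects drawn
multivariate normal with correlation ``M = lambda * V + (1 - lambda) * I``,
study/subject/task effects drawn independent normal, a standard-normal
species predictor acting through ``beta1``, and every binary trial outcome
drawn Bernoulli with the linear-scale psychophysical accuracy.  Ground
truth is returned alongside the data, so parameter recovery can be tested
end to end without any external dataset.

The default configuration emulates the structural scale of the compiled
comparative literature — 33 species, 49 studies, 672 subjects — while
``desk8`` is the reduced desk-scale preset (8 species, 6 studies, 40
subjects, 50 trials each) used for recovery and convergence checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .phylogeny import PhyloTree, load_tree, tree_to_correlation
from .model import TASKS
from .psychophysics import predict_accuracy

#: quantity pairs spanning ratios ~1.1-3.0, the range over which Weber
#: fractions in [0.1, 1] are identifiable from binary outcomes
DEFAULT_PAIR_POOL = (
    (1, 2), (1, 3), (2, 3), (2, 4), (3, 4), (4, 5), (4, 8),
    (5, 6), (6, 8), (8, 10), (9, 10), (10, 15),
)


@dataclass
class SimulationConfig:
    """Ground-truth parameters and structural scale of a synthetic dataset."""

    n_species: int = 33
    n_studies: int = 49
    n_subjects: int = 672
    trials_per_subject: tuple[int, int] = (20, 80)
    task_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)
    beta0: float = math.log(0.4)
    beta1: float = -0.3
    lam: float = 0.8
    sigma_species: float = 0.5
    sigma_study: float = 0.25
    sigma_subject: float = 0.25
    sigma_task: float = 0.25
    pair_pool: tuple[tuple[int, int], ...] = DEFAULT_PAIR_POOL
    seed: int = 0

    def validate(self):
        if abs(sum(self.task_mix) - 1.0) > 1e-9:
            raise ValueError("task mix proportions must sum to 1")
        if min(
            self.sigma_species, self.sigma_study,
            self.sigma_subject, self.sigma_task,
        ) < 0:
            raise ValueError("effect scales must be non-negative")
        if not 0 <= self.lam <= 1:
            raise ValueError("lambda must lie in [0, 1]")
        if self.n_species < 2 or self.n_studies < 1 or self.n_subjects < 1:
            raise ValueError("invalid structural sizes")


def paper33(**overrides) -> SimulationConfig:
    """Full structural scale: 33 species / 49 studies / 672 subjects."""
    return SimulationConfig(**overrides)


def desk8(**overrides) -> SimulationConfig:
    """Desk-scale preset: 8 species, 6 studies, 40 subjects, 50 trials each."""
    defaults = dict(
        n_species=8,
        n_studies=6,
        n_subjects=40,
        trials_per_subject=(50, 50),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def simulate_tree(n_species: int, seed: int) -> PhyloTree:
    """Random ultrametric tree (coalescent topology, rescaled to unit depth)."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    import msprime

    ts = msprime.sim_ancestry(
        samples=n_species,
        ploidy=1,
        population_size=1.0,
        random_seed=int(seed) % (2**31 - 1) + 1,
    )
    tr = ts.first()
    labels = {u: f"sp{i:02d}" for i, u in enumerate(tr.leaves())}
    newick = tr.as_newick(node_labels=labels)
    tree = load_tree(newick)
    depth = tree.depth
    for node in tree.tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length /= depth
    return tree


def simulate_dataset(
    tree: PhyloTree, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (trials, predictor table, ground truth) from the model.

    Structure: each study belongs to one species (cycling) when there are
    at least as many studies as species, otherwise each species is assigned
    to one study (studies then span species).  Subjects cycle over species
    and pick one of their species' studies; each study carries one task
    paradigm drawn from the task mix.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = sorted(tree.labels)
    S = len(species)
    if S != config.n_species:
        raise ValueError(
            f"tree has {S} tips but config.n_species = {config.n_species}"
        )

    cov = tree_to_correlation(tree, species)
    M = config.lam * cov.V + (1 - config.lam) * np.eye(S)
    L = np.linalg.cholesky(M + 1e-10 * np.eye(S))
    v = L @ rng.standard_normal(S)
    u = config.sigma_species * v
    x = rng.standard_normal(S)

    studies = [f"study{j:02d}" for j in range(config.n_studies)]
    if config.n_studies >= S:
        study_species = {studies[j]: j % S for j in range(config.n_studies)}
        species_studies = {i: [] for i in range(S)}
        for st, i in study_species.items():
            species_studies[i].append(st)
    else:
        species_studies = {
            i: [studies[i % config.n_studies]] for i in range(S)
        }
    study_task = {
        st: TASKS[rng.choice(3, p=config.task_mix)] for st in studies
    }
    a_study = {
        st: config.sigma_study * rng.standard_normal() for st in studies
    }
    c_task = {t: config.sigma_task * rng.standard_normal() for t in TASKS}

    pool = np.asarray(config.pair_pool)
    lo, hi = config.trials_per_subject
    rows = []
    b_subject = {}
    per_species_count = {i: 0 for i in range(S)}
    for k in range(config.n_subjects):
        i = k % S
        sp = species[i]
        per_species_count[i] += 1
        subject = f"{sp}/s{per_species_count[i]:03d}"
        study = species_studies[i][rng.integers(len(species_studies[i]))]
        task = study_task[study]
        b = config.sigma_subject * rng.standard_normal()
        b_subject[subject] = b
        log_w = (
            config.beta0 + config.beta1 * x[i] + u[i]
            + a_study[study] + b + c_task[task]
        )
        w = math.exp(log_w)
        nt = int(rng.integers(lo, hi + 1))
        pick = pool[rng.integers(len(pool), size=nt)]
        swap = rng.random(nt) < 0.5
        n1 = np.where(swap, pick[:, 1], pick[:, 0])
        n2 = np.where(swap, pick[:, 0], pick[:, 1])
        p = predict_accuracy(n1, n2, w)
        correct = rng.random(nt) < p
        for t in range(nt):
            rows.append(
                (sp, subject, study, task, int(n1[t]), int(n2[t]), int(correct[t]))
            )

    trials = pd.DataFrame(
        rows,
        columns=["species", "subject", "study", "task", "n1", "n2", "correct"],
    )
    predictors = pd.DataFrame({"x": x}, index=pd.Index(species, name="species"))

    truth = {
        "config": asdict(config),
        "beta0": config.beta0,
        "beta1": config.beta1,
        "lam": config.lam,
        "sigma_species": config.sigma_species,
        "sigma_study": config.sigma_study,
        "sigma_subject": config.sigma_subject,
        "sigma_task": config.sigma_task,
        "species_effect": dict(zip(species, u.tolist())),
        "x": dict(zip(species, x.tolist())),
        "study_effect": a_study,
        "subject_effect": b_subject,
        "task_effect": c_task,
        "species_log_w": {
            sp: config.beta0 + config.beta1 * x[i] + u[i]
            for i, sp in enumerate(species)
        },
    }
    return trials, predictors, truth
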