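import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

import phyloweber as pw
from phyloweber.model import (
    ModelSpec,
    PosteriorDraws,
    PriorSpec,
    _Posterior,
    _encode,
    fit,
    log_likelihood,
    species_weber_summary,
)
from phyloweber.psychophysics import predict_accuracy


def _flat_params(species, studies, subjects, tasks, **over):
    p = {
        "beta0": over.get("beta0", math.log(0.2)),
        "species_effect": {s: 0.0 for s in species},
        "study_effect": {s: 0.0 for s in studies},
        "subject_effect": {s: 0.0 for s in subjects},
        "task_effect": {t: 0.0 for t in tasks},
    }
    p.update(over)
    return p


def _one_trial(n1, n2, correct=1):
    return pd.DataFrame(
        {
            "species": ["a"],
            "subject": ["a/s1"],
            "study": ["st1"],
            "task": ["sequential"],
            "n1": [n1],
            "n2": [n2],
            "correct": [correct],
        }
    )


class TestLogLikelihood:
    cov = pw.SpeciesCovariance(("a",), np.eye(1))

    def test_equal_pair_contributes_log_half(self):
        params = _flat_params(["a"], ["st1"], ["a/s1"], ["sequential"])
        ll = log_likelihood(_one_trial(6, 6), params, self.cov)
        assert ll == pytest.approx(math.log(0.5))

    def test_composition_with_psychophysical_link(self):
        params = _flat_params(["a"], ["st1"], ["a/s1"], ["sequential"])
        ll = log_likelihood(_one_trial(10, 12), params, self.cov)
        assert ll == pytest.approx(math.log(predict_accuracy(10, 12, 0.2)))

    def test_unindexed_label_raises(self):
        params = _flat_params(["a"], ["st1"], ["a/s1"], ["sequential"])
        trial = _one_trial(4, 5)
        trial["species"] = "zebra"
        with pytest.raises(KeyError):
            log_likelihood(trial, params, self.cov)

    def test_matches_straight_loop_resummation(self, desk_data, rng):
        """Independent per-trial oracle agrees to 1e-10 on 20 fixed trials."""
        trials = desk_data["trials"].sample(20, random_state=3)
        species = sorted(trials["species"].unique())
        params = {
            "beta0": math.log(0.35),
            "beta1": -0.2,
            "x": dict(
                zip(species, rng.standard_normal(len(species)).tolist())
            ),
            "species_effect": {
                s: 0.1 * i for i, s in enumerate(species)
            },
            "study_effect": {
                s: 0.05 * i for i, s in enumerate(sorted(trials["study"].unique()))
            },
            "subject_effect": {
                s: -0.02 * i
                for i, s in enumerate(sorted(trials["subject"].unique()))
            },
            "task_effect": {
                t: 0.3 * i for i, t in enumerate(sorted(trials["task"].unique()))
            },
        }
        oracle = 0.0
        for row in trials.itertuples(index=False):
            lw = (
                params["beta0"]
                + params["beta1"] * params["x"][row.species]
                + params["species_effect"][row.species]
                + params["study_effect"][row.study]
                + params["subject_effect"][row.subject]
                + params["task_effect"][row.task]
            )
            p = predict_accuracy(row.n1, row.n2, math.exp(lw))
            oracle += math.log(p if row.correct else 1.0 - p)
        ll = log_likelihood(trials, params, desk_data["cov"])
        assert ll == pytest.approx(oracle, abs=1e-10)


def _build_posterior(trials, cov, x=None, lambda_fixed=None):
    species = sorted(trials["species"].unique())
    n1 = trials["n1"].to_numpy(float)
    n2 = trials["n2"].to_numpy(float)
    return (
        _Posterior(
            c=np.abs(n1 - n2) / np.hypot(n1, n2),
            y=trials["correct"].to_numpy(),
            sp_idx=_encode(trials["species"], species),
            study_idx=_encode(trials["study"], sorted(trials["study"].unique())),
            subj_idx=_encode(
                trials["subject"], sorted(trials["subject"].unique())
            ),
            task_idx=_encode(trials["task"], sorted(trials["task"].unique())),
            x=x,
            V=cov.reorder(species).V,
            priors=PriorSpec(),
            lambda_fixed=lambda_fixed,
        ),
        species,
    )


class TestPosteriorDensity:
    def test_vectorized_likelihood_matches_loop_oracle(self, desk_data):
        """The aggregated binomial likelihood inside the sampler equals the
        public per-trial log_likelihood plus analytic prior terms."""
        trials = desk_data["trials"].iloc[:200]
        post, species = _build_posterior(trials, desk_data["cov"])
        rng = np.random.default_rng(11)
        theta = 0.3 * rng.standard_normal(post.dim)
        logp, _ = post.logp_grad(theta)

        point = post.unpack(theta[None, :])
        studies = sorted(trials["study"].unique())
        subjects = sorted(trials["subject"].unique())
        tasks = sorted(trials["task"].unique())
        params = {
            "beta0": float(point["beta0"][0]),
            "species_effect": dict(zip(species, point["species_effect"][0])),
            "study_effect": dict(zip(studies, point["study_effect"][0])),
            "subject_effect": dict(zip(subjects, point["subject_effect"][0])),
            "task_effect": dict(zip(tasks, point["task_effect"][0])),
        }
        ll = log_likelihood(trials, params, desk_data["cov"])

        # analytic priors at the same unconstrained point
        pr = PriorSpec()
        beta0 = theta[0]
        llam = theta[post.i_lam]
        lam = 1.0 / (1.0 + math.exp(-llam))
        s = theta[post.i_s : post.i_s + 4]
        sig = np.exp(s)
        v = theta[post.i_v : post.i_v + post.S]
        z = theta[post.i_zst :]
        M = lam * post.V + (1 - lam) * np.eye(post.S) + 1e-10 * np.eye(post.S)
        prior = -0.5 * ((beta0 - pr.beta0_loc) / pr.beta0_scale) ** 2
        prior += float(np.sum(-0.5 * sig**2 + s))
        prior += math.log(lam) + math.log(1 - lam)
        sign, logdet = np.linalg.slogdet(M)
        prior += -0.5 * float(v @ np.linalg.solve(M, v)) - 0.5 * logdet
        prior += -0.5 * float(z @ z)
        assert logp == pytest.approx(ll + prior, abs=1e-8)

    def test_invariant_to_species_relabeling(self, desk_data):
        """Permuting species labels and the covariance rows/columns together
        leaves the joint density unchanged."""
        trials = desk_data["trials"].iloc[:400].copy()
        post, species = _build_posterior(trials, desk_data["cov"])
        rng = np.random.default_rng(5)
        theta = 0.3 * rng.standard_normal(post.dim)
        logp, _ = post.logp_grad(theta)

        perm = {s: f"renamed_{s}" for s in species}
        trials2 = trials.assign(species=trials["species"].map(perm))
        labels2 = sorted(trials2["species"].unique())
        old_for_new = {v: k for k, v in perm.items()}
        order = [species.index(old_for_new[l]) for l in labels2]
        V2 = desk_data["cov"].V[np.ix_(order, order)]
        cov2 = pw.SpeciesCovariance(tuple(labels2), V2)
        post2, _ = _build_posterior(trials2, cov2)
        theta2 = theta.copy()
        theta2[post.i_v : post.i_v + post.S] = theta[post.i_v : post.i_v + post.S][
            order
        ]
        logp2, _ = post2.logp_grad(theta2)
        assert logp2 == pytest.approx(logp, abs=1e-9)


class TestFit:
    def test_deterministic_under_fixed_seed(self, desk_data):
        sub = desk_data["trials"][
            desk_data["trials"]["species"].isin(["sp00", "sp01", "sp02"])
        ]
        spec = ModelSpec(chains=2, warmup=60, draws=30, seed=123)
        d1 = fit(sub, None, desk_data["cov"], spec)
        d2 = fit(sub, None, desk_data["cov"], spec)
        for name in d1.params:
            np.testing.assert_array_equal(d1.params[name], d2.params[name])

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec(chains=1).validate()
        with pytest.raises(ValueError):
            ModelSpec(lambda_fixed=1.5).validate()

    def test_unknown_species_aborts(self, desk_data):
        trials = desk_data["trials"].copy()
        trials.loc[trials.index[:5], "species"] = "unknown_sp"
        cov = desk_data["cov"]
        with pytest.raises(KeyError, match="unknown_sp"):
            fit(trials, None, cov, ModelSpec(chains=2, warmup=10, draws=10))

    def test_all_equal_pairs_rejected(self, desk_data):
        trials = desk_data["trials"].iloc[:50].copy()
        trials["n2"] = trials["n1"]
        with pytest.raises(ValueError, match="informative"):
            fit(trials, None, desk_data["cov"], ModelSpec(chains=2))

    def test_missing_predictor_species_dropped(self, desk_data):
        pred = desk_data["predictors"].copy()
        pred.loc["sp00", "x"] = np.nan
        spec = ModelSpec(predictor_name="x", chains=2, warmup=30, draws=20, seed=0)
        d = fit(desk_data["trials"], pred, desk_data["cov"], spec)
        assert "sp00" not in d.coords["species"]
        assert len(d.coords["species"]) == 7

    def test_species_subset_restricts_fit(self, desk_data):
        spec = ModelSpec(
            chains=2, warmup=30, draws=20, seed=2,
            species_subset=("sp01", "sp03", "sp05"),
        )
        d = fit(desk_data["trials"], None, desk_data["cov"], spec)
        assert d.coords["species"] == ("sp01", "sp03", "sp05")

    def test_lambda_draws_bounded(self, small_fit):
        lam = small_fit.stacked("lam")
        assert np.all((lam >= 0) & (lam <= 1))

    def test_single_species_matches_grid_mle(self, desk_data):
        """With one species, lambda fixed 0 and no extra variation in the
        generating process, the posterior Weber fraction brackets the
        grid-search maximum-likelihood estimate."""
        cfg = pw.desk8(
            seed=5, beta1=0.0, sigma_species=0.0, sigma_study=0.0,
            sigma_subject=0.0, sigma_task=0.0,
        )
        tree = desk_data["tree"]
        trials, _, truth = pw.simulate_dataset(tree, cfg)
        one = trials[trials["species"] == "sp00"]
        spec = ModelSpec(
            chains=2, warmup=250, draws=250, seed=3, lambda_fixed=0.0
        )
        d = fit(one, None, desk_data["cov"], spec)

        grid = np.exp(np.linspace(np.log(0.05), np.log(3.0), 400))
        n1 = one["n1"].to_numpy(float)
        n2 = one["n2"].to_numpy(float)
        y = one["correct"].to_numpy(bool)
        lls = []
        for w in grid:
            p = predict_accuracy(n1, n2, w)
            lls.append(np.sum(np.where(y, np.log(p), np.log1p(-p))))
        w_mle = grid[int(np.argmax(lls))]

        w_draws = np.exp(
            d.stacked("beta0") + d.stacked("species_effect")[:, 0]
        )
        lo, hi = np.quantile(w_draws, [0.025, 0.975])
        assert lo <= w_mle <= hi


class TestSpeciesWeberSummary:
    def test_constant_draws_give_constant_quantiles(self):
        params = {
            "beta0": np.full((2, 50), math.log(0.3)),
            "species_effect": np.zeros((2, 50, 2)),
        }
        d = PosteriorDraws(
            params=params,
            coords={"species": ("a", "b"), "study": (), "subject": (), "task": ()},
        )
        table = species_weber_summary(d)
        assert np.allclose(table.to_numpy(), 0.3)

    def test_quantiles_are_exp_of_log_scale_quantiles(self, small_fit_nopred):
        d = small_fit_nopred
        table = species_weber_summary(d)
        logw = d.stacked("beta0")[:, None] + d.stacked("species_effect")
        expected = np.exp(np.quantile(logw, 0.5, axis=0))
        # exact up to the linear interpolation between order statistics
        np.testing.assert_allclose(table["q50"].to_numpy(), expected, rtol=1e-3)

    def test_quantiles_monotone(self, small_fit_nopred):
        table = species_weber_summary(small_fit_nopred)
        arr = table.to_numpy()
        assert np.all(np.diff(arr, axis=1) >= 0)

    def test_predictor_fit_rejected(self, small_fit):
        with pytest.raises(ValueError, match="no-predictor"):
            species_weber_summary(small_fit)

    def test_recovers_true_species_weber(self, desk_data, small_fit_nopred):
        """True per-species w inside the central 50% interval for at least
        half the species at desk scale."""
        table = species_weber_summary(small_fit_nopred)
        truth = desk_data["truth"]["species_log_w"]
        hits = sum(
            table.at[sp, "q25"] <= math.exp(lw) <= table.at[sp, "q75"]
            for sp, lw in truth.items()
        )
        assert hits >= len(truth) / 2


class TestCalibration:
    def test_simulation_based_calibration_ranks_uniform(self):
        """Rank statistics of prior-drawn truths within posterior draws are
        consistent with uniformity (coarse chi-square, alpha = 0.01)."""
        rng = np.random.default_rng(2024)
        n_rep, thin_to = 12, 100
        ranks = []
        tree = pw.simulate_tree(8, 99)
        for rep in range(n_rep):
            cfg = pw.SimulationConfig(
                n_species=8,
                n_studies=3,
                n_subjects=16,
                trials_per_subject=(20, 20),
                beta0=float(rng.normal(math.log(0.5), 1.0)),
                beta1=float(rng.normal(0.0, 1.0)),
                lam=float(rng.uniform()),
                sigma_species=float(abs(rng.normal(0.0, 1.0))),
                sigma_study=float(abs(rng.normal(0.0, 1.0))),
                sigma_subject=float(abs(rng.normal(0.0, 1.0))),
                sigma_task=float(abs(rng.normal(0.0, 1.0))),
                seed=int(rng.integers(2**31)),
            )
            trials, pred, truth = pw.simulate_dataset(tree, cfg)
            cov = pw.tree_to_correlation(tree)
            # the fitted beta1 acts on the standardized predictor
            x = pred["x"].to_numpy()
            beta1_std = truth["beta1"] * x.std()
            spec = ModelSpec(
                predictor_name="x", chains=2, warmup=250, draws=250,
                seed=1000 + rep,
            )
            d = fit(trials, pred, cov, spec)
            for name, true_val in (("beta0", truth["beta0"]), ("beta1", beta1_std)):
                draws = d.stacked(name)
                step = max(1, len(draws) // thin_to)
                thinned = draws[::step][:thin_to]
                ranks.append(np.mean(thinned < true_val))
        counts, _ = np.histogram(ranks, bins=4, range=(0.0, 1.0))
        stat, pval = chisquare(counts)
        assert pval > 0.01
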