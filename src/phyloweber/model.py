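"""Joint Bayesian model of quantity discrimination across species.

Each binary trial outcome is modelled through a latent per-trial log Weber
fraction assembled additively:

    log w_trial = beta0 + beta1 * x[species]
                  + sigma_species * u[species]
                  + sigma_study * z_study[study]
                  + sigma_subject * z_subject[subject]
                  + sigma_task * z_task[task]

where ``x`` is one standardized species-level predictor, the species-effect
vector ``u`` is multivariate normal with correlation
``M = lambda * V + (1 - lambda) * I`` (V from the phylogeny, lambda in
[0, 1] fitted jointly), and the study/subject/task effects are independent
standard normals scaled by their half-normal scale parameters.  The trial
likelihood is Bernoulli with

    P(correct) = Phi(|n1 - n2| / (w_trial * sqrt(n1**2 + n2**2)))

the linear-scale scalar-variability psychophysical link.  Posteriors are
sampled with the package's NUTS implementation over an unconstrained
parameterization (logit lambda, log scales); convergence is assessed by
split-chain rank-normalized Rhat via arviz.

Priors (weakly informative, centred on the plausible animal Weber range):
beta0 ~ Normal(log 0.5, 1); beta1 ~ Normal(0, 1) on the standardized
predictor; all scales ~ HalfNormal(1); lambda ~ Uniform(0, 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import erfcx, expit, log_ndtr

from .phylogeny import SpeciesCovariance
from .psychophysics import predict_accuracy
from .sampler import nuts

TASKS = ("controlled_array", "sequential", "simultaneous")

_LOG_HALF = math.log(0.5)
_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)
_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)
_INV_SQRT2 = 1.0 / math.sqrt(2.0)


@dataclass
class PriorSpec:
    beta0_loc: float = _LOG_HALF
    beta0_scale: float = 1.0
    beta1_loc: float = 0.0
    beta1_scale: float = 1.0
    sigma_scale: float = 1.0  # HalfNormal scale for all four effect scales

    def validate(self):
        if min(self.beta0_scale, self.beta1_scale, self.sigma_scale) <= 0:
            raise ValueError("all prior scales must be positive")


@dataclass
class ModelSpec:
    """Configuration of one model run (one predictor at a time, or none)."""

    predictor_name: str | None = None
    priors: PriorSpec = field(default_factory=PriorSpec)
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    species_subset: tuple[str, ...] | None = None
    lambda_fixed: float | None = None
    target_accept: float = 0.8
    max_treedepth: int = 10

    def validate(self):
        if self.chains < 2:
            raise ValueError("at least 2 chains are required (Rhat)")
        if self.warmup < 0 or self.draws < 1:
            raise ValueError("invalid sampler sizes")
        if self.lambda_fixed is not None and not 0 <= self.lambda_fixed <= 1:
            raise ValueError("lambda_fixed must lie in [0, 1]")
        self.priors.validate()


@dataclass
class PosteriorDraws:
    """Posterior samples (chains x draws [x effect dimension]) plus metadata."""

    params: dict[str, np.ndarray]
    coords: dict[str, tuple[str, ...]]
    predictor_name: str | None = None
    x_mean: float | None = None
    x_std: float | None = None
    divergent: np.ndarray | None = None
    seed: int | None = None

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter with chains merged along the first axis."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def to_inference_data(self):
        import arviz as az

        dims = {}
        for name, arr in self.params.items():
            if arr.ndim == 3:
                dims[name] = [_DIM_FOR[name]]
        return az.from_dict(
            posterior=self.params,
            coords={k: list(v) for k, v in self.coords.items()},
            dims=dims,
        )


_DIM_FOR = {
    "species_effect": "species",
    "study_effect": "study",
    "subject_effect": "subject",
    "task_effect": "task",
}


class _Posterior:
    """Unconstrained log posterior and gradient for the joint model."""

    def __init__(
        self,
        c: np.ndarray,
        y: np.ndarray,
        sp_idx: np.ndarray,
        study_idx: np.ndarray,
        subj_idx: np.ndarray,
        task_idx: np.ndarray,
        x: np.ndarray | None,
        V: np.ndarray,
        priors: PriorSpec,
        lambda_fixed: float | None = None,
    ):
        # trials sharing (species, study, subject, task, ratio) share eta and
        # c, so collapse them to binomial counts: same likelihood, fewer rows
        y = y.astype(bool)
        key = np.column_stack([sp_idx, study_idx, subj_idx, task_idx, c])
        uniq, inverse = np.unique(key, axis=0, return_inverse=True)
        self.kc = np.bincount(inverse, weights=y.astype(float))
        self.ki = np.bincount(inverse, weights=(~y).astype(float))
        self.sp = uniq[:, 0].astype(int)
        self.st = uniq[:, 1].astype(int)
        self.su = uniq[:, 2].astype(int)
        self.ta = uniq[:, 3].astype(int)
        self.c = uniq[:, 4]
        self.x = x
        self.V = V
        self.priors = priors
        self.lambda_fixed = lambda_fixed
        self.S = V.shape[0]
        self.J = int(study_idx.max()) + 1
        self.K = int(subj_idx.max()) + 1
        self.G = int(task_idx.max()) + 1
        self.I = np.eye(self.S)

        self.has_x = x is not None
        self.free_lam = lambda_fixed is None
        # packing: beta0 [beta1] [logit lam] 4x log sigma, v, z_st, z_su, z_ta
        self.i_beta1 = 1 if self.has_x else None
        k = 1 + int(self.has_x)
        self.i_lam = k if self.free_lam else None
        k += int(self.free_lam)
        self.i_s = k
        k += 4
        self.i_v = k
        k += self.S
        self.i_zst = k
        k += self.J
        self.i_zsu = k
        k += self.K
        self.i_zta = k
        k += self.G
        self.dim = k

        if not self.free_lam:
            M = lambda_fixed * V + (1 - lambda_fixed) * self.I
            self._fixed_cf = cho_factor(M + 1e-10 * self.I, lower=True)
            self._fixed_logdet = 2.0 * np.sum(
                np.log(np.diag(self._fixed_cf[0]))
            )

    def logp_grad(self, theta: np.ndarray):
        if not np.all(np.isfinite(theta)):
            return -np.inf, np.zeros(self.dim)
        p = self.priors
        beta0 = theta[0]
        beta1 = theta[self.i_beta1] if self.has_x else 0.0
        s = theta[self.i_s : self.i_s + 4]
        sig = np.exp(np.clip(s, -20.0, 5.0))
        v = theta[self.i_v : self.i_v + self.S]
        zst = theta[self.i_zst : self.i_zst + self.J]
        zsu = theta[self.i_zsu : self.i_zsu + self.K]
        zta = theta[self.i_zta : self.i_zta + self.G]

        if self.free_lam:
            llam = theta[self.i_lam]
            lam = expit(llam)
            lam = min(max(lam, 1e-12), 1 - 1e-12)
            M = lam * self.V + (1 - lam) * self.I
            cf = cho_factor(M + 1e-10 * self.I, lower=True)
            logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        else:
            lam = self.lambda_fixed
            cf = self._fixed_cf
            logdet = self._fixed_logdet

        Minv_v = cho_solve(cf, v)

        eta = beta0 + sig[0] * v[self.sp]
        if self.has_x:
            eta = eta + beta1 * self.x[self.sp]
        eta = eta + sig[1] * zst[self.st] + sig[2] * zsu[self.su] + sig[3] * zta[self.ta]
        eta = np.clip(eta, -40.0, 40.0)

        q = self.c * np.exp(-eta)
        lp_c = log_ndtr(q)
        lp_i = log_ndtr(-q)
        ll = float(np.dot(self.kc, lp_c) + np.dot(self.ki, lp_i))

        # hazard ratios phi(q)/Phi(+-q); the incorrect-side ratio is
        # computed via erfcx to avoid cancellation at large q
        logphi = -0.5 * q * q - _HALF_LOG_2PI
        ratio_c = np.exp(logphi - lp_c)  # bounded by phi(0)/0.5
        ratio_i = _SQRT_2_OVER_PI / erfcx(q * _INV_SQRT2)
        dll_deta = q * (self.ki * ratio_i - self.kc * ratio_c)

        logp = ll
        logp += -0.5 * ((beta0 - p.beta0_loc) / p.beta0_scale) ** 2
        if self.has_x:
            logp += -0.5 * ((beta1 - p.beta1_loc) / p.beta1_scale) ** 2
        logp += float(np.sum(-0.5 * (sig / p.sigma_scale) ** 2 + s))
        logp += -0.5 * float(v @ Minv_v) - 0.5 * logdet
        logp += -0.5 * float(zst @ zst + zsu @ zsu + zta @ zta)
        if self.free_lam:
            logp += math.log(lam) + math.log(1.0 - lam)

        g = np.zeros(self.dim)
        G_sp = np.bincount(self.sp, weights=dll_deta, minlength=self.S)
        G_st = np.bincount(self.st, weights=dll_deta, minlength=self.J)
        G_su = np.bincount(self.su, weights=dll_deta, minlength=self.K)
        G_ta = np.bincount(self.ta, weights=dll_deta, minlength=self.G)

        g[0] = dll_deta.sum() - (beta0 - p.beta0_loc) / p.beta0_scale**2
        if self.has_x:
            g[self.i_beta1] = float(
                np.dot(G_sp, self.x)
            ) - (beta1 - p.beta1_loc) / p.beta1_scale**2
        # log-sigma gradients (chain rule through sig = exp(s)), plus
        # half-normal prior and Jacobian: d/ds (-sig^2/(2 tau^2) + s)
        g[self.i_s + 0] = sig[0] * float(np.dot(G_sp, v))
        g[self.i_s + 1] = sig[1] * float(np.dot(G_st, zst))
        g[self.i_s + 2] = sig[2] * float(np.dot(G_su, zsu))
        g[self.i_s + 3] = sig[3] * float(np.dot(G_ta, zta))
        g[self.i_s : self.i_s + 4] += 1.0 - (sig / p.sigma_scale) ** 2

        g[self.i_v : self.i_v + self.S] = sig[0] * G_sp - Minv_v
        g[self.i_zst : self.i_zst + self.J] = sig[1] * G_st - zst
        g[self.i_zsu : self.i_zsu + self.K] = sig[2] * G_su - zsu
        g[self.i_zta : self.i_zta + self.G] = sig[3] * G_ta - zta

        if self.free_lam:
            A = self.V - self.I
            Minv = cho_solve(cf, self.I)
            dlam = 0.5 * float(Minv_v @ A @ Minv_v) - 0.5 * float(
                np.sum(Minv * A)
            )
            g[self.i_lam] = dlam * lam * (1 - lam) + (1.0 - 2.0 * lam)

        return logp, g

    def unpack(self, draws: np.ndarray) -> dict[str, np.ndarray]:
        """Map unconstrained draws (n, dim) to named constrained arrays."""
        out = {"beta0": draws[:, 0]}
        if self.has_x:
            out["beta1"] = draws[:, self.i_beta1]
        if self.free_lam:
            out["lam"] = expit(draws[:, self.i_lam])
        else:
            out["lam"] = np.full(draws.shape[0], float(self.lambda_fixed))
        sig = np.exp(draws[:, self.i_s : self.i_s + 4])
        out["sigma_species"] = sig[:, 0]
        out["sigma_study"] = sig[:, 1]
        out["sigma_subject"] = sig[:, 2]
        out["sigma_task"] = sig[:, 3]
        out["species_effect"] = sig[:, [0]] * draws[:, self.i_v : self.i_v + self.S]
        out["study_effect"] = sig[:, [1]] * draws[:, self.i_zst : self.i_zst + self.J]
        out["subject_effect"] = sig[:, [2]] * draws[:, self.i_zsu : self.i_zsu + self.K]
        out["task_effect"] = sig[:, [3]] * draws[:, self.i_zta : self.i_zta + self.G]
        return out


def _encode(values: pd.Series, categories: list) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(categories)}
    return values.map(lookup).to_numpy()


def fit(
    trials: pd.DataFrame,
    predictors: pd.DataFrame | None,
    cov: SpeciesCovariance,
    spec: ModelSpec,
) -> PosteriorDraws:
    """Fit the joint model by NUTS and return posterior draws.

    ``trials`` needs columns species, subject, study, task, n1, n2,
    correct.  ``predictors`` (species-indexed) supplies the column named by
    ``spec.predictor_name``; species missing that predictor are dropped for
    the run.  Runs ``spec.chains`` sequential chains with deterministically
    spawned seeds; identical spec + data give identical draws.
    """
    spec.validate()
    trials = trials.copy()
    required = {"species", "subject", "study", "task", "n1", "n2", "correct"}
    missing_cols = required - set(trials.columns)
    if missing_cols:
        raise ValueError(f"trial table missing columns: {sorted(missing_cols)}")
    bad_tasks = set(trials["task"]) - set(TASKS)
    if bad_tasks:
        raise ValueError(f"unknown task paradigms: {sorted(bad_tasks)}")

    if spec.species_subset is not None:
        trials = trials[trials["species"].isin(spec.species_subset)]

    x = None
    x_mean = x_std = None
    if spec.predictor_name is not None:
        if predictors is None:
            raise ValueError("predictor_name given but no predictor table")
        col = predictors[spec.predictor_name]
        have = set(col.dropna().index)
        trials = trials[trials["species"].isin(have)]

    if len(trials) == 0:
        raise ValueError("no trials left after filtering")
    if not (trials["n1"] != trials["n2"]).any():
        raise ValueError("no informative trials (all quantity pairs equal)")

    species = sorted(trials["species"].unique())
    absent = [s for s in species if s not in cov.labels]
    if absent:
        raise KeyError(
            f"species present in trials but absent from the tree: {absent}"
        )
    studies = sorted(trials["study"].unique())
    subjects = sorted(trials["subject"].unique())
    tasks = [t for t in TASKS if t in set(trials["task"])]

    if spec.predictor_name is not None:
        raw = predictors[spec.predictor_name].loc[species].to_numpy(float)
        x_mean = float(raw.mean())
        x_std = float(raw.std())
        if x_std == 0:
            raise ValueError(
                f"predictor {spec.predictor_name!r} is constant across species"
            )
        x = (raw - x_mean) / x_std

    sub = cov.reorder(species)
    n1 = trials["n1"].to_numpy(float)
    n2 = trials["n2"].to_numpy(float)
    if (n1 < 1).any() or (n2 < 1).any():
        raise ValueError("quantities must be >= 1")
    c = np.abs(n1 - n2) / np.hypot(n1, n2)
    y = trials["correct"].to_numpy()

    post = _Posterior(
        c=c,
        y=y,
        sp_idx=_encode(trials["species"], species),
        study_idx=_encode(trials["study"], studies),
        subj_idx=_encode(trials["subject"], subjects),
        task_idx=_encode(trials["task"], tasks),
        x=x,
        V=sub.V,
        priors=spec.priors,
        lambda_fixed=spec.lambda_fixed,
    )

    chain_params: list[dict[str, np.ndarray]] = []
    divergent = []
    for chain in range(spec.chains):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed), chain])
        )
        theta0 = 0.1 * rng.standard_normal(post.dim)
        theta0[0] += spec.priors.beta0_loc
        draws, stats = nuts(
            post.logp_grad,
            theta0,
            n_warmup=spec.warmup,
            n_draws=spec.draws,
            rng=rng,
            target_accept=spec.target_accept,
            max_treedepth=spec.max_treedepth,
        )
        chain_params.append(post.unpack(draws))
        divergent.append(stats.divergent)

    divergent = np.asarray(divergent)
    frac = divergent.mean()
    if frac > 0.10:
        warnings.warn(
            f"{int(divergent.sum())} divergent transitions "
            f"({100 * frac:.1f}% of post-warmup draws)",
            stacklevel=2,
        )

    params = {
        name: np.stack([cp[name] for cp in chain_params])
        for name in chain_params[0]
    }
    return PosteriorDraws(
        params=params,
        coords={
            "species": tuple(species),
            "study": tuple(studies),
            "subject": tuple(subjects),
            "task": tuple(tasks),
        },
        predictor_name=spec.predictor_name,
        x_mean=x_mean,
        x_std=x_std,
        divergent=divergent,
        seed=spec.seed,
    )


def log_likelihood(
    trials: pd.DataFrame, params: Mapping, cov: SpeciesCovariance
) -> float:
    """Data log likelihood at one parameter point (sum of Bernoulli terms).

    ``params`` maps: beta0 (float), optionally beta1 (float) with ``x``
    (species -> predictor value), species_effect / study_effect /
    subject_effect / task_effect (label -> effect on the log-w scale).
    Labels missing from the effect maps raise KeyError.
    """
    beta0 = float(params["beta0"])
    beta1 = float(params.get("beta1", 0.0))
    x = params.get("x", {})
    sp_eff = params["species_effect"]
    st_eff = params["study_effect"]
    su_eff = params["subject_effect"]
    ta_eff = params["task_effect"]

    eta = np.empty(len(trials))
    for i, row in enumerate(trials.itertuples(index=False)):
        e = beta0 + sp_eff[row.species] + st_eff[row.study]
        e += su_eff[row.subject] + ta_eff[row.task]
        if beta1 != 0.0:
            e += beta1 * x[row.species]
        eta[i] = e

    w = np.exp(eta)
    n1 = trials["n1"].to_numpy(float)
    n2 = trials["n2"].to_numpy(float)
    q = np.abs(n1 - n2) / (w * np.hypot(n1, n2))
    y = trials["correct"].to_numpy(bool)
    total = float(np.sum(np.where(y, log_ndtr(q), log_ndtr(-q))))
    if not np.isfinite(total):
        raise FloatingPointError("non-finite log likelihood")
    return total


def rhat(draws: PosteriorDraws) -> dict[str, float]:
    """Split-chain rank-normalized Rhat per scalar parameter.

    Vector-valued effects are expanded to ``name[label]`` entries.  Chains
    with zero variance (degenerate but agreeing) report 1.0 by convention.
    """
    if draws.n_chains < 2:
        raise ValueError("Rhat requires at least 2 chains")
    if draws.n_draws < 10:
        raise ValueError("Rhat requires at least 10 draws per chain")
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = az.rhat(draws.to_inference_data(), method="rank")
    out: dict[str, float] = {}
    for name in draws.params:
        values = np.asarray(result[name].values)
        if values.ndim == 0:
            out[name] = 1.0 if np.isnan(values) else float(values)
        else:
            labels = draws.coords[_DIM_FOR[name]]
            for label, val in zip(labels, values):
                out[f"{name}[{label}]"] = 1.0 if np.isnan(val) else float(val)
    return out


def species_weber_summary(
    draws: PosteriorDraws,
    probs: tuple[float, ...] = (0.025, 0.25, 0.5, 0.75, 0.975),
) -> pd.DataFrame:
    """Posterior quantiles of each species' overall Weber fraction.

    Requires a no-predictor fit (beta1 absent): per species the summarized
    quantity is exp(beta0 + species_effect) on the w scale.
    """
    if "beta1" in draws.params and np.any(draws.params["beta1"] != 0):
        raise ValueError(
            "species Weber summary requires a no-predictor fit "
            "(beta1 absent or fixed at 0)"
        )
    beta0 = draws.stacked("beta0")
    u = draws.stacked("species_effect")
    w = np.exp(beta0[:, None] + u)
    qs = np.quantile(w, probs, axis=0)
    return pd.DataFrame(
        qs.T,
        index=list(draws.coords["species"]),
        columns=[f"q{100 * p:g}" for p in probs],
    )
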