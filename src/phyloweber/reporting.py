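"""Posterior summaries: coefficient tables, lambda, effect scales, scatter data.

All numbers come from quantile tables computed here; plotting helpers are
thin side-effects over those tables.  Chains are merged before
summarizing (and before kernel density estimation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .model import PosteriorDraws, species_weber_summary  # re-export

__all__ = [
    "coefficient_summary",
    "lambda_summary",
    "scale_summary",
    "posterior_density",
    "weber_predictor_scatter",
    "species_weber_summary",
    "plot_coefficient_intervals",
    "plot_species_weber",
]


def _one_coefficient_row(draws: PosteriorDraws) -> dict:
    b = draws.stacked("beta1")
    q = np.quantile(b, [0.025, 0.25, 0.75, 0.975])
    return {
        "mean": float(b.mean()),
        "q2.5": q[0],
        "q25": q[1],
        "q75": q[2],
        "q97.5": q[3],
        "sign_consistent": bool(q[0] > 0 or q[3] < 0),
    }


def coefficient_summary(runs) -> pd.DataFrame:
    """Posterior mean, 50% and 95% intervals of beta1 per predictor run.

    ``runs`` is either one :class:`PosteriorDraws` from a predictor fit or
    a mapping ``predictor name -> PosteriorDraws``.  The sign-consistency
    flag marks runs whose whole central 95% interval lies on one side of 0.
    """
    if isinstance(runs, PosteriorDraws):
        runs = {runs.predictor_name or "predictor": runs}
    rows = {}
    for name, draws in runs.items():
        if "beta1" not in draws.params:
            raise ValueError(f"run {name!r} has no predictor coefficient")
        rows[name] = _one_coefficient_row(draws)
    return pd.DataFrame.from_dict(rows, orient="index")


def lambda_summary(draws: PosteriorDraws, threshold: float = 0.05) -> dict:
    """Posterior quantiles of lambda plus the exceedance P(lambda > threshold).

    Lambda > 0 means species are not phylogenetically independent; the
    exceedance probability reports that as a posterior probability rather
    than a point decision.
    """
    lam = draws.stacked("lam")
    probs = (0.025, 0.25, 0.5, 0.75, 0.975)
    qs = np.quantile(lam, probs)
    out = {f"q{100 * p:g}": float(v) for p, v in zip(probs, qs)}
    out["mean"] = float(lam.mean())
    out["p_exceeds"] = float(np.mean(lam > threshold))
    out["threshold"] = threshold
    return out


def scale_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Means, 50% and 90% intervals of the four effect scales (and beta1).

    All entries act multiplicatively on the log-w scale, so their
    magnitudes are directly comparable with the predictor coefficient.
    """
    names = ["sigma_species", "sigma_study", "sigma_subject", "sigma_task"]
    if "beta1" in draws.params:
        names.append("beta1")
    rows = {}
    for name in names:
        s = draws.stacked(name)
        q = np.quantile(s, [0.05, 0.25, 0.75, 0.95])
        rows[name] = {
            "mean": float(s.mean()),
            "q5": q[0],
            "q25": q[1],
            "q75": q[2],
            "q95": q[3],
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def posterior_density(
    draws: PosteriorDraws, param: str, grid: np.ndarray | None = None
):
    """Gaussian kernel density of one scalar parameter, chains merged.

    Bandwidth follows the Scott reference rule.  Returns (grid, density).
    """
    samples = draws.stacked(param)
    if samples.ndim != 1:
        raise ValueError(f"{param!r} is not a scalar parameter")
    kde = gaussian_kde(samples)
    if grid is None:
        lo, hi = samples.min(), samples.max()
        pad = 0.1 * (hi - lo + 1e-12)
        grid = np.linspace(lo - pad, hi + pad, 256)
    return grid, kde(grid)


def weber_predictor_scatter(
    weber_table: pd.DataFrame,
    predictor_table: pd.DataFrame,
    predictor_name: str,
) -> pd.DataFrame:
    """Join per-species w quantiles with one predictor for scatter plotting."""
    out = weber_table.join(predictor_table[predictor_name], how="inner")
    return out.rename(columns={predictor_name: "predictor"}).assign(
        predictor_name=predictor_name
    )


def plot_coefficient_intervals(table: pd.DataFrame, path) -> None:
    """Interval plot of coefficient posteriors (side effect only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.5 * len(table) + 1))
    ypos = np.arange(len(table))[::-1]
    ax.hlines(ypos, table["q2.5"], table["q97.5"], lw=1)
    ax.hlines(ypos, table["q25"], table["q75"], lw=4)
    ax.plot(table["mean"], ypos, "o", color="k")
    ax.axvline(0, ls=":", color="grey")
    ax.set_yticks(ypos, table.index)
    ax.set_xlabel("effect on log Weber fraction (per SD of predictor)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_species_weber(weber_table: pd.DataFrame, path) -> None:
    """Per-species Weber fraction interval plot (side effect only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = weber_table.sort_values("q50")
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(table) + 1))
    ypos = np.arange(len(table))
    ax.hlines(ypos, table["q2.5"], table["q97.5"], lw=1)
    ax.hlines(ypos, table["q25"], table["q75"], lw=4)
    ax.plot(table["q50"], ypos, "o", color="k", ms=3)
    ax.set_yticks(ypos, table.index, fontsize=7)
    ax.set_xlabel("Weber fraction w")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
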