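"""Species-level predictor table: conversions, imputations and transforms.

One row per species; columns are the candidate correlates of quantitative
precision: endocranial volume (ECV, cm^3), body mass (g), group size,
percentage of fruit in the diet, home range, day journey length, cortical
and cerebellar neuron numbers and densities, a self-control composite score
and a domain-general cognition score.  Missingness is allowed everywhere
except the species column and is tracked per cell.

Standard preprocessing steps implemented here:

* ECV from brain mass via a brain tissue density of 1.036 g/cm^3.
* Primate cortical / cerebellar neuron numbers imputed from brain mass via
  published power-law scaling rules (never overwriting measured values, and
  never for *density* columns — density and number are decoupled in
  primates, so density is left missing when unmeasured).
* Natural-log transform of eight size-like columns.
* Residual brain volume (RBV): residuals of a phylogenetic GLS regression
  of log ECV on log body mass.
* Reversal of the general-cognition score so that high = good.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .phylogeny import SpeciesCovariance, pgls_residuals

BRAIN_TISSUE_DENSITY_G_PER_CM3 = 1.036

# power-law scaling of neuron counts on brain mass (grams) in primates
CORTEX_NEURON_COEF = 37_813_551.018
CORTEX_NEURON_EXP = 0.891
CEREBELLUM_NEURON_COEF = 69_640_042.656
CEREBELLUM_NEURON_EXP = 0.936

#: columns receiving a natural-log transform before modelling
LOG_COLUMNS = (
    "ecv",
    "group_size",
    "home_range",
    "day_journey",
    "cortex_neurons",
    "cerebellum_neurons",
    "cortex_neuron_density",
    "cerebellum_neuron_density",
)

#: neuron-count columns that may be imputed from brain mass (primates only)
IMPUTABLE_COLUMNS = ("cortex_neurons", "cerebellum_neurons")

DENSITY_COLUMNS = ("cortex_neuron_density", "cerebellum_neuron_density")


def ecv_from_brain_mass(brain_mass: float) -> float:
    """Endocranial volume (cm^3) from brain mass (g) via tissue density."""
    if brain_mass <= 0:
        raise ValueError("brain mass must be positive")
    return brain_mass / BRAIN_TISSUE_DENSITY_G_PER_CM3


def primate_cortex_neurons(brain_mass: float) -> float:
    """Predicted primate cortical neuron count from brain mass (g)."""
    if brain_mass <= 0:
        raise ValueError("brain mass must be positive")
    return CORTEX_NEURON_COEF * brain_mass**CORTEX_NEURON_EXP


def primate_cerebellum_neurons(brain_mass: float) -> float:
    """Predicted primate cerebellar neuron count from brain mass (g)."""
    if brain_mass <= 0:
        raise ValueError("brain mass must be positive")
    return CEREBELLUM_NEURON_COEF * brain_mass**CEREBELLUM_NEURON_EXP


def reverse_cognition_score(raw) -> np.ndarray:
    """Reverse a score vector (negation) so that high = good.

    Exactly order-reversing: the Spearman correlation of input and output
    is -1 for any non-constant input.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty score vector")
    return -raw


def impute_primate_neurons(
    table: pd.DataFrame,
    brain_mass: pd.Series,
    is_primate: pd.Series,
    columns: tuple[str, ...] = IMPUTABLE_COLUMNS,
) -> pd.DataFrame:
    """Fill missing primate neuron *counts* from brain mass scaling rules.

    Measured values always win: only NaN cells of primate species are
    filled, so the operation is idempotent.  Requesting a density column
    raises — density cannot be recovered from the count scaling rules.
    """
    for col in columns:
        if col in DENSITY_COLUMNS:
            raise ValueError(
                f"{col}: neuron density cannot be imputed from brain mass "
                "(density and number are decoupled in primates)"
            )
        if col not in IMPUTABLE_COLUMNS:
            raise ValueError(f"no scaling rule for column {col!r}")
    rule = {
        "cortex_neurons": primate_cortex_neurons,
        "cerebellum_neurons": primate_cerebellum_neurons,
    }
    out = table.copy()
    for sp in out.index:
        if not bool(is_primate.get(sp, False)):
            continue
        bm = brain_mass.get(sp, np.nan)
        if not np.isfinite(bm):
            continue
        for col in columns:
            if col in out.columns and pd.isna(out.at[sp, col]):
                out.at[sp, col] = rule[col](float(bm))
    return out


def exclude_cerebellum_outlier(
    table: pd.DataFrame, species: str = "african_elephant"
) -> pd.DataFrame:
    """Robustness switch: blank one species' cerebellar neuron values.

    The African elephant is an extreme cerebellar outlier (most of its
    neurons sit in the cerebellum); it is *included* by default, and this
    helper produces the companion table for refitting without it.
    """
    if species not in table.index:
        raise KeyError(f"species {species!r} not in table")
    out = table.copy()
    for col in ("cerebellum_neurons", "cerebellum_neuron_density"):
        if col in out.columns:
            out.at[species, col] = np.nan
    return out


def provenance(raw: pd.DataFrame, imputed: pd.DataFrame) -> dict:
    """Per-cell provenance: measured | scaled_from_brain_mass | missing."""
    prov: dict[str, dict[str, str]] = {}
    for col in imputed.columns:
        prov[col] = {}
        for sp in imputed.index:
            if pd.isna(imputed.at[sp, col]):
                prov[col][sp] = "missing"
            elif col in raw.columns and not pd.isna(raw.at[sp, col]):
                prov[col][sp] = "measured"
            else:
                prov[col][sp] = "scaled_from_brain_mass"
    return prov


def apply_transforms(
    table: pd.DataFrame, cov: SpeciesCovariance | None = None
) -> pd.DataFrame:
    """Natural-log the eight size-like columns; optionally compute RBV.

    Percentage fruit, self-control and general cognition are left on their
    native scales.  If ``cov`` is given and both ``ecv`` and ``body_mass``
    are present, an ``rbv`` column is added: residuals of log ECV on log
    body mass under the Brownian phylogenetic GLS, over the species with
    both values (others get NaN).
    """
    out = table.copy()
    for col in LOG_COLUMNS:
        if col not in out.columns:
            continue
        vals = out[col].astype(float)
        bad = vals.index[(vals <= 0) & vals.notna()]
        if len(bad):
            raise ValueError(
                f"non-positive value in log column {col!r} for species "
                f"{list(bad)}"
            )
        out[col] = np.log(vals)

    if cov is not None and "ecv" in out.columns and "body_mass" in out.columns:
        log_bm = np.log(out["body_mass"].astype(float))
        complete = out.index[out["ecv"].notna() & log_bm.notna()]
        sub = cov.reorder([sp for sp in cov.labels if sp in set(complete)])
        y = out.loc[list(sub.labels), "ecv"].to_numpy(float)
        x = log_bm.loc[list(sub.labels)].to_numpy(float)
        out["rbv"] = np.nan
        out.loc[list(sub.labels), "rbv"] = pgls_residuals(y, x, sub)
    return out


def write_table(table: pd.DataFrame, path, prov: dict | None = None) -> None:
    """Write the table as CSV plus a JSON sidecar of units and provenance."""
    path = Path(path)
    table.to_csv(path, index_label="species")
    sidecar = {
        "units": {
            "ecv": "cm^3",
            "body_mass": "g",
            "group_size": "count",
            "pct_fruit": "%",
            "cortex_neurons": "count",
            "cerebellum_neurons": "count",
            "cortex_neuron_density": "count per mg",
            "cerebellum_neuron_density": "count per mg",
        },
        "log_transformed": list(LOG_COLUMNS),
        "provenance": prov or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="species")
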