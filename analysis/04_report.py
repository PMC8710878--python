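"""Result surfaces: interval plots and scatter tables from the fitted runs.

Reads the posterior summaries of 02_fit.py and produces the per-species
Weber interval plot, the coefficient interval plot and the w-vs-predictor
scatter table under results/report/.
"""

from pathlib import Path

import pandas as pd

from phyloweber.reporting import (
    plot_coefficient_intervals,
    plot_species_weber,
    weber_predictor_scatter,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "report"
    out.mkdir(parents=True, exist_ok=True)

    weber = pd.read_csv(ROOT / "fit" / "species_weber.csv", index_col=0)
    coef = pd.read_csv(ROOT / "fit" / "coefficient.csv", index_col=0)
    predictors = pd.read_csv(
        ROOT / "sim" / "predictors.csv", index_col="species"
    )

    plot_species_weber(weber, out / "species_weber.svg")
    plot_coefficient_intervals(coef, out / "coefficient.svg")
    scatter = weber_predictor_scatter(weber, predictors, "x")
    scatter.to_csv(out / "weber_vs_predictor.csv")

    print("species Weber medians span "
          f"[{weber['q50'].min():.3f}, {weber['q50'].max():.3f}]")
    print(f"wrote plots and scatter table to {out}")


if __name__ == "__main__":
    main()
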