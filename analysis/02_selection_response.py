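#!/usr/bin/env python
"""Selection differentials and control-adjusted responses of the simulated run.

Reads the tables written by 01_simulate.py, recomputes the contribution-
weighted differential per generation x line x replicate, builds each line's
(cumulative |S|, R) series, and writes them under results/selection/.
A diagnostic scatter of R against cumulative |S| goes to scratch/ (not a
deliverable).
"""

from pathlib import Path

import pandas as pd

from selexsim.selection import Direction, response_series_from_tables

HERE = Path(__file__).resolve().parent.parent
EXP = HERE / "scratch" / "experiment"
OUT = HERE / "results" / "selection"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    pheno = pd.read_csv(EXP / "phenotypes.csv")
    contrib = pd.read_csv(EXP / "contributions.csv")

    rows = []
    for direction in Direction:
        for rep in sorted(contrib["replicate"].unique()):
            series = response_series_from_tables(pheno, contrib, direction, int(rep))
            for g, x, y in zip(series.generations, series.cumulative_s,
                               series.response):
                rows.append(
                    {"line": direction.selected_line.value, "replicate": rep,
                     "generation": g, "cumulative_S_mm": x, "response_mm": y}
                )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "response_series.csv", index=False)
    print(table.to_string(index=False))

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        for (line, rep), grp in table.groupby(["line", "replicate"]):
            ax.plot(grp["cumulative_S_mm"], grp["response_mm"], "o-",
                    label=f"{line} rep {rep}")
        ax.set_xlabel("cumulative |S| (mm)")
        ax.set_ylabel("control-adjusted response R (mm)")
        ax.legend()
        fig_dir = HERE / "scratch"
        fig_dir.mkdir(exist_ok=True)
        fig.savefig(fig_dir / "response_vs_cumulative_S.png", dpi=120)
        print(f"diagnostic figure: {fig_dir / 'response_vs_cumulative_S.png'}")
    except ImportError:
        pass


if __name__ == "__main__":
    main()
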