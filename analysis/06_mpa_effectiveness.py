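"""Effectiveness of the MPA set versus the priority areas.

Scores both cell sets for the percentage of taxonomic, genetic and
phylogenetic diversity they conserve, against biodiversity-preservation
accumulation curves built from 1000 random cell draws per size. Writes
coverage.csv, coverage_vs_null.csv and accumulation_curve.csv, plus a
summary figure.
"""

import dataclasses
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import N_REPLICATES, RESULTS, STUDY_SEED, WORLD_DIR

from biodivgrid.efficiency import accumulation_curve, compare_to_null, coverage_report
from biodivgrid.genetic_diversity import species_pi_table
from biodivgrid.phylodiversity import TreeIndex
from biodivgrid.synthetic_data import read_world


def main() -> None:
    world = read_world(WORLD_DIR)
    pi_tab = pd.read_csv(RESULTS / "species_pi.csv")
    pi_map = dict(zip(pi_tab["species_id"], pi_tab["pi"]))
    tree = TreeIndex(world.tree)
    presence = world.presence

    prio = pd.read_csv(RESULTS / "priority_assignments.csv")
    priority_cells = set(prio.loc[prio["is_priority"], "cell_id"])

    sizes = sorted(
        {0, presence.n_cells, len(world.mpa_cells), len(priority_cells)}
        | set(np.linspace(0, presence.n_cells, 11, dtype=int).tolist())
    )
    curve = accumulation_curve(presence, pi_map, tree, sizes,
                               n_replicates=N_REPLICATES, seed=STUDY_SEED)
    curve.table.to_csv(RESULTS / "accumulation_curve.csv", index=False)

    rows, verdicts = [], []
    for name, cells in (("mpa", world.mpa_cells), ("priority", priority_cells)):
        rep = coverage_report(cells, presence, pi_map, tree, name)
        rows.append(dataclasses.asdict(rep))
        v = compare_to_null(rep, curve)
        v.insert(0, "cell_set_id", name)
        verdicts.append(v)
        print(f"{name}: {rep.n_cells} cells "
              f"({100 * rep.fraction_of_ocean:.1f}% of ocean) conserve "
              f"{rep.pct_taxonomic:.1f}% taxonomic, "
              f"{rep.pct_genetic:.1f}% genetic, "
              f"{rep.pct_phylogenetic:.1f}% phylogenetic diversity")
        for _, r in v.iterrows():
            print(f"    {r.dimension:13s} vs random null: {r.verdict:6s} "
                  f"(null mean {r.null_mean:.1f}, band [{r.lo:.1f}, {r.hi:.1f}], p={r.p:.3f})")
    pd.DataFrame(rows).to_csv(RESULTS / "coverage.csv", index=False)
    pd.concat(verdicts, ignore_index=True).to_csv(RESULTS / "coverage_vs_null.csv", index=False)

    _plot(curve.table, rows, RESULTS / "accumulation_curves.png")


def _plot(curve_table: pd.DataFrame, reports: list[dict], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
    for ax, dim in zip(axes, ("taxonomic", "genetic", "phylogenetic")):
        sub = curve_table[curve_table.dimension == dim].sort_values("size")
        ax.fill_between(sub["size"], sub["lo"], sub["hi"], alpha=0.3, label="random 95% band")
        ax.plot(sub["size"], sub["mean"], label="random mean")
        for rep, color in zip(reports, ("tab:red", "tab:green")):
            ax.scatter(rep["n_cells"], rep[f"pct_{dim}"], color=color, zorder=3,
                       label=rep["cell_set_id"])
        ax.set_title(dim)
        ax.set_xlabel("protected cells")
    axes[0].set_ylabel("% diversity conserved")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    print(f"figure written to {path}")


if __name__ == "__main__":
    main()
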