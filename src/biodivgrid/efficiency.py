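"""Effectiveness of a protected cell set across three diversity dimensions.

A species counts as covered when it is present in at least one cell of
the set. The three coverage percentages are

* taxonomic — covered species / all species occurring in retained cells;
* genetic  — sum of species pi over covered pi-estimable species /
  the same sum over all pi-estimable species (pi-weighted species
  coverage: 100 at full coverage, 0 at none, monotone under inclusion);
* phylogenetic — Faith's PD of the covered tree-tip species / PD of all
  tree-tip species occurring in retained cells.

The null reference is a biodiversity-preservation accumulation curve:
for each sample size, cells are drawn uniformly without replacement
(1000 replicates by default) and the 2.5/97.5 coverage percentiles form
the 95% band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gridding import PresenceMatrix
from .phylodiversity import TreeIndex, as_tree_index

DEFAULT_N_REPLICATES = 1000

DIMENSIONS = ("taxonomic", "genetic", "phylogenetic")


@dataclass(frozen=True)
class CoverageReport:
    cell_set_id: str
    pct_taxonomic: float
    pct_genetic: float
    pct_phylogenetic: float
    n_cells: int
    fraction_of_ocean: float

    def pct(self, dim: str) -> float:
        return {"taxonomic": self.pct_taxonomic, "genetic": self.pct_genetic,
                "phylogenetic": self.pct_phylogenetic}[dim]


class _CoverageEngine:
    """Precomputed denominators and tree projections for fast coverage sums."""

    def __init__(
        self,
        presence: PresenceMatrix,
        pi_by_species: Mapping[str, float],
        tree: "TreeIndex | object",
    ):
        self.presence = presence
        ti = as_tree_index(tree)
        occurs = presence.matrix.any(axis=0)  # species present somewhere
        self.occurs = occurs
        self.n_species_total = int(occurs.sum())
        pi = np.array([pi_by_species.get(s, float("nan")) for s in presence.species_ids])
        pi = np.where(np.isnan(pi), 0.0, np.where(occurs, pi, 0.0))
        self.pi = pi
        self.pi_total = float(pi.sum())
        tip_rows = np.array(
            [ti.tip_index.get(s, -1) if ok else -1 for s, ok in zip(presence.species_ids, occurs)]
        )
        self.on_tree = tip_rows >= 0
        self.paths_f = ti._paths_f[tip_rows[self.on_tree]]  # (n_tree_species, E)
        self.edge_lengths = ti.edge_lengths
        union = ti.tip_paths[tip_rows[self.on_tree]].any(axis=0) if self.on_tree.any() else np.zeros(len(ti.edge_lengths), bool)
        self.pd_total = float(ti.edge_lengths[union].sum())

    def coverage(self, covered: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-replicate coverage percentages from a (reps, n_species)
        covered-species boolean matrix."""
        covered = covered & self.occurs
        tax = 100.0 * covered.sum(axis=1) / max(self.n_species_total, 1)
        gen = (100.0 * (covered @ self.pi) / self.pi_total) if self.pi_total > 0 else np.zeros(len(covered))
        if self.pd_total > 0:
            sel = covered[:, self.on_tree].astype(np.float32)
            pdv = ((sel @ self.paths_f) > 0) @ self.edge_lengths
            phy = 100.0 * pdv / self.pd_total
        else:
            phy = np.zeros(len(covered))
        return tax, gen, phy


def coverage_report(
    cell_set: Iterable[int],
    presence: PresenceMatrix,
    pi_by_species: Mapping[str, float],
    tree: "TreeIndex | object",
    cell_set_id: str = "cell_set",
) -> CoverageReport:
    """Score a protected cell set on taxonomic, genetic and phylogenetic
    coverage. Unknown cell ids raise KeyError listing them."""
    cells = sorted(set(int(c) for c in cell_set))
    eng = _CoverageEngine(presence, pi_by_species, tree)
    if cells:
        pos = presence.cell_index(cells)
        covered = presence.matrix[pos].any(axis=0)[None, :]
    else:
        covered = np.zeros((1, presence.n_species), dtype=bool)
    tax, gen, phy = eng.coverage(covered)
    return CoverageReport(
        cell_set_id=cell_set_id,
        pct_taxonomic=float(tax[0]),
        pct_genetic=float(gen[0]),
        pct_phylogenetic=float(phy[0]),
        n_cells=len(cells),
        fraction_of_ocean=len(cells) / presence.n_cells,
    )


@dataclass
class AccumulationCurve:
    """Random-sampling biodiversity-preservation curve with 95% band."""

    sample_sizes: list[int]
    table: pd.DataFrame = field(repr=False)   # size, dimension, mean, lo, hi
    replicates: dict[int, dict[str, np.ndarray]] = field(repr=False)
    n_replicates: int = DEFAULT_N_REPLICATES
    seed: int | None = None

    def at(self, size: int, dimension: str) -> np.ndarray:
        return self.replicates[size][dimension]


def accumulation_curve(
    presence: PresenceMatrix,
    pi_by_species: Mapping[str, float],
    tree: "TreeIndex | object",
    sample_sizes: Sequence[int],
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int | None = None,
) -> AccumulationCurve:
    """Coverage of uniformly drawn random cell sets at each sample size.

    Per size, cells are drawn without replacement per replicate; the
    band is the 2.5/97.5 percentile of the replicate coverages. Sizes 0
    and n_cells are exact (no sampling noise)."""
    n_cells = presence.n_cells
    sizes = sorted(set(int(s) for s in sample_sizes))
    if any(s < 0 or s > n_cells for s in sizes):
        raise ValueError("sample sizes must lie in [0, n_cells]")
    eng = _CoverageEngine(presence, pi_by_species, tree)
    rng = np.random.default_rng(seed)
    rows = []
    reps_store: dict[int, dict[str, np.ndarray]] = {}
    for size in sizes:
        if size == 0:
            covered = np.zeros((1, presence.n_species), dtype=bool)
        elif size == n_cells:
            covered = presence.matrix.any(axis=0)[None, :]
        else:
            keys = rng.random((n_replicates, n_cells))
            picks = np.argsort(keys, axis=1)[:, :size]
            covered = presence.matrix[picks].any(axis=1)
        tax, gen, phy = eng.coverage(covered)
        if size in (0, n_cells):  # deterministic endpoint, broadcast
            tax = np.repeat(tax, n_replicates)
            gen = np.repeat(gen, n_replicates)
            phy = np.repeat(phy, n_replicates)
        per_dim = {"taxonomic": tax, "genetic": gen, "phylogenetic": phy}
        reps_store[size] = per_dim
        for dim, vals in per_dim.items():
            rows.append(
                {
                    "size": size,
                    "dimension": dim,
                    "mean": float(vals.mean()),
                    "lo": float(np.percentile(vals, 2.5)),
                    "hi": float(np.percentile(vals, 97.5)),
                }
            )
    return AccumulationCurve(
        sample_sizes=sizes,
        table=pd.DataFrame(rows),
        replicates=reps_store,
        n_replicates=n_replicates,
        seed=seed,
    )


def compare_to_null(
    observed: CoverageReport, curve: AccumulationCurve
) -> pd.DataFrame:
    """Position of an observed cell set against the random-sampling null.

    Verdict per dimension: "below" the 2.5 percentile, "above" the 97.5
    percentile, else "within"; the empirical two-sided p is twice the
    smaller tail fraction of replicates at the set's size, capped at 1.
    """
    size = observed.n_cells
    if size not in curve.replicates:
        raise ValueError(
            f"curve has no replicates at size {size}; regenerate with this size included"
        )
    rows = []
    for dim in DIMENSIONS:
        vals = curve.at(size, dim)
        obs = observed.pct(dim)
        lo, hi = np.percentile(vals, 2.5), np.percentile(vals, 97.5)
        if obs < lo:
            verdict = "below"
        elif obs > hi:
            verdict = "above"
        else:
            verdict = "within"
        frac_ge = float((vals >= obs).mean())
        frac_le = float((vals <= obs).mean())
        p = min(1.0, 2.0 * min(frac_ge, frac_le))
        rows.append({"dimension": dim, "observed_pct": obs, "null_mean": float(vals.mean()),
                     "lo": float(lo), "hi": float(hi), "verdict": verdict, "p": p})
    return pd.DataFrame(rows)
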