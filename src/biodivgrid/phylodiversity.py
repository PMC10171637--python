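"""Faith's phylogenetic diversity, SES-PD and decile classification.

Faith's PD of a species set is the summed branch length of the minimal
subtree connecting the set, including the path to the root (so the PD
of a single species is its tip-to-root distance — the convention of the
rooted, include-root picante default). SES-PD standardizes observed PD
against a null built by shuffling taxa labels over the species pool,
which for a fixed pool is equivalent to drawing equal-sized communities
uniformly without replacement:

    SES-PD = (PD_obs - mean(PD_null)) / sd(PD_null)

Because that null depends only on community size, per-cell surfaces
share one null distribution per distinct richness value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .gridding import PresenceMatrix

logger = logging.getLogger(__name__)

DEFAULT_N_RAND = 1000


class TreeIndex:
    """Edge-indexed view of a rooted dendropy tree for fast PD sums.

    ``tip_paths[i]`` is the boolean edge set on the path from tip ``i``
    to the root; PD of a community is the branch-length sum over the
    union of its tips' paths.
    """

    def __init__(self, tree: dendropy.Tree):
        edges = []
        node_edge: dict[int, int] = {}
        for node in tree.preorder_node_iter():
            length = node.edge.length
            if node.parent_node is None and length is None:
                length = 0.0
            if length is None:
                length = 0.0
            if length < 0:
                raise ValueError("negative branch length")
            node_edge[id(node)] = len(edges)
            edges.append(float(length))
        self.edge_lengths = np.asarray(edges, dtype=float)
        leaves = [lf for lf in tree.leaf_node_iter()]
        labels = [lf.taxon.label if lf.taxon is not None else None for lf in leaves]
        if any(l is None for l in labels):
            raise ValueError("tree has unlabeled tips")
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels are not unique")
        self.tip_labels: list[str] = labels  # type: ignore[assignment]
        self.tip_index = {l: i for i, l in enumerate(self.tip_labels)}
        paths = np.zeros((len(leaves), len(edges)), dtype=bool)
        for i, lf in enumerate(leaves):
            node = lf
            while node is not None:
                paths[i, node_edge[id(node)]] = True
                node = node.parent_node
        self.tip_paths = paths
        self._paths_f = paths.astype(np.float32)

    @classmethod
    def from_newick(cls, source: str | Path) -> "TreeIndex":
        text = str(source)
        if isinstance(source, Path) or ("(" not in text and Path(text).exists()):
            text = Path(source).read_text()
        tree = dendropy.Tree.get(data=text, schema="newick")
        return cls(tree)

    def rows(self, taxa: Iterable[str]) -> np.ndarray:
        idx = []
        for t in taxa:
            if t not in self.tip_index:
                raise KeyError(f"taxon {t!r} is not a tip of the tree")
            idx.append(self.tip_index[t])
        return np.asarray(idx, dtype=int)

    def total_pd(self) -> float:
        return float(self.edge_lengths.sum())


def as_tree_index(tree: "TreeIndex | dendropy.Tree | str | Path") -> TreeIndex:
    if isinstance(tree, TreeIndex):
        return tree
    if isinstance(tree, dendropy.Tree):
        return TreeIndex(tree)
    return TreeIndex.from_newick(tree)


def faith_pd(
    tree: "TreeIndex | dendropy.Tree | str | Path",
    taxa: Iterable[str],
    include_root: bool = True,
) -> float:
    """Faith's PD of ``taxa``: branch-length sum of their spanning subtree.

    With ``include_root`` (default) the path from the subtree's MRCA up
    to the root is included; without it, only edges below the MRCA
    count. PD of the empty set is 0; an unknown taxon raises KeyError
    naming it.
    """
    ti = as_tree_index(tree)
    idx = ti.rows(taxa)
    if idx.size == 0:
        return 0.0
    union = ti.tip_paths[idx].any(axis=0)
    pd_val = float(ti.edge_lengths[union].sum())
    if not include_root:
        shared = ti.tip_paths[idx].all(axis=0)  # MRCA-to-root path edges
        pd_val -= float(ti.edge_lengths[shared].sum())
    return pd_val


@dataclass(frozen=True)
class PDResult:
    cell_id: int | None
    pd_obs: float
    ses_pd: float            # NaN when the null is degenerate
    null_mean: float
    null_sd: float
    n_randomizations: int
    rng_seed: int | None

    @property
    def ses_defined(self) -> bool:
        return not math.isnan(self.ses_pd)


def _null_pd(
    ti: TreeIndex,
    pool_rows: np.ndarray,
    size: int,
    n_rand: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """PD of n_rand communities of given size drawn uniformly from the pool."""
    n_pool = len(pool_rows)
    # per-replicate uniform subsets via random-key argsort
    keys = rng.random((n_rand, n_pool))
    picks = np.argsort(keys, axis=1)[:, :size]
    sel = np.zeros((n_rand, n_pool), dtype=np.float32)
    np.put_along_axis(sel, picks, 1.0, axis=1)
    covered = (sel @ ti._paths_f[pool_rows]) > 0
    return covered @ ti.edge_lengths


def ses_pd(
    tree: "TreeIndex | dendropy.Tree | str | Path",
    community: Iterable[str],
    pool: Iterable[str],
    n_rand: int = DEFAULT_N_RAND,
    seed: int | None = None,
) -> PDResult:
    """Standardized effect size of Faith's PD under a taxa-label null.

    The null shuffles taxa labels over the pool: each replicate is an
    equal-sized uniform sample of pool species. A community equal to
    the pool gives a zero-variance null and a NaN (flagged-undefined)
    SES.
    """
    ti = as_tree_index(tree)
    comm = list(dict.fromkeys(community))
    pool_list = list(dict.fromkeys(pool))
    if len(pool_list) < 2:
        raise ValueError("pool must contain at least two species")
    if not comm:
        raise ValueError("community must be nonempty")
    pool_set = set(pool_list)
    missing = [c for c in comm if c not in pool_set]
    if missing:
        raise KeyError(f"community species not in pool: {missing}")
    pool_rows = ti.rows(pool_list)
    pd_obs = faith_pd(ti, comm)
    rng = np.random.default_rng(seed)
    nulls = _null_pd(ti, pool_rows, len(comm), n_rand, rng)
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1))
    ses = (pd_obs - null_mean) / null_sd if null_sd > 0 else float("nan")
    return PDResult(None, pd_obs, ses, null_mean, null_sd, n_rand, seed)


def pd_surface(
    tree: "TreeIndex | dendropy.Tree | str | Path",
    presence: PresenceMatrix,
    n_rand: int = DEFAULT_N_RAND,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-cell PD and SES-PD over all retained cells with richness >= 1.

    The randomization pool is the full set of presence-matrix species
    that are tree tips; species absent from the tree are dropped with a
    logged count. Null distributions are shared across cells of equal
    tree richness (the label null depends only on community size).
    """
    ti = as_tree_index(tree)
    in_tree = np.array([s in ti.tip_index for s in presence.species_ids])
    n_dropped = int((~in_tree).sum())
    if n_dropped:
        logger.info("pd_surface: %d species absent from the tree were dropped", n_dropped)
    pool_species = [s for s, ok in zip(presence.species_ids, in_tree) if ok]
    pool_rows = ti.rows(pool_species)
    sub = presence.matrix[:, in_tree]
    rng = np.random.default_rng(seed)
    null_cache: dict[int, tuple[float, float]] = {}
    rows = []
    for i, cid in enumerate(presence.cell_ids):
        members = np.flatnonzero(sub[i])
        if members.size == 0:
            continue
        union = ti.tip_paths[pool_rows[members]].any(axis=0)
        pd_obs = float(ti.edge_lengths[union].sum())
        size = int(members.size)
        if size == len(pool_rows):
            null_mean, null_sd = pd_obs, 0.0
        elif size in null_cache:
            null_mean, null_sd = null_cache[size]
        else:
            nulls = _null_pd(ti, pool_rows, size, n_rand, rng)
            null_mean, null_sd = float(nulls.mean()), float(nulls.std(ddof=1))
            null_cache[size] = (null_mean, null_sd)
        ses = (pd_obs - null_mean) / null_sd if null_sd > 0 else float("nan")
        rows.append(
            {
                "cell_id": int(cid),
                "sr_tree": size,
                "pd_obs": pd_obs,
                "ses_pd": ses,
                "null_mean": null_mean,
                "null_sd": null_sd,
            }
        )
    return pd.DataFrame(rows)


def ses_deciles(pd_table: pd.DataFrame) -> pd.Series:
    """Classify cells into top/bottom 10% of SES-PD and a middle bulk.

    Only cells with a defined SES take part; the extreme-decile size is
    floor(n/10) cells at each end of the (ses, cell_id)-sorted order,
    so ties resolve by cell id. Requires >= 10 defined cells and a
    non-degenerate SES distribution.
    """
    defined = pd_table.dropna(subset=["ses_pd"])
    n = len(defined)
    if n < 10:
        raise ValueError(f"need >= 10 cells with defined SES-PD, got {n}")
    if defined["ses_pd"].nunique() == 1:
        raise ValueError("SES-PD distribution is degenerate (all values equal)")
    k = n // 10
    order = defined.sort_values(["ses_pd", "cell_id"]).reset_index(drop=True)
    bottom = set(order["cell_id"].iloc[:k])
    top = set(order["cell_id"].iloc[n - k:])
    out = pd.Series("middle", index=pd_table["cell_id"].to_numpy(), name="decile_class", dtype=object)
    out.loc[list(top)] = "top10"
    out.loc[list(bottom)] = "bottom10"
    undefined = pd_table.loc[pd_table["ses_pd"].isna(), "cell_id"]
    out.loc[undefined.to_numpy()] = "undefined"
    return out
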