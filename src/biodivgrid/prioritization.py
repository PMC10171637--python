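"""Conservation-priority areas from three normalized diversity dimensions.

Each retained cell with all three dimensions defined — species richness
(SR), genetic diversity (GD) and the standardized effect size of
phylogenetic diversity (SES-PD) — is min–max normalized to [0, 1],
cells are clustered by k-means in that 3-space (k = 6 in the reference
analysis, or chosen by silhouette), clusters are ranked by the mean of
their members' mean normalized value, and the cells of the top n_top
(default 3) clusters form the priority set. The coverage fraction is
the priority-cell count over all retained ocean cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

DEFAULT_K = 6
DEFAULT_N_TOP = 3
DEFAULT_N_RESTARTS = 25
DEFAULT_MAX_ITER = 300

FEATURE_COLUMNS = ["sr_norm", "gd_norm", "sespd_norm"]


def minmax_normalize(values: np.ndarray | pd.Series) -> np.ndarray:
    """Rescale to [0, 1] by the observed range: (v - min) / (max - min).

    A constant input maps to all zeros with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot normalize an empty vector")
    if np.isnan(v).any():
        raise ValueError("normalize over defined values only")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        warnings.warn("constant input to min-max normalization; returning zeros", stacklevel=2)
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def build_feature_table(
    sr: pd.Series, gd: pd.Series, sespd: pd.Series
) -> pd.DataFrame:
    """Min–max normalized feature table over cells where all three
    dimensions are defined; excluded cells are logged."""
    df = pd.concat([sr.rename("sr"), gd.rename("gd"), sespd.rename("sespd")], axis=1)
    complete = df.dropna()
    n_dropped = len(df) - len(complete)
    if n_dropped:
        logger.info("feature table: %d cells dropped for missing dimensions", n_dropped)
    if complete.empty:
        raise ValueError("no cell has all three dimensions defined")
    out = pd.DataFrame(index=complete.index)
    out["sr_norm"] = minmax_normalize(complete["sr"])
    out["gd_norm"] = minmax_normalize(complete["gd"])
    out["sespd_norm"] = minmax_normalize(complete["sespd"])
    out.index.name = "cell_id"
    return out


def kmeans_cluster(
    features: pd.DataFrame | np.ndarray,
    k: int,
    n_restarts: int = DEFAULT_N_RESTARTS,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """k-means (Lloyd, k-means++ seeding, best of ``n_restarts`` by WCSS).

    Returns (labels, centroids, wcss); deterministic under ``seed``.
    """
    X = np.asarray(features, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    n_distinct = np.unique(X, axis=0).shape[0]
    if n_distinct < k:
        raise ValueError(f"only {n_distinct} distinct points for k={k}")
    km = KMeans(
        n_clusters=k, n_init=n_restarts, max_iter=max_iter, random_state=seed
    ).fit(X)
    return km.labels_, km.cluster_centers_, float(km.inertia_)


def select_k(
    features: pd.DataFrame | np.ndarray,
    k_range: range | list[int] = range(2, 11),
    seed: int | None = None,
    n_restarts: int = DEFAULT_N_RESTARTS,
) -> tuple[int, pd.DataFrame]:
    """Choose k by mean silhouette width over ``k_range``.

    Returns the maximizing k and the full diagnostic table; the caller
    may override the choice (e.g. fix k = 6). k values with fewer
    distinct points than clusters are skipped.
    """
    X = np.asarray(features, dtype=float)
    ks = list(k_range)
    if len(X) < max(ks) + 1:
        raise ValueError(f"need at least {max(ks) + 1} cells for k up to {max(ks)}")
    rows = []
    for k in ks:
        try:
            labels, _, wcss = kmeans_cluster(X, k, n_restarts=n_restarts, seed=seed)
        except ValueError:
            rows.append({"k": k, "silhouette": float("nan"), "wcss": float("nan")})
            continue
        sil = float(silhouette_score(X, labels))
        rows.append({"k": k, "silhouette": sil, "wcss": wcss})
    diag = pd.DataFrame(rows)
    if diag["silhouette"].isna().all():
        raise ValueError("no feasible k in range")
    best = int(diag.loc[diag["silhouette"].idxmax(), "k"])
    return best, diag


@dataclass
class PriorityModel:
    k: int
    n_top: int
    assignments: pd.Series          # cell_id -> cluster label
    centroids: np.ndarray
    cluster_scores: pd.Series       # cluster -> mean of member cells' mean normalized value
    ranking: list[int]              # clusters, best first
    priority_clusters: list[int]
    priority_cells: set[int]
    coverage_fraction: float
    features: pd.DataFrame = field(repr=False)

    def summary(self) -> pd.DataFrame:
        """Per-cluster means, size, rank and priority flag."""
        df = self.features.copy()
        df["cluster"] = self.assignments
        agg = df.groupby("cluster")[FEATURE_COLUMNS].mean()
        agg["size"] = df.groupby("cluster").size()
        agg["score"] = self.cluster_scores
        agg["rank"] = [self.ranking.index(c) + 1 for c in agg.index]
        agg["is_priority"] = [c in self.priority_clusters for c in agg.index]
        return agg.sort_values("rank")


def rank_and_select(
    features: pd.DataFrame,
    n_total_cells: int,
    k: int = DEFAULT_K,
    n_top: int = DEFAULT_N_TOP,
    seed: int | None = None,
    n_restarts: int = DEFAULT_N_RESTARTS,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> PriorityModel:
    """Cluster cells, rank clusters and emit the priority cell set.

    ``features`` is a cell_id-indexed table with the three normalized
    columns. A cluster's score is the mean over member cells of the
    (weighted) mean of the three dimensions; ties in score break toward
    the larger cluster, then the lower cluster index. ``n_total_cells``
    is the retained-ocean-cell count used for the coverage fraction.
    """
    if not 1 <= n_top <= k:
        raise ValueError("n_top must lie in [1, k]")
    X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    labels, centroids, _ = kmeans_cluster(X, k, n_restarts=n_restarts, seed=seed)
    assignments = pd.Series(labels, index=features.index, name="cluster")
    w = np.asarray(weights, dtype=float)
    cell_score = (X * w).sum(axis=1) / w.sum()
    scores = pd.Series(cell_score, index=features.index).groupby(assignments).mean()
    sizes = assignments.value_counts()
    order = sorted(scores.index, key=lambda c: (-scores[c], -sizes[c], c))
    priority_clusters = order[:n_top]
    priority_cells = set(features.index[assignments.isin(priority_clusters)].tolist())
    return PriorityModel(
        k=k,
        n_top=n_top,
        assignments=assignments,
        centroids=centroids,
        cluster_scores=scores,
        ranking=order,
        priority_clusters=priority_clusters,
        priority_cells=priority_cells,
        coverage_fraction=len(priority_cells) / n_total_cells,
        features=features,
    )
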