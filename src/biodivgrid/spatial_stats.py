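"""Spatially corrected correlation between gridded surfaces.

Pearson's r between two per-cell surfaces is unchanged by spatial
autocorrelation, but its significance is not: positively autocorrelated
fields carry fewer independent observations than cells. The modified
t-test of Clifford, Richardson & Dutilleul replaces the sample size n
with an effective size estimated from both variables' spatial
autocorrelation, binned over equal-width distance classes k:

    m_eff = n / (1 + 2 * sum_k (n_k / n) * rho_x[k] * rho_y[k])

with n_k the pair count of class k and rho the per-class Moran-type
autocorrelations. The test statistic is t = r * sqrt((m_eff - 2) /
(1 - r^2)) on m_eff - 2 degrees of freedom. Only the p-value is
corrected; r itself is plain Pearson.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

DEFAULT_N_DISTANCE_CLASSES = 10


@dataclass(frozen=True)
class SurfacePair:
    """Two surfaces restricted to their common defined cells."""

    x: np.ndarray
    y: np.ndarray
    coords: np.ndarray  # (n, 2) centroid coordinates, km

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y) or len(self.x) != len(self.coords):
            raise ValueError("x, y and coords must have equal length")
        if len(self.x) < 3:
            raise ValueError(f"need >= 3 common defined cells, got {len(self.x)}")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise ValueError("missing values after intersection")

    @property
    def n(self) -> int:
        return len(self.x)


def make_surface_pair(
    x: pd.Series, y: pd.Series, coords: pd.DataFrame
) -> SurfacePair:
    """Intersect two cell-indexed surfaces on their common defined cells.

    ``coords`` is indexed by cell id with columns ``x_km, y_km``.
    """
    common = x.dropna().index.intersection(y.dropna().index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 common defined cells, got {len(common)}")
    return SurfacePair(
        x=x.loc[common].to_numpy(dtype=float),
        y=y.loc[common].to_numpy(dtype=float),
        coords=coords.loc[common, ["x_km", "y_km"]].to_numpy(dtype=float),
    )


@dataclass(frozen=True)
class ModifiedTTestResult:
    r: float
    n: int
    m_eff: float
    t_stat: float
    df: float
    p_value: float
    degenerate: bool = False


def modified_t_test(
    pair: SurfacePair, n_distance_classes: int = DEFAULT_N_DISTANCE_CLASSES
) -> ModifiedTTestResult:
    """Pearson correlation with Clifford–Dutilleul corrected significance.

    Autocovariances are estimated over equal-width classes of
    inter-centroid Euclidean distance; the effective sample size is
    clamped to [2, n] (clamping is logged). Zero variance in either
    surface is an error; |r| = 1 is reported with p = 0 and a
    degeneracy flag.
    """
    x, y = pair.x, pair.y
    n = pair.n
    dx = x - x.mean()
    dy = y - y.mean()
    s2x = float((dx**2).mean())
    s2y = float((dy**2).mean())
    if s2x == 0 or s2y == 0:
        raise ValueError("zero variance in one of the surfaces")
    r = float((dx * dy).mean() / np.sqrt(s2x * s2y))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return ModifiedTTestResult(r, n, float(n), float("inf"), float(n - 2), 0.0, True)

    d = pdist(pair.coords)
    dmax = float(d.max())
    if dmax == 0:
        raise ValueError("all centroids coincide")
    width = dmax / n_distance_classes
    cls = np.minimum((d / width).astype(int), n_distance_classes - 1)
    iu, ju = np.triu_indices(n, k=1)
    px = dx[iu] * dx[ju]
    py = dy[iu] * dy[ju]
    n_k = np.bincount(cls, minlength=n_distance_classes).astype(float)
    sum_x = np.bincount(cls, weights=px, minlength=n_distance_classes)
    sum_y = np.bincount(cls, weights=py, minlength=n_distance_classes)
    nonzero = n_k > 0
    rho_x = np.zeros(n_distance_classes)
    rho_y = np.zeros(n_distance_classes)
    rho_x[nonzero] = (sum_x[nonzero] / n_k[nonzero]) / s2x
    rho_y[nonzero] = (sum_y[nonzero] / n_k[nonzero]) / s2y
    denom = 1.0 + 2.0 * float(np.sum((n_k / n) * rho_x * rho_y))
    m_eff = n / denom if denom > 0 else float(n)
    if m_eff < 2 or m_eff > n:
        logger.debug("modified_t_test: clamping m_eff=%.2f to [2, %d]", m_eff, n)
        m_eff = float(np.clip(m_eff, 2.0, n))
    df = m_eff - 2.0
    if df <= 0:
        return ModifiedTTestResult(r, n, m_eff, 0.0, df, 1.0, True)
    t_stat = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t_stat), df))
    return ModifiedTTestResult(r, n, float(m_eff), float(t_stat), float(df), p)


def surface_correlation_matrix(
    surfaces: Mapping[str, pd.Series],
    coords: pd.DataFrame,
    n_distance_classes: int = DEFAULT_N_DISTANCE_CLASSES,
) -> pd.DataFrame:
    """All pairwise spatially corrected correlations between named surfaces.

    Returns a long-form table with one row per unordered pair plus unit
    diagonal entries.
    """
    names = list(surfaces)
    if len(names) < 2:
        raise ValueError("need at least two surfaces")
    rows = []
    for i, a in enumerate(names):
        rows.append({"x": a, "y": a, "r": 1.0, "n": int(surfaces[a].dropna().size),
                     "m_eff": float("nan"), "t": float("nan"), "df": float("nan"), "p": float("nan")})
        for b in names[i + 1:]:
            res = modified_t_test(make_surface_pair(surfaces[a], surfaces[b], coords), n_distance_classes)
            rows.append({"x": a, "y": b, "r": res.r, "n": res.n, "m_eff": res.m_eff,
                         "t": res.t_stat, "df": res.df, "p": res.p_value})
    return pd.DataFrame(rows)
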