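"""Analysis grid, ocean-fraction exclusion and range rasterization.

The analysis world is an abstract planar grid of square cells (row-major,
origin at the north-west cell centroid, x increasing east, y increasing
south, both in km). Cells whose ocean fraction is below one half are
excluded from every downstream surface, mirroring the coastal-cell
exclusion rule used when gridding a global ocean map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_CELL_SIDE_KM = 385.9
OCEAN_FRACTION_CUTOFF = 0.5  # cells strictly below are excluded


@dataclass(frozen=True)
class GridSpec:
    """A rows x cols planar grid of square cells.

    ``cells`` has one row per cell with columns
    ``cell_id, row, col, x_km, y_km, ocean_fraction, retained``;
    ``cell_id = row * n_cols + col``. Only retained cells
    (ocean_fraction >= 0.5) take part in the analysis.
    """

    n_rows: int
    n_cols: int
    cell_side_km: float
    cells: pd.DataFrame = field(repr=False)

    @property
    def retained(self) -> pd.DataFrame:
        return self.cells[self.cells["retained"]]

    @property
    def retained_ids(self) -> np.ndarray:
        return self.retained["cell_id"].to_numpy()

    def centroids(self, cell_ids: Sequence[int] | None = None) -> pd.DataFrame:
        """Centroid coordinates (km), indexed by cell_id."""
        out = self.cells.set_index("cell_id")[["x_km", "y_km"]]
        if cell_ids is not None:
            out = out.loc[list(cell_ids)]
        return out

    def neighbors(self, cell_id: int) -> list[int]:
        """4-neighborhood restricted to retained cells."""
        r, c = divmod(int(cell_id), self.n_cols)
        out = []
        retained = set(self.retained_ids.tolist())
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < self.n_rows and 0 <= cc < self.n_cols:
                nid = rr * self.n_cols + cc
                if nid in retained:
                    out.append(nid)
        return out


def build_grid(
    n_rows: int,
    n_cols: int,
    cell_side_km: float = DEFAULT_CELL_SIDE_KM,
    ocean_fraction: np.ndarray | float | None = None,
) -> GridSpec:
    """Build the analysis grid and apply the ocean-fraction exclusion rule.

    ``ocean_fraction`` is a (n_rows, n_cols) array of per-cell ocean
    fractions in [0, 1]; a scalar broadcasts; None means all-ocean.
    Cells with ocean fraction strictly below 0.5 are marked excluded;
    a cell at exactly 0.5 is retained.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid must have at least one row and one column")
    if cell_side_km <= 0:
        raise ValueError("cell_side_km must be positive")
    if ocean_fraction is None:
        frac = np.ones((n_rows, n_cols))
    else:
        frac = np.broadcast_to(np.asarray(ocean_fraction, dtype=float), (n_rows, n_cols))
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("ocean fractions must lie in [0, 1]")
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_rows * n_cols),
            "row": rows,
            "col": cols,
            "x_km": cols * cell_side_km,
            "y_km": rows * cell_side_km,
            "ocean_fraction": frac.ravel(),
        }
    )
    cells["retained"] = cells["ocean_fraction"] >= OCEAN_FRACTION_CUTOFF
    return GridSpec(n_rows=n_rows, n_cols=n_cols, cell_side_km=cell_side_km, cells=cells)


@dataclass
class PresenceMatrix:
    """Boolean cells x species incidence over the retained cells of a grid."""

    cell_ids: np.ndarray          # (n_cells,) retained cell ids, ascending
    species_ids: list[str]
    matrix: np.ndarray            # bool (n_cells, n_species)

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=int)
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.shape != (len(self.cell_ids), len(self.species_ids)):
            raise ValueError("presence matrix shape does not match ids")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("species ids must be unique")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def richness(self) -> pd.Series:
        """Per-cell species richness (SR): row sums of the incidence matrix."""
        return pd.Series(self.matrix.sum(axis=1), index=self.cell_ids, name="sr")

    def cell_index(self, cell_ids: Iterable[int]) -> np.ndarray:
        """Row positions for the given cell ids; raises on unknown ids."""
        wanted = np.asarray(list(cell_ids), dtype=int)
        pos = np.searchsorted(self.cell_ids, wanted)
        bad = (pos >= len(self.cell_ids)) | (self.cell_ids[np.minimum(pos, len(self.cell_ids) - 1)] != wanted)
        if bad.any():
            raise KeyError(f"unknown cell ids: {sorted(wanted[bad].tolist())}")
        return pos

    def species_in_cell(self, cell_id: int) -> list[str]:
        row = self.matrix[self.cell_index([cell_id])[0]]
        return [s for s, p in zip(self.species_ids, row) if p]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix.astype(int), columns=self.species_ids)
        df.insert(0, "cell_id", self.cell_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PresenceMatrix":
        species = [c for c in df.columns if c != "cell_id"]
        return cls(
            cell_ids=df["cell_id"].to_numpy(),
            species_ids=list(species),
            matrix=df[species].to_numpy().astype(bool),
        )


def rasterize_ranges(
    ranges: "PresenceMatrix | Mapping[str, object]",
    grid: GridSpec,
) -> PresenceMatrix:
    """Turn per-species ranges into a presence-absence matrix.

    ``ranges`` maps species id to either an iterable of cell ids or a
    shapely polygon (any positive-area intersection with a cell's square
    marks presence). Passing an existing :class:`PresenceMatrix` returns
    it unchanged (idempotence). Excluded (land-heavy) cells are dropped;
    a species whose range touches no retained cell is kept with an
    all-zero row contribution and triggers a warning.
    """
    if isinstance(ranges, PresenceMatrix):
        return ranges
    retained = grid.retained
    cell_ids = np.sort(retained["cell_id"].to_numpy())
    id_to_pos = {int(cid): i for i, cid in enumerate(cell_ids)}
    species_ids = list(ranges.keys())
    if len(set(species_ids)) != len(species_ids):
        raise ValueError("species ids must be unique")
    matrix = np.zeros((len(cell_ids), len(species_ids)), dtype=bool)
    half = grid.cell_side_km / 2.0
    boxes = None
    for j, sp in enumerate(species_ids):
        rng = ranges[sp]
        if hasattr(rng, "geom_type"):  # shapely geometry
            from shapely.geometry import box

            if boxes is None:
                cen = grid.centroids(cell_ids)
                boxes = [
                    box(x - half, y - half, x + half, y + half)
                    for x, y in zip(cen["x_km"], cen["y_km"])
                ]
            for i, b in enumerate(boxes):
                inter = rng.intersection(b)
                if not inter.is_empty and inter.area > 0:
                    matrix[i, j] = True
        else:
            for cid in rng:
                pos = id_to_pos.get(int(cid))
                if pos is not None:
                    matrix[pos, j] = True
        if not matrix[:, j].any():
            warnings.warn(
                f"species {sp!r} is present in no retained cell", stacklevel=2
            )
    return PresenceMatrix(cell_ids=cell_ids, species_ids=species_ids, matrix=matrix)


def richness_surface(presence: PresenceMatrix) -> pd.Series:
    """Species richness per retained cell (the S of the per-cell GD mean)."""
    return presence.richness()
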