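"""Synthetic world generator with known ground truth.

Emulates the statistical structure of a global gridded marine
biodiversity dataset without any external downloads:

* a planar grid of square cells with a per-cell ocean fraction;
* species ranges of lognormal size grown by a spreading-dye process,
  with seed cells drawn preferentially near a diversity hotspot;
* a pure-birth species tree whose tips are the species list;
* per-species aligned barcode sets whose expected pairwise difference
  per site matches a drawn per-species theta (hotspot species get a
  multiplicative theta boost);
* a smooth sea-surface-temperature field peaking at the hotspot;
* a protected-cell (MPA) set whose sampling weight decreases toward the
  hotspot, emulating protection that under-represents the hotspot.

Identical config + seed give a bit-identical world; the ``truth``
record (hotspot cells, per-species theta and range size) supports
parameter-recovery tests downstream.
"""

from __future__ import annotations

import dataclasses
import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .genetic_diversity import AlignmentRecord, SpeciesAlignment
from .gridding import GridSpec, PresenceMatrix, build_grid, rasterize_ranges

_BASES = np.array([1, 2, 3, 4], dtype=np.uint8)
_BASE_CHARS = np.array(list("NACGT"))


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of a synthetic world; defaults are the study conditions.

    ``hotspot_strength`` controls how strongly species seed cells
    concentrate near ``hotspot_center`` (0 = uniform); the MPA set
    avoids the hotspot with weight exp(mpa_hotspot_avoidance * d_norm).
    theta is the per-site expected pairwise difference of a species'
    sequences, drawn uniformly on [theta_low, theta_high] and
    multiplied by ``hotspot_theta_boost`` for species whose range
    touches a hotspot cell.
    """

    grid_rows: int = 20
    grid_cols: int = 20
    cell_side_km: float = 385.9
    ocean_fraction_field: tuple | None = None   # (rows, cols) nested tuple or None = all ocean
    n_species: int = 150
    range_size_log_mean: float = 1.6            # lognormal, in cells (median ~5)
    range_size_log_sd: float = 0.8
    hotspot_center: int | None = None           # cell id; None = grid center
    hotspot_strength: float = 8.0
    hotspot_radius_cells: float = 2.5           # truth hotspot = cells within this radius
    hotspot_theta_boost: float = 2.0
    birth_rate: float = 1.0
    seq_per_species_mean: float = 8.0
    theta_low: float = 0.002
    theta_high: float = 0.02
    seq_length: int = 600
    sst_base: float = 2.0
    sst_amplitude: float = 25.0
    sst_noise_sd: float = 0.5
    mpa_fraction: float = 0.12
    mpa_hotspot_avoidance: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_rows, self.grid_cols, self.n_species, self.seq_length) < 1:
            raise ValueError("counts must be >= 1")
        if not (0 <= self.mpa_fraction <= 1):
            raise ValueError("mpa_fraction must lie in [0, 1]")
        if not (0 <= self.theta_low <= self.theta_high):
            raise ValueError("need 0 <= theta_low <= theta_high")
        if self.theta_high >= 0.75:
            raise ValueError("theta_high must be < 0.75 (p-distance saturation)")
        if self.hotspot_strength < 0 or self.mpa_hotspot_avoidance < 0:
            raise ValueError("hotspot_strength and mpa_hotspot_avoidance must be >= 0")
        if self.seq_per_species_mean < 1:
            raise ValueError("seq_per_species_mean must be >= 1")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "WorldConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown world config keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("ocean_fraction_field") is not None:
            d["ocean_fraction_field"] = tuple(tuple(row) for row in d["ocean_fraction_field"])
        return cls(**d)


@dataclass
class SyntheticWorld:
    config: WorldConfig
    grid: GridSpec
    presence: PresenceMatrix
    tree: dendropy.Tree = field(repr=False)
    alignments: dict[str, SpeciesAlignment] = field(repr=False)
    sst: pd.Series = field(repr=False)          # per retained cell, deg C
    mpa_cells: set[int] = field(default_factory=set)
    truth: dict = field(default_factory=dict, repr=False)

    @property
    def species_ids(self) -> list[str]:
        return self.presence.species_ids

    def tree_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def _theta_to_site_rate(theta: float) -> float:
    """Per-sequence per-site mutation probability p such that two
    star-descendants differ at a site with probability theta.

    d(p) = 2p(1-p) + p^2 * 2/3 = 2p - (4/3)p^2  =>  invert for p.
    """
    if theta <= 0:
        return 0.0
    return 0.375 * (2.0 - math.sqrt(4.0 - 16.0 * theta / 3.0))


def _grow_range(
    seed_cell: int,
    target: int,
    grid: GridSpec,
    retained: set[int],
    rng: np.random.Generator,
) -> set[int]:
    """Spreading dye: grow a contiguous region of ``target`` ocean cells
    from a seed cell through ocean-valid 4-neighbors."""
    cells = {seed_cell}
    frontier = [n for n in grid.neighbors(seed_cell) if n in retained]
    while len(cells) < target and frontier:
        pick = int(rng.integers(len(frontier)))
        nxt = frontier.pop(pick)
        if nxt in cells:
            continue
        cells.add(nxt)
        for n in grid.neighbors(nxt):
            if n in retained and n not in cells:
                frontier.append(n)
    return cells


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate the full synthetic world; deterministic under the seed."""
    ss = np.random.SeedSequence(config.seed)
    rng_range, rng_tree, rng_theta, rng_seq, rng_sst, rng_mpa = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    frac = None
    if config.ocean_fraction_field is not None:
        frac = np.asarray(config.ocean_fraction_field, dtype=float)
    grid = build_grid(config.grid_rows, config.grid_cols, config.cell_side_km, frac)
    retained_ids = np.sort(grid.retained_ids)
    n_ocean = len(retained_ids)
    if n_ocean == 0:
        raise ValueError("no retained ocean cells")
    retained_set = set(int(c) for c in retained_ids)

    # hotspot geometry
    if config.hotspot_center is None:
        center = int((config.grid_rows // 2) * config.grid_cols + config.grid_cols // 2)
    else:
        center = int(config.hotspot_center)
    cen = grid.centroids(retained_ids.tolist())
    cx, cy = grid.cells.set_index("cell_id").loc[center, ["x_km", "y_km"]]
    d = np.hypot(cen["x_km"] - cx, cen["y_km"] - cy).to_numpy()
    d_norm = d / d.max() if d.max() > 0 else np.zeros_like(d)
    hotspot_cells = set(
        int(c) for c, dist in zip(retained_ids, d)
        if dist <= config.hotspot_radius_cells * config.cell_side_km
    )

    # species ranges: lognormal target sizes, hotspot-weighted seed cells
    species_ids = [f"sp{i:04d}" for i in range(config.n_species)]
    targets = np.maximum(
        1,
        np.round(
            rng_range.lognormal(config.range_size_log_mean, config.range_size_log_sd, config.n_species)
        ).astype(int),
    )
    too_big = np.flatnonzero(targets > n_ocean)
    if too_big.size:
        i = int(too_big[0])
        raise ValueError(
            f"species index {i}: requested range size {targets[i]} exceeds "
            f"the {n_ocean} available ocean cells"
        )
    seed_w = np.exp(-config.hotspot_strength * d_norm)
    seed_w = seed_w / seed_w.sum()
    ranges: dict[str, set[int]] = {}
    for i, sp in enumerate(species_ids):
        seed_cell = int(rng_range.choice(retained_ids, p=seed_w))
        ranges[sp] = _grow_range(seed_cell, int(targets[i]), grid, retained_set, rng_range)
    presence = rasterize_ranges(ranges, grid)

    # pure-birth species tree
    py_rng = random.Random(int(rng_tree.integers(2**31)))
    tree = treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=0.0,
        num_extant_tips=config.n_species,
        rng=py_rng,
    )
    for leaf, sp in zip(tree.leaf_node_iter(), species_ids):
        leaf.taxon.label = sp
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(edge.length)  # canonical serialization (0 -> 0.0)

    # per-species theta, boosted for hotspot-touching species
    theta = rng_theta.uniform(config.theta_low, config.theta_high, config.n_species)
    hotspot_species = [
        sp for sp in species_ids if ranges[sp] & hotspot_cells
    ]
    boost_idx = [species_ids.index(sp) for sp in hotspot_species]
    theta[boost_idx] *= config.hotspot_theta_boost
    theta = np.minimum(theta, 0.74)  # stay below p-distance saturation

    # star-model aligned sequences with cell-jittered coordinates
    alignments: dict[str, SpeciesAlignment] = {}
    id_to_xy = grid.cells.set_index("cell_id")[["x_km", "y_km"]]
    half = config.cell_side_km / 2.0
    for i, sp in enumerate(species_ids):
        n_seq = max(2, int(rng_seq.poisson(config.seq_per_species_mean)))
        ancestral = rng_seq.choice(_BASES, size=config.seq_length)
        p = _theta_to_site_rate(float(theta[i]))
        muts = rng_seq.random((n_seq, config.seq_length)) < p
        shifts = rng_seq.integers(1, 4, size=(n_seq, config.seq_length))
        seqs = np.where(muts, ((ancestral - 1 + shifts) % 4) + 1, ancestral).astype(np.uint8)
        range_cells = np.array(sorted(ranges[sp]))
        homes = rng_seq.choice(range_cells, size=n_seq)
        jit = rng_seq.uniform(-half, half, size=(n_seq, 2))
        records = []
        for j in range(n_seq):
            x = float(id_to_xy.loc[homes[j], "x_km"] + jit[j, 0])
            y = float(id_to_xy.loc[homes[j], "y_km"] + jit[j, 1])
            seq_str = "".join(_BASE_CHARS[seqs[j]])
            records.append(AlignmentRecord(f"{sp}_{j}", seq_str, y, x))
        alignments[sp] = SpeciesAlignment(species_id=sp, records=records)

    # SST: smooth hotspot-peaked gradient + white noise
    sigma = 0.35 * d.max() if d.max() > 0 else 1.0
    sst_vals = (
        config.sst_base
        + config.sst_amplitude * np.exp(-(d**2) / (2 * sigma**2))
        + rng_sst.normal(0, config.sst_noise_sd, n_ocean)
    )
    sst = pd.Series(sst_vals, index=retained_ids, name="sst")

    # MPA cells: weighted away from the hotspot (Gumbel top-k sampling)
    n_mpa = int(round(config.mpa_fraction * n_ocean))
    if n_mpa > 0:
        logw = config.mpa_hotspot_avoidance * d_norm
        keys = logw + rng_mpa.gumbel(size=n_ocean)
        mpa_cells = set(int(c) for c in retained_ids[np.argsort(-keys)[:n_mpa]])
    else:
        mpa_cells = set()

    truth = {
        "hotspot_center": center,
        "hotspot_cells": sorted(hotspot_cells),
        "hotspot_species": hotspot_species,
        "theta": {sp: float(theta[i]) for i, sp in enumerate(species_ids)},
        "range_size": {sp: len(ranges[sp]) for sp in species_ids},
    }
    return SyntheticWorld(
        config=config,
        grid=grid,
        presence=presence,
        tree=tree,
        alignments=alignments,
        sst=sst,
        mpa_cells=mpa_cells,
        truth=truth,
    )


# ---------------------------------------------------------------- I/O

def write_world(world: SyntheticWorld, directory: str | Path, overwrite: bool = False) -> dict:
    """Write a world as plain-text artifacts and return the manifest.

    Layout: one aligned FASTA per species under ``fasta/`` (headers
    ``seqID|speciesID|lat|lon``), ``tree.nwk``, ``presence.csv``,
    ``grid.csv``, ``sst.csv``, ``mpa_cells.txt`` and
    ``manifest.json`` (config + seed + truth). Refuses to clobber an
    existing manifest unless ``overwrite``.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    (directory / "fasta").mkdir(parents=True, exist_ok=True)

    for sp, aln in world.alignments.items():
        with open(directory / "fasta" / f"{sp}.fasta", "w") as fh:
            for rec in aln.records:
                fh.write(f">{rec.seq_id}|{sp}|{rec.lat!r}|{rec.lon!r}\n{rec.sequence}\n")
    (directory / "tree.nwk").write_text(world.tree_newick() + "\n")
    world.presence.to_frame().to_csv(directory / "presence.csv", index=False)
    world.grid.cells.to_csv(directory / "grid.csv", index=False)
    world.sst.rename_axis("cell_id").reset_index().to_csv(directory / "sst.csv", index=False)
    (directory / "mpa_cells.txt").write_text(
        "\n".join(str(c) for c in sorted(world.mpa_cells)) + "\n"
    )
    manifest = {
        "config": world.config.to_dict(),
        "seed": world.config.seed,
        "truth": world.truth,
        "files": {
            "fasta_dir": "fasta",
            "tree": "tree.nwk",
            "presence": "presence.csv",
            "grid": "grid.csv",
            "sst": "sst.csv",
            "mpa": "mpa_cells.txt",
        },
        "n_species": len(world.species_ids),
        "n_cells": world.presence.n_cells,
    }
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


def read_world(directory: str | Path) -> SyntheticWorld:
    """Read a world written by :func:`write_world`; round-trips bit-identically."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    config = WorldConfig.from_dict(manifest["config"])
    grid_df = pd.read_csv(directory / "grid.csv", float_precision="round_trip")
    grid = GridSpec(
        n_rows=config.grid_rows,
        n_cols=config.grid_cols,
        cell_side_km=config.cell_side_km,
        cells=grid_df.astype({"retained": bool}),
    )
    presence = PresenceMatrix.from_frame(pd.read_csv(directory / "presence.csv"))
    tree = dendropy.Tree.get(path=str(directory / "tree.nwk"), schema="newick")
    alignments = {}
    for sp in presence.species_ids:
        alignments[sp] = SpeciesAlignment.from_fasta(directory / "fasta" / f"{sp}.fasta", sp)
    sst_df = pd.read_csv(directory / "sst.csv", float_precision="round_trip")
    sst = pd.Series(sst_df["sst"].to_numpy(), index=sst_df["cell_id"].to_numpy(), name="sst")
    mpa_text = (directory / "mpa_cells.txt").read_text().split()
    mpa_cells = set(int(c) for c in mpa_text)
    truth = manifest["truth"]
    truth["theta"] = {k: float(v) for k, v in truth["theta"].items()}
    return SyntheticWorld(
        config=config,
        grid=grid,
        presence=presence,
        tree=tree,
        alignments=alignments,
        sst=sst,
        mpa_cells=mpa_cells,
        truth=truth,
    )


def worlds_equal(a: SyntheticWorld, b: SyntheticWorld) -> bool:
    """Value equality of two worlds (used by the round-trip contract)."""
    if a.config != b.config:
        return False
    if not a.grid.cells.reset_index(drop=True).equals(b.grid.cells.reset_index(drop=True)):
        return False
    if a.presence.species_ids != b.presence.species_ids:
        return False
    if not np.array_equal(a.presence.cell_ids, b.presence.cell_ids):
        return False
    if not np.array_equal(a.presence.matrix, b.presence.matrix):
        return False
    if a.tree_newick() != b.tree_newick():
        return False
    if set(a.alignments) != set(b.alignments):
        return False
    for sp in a.alignments:
        if a.alignments[sp].records != b.alignments[sp].records:
            return False
    if not np.array_equal(a.sst.index, b.sst.index) or not np.array_equal(
        a.sst.to_numpy(), b.sst.to_numpy()
    ):
        return False
    if a.mpa_cells != b.mpa_cells:
        return False
    ta, tb = a.truth, b.truth
    return (
        ta["hotspot_center"] == tb["hotspot_center"]
        and list(ta["hotspot_cells"]) == list(tb["hotspot_cells"])
        and ta["theta"] == tb["theta"]
        and {k: int(v) for k, v in ta["range_size"].items()}
        == {k: int(v) for k, v in tb["range_size"].items()}
    )
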