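"""Per-species nucleotide diversity (pi) and per-cell genetic diversity (GD).

pi is the mean uncorrected pairwise difference per compared site
(p-distance) over sequence pairs that pass two filters: the pair must
share unambiguous bases at more than 60% of alignment columns, and
differ at fewer than 10% of the compared columns. Both bounds are
strict, and columns where either sequence carries a gap or an ambiguity
code are dropped from the comparison entirely. Per-cell GD is the
arithmetic mean of pi over the species present in the cell:
GD = (1/S) * sum(pi_p), S the number of pi-estimable species present.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gridding import GridSpec, PresenceMatrix, build_grid, rasterize_ranges

DEFAULT_MIN_OVERLAP = 0.60
DEFAULT_MAX_DIFFERENCE = 0.10
DEFAULT_MIN_SEQUENCES = 2

# only unambiguous bases take part in a comparison
_BASE_CODE = {"A": 1, "C": 2, "G": 3, "T": 4}


@dataclass(frozen=True)
class AlignmentRecord:
    seq_id: str
    sequence: str
    lat: float
    lon: float


@dataclass
class SpeciesAlignment:
    """One species' aligned barcode sequences with sampling coordinates."""

    species_id: str
    records: list[AlignmentRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"{self.species_id}: alignment has no records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(
                f"{self.species_id}: aligned sequences differ in length {sorted(lengths)}"
            )

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @classmethod
    def from_fasta(cls, path: str | Path, species_id: str | None = None) -> "SpeciesAlignment":
        """Read an aligned FASTA whose headers follow ``seqID|speciesID|lat|lon``."""
        from Bio import SeqIO

        records = []
        sp = species_id
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.description.split("|")
            if len(parts) != 4:
                raise ValueError(f"{path}: header {rec.description!r} is not seqID|speciesID|lat|lon")
            seq_id, rec_sp, lat, lon = parts
            if sp is None:
                sp = rec_sp
            elif rec_sp != sp:
                raise ValueError(f"{path}: mixed species ids {sp!r} and {rec_sp!r}")
            records.append(AlignmentRecord(seq_id, str(rec.seq).upper(), float(lat), float(lon)))
        if sp is None:
            raise ValueError(f"{path}: empty FASTA")
        return cls(species_id=sp, records=records)


@dataclass(frozen=True)
class PairStats:
    """Overlap and p-distance of one sequence pair.

    ``difference_fraction`` is NaN (and ``comparable`` False) when the
    pair shares no unambiguously called column.
    """

    overlap_fraction: float
    difference_fraction: float
    comparable: bool


@dataclass(frozen=True)
class SpeciesDiversity:
    species_id: str
    pi: float                # NaN when no estimate
    n_sequences: int
    n_valid_pairs: int
    n_filtered_pairs: int

    @property
    def has_estimate(self) -> bool:
        return not math.isnan(self.pi)


def _encode(seq: str) -> np.ndarray:
    """uint8 codes: 1..4 for A/C/G/T, 0 for gaps, N and ambiguity codes."""
    out = np.zeros(len(seq), dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return out


def pair_stats(a: str | np.ndarray, b: str | np.ndarray) -> PairStats:
    """Overlap fraction and p-distance for one pair of aligned sequences.

    Columns where either sequence has a gap, N, or an IUPAC ambiguity
    code are excluded from both the overlap numerator and the distance.
    """
    ea = _encode(a) if isinstance(a, str) else a
    eb = _encode(b) if isinstance(b, str) else b
    if len(ea) != len(eb):
        raise ValueError(f"aligned sequences differ in length: {len(ea)} vs {len(eb)}")
    if len(ea) == 0:
        raise ValueError("empty alignment")
    both = (ea > 0) & (eb > 0)
    n_comp = int(both.sum())
    overlap = n_comp / len(ea)
    if n_comp == 0:
        return PairStats(overlap_fraction=0.0, difference_fraction=float("nan"), comparable=False)
    n_diff = int((ea[both] != eb[both]).sum())
    return PairStats(overlap_fraction=overlap, difference_fraction=n_diff / n_comp, comparable=True)


def species_pi(
    aln: SpeciesAlignment,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    max_difference: float = DEFAULT_MAX_DIFFERENCE,
    min_sequences: int = DEFAULT_MIN_SEQUENCES,
) -> SpeciesDiversity:
    """Nucleotide diversity of one species under the pair filters.

    All unordered pairs are evaluated; a pair survives only if its
    overlap fraction exceeds ``min_overlap`` AND its difference fraction
    is defined and below ``max_difference`` (both strictly). pi is the
    mean difference fraction over surviving pairs. Species with fewer
    than ``min_sequences`` sequences, or with no surviving pair, yield a
    NaN-pi "no estimate" record.
    """
    n = aln.n_sequences
    if n < min_sequences:
        return SpeciesDiversity(aln.species_id, float("nan"), n, 0, 0)
    enc = [_encode(r.sequence) for r in aln.records]
    kept: list[float] = []
    n_filtered = 0
    for i, j in itertools.combinations(range(n), 2):
        st = pair_stats(enc[i], enc[j])
        if st.comparable and st.overlap_fraction > min_overlap and st.difference_fraction < max_difference:
            kept.append(st.difference_fraction)
        else:
            n_filtered += 1
    if not kept:
        return SpeciesDiversity(aln.species_id, float("nan"), n, 0, n_filtered)
    return SpeciesDiversity(aln.species_id, float(np.mean(kept)), n, len(kept), n_filtered)


def species_pi_table(
    alignments: Iterable[SpeciesAlignment],
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    max_difference: float = DEFAULT_MAX_DIFFERENCE,
    min_sequences: int = DEFAULT_MIN_SEQUENCES,
) -> pd.DataFrame:
    """Per-species diversity table (one row per species, NaN pi = no estimate)."""
    rows = [
        species_pi(a, min_overlap, max_difference, min_sequences) for a in alignments
    ]
    return pd.DataFrame(
        {
            "species_id": [r.species_id for r in rows],
            "pi": [r.pi for r in rows],
            "n_sequences": [r.n_sequences for r in rows],
            "n_valid_pairs": [r.n_valid_pairs for r in rows],
            "n_filtered_pairs": [r.n_filtered_pairs for r in rows],
        }
    )


def cell_gd(pi_values: Sequence[float]) -> float:
    """GD of one cell: the mean of the pi values of its S contributing species.

    NaN entries (species without an estimate) are dropped from S; a cell
    with no contributing species gets NaN as its missing-value marker.
    """
    vals = np.asarray([v for v in pi_values if not math.isnan(v)], dtype=float)
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def gd_surface(presence: PresenceMatrix, pi_by_species: Mapping[str, float]) -> pd.Series:
    """Per-cell GD: mean species pi over species present in each cell.

    pi is a global per-species estimate (all of a species' sequences,
    wherever sampled), averaged across the species located in the cell.
    """
    pi = np.array(
        [pi_by_species.get(s, float("nan")) for s in presence.species_ids], dtype=float
    )
    has = ~np.isnan(pi)
    counts = presence.matrix[:, has].sum(axis=1)
    sums = presence.matrix[:, has] @ pi[has]
    with np.errstate(invalid="ignore"):
        gd = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(gd, index=presence.cell_ids, name="gd")


def _coarsen(presence: PresenceMatrix, grid: GridSpec, factor: int) -> tuple[PresenceMatrix, GridSpec, dict[int, int]]:
    """Aggregate base cells into factor x factor blocks (presence = any).

    Returns the coarse presence, coarse grid, and the base-cell -> block
    cell-id map used to project coarse surfaces back onto base cells.
    """
    n_rows = -(-grid.n_rows // factor)
    n_cols = -(-grid.n_cols // factor)
    frac = np.zeros((n_rows, n_cols))
    count = np.zeros((n_rows, n_cols))
    cells = grid.cells
    block_of = {}
    for cid, r, c, of in zip(cells["cell_id"], cells["row"], cells["col"], cells["ocean_fraction"]):
        br, bc = r // factor, c // factor
        frac[br, bc] += of
        count[br, bc] += 1
        block_of[int(cid)] = int(br * n_cols + bc)
    coarse_grid = build_grid(n_rows, n_cols, grid.cell_side_km * factor, frac / np.maximum(count, 1))
    ranges = {
        sp: {
            block_of[int(cid)]
            for cid in presence.cell_ids[presence.matrix[:, j]]
        }
        for j, sp in enumerate(presence.species_ids)
    }
    coarse = rasterize_ranges(ranges, coarse_grid)
    return coarse, coarse_grid, block_of


def gd_sensitivity(
    alignments: Sequence[SpeciesAlignment],
    presence: PresenceMatrix,
    grid: GridSpec,
    min_sequences_values: Sequence[int] = (2, 5, 10),
    coarsen_factors: Sequence[int] = (),
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    max_difference: float = DEFAULT_MAX_DIFFERENCE,
) -> pd.DataFrame:
    """Robustness of the GD surface to the per-species sequence threshold
    and to grid-cell resolution.

    Recomputes the GD surface per setting and reports the spatially
    corrected (modified t-test) correlation between each pair of
    surfaces on the intersection of defined cells. Coarse surfaces are
    projected back onto their base cells before comparison.
    """
    from .spatial_stats import make_surface_pair, modified_t_test

    if len(min_sequences_values) + len(coarsen_factors) < 2:
        raise ValueError("need at least two settings to compare")
    coords = grid.centroids(presence.cell_ids.tolist())
    surfaces: list[tuple[str, pd.Series]] = []
    base_tables: dict[int, Mapping[str, float]] = {}
    for i, ms in enumerate(min_sequences_values):
        tab = species_pi_table(alignments, min_overlap, max_difference, ms)
        pi_map = dict(zip(tab["species_id"], tab["pi"]))
        base_tables[ms] = pi_map
        name = f"min_seq={ms}"
        if any(n == name for n, _ in surfaces):
            name = f"{name}#{i}"
        surfaces.append((name, gd_surface(presence, pi_map)))
    if coarsen_factors:
        ms0 = min_sequences_values[0] if min_sequences_values else DEFAULT_MIN_SEQUENCES
        if ms0 in base_tables:
            pi_map = base_tables[ms0]
        else:
            tab = species_pi_table(alignments, min_overlap, max_difference, ms0)
            pi_map = dict(zip(tab["species_id"], tab["pi"]))
        for f in coarsen_factors:
            if f < 1:
                raise ValueError("coarsening factor must be >= 1")
            coarse, _, block_of = _coarsen(presence, grid, int(f))
            coarse_gd = gd_surface(coarse, pi_map)
            projected = pd.Series(
                [coarse_gd.get(block_of[int(c)], float("nan")) for c in presence.cell_ids],
                index=presence.cell_ids,
            )
            surfaces.append((f"cell_side={grid.cell_side_km * f:g}km", projected))
    rows = []
    by_name = dict(surfaces)
    for a, b in itertools.combinations([n for n, _ in surfaces], 2):
        pair = make_surface_pair(by_name[a], by_name[b], coords)
        res = modified_t_test(pair)
        rows.append(
            {
                "setting_a": a,
                "setting_b": b,
                "r": res.r,
                "n": res.n,
                "m_eff": res.m_eff,
                "t": res.t_stat,
                "df": res.df,
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows)
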