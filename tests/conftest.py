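import itertools

import dendropy
import numpy as np
import pytest

from biodivgrid.synthetic_data import WorldConfig, generate_world

TOY_NEWICK = "((A:1,B:2):3,(C:4,D:5):6);"


@pytest.fixture(scope="session")
def toy_tree():
    return dendropy.Tree.get(data=TOY_NEWICK, schema="newick")


@pytest.fixture(scope="session")
def small_world():
    """15x15 world, 60 species: shared by tests that only read it."""
    return generate_world(
        WorldConfig(grid_rows=15, grid_cols=15, n_species=60, seed=11)
    )


@pytest.fixture(scope="session")
def study_world():
    """The default study conditions (20x20 grid, 150 species, strong hotspot)."""
    return generate_world(WorldConfig(seed=5))


# ---------------------------------------------------------------- oracles

VALID_BASES = set("ACGT")


def pair_oracle(a: str, b: str):
    """Hand enumeration of overlap fraction and p-distance for one pair."""
    comp = [(x, y) for x, y in zip(a, b) if x in VALID_BASES and y in VALID_BASES]
    overlap = len(comp) / len(a)
    if not comp:
        return overlap, None
    return overlap, sum(x != y for x, y in comp) / len(comp)


def pi_oracle(seqs, min_overlap=0.60, max_difference=0.10):
    """Explicit all-pairs enumeration of pi under the strict filters."""
    kept, filtered = [], 0
    for a, b in itertools.combinations(seqs, 2):
        overlap, diff = pair_oracle(a, b)
        if diff is not None and overlap > min_overlap and diff < max_difference:
            kept.append(diff)
        else:
            filtered += 1
    pi = sum(kept) / len(kept) if kept else float("nan")
    return pi, len(kept), filtered


def faith_pd_oracle(tree: dendropy.Tree, taxa) -> float:
    """Brute-force edge-union sum over tip-to-root paths."""
    taxa = set(taxa)
    edges = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label in taxa:
            node = leaf
            while node is not None:
                edges.add(id(node))
                node = node.parent_node
    total = 0.0
    for node in tree.preorder_node_iter():
        if id(node) in edges and node.edge.length:
            total += node.edge.length
    return total


def random_alignment(rng: np.random.Generator, n_seqs: int, length: int = 40,
                     messy: bool = True) -> list[str]:
    """Random aligned sequences with gaps/N/ambiguity codes mixed in."""
    alphabet = list("ACGT")
    base = rng.choice(alphabet, size=length)
    out = []
    for _ in range(n_seqs):
        seq = base.copy()
        mut = rng.random(length) < rng.uniform(0.0, 0.25)
        seq[mut] = rng.choice(alphabet, size=int(mut.sum()))
        if messy:
            junk = rng.random(length) < 0.1
            seq[junk] = rng.choice(list("-NRYWS"), size=int(junk.sum()))
        out.append("".join(seq))
    return out
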