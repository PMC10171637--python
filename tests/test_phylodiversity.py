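import itertools
import math
import random

import dendropy
import numpy as np
import pandas as pd
import pytest
from dendropy.simulate import treesim

from biodivgrid.gridding import PresenceMatrix
from biodivgrid.phylodiversity import (
    TreeIndex,
    faith_pd,
    pd_surface,
    ses_deciles,
    ses_pd,
)

from conftest import faith_pd_oracle


class TestFaithPD:
    def test_toy_tree_hand_sums(self, toy_tree):
        """((A:1,B:2):3,(C:4,D:5):6): {A,B} -> 6, {A} -> 4 (tip-to-root)."""
        assert faith_pd(toy_tree, {"A", "B"}) == pytest.approx(6.0)
        assert faith_pd(toy_tree, {"A"}) == pytest.approx(4.0)
        assert faith_pd(toy_tree, {"A", "B", "C", "D"}) == pytest.approx(21.0)

    def test_empty_set_and_unknown_taxon(self, toy_tree):
        assert faith_pd(toy_tree, set()) == 0.0
        with pytest.raises(KeyError, match="X"):
            faith_pd(toy_tree, {"X"})

    def test_exclude_root_variant(self, toy_tree):
        # without the root path, PD({A,B}) drops the stem edge of (A,B)
        assert faith_pd(toy_tree, {"A", "B"}, include_root=False) == pytest.approx(3.0)
        assert faith_pd(toy_tree, {"A"}, include_root=False) == 0.0

    def test_monotone_under_species_addition(self, toy_tree):
        taxa = ["A", "B", "C", "D"]
        prev = 0.0
        for k in range(1, 5):
            cur = faith_pd(toy_tree, taxa[:k])
            assert cur >= prev
            prev = cur
        assert prev == pytest.approx(faith_pd(toy_tree, taxa))

    def test_matches_brute_force_on_random_trees(self):
        """Edge-union oracle equivalence on random 10-tip trees."""
        rng = random.Random(42)
        np_rng = np.random.default_rng(42)
        for _ in range(25):
            tree = treesim.birth_death_tree(
                birth_rate=1.0, death_rate=0.0, num_extant_tips=10, rng=rng
            )
            labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
            ti = TreeIndex(tree)
            for size in (1, 3, 7, 10):
                taxa = list(np_rng.choice(labels, size=size, replace=False))
                assert faith_pd(ti, taxa) == pytest.approx(faith_pd_oracle(tree, taxa))


class TestSESPD:
    def test_degenerate_null_community_equals_pool(self, toy_tree):
        res = ses_pd(toy_tree, ["A", "B", "C", "D"], ["A", "B", "C", "D"], n_rand=50, seed=0)
        assert math.isnan(res.ses_pd) and not res.ses_defined

    def test_small_pool_rejected(self, toy_tree):
        with pytest.raises(ValueError):
            ses_pd(toy_tree, ["A"], ["A"])

    def test_null_matches_exhaustive_enumeration(self, toy_tree):
        """MC null mean/SD within 3 MC standard errors of the 6-pair enumeration."""
        labels = ["A", "B", "C", "D"]
        pds = [faith_pd(toy_tree, c) for c in itertools.combinations(labels, 2)]
        exact_mean = np.mean(pds)
        exact_sd = np.std(pds)
        n_rand = 1000
        res = ses_pd(toy_tree, ["A", "C"], labels, n_rand=n_rand, seed=3)
        se_mean = exact_sd / math.sqrt(n_rand)
        assert abs(res.null_mean - exact_mean) < 3 * se_mean
        se_sd = exact_sd / math.sqrt(2 * (n_rand - 1))
        assert abs(res.null_sd - exact_sd) < 3 * se_sd

    def test_ses_distribution_calibrated_under_own_null(self):
        """SES of pool-random communities has mean ~0 and SD ~1."""
        tree = treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=40, rng=random.Random(9)
        )
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        rng = np.random.default_rng(9)
        ses = []
        for i in range(300):
            size = int(rng.integers(2, 20))
            comm = list(rng.choice(labels, size=size, replace=False))
            res = ses_pd(tree, comm, labels, n_rand=400, seed=int(rng.integers(2**31)))
            ses.append(res.ses_pd)
        ses = np.asarray(ses)
        assert abs(ses.mean()) < 0.1
        assert abs(ses.std(ddof=1) - 1) < 0.15


class TestPDSurface:
    def make_presence(self, tree, rng, n_cells=30):
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        mat = rng.random((n_cells, len(labels))) < 0.3
        mat[0] = True  # one cell with the full pool
        return PresenceMatrix(np.arange(n_cells), labels, mat)

    def test_per_cell_pd_matches_oracle_and_full_pool_flag(self):
        rng = np.random.default_rng(1)
        tree = treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=12, rng=random.Random(1)
        )
        pm = self.make_presence(tree, rng, n_cells=15)
        tab = pd_surface(tree, pm, n_rand=100, seed=0).set_index("cell_id")
        for cid in tab.index:
            taxa = pm.species_in_cell(int(cid))
            assert tab.loc[cid, "pd_obs"] == pytest.approx(faith_pd_oracle(tree, taxa))
        # the full-pool cell has a degenerate null
        assert math.isnan(tab.loc[0, "ses_pd"])

    def test_identical_species_sets_get_identical_pd(self, toy_tree):
        pm = PresenceMatrix(
            np.array([0, 1]), ["A", "B", "C", "D"],
            np.array([[1, 1, 0, 0], [1, 1, 0, 0]], bool),
        )
        tab = pd_surface(toy_tree, pm, n_rand=100, seed=0)
        assert tab["pd_obs"].nunique() == 1

    def test_species_missing_from_tree_are_dropped(self, toy_tree):
        pm = PresenceMatrix(
            np.array([0]), ["A", "B", "ghost"], np.ones((1, 3), bool)
        )
        tab = pd_surface(toy_tree, pm, n_rand=10, seed=0)
        assert tab.iloc[0]["sr_tree"] == 2

    def test_sr_pd_positively_correlated_on_synthetic_world(self, study_world):
        """Richer cells span more tree: Spearman rho > 0, p < 0.01."""
        from scipy.stats import spearmanr

        w = study_world
        tab = pd_surface(w.tree, w.presence, n_rand=50, seed=0).set_index("cell_id")
        sr = w.presence.richness().loc[tab.index]
        rho, p = spearmanr(sr, tab["pd_obs"])
        assert rho > 0 and p < 0.01


class TestSesDeciles:
    @staticmethod
    def table(values):
        return pd.DataFrame({"cell_id": np.arange(len(values)), "ses_pd": values})

    def test_ten_distinct_cells_one_each(self):
        cls = ses_deciles(self.table(np.arange(10.0)))
        assert (cls == "top10").sum() == 1 and (cls == "bottom10").sum() == 1
        assert cls.loc[9] == "top10" and cls.loc[0] == "bottom10"

    def test_all_equal_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ses_deciles(self.table(np.ones(12)))

    def test_hundred_cells_sort_oracle(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=100)
        cls = ses_deciles(self.table(vals))
        order = np.argsort(vals, kind="stable")
        assert set(np.flatnonzero((cls == "bottom10").to_numpy())) == set(order[:10])
        assert set(np.flatnonzero((cls == "top10").to_numpy())) == set(order[-10:])

    def test_too_few_defined_cells_rejected(self):
        vals = np.r_[np.arange(5.0), [np.nan] * 8]
        with pytest.raises(ValueError):
            ses_deciles(self.table(vals))
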