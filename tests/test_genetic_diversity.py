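import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biodivgrid.genetic_diversity import (
    AlignmentRecord,
    SpeciesAlignment,
    cell_gd,
    gd_sensitivity,
    gd_surface,
    pair_stats,
    species_pi,
    species_pi_table,
)
from biodivgrid.gridding import PresenceMatrix
from biodivgrid.synthetic_data import WorldConfig, generate_world

from conftest import pi_oracle, random_alignment


def make_aln(seqs, species_id="sp"):
    return SpeciesAlignment(
        species_id,
        [AlignmentRecord(f"q{i}", s, 0.0, 0.0) for i, s in enumerate(seqs)],
    )


class TestPairStats:
    @pytest.mark.parametrize(
        "a,b,overlap,diff",
        [
            ("ACGT", "ACGT", 1.0, 0.0),
            ("ACGT", "ACGA", 1.0, 0.25),
            ("AC--", "--GT", 0.0, None),          # disjoint coverage
            ("ACGTNN", "ACTT--", 4 / 6, 0.25),    # N and gaps never compared
            ("ARGT", "AAGT", 0.75, 0.0),          # ambiguity code drops the column
        ],
    )
    def test_examples(self, a, b, overlap, diff):
        st_ = pair_stats(a, b)
        assert st_.overlap_fraction == pytest.approx(overlap)
        if diff is None:
            assert not st_.comparable and math.isnan(st_.difference_fraction)
        else:
            assert st_.comparable
            assert st_.difference_fraction == pytest.approx(diff)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pair_stats("ACG", "ACGT")


class TestSpeciesPi:
    def test_three_sequence_hand_oracle(self):
        """{AAAA, AAAT, AATT}: filters off -> differences {0.25, 0.5, 0.25}."""
        div = species_pi(make_aln(["AAAA", "AAAT", "AATT"]), max_difference=1.0)
        assert div.pi == pytest.approx(1 / 3)
        assert div.n_valid_pairs == 3

    def test_identical_pair(self):
        div = species_pi(make_aln(["ACGT", "ACGT"]))
        assert div.pi == 0.0 and div.n_valid_pairs == 1

    def test_strict_difference_filter_boundary(self):
        # 3/20 = 0.15 difference: excluded by the <10% rule
        a = "A" * 20
        b = "T" * 3 + "A" * 17
        div = species_pi(make_aln([a, b]))
        assert div.n_filtered_pairs == 1 and not div.has_estimate
        # exactly at the boundary (0.10) is still excluded: strict inequality
        c = "T" * 2 + "A" * 18
        div2 = species_pi(make_aln([a, c]))
        assert div2.n_filtered_pairs == 1

    def test_strict_overlap_boundary(self):
        # exactly 60% overlap is excluded (> rule)
        a = "ACGTACGTAC"
        b = "ACGTAC" + "-" * 4
        assert pair_stats(a, b).overlap_fraction == pytest.approx(0.6)
        assert species_pi(make_aln([a, b])).n_valid_pairs == 0

    def test_min_sequences_flag(self):
        div = species_pi(make_aln(["ACGT"]))
        assert not div.has_estimate and div.n_sequences == 1

    def test_invariant_under_reordering_and_relabeling(self):
        rng = np.random.default_rng(7)
        seqs = random_alignment(rng, 6)
        base = species_pi(make_aln(seqs))
        perm = rng.permutation(len(seqs))
        shuffled = make_aln([seqs[i] for i in perm], species_id="other")
        other = species_pi(shuffled)
        assert other.pi == pytest.approx(base.pi, nan_ok=True)
        assert other.n_valid_pairs == base.n_valid_pairs

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_enumeration_oracle(self, seed):
        """pi equals the explicit all-pairs enumeration for <= 8 sequences."""
        rng = np.random.default_rng(seed)
        seqs = random_alignment(rng, int(rng.integers(2, 9)))
        div = species_pi(make_aln(seqs))
        pi, n_valid, n_filt = pi_oracle(seqs)
        assert div.n_valid_pairs == n_valid and div.n_filtered_pairs == n_filt
        assert div.pi == pytest.approx(pi, nan_ok=True)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_filter_monotonicity(self, seed):
        """Raising max_difference never loses pairs; raising min_overlap never gains."""
        rng = np.random.default_rng(seed)
        aln = make_aln(random_alignment(rng, int(rng.integers(2, 7))))
        d1, d2 = sorted(rng.uniform(0.01, 0.6, 2))
        o1, o2 = sorted(rng.uniform(0.1, 0.95, 2))
        assert (
            species_pi(aln, max_difference=d2).n_valid_pairs
            >= species_pi(aln, max_difference=d1).n_valid_pairs
        )
        assert (
            species_pi(aln, min_overlap=o1).n_valid_pairs
            >= species_pi(aln, min_overlap=o2).n_valid_pairs
        )


class TestCellGD:
    def test_mean_and_missing_marker(self):
        assert cell_gd([0.1, 0.3]) == pytest.approx(0.2)
        assert cell_gd([0.25]) == 0.25
        assert math.isnan(cell_gd([]))
        assert cell_gd([0.1, float("nan")]) == pytest.approx(0.1)

    def test_gd_surface_drops_unestimated_species(self):
        pm = PresenceMatrix(
            np.array([0, 1]), ["a", "b"], np.array([[1, 1], [0, 1]], bool)
        )
        gd = gd_surface(pm, {"a": 0.1, "b": float("nan")})
        assert gd.loc[0] == pytest.approx(0.1)
        assert math.isnan(gd.loc[1])


class TestRecoveryOnSyntheticData:
    def test_pi_estimates_recover_true_theta_slope(self):
        """Regression of estimated pi on true theta has slope near 1 for small theta."""
        from scipy.stats import linregress

        w = generate_world(
            WorldConfig(
                grid_rows=10, grid_cols=10, n_species=100,
                seq_per_species_mean=20, theta_low=0.005, theta_high=0.025,
                hotspot_theta_boost=2.0, seed=21,
            )
        )
        tab = species_pi_table(w.alignments.values())
        theta = np.array([w.truth["theta"][s] for s in tab["species_id"]])
        assert theta.max() <= 0.05
        ok = tab["pi"].notna()
        slope = linregress(theta[ok], tab.loc[ok, "pi"]).slope
        assert 0.7 <= slope <= 1.3

    def test_sensitivity_thresholds_and_resolution(self):
        """GD pattern robust to the sequence threshold and grid resolution
        (positive spatially corrected correlation on a 20x20, 300-species world)."""
        w = generate_world(
            WorldConfig(grid_rows=20, grid_cols=20, n_species=300, seed=11)
        )
        alns = list(w.alignments.values())
        tab = gd_sensitivity(
            alns, w.presence, w.grid,
            min_sequences_values=(2, 10), coarsen_factors=(3,),
        )
        assert len(tab) == 3  # all unordered setting pairs
        row = tab[(tab.setting_a == "min_seq=2") & (tab.setting_b == "min_seq=10")].iloc[0]
        assert row.r > 0 and row.p < 0.05

    def test_sensitivity_identical_settings_give_r_one(self, small_world):
        w = small_world
        tab = gd_sensitivity(
            list(w.alignments.values()), w.presence, w.grid,
            min_sequences_values=(2, 2),
        )
        assert tab.iloc[0].r == pytest.approx(1.0)

    def test_sensitivity_requires_two_settings(self, small_world):
        with pytest.raises(ValueError):
            gd_sensitivity(
                list(small_world.alignments.values()),
                small_world.presence, small_world.grid,
                min_sequences_values=(2,),
            )
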