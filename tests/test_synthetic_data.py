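import itertools

import numpy as np
import pytest
from scipy import stats

from biodivgrid.genetic_diversity import species_pi
from biodivgrid.synthetic_data import (
    WorldConfig,
    generate_world,
    read_world,
    worlds_equal,
    write_world,
)


class TestConfigValidation:
    def test_defaults_are_valid(self):
        WorldConfig()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_species": 0},
            {"mpa_fraction": 1.5},
            {"theta_low": 0.05, "theta_high": 0.01},
            {"hotspot_strength": -1},
            {"birth_rate": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            WorldConfig(**kwargs)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            WorldConfig.from_dict({"n_species": 5, "typo_key": 1})


class TestGenerateWorld:
    def test_determinism_and_seed_sensitivity(self):
        cfg = WorldConfig(grid_rows=8, grid_cols=8, n_species=20, seed=3)
        w1, w2 = generate_world(cfg), generate_world(cfg)
        assert worlds_equal(w1, w2)
        w3 = generate_world(WorldConfig(grid_rows=8, grid_cols=8, n_species=20, seed=4))
        assert not np.array_equal(w1.presence.matrix, w3.presence.matrix)

    def test_species_identifiers_consistent_across_artifacts(self, small_world):
        w = small_world
        tips = {lf.taxon.label for lf in w.tree.leaf_node_iter()}
        assert tips == set(w.presence.species_ids) == set(w.alignments)

    def test_sequences_sampled_inside_species_range(self, small_world):
        w = small_world
        cells = w.grid.cells.set_index("cell_id")
        half = w.config.cell_side_km / 2
        for sp, aln in list(w.alignments.items())[:10]:
            present = {
                int(c) for c in w.presence.cell_ids[
                    w.presence.matrix[:, w.presence.species_ids.index(sp)]
                ]
            }
            for rec in aln.records:
                # the cell whose centroid is nearest the coordinate
                d = np.hypot(cells["x_km"] - rec.lon, cells["y_km"] - rec.lat)
                assert int(d.idxmin()) in present

    def test_zero_theta_gives_identical_sequences(self):
        w = generate_world(
            WorldConfig(grid_rows=4, grid_cols=4, n_species=1,
                        seq_per_species_mean=2, theta_low=0.0, theta_high=0.0,
                        hotspot_theta_boost=1.0, seed=0)
        )
        aln = next(iter(w.alignments.values()))
        assert len({r.sequence for r in aln.records}) == 1

    def test_oversized_range_names_species(self):
        with pytest.raises(ValueError, match="species index"):
            generate_world(
                WorldConfig(grid_rows=2, grid_cols=2, n_species=5,
                            range_size_log_mean=5.0, range_size_log_sd=0.01, seed=0)
            )

    def test_uniform_seed_cells_without_hotspot(self):
        """hotspot_strength=0: single-cell ranges spread uniformly over the
        ocean (chi-square over distance-to-center bins not rejected)."""
        w = generate_world(
            WorldConfig(grid_rows=20, grid_cols=20, n_species=500,
                        range_size_log_mean=-5.0, range_size_log_sd=0.01,
                        hotspot_strength=0.0, hotspot_theta_boost=1.0, seed=13)
        )
        cen = w.grid.centroids(w.presence.cell_ids.tolist())
        cx, cy = w.grid.cells.set_index("cell_id").loc[
            w.truth["hotspot_center"], ["x_km", "y_km"]
        ]
        d_cell = np.hypot(cen["x_km"] - cx, cen["y_km"] - cy).to_numpy()
        edges = np.quantile(d_cell, np.linspace(0, 1, 9))
        edges[-1] += 1
        cell_bin = np.digitize(d_cell, edges) - 1
        expected_share = np.bincount(cell_bin, minlength=8) / len(d_cell)
        counts = np.zeros(8)
        for j in range(w.presence.n_species):
            rows = np.flatnonzero(w.presence.matrix[:, j])
            counts[cell_bin[rows[0]]] += 1
        chi2, p = stats.chisquare(counts, f_exp=500 * expected_share)
        assert p > 0.01

    def test_hotspot_species_have_larger_theta(self):
        """One-sided paired test over 20 worlds: hotspot-touching species
        carry boosted theta."""
        diffs = []
        for seed in range(20):
            w = generate_world(
                WorldConfig(grid_rows=12, grid_cols=12, n_species=40,
                            hotspot_strength=6.0, hotspot_theta_boost=2.0, seed=seed)
            )
            hot = set(w.truth["hotspot_species"])
            assert hot and len(hot) < len(w.species_ids)
            th = w.truth["theta"]
            diffs.append(
                np.mean([th[s] for s in hot])
                - np.mean([th[s] for s in th if s not in hot])
            )
        t, p = stats.ttest_1samp(diffs, 0.0, alternative="greater")
        assert p < 1e-6

    def test_realized_pi_converges_to_theta(self):
        """Mean pairwise difference tracks theta within 20% at 50 sequences."""
        w = generate_world(
            WorldConfig(grid_rows=8, grid_cols=8, n_species=25,
                        seq_per_species_mean=50, theta_low=0.01, theta_high=0.05,
                        hotspot_theta_boost=1.0, seq_length=800, seed=29)
        )
        ratios = []
        for sp, aln in w.alignments.items():
            div = species_pi(aln, max_difference=1.0)  # raw mean pairwise difference
            ratios.append(div.pi / w.truth["theta"][sp])
        assert abs(np.mean(ratios) - 1) < 0.2

    def test_mpa_set_avoids_hotspot(self, study_world):
        w = study_world
        cen = w.grid.centroids(w.presence.cell_ids.tolist())
        cx, cy = w.grid.cells.set_index("cell_id").loc[
            w.truth["hotspot_center"], ["x_km", "y_km"]
        ]
        d = np.hypot(cen["x_km"] - cx, cen["y_km"] - cy)
        mpa_d = d.loc[sorted(w.mpa_cells)].mean()
        assert mpa_d > d.mean()


class TestWorldIO:
    def test_round_trip_identity(self, tmp_path):
        w = generate_world(WorldConfig(grid_rows=6, grid_cols=6, n_species=8, seed=1))
        write_world(w, tmp_path / "w")
        assert worlds_equal(w, read_world(tmp_path / "w"))

    def test_artifact_counts(self, tmp_path):
        w = generate_world(WorldConfig(grid_rows=5, grid_cols=5, n_species=4, seed=2))
        write_world(w, tmp_path / "w")
        fastas = list((tmp_path / "w" / "fasta").glob("*.fasta"))
        assert len(fastas) == 4
        assert sum(1 for lf in w.tree.leaf_node_iter()) == 4
        header = (tmp_path / "w" / "presence.csv").read_text().splitlines()[0]
        assert len(header.split(",")) == 4 + 1  # species columns + cell_id

    def test_manifest_collision_requires_overwrite(self, tmp_path):
        w = generate_world(WorldConfig(grid_rows=4, grid_cols=4, n_species=3, seed=3))
        write_world(w, tmp_path / "w")
        with pytest.raises(FileExistsError):
            write_world(w, tmp_path / "w")
        write_world(w, tmp_path / "w", overwrite=True)
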