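"""End-to-end pipeline: simulate -> gd -> pd -> correlate -> prioritize -> assess.

A :class:`RunConfig` (usually loaded from YAML) fixes every threshold,
count and the global seed. Per-stage seeds are derived from the global
seed by hashing the stage name, so any stage can be re-run in isolation
and reproduce its full-pipeline output. All tabular outputs are CSV
with a ``# config=<hash> seed=<seed>`` header comment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import efficiency, genetic_diversity, phylodiversity, prioritization, spatial_stats
from .gridding import richness_surface
from .phylodiversity import TreeIndex
from .synthetic_data import SyntheticWorld, WorldConfig, generate_world, read_world, write_world

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    out_dir: str = "results/run"
    world: WorldConfig = field(default_factory=WorldConfig)
    world_dir: str | None = None        # read an existing world instead of simulating
    min_overlap: float = 0.60
    max_difference: float = 0.10
    min_sequences: int = 2
    n_randomizations: int = 1000
    k: int | str = 6                    # cluster count, or "auto" for silhouette choice
    n_top: int = 3
    n_replicates: int = 1000
    n_curve_points: int = 12
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.min_overlap < 1) or not (0 < self.max_difference < 1):
            raise ValueError("filter thresholds must lie strictly within (0, 1)")
        if min(self.min_sequences, self.n_randomizations, self.n_top, self.n_replicates) < 1:
            raise ValueError("counts must be >= 1")
        if not (self.k == "auto" or (isinstance(self.k, int) and self.k >= 2)):
            raise ValueError("k must be an integer >= 2 or 'auto'")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if isinstance(d.get("world"), Mapping):
            d["world"] = WorldConfig.from_dict(d["world"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths and logging excluded)."""
        d = {k: v for k, v in self.to_dict().items()
             if k not in ("out_dir", "world_dir", "log_level")}
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(h, 16) % (2**31)


def write_csv(df: pd.DataFrame, path: str | Path, config: RunConfig, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config={config.config_hash()} seed={config.seed}\n")
        df.to_csv(fh, index=index)


def read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest.

    A stage failure aborts the run with the failing stage named.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    stage = "simulate"
    try:
        # ---- simulate / load ------------------------------------------
        if config.world_dir is not None:
            world = read_world(config.world_dir)
        else:
            wc = dataclasses.replace(config.world, seed=stage_seed(config.seed, "simulate"))
            world = generate_world(wc)
            write_world(world, out / "world", overwrite=True)
        presence = world.presence
        coords = world.grid.centroids(presence.cell_ids.tolist())
        manifest["stages"]["simulate"] = {
            "n_species": len(world.species_ids),
            "n_cells": presence.n_cells,
            "n_mpa_cells": len(world.mpa_cells),
        }

        # ---- genetic diversity ----------------------------------------
        stage = "gd"
        pi_tab = genetic_diversity.species_pi_table(
            world.alignments.values(),
            config.min_overlap,
            config.max_difference,
            config.min_sequences,
        )
        write_csv(pi_tab, out / "species_pi.csv", config)
        pi_map = dict(zip(pi_tab["species_id"], pi_tab["pi"]))
        gd = genetic_diversity.gd_surface(presence, pi_map)
        sr = richness_surface(presence)
        manifest["stages"]["gd"] = {
            "n_species_with_estimate": int(pi_tab["pi"].notna().sum()),
            "n_cells_with_gd": int(gd.notna().sum()),
        }

        # ---- phylogenetic diversity -----------------------------------
        stage = "pd"
        tree_index = TreeIndex(world.tree)
        pd_tab = phylodiversity.pd_surface(
            tree_index, presence, n_rand=config.n_randomizations,
            seed=stage_seed(config.seed, "pd"),
        )
        pd_tab = pd_tab.set_index("cell_id")
        deciles = phylodiversity.ses_deciles(pd_tab.reset_index())
        pd_out = pd_tab.copy()
        pd_out["decile_class"] = deciles
        write_csv(pd_out.reset_index(), out / "pd_surface.csv", config)
        manifest["stages"]["pd"] = {"n_cells_with_pd": len(pd_tab)}

        # ---- diversity surface table ----------------------------------
        stage = "surfaces"
        surface = pd.DataFrame({"sr": sr, "gd": gd})
        surface["pd_obs"] = pd_tab["pd_obs"]
        surface["ses_pd"] = pd_tab["ses_pd"]
        surface["sst"] = world.sst
        surface.index.name = "cell_id"
        write_csv(surface.reset_index(), out / "surfaces.csv", config)

        # ---- SST correlations (modified t-test) -----------------------
        stage = "cortest"
        sr_f = sr.astype(float)
        cors = spatial_stats.surface_correlation_matrix(
            {"sst": world.sst, "sr": sr_f, "gd": gd,
             "pd": surface["pd_obs"], "ses_pd": surface["ses_pd"]},
            coords,
        )
        write_csv(cors, out / "sst_correlations.csv", config)
        manifest["stages"]["cortest"] = {"n_pairs": len(cors)}

        # ---- prioritization -------------------------------------------
        stage = "prioritize"
        features = prioritization.build_feature_table(sr_f, gd, surface["ses_pd"])
        prio_seed = stage_seed(config.seed, "prioritize")
        if config.k == "auto":
            k, diag = prioritization.select_k(features, seed=prio_seed)
            write_csv(diag, out / "k_selection.csv", config)
        else:
            k = int(config.k)
        model = prioritization.rank_and_select(
            features, n_total_cells=presence.n_cells, k=k,
            n_top=config.n_top, seed=prio_seed,
        )
        assign = model.assignments.rename_axis("cell_id").reset_index()
        assign["is_priority"] = assign["cell_id"].isin(model.priority_cells)
        write_csv(assign, out / "priority_assignments.csv", config)
        write_csv(model.summary().reset_index(), out / "cluster_summary.csv", config)
        manifest["stages"]["prioritize"] = {
            "k": k,
            "n_priority_cells": len(model.priority_cells),
            "coverage_fraction": model.coverage_fraction,
        }

        # ---- effectiveness assessment ---------------------------------
        stage = "assess"
        eff_seed = stage_seed(config.seed, "assess")
        sizes = sorted(
            {0, presence.n_cells, len(world.mpa_cells), len(model.priority_cells)}
            | {
                int(round(f * presence.n_cells))
                for f in np.linspace(0, 1, config.n_curve_points)
            }
        )
        curve = efficiency.accumulation_curve(
            presence, pi_map, tree_index, sizes,
            n_replicates=config.n_replicates, seed=eff_seed,
        )
        write_csv(curve.table, out / "accumulation_curve.csv", config)
        reports = []
        verdicts = []
        for name, cells in (("mpa", world.mpa_cells), ("priority", model.priority_cells)):
            rep = efficiency.coverage_report(cells, presence, pi_map, tree_index, cell_set_id=name)
            reports.append(rep)
            v = efficiency.compare_to_null(rep, curve)
            v.insert(0, "cell_set_id", name)
            verdicts.append(v)
        cov_df = pd.DataFrame([dataclasses.asdict(r) for r in reports])
        write_csv(cov_df, out / "coverage.csv", config)
        write_csv(pd.concat(verdicts, ignore_index=True), out / "coverage_vs_null.csv", config)
        manifest["stages"]["assess"] = {
            "coverage": {
                r.cell_set_id: {
                    "taxonomic": r.pct_taxonomic,
                    "genetic": r.pct_genetic,
                    "phylogenetic": r.pct_phylogenetic,
                }
                for r in reports
            }
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["outputs"] = sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
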