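# biodivgrid

Gridded, multi-dimensional analysis of marine biodiversity for
conservation planning. The package quantifies three complementary
dimensions of diversity on an equal-area ocean grid —

* **species richness** (SR): species per grid cell, from rasterized
  range maps;
* **genetic diversity** (GD): per-cell mean of species-level nucleotide
  diversity, `GD = (1/S) Σ_p π_p`, where each species' π is the mean
  pairwise p-distance over its aligned barcode sequences, keeping only
  pairs with > 60% sequence overlap and < 10% sequence difference;
* **phylogenetic diversity** (PD): Faith's PD per cell, plus its
  standardized effect size, `SES-PD = (PD_obs − mean PD_null) / sd PD_null`,
  under 1000 taxa-label randomizations, which removes the confounding
  effect of richness —

and turns them into conservation products: cells are min–max
normalized, clustered by k-means (k = 6), the top three clusters form
the **priority areas**, and any protected cell set (e.g. current MPAs)
is scored for the percentage of taxonomic, genetic and phylogenetic
diversity it conserves against **biodiversity-preservation
accumulation curves** built from 1000 random cell draws per sample
size. Correlations between surfaces (e.g. sea-surface temperature vs
diversity) use the Clifford–Dutilleul **modified t-test**, whose
effective sample size `m_eff = n / (1 + 2 Σ_k (n_k/n) ρx_k ρy_k)`
corrects significance for spatial autocorrelation.

Because the real inputs (GenBank/BOLD barcodes, IUCN ranges, WDPA
polygons, MARSPEC temperature) are large external databases, the
package ships a first-class **synthetic world generator**: species
ranges of lognormal size grown by a spreading-dye process around a
diversity hotspot, a pure-birth species tree, star-model barcode sets
with controlled per-species θ, an SST field peaking at the hotspot,
and an MPA set that under-represents the hotspot — all with known
ground truth, so every stage is testable end to end.

Intended users: macroecologists and conservation scientists who want a
reproducible, fully tested implementation of this analysis chain to run
on their own per-cell inputs (aligned FASTA per species, Newick tree,
presence–absence CSV, grid CSV).

## Worked example

The numbered scripts under `analysis/` run the whole study on one
seeded synthetic world (`python analysis/01_simulate_world.py` through
`06_mpa_effectiveness.py`, outputs under `results/study/`). Script 05
prints, for the default study world:

```
priority areas: 43 cells (10.75% of the ocean)
  true-hotspot recall: 100.0% of 21 hotspot cells
```

— the k-means top-3-cluster selection concentrates on ~11% of the
ocean yet captures the entire true diversity hotspot. Script 06 then
scores the two candidate protection schemes:

```
mpa: 48 cells (12.0% of ocean) conserve 10.0% taxonomic, 8.2% genetic, 26.7% phylogenetic diversity
    taxonomic     vs random null: below  (null mean 50.2, band [30.0, 66.7], p=0.000)
priority: 43 cells (10.8% of ocean) conserve 76.7% taxonomic, 85.9% genetic, 86.7% phylogenetic diversity
    taxonomic     vs random null: above  (null mean 46.9, band [26.0, 64.7], p=0.000)
```

The hotspot-avoiding MPA set conserves significantly *less* diversity
than randomly placed cells of the same total area, while the priority
areas conserve significantly *more* — on all three dimensions.

The same steps are available as a CLI
(`biodivgrid {simulate,gd,grid,pd,cortest,prioritize,assess,run}`) and
as one call, `biodivgrid run --config run.yaml`, which executes
simulate → gd → pd → cortest → prioritize → assess with per-stage
seeds derived from one global seed.

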