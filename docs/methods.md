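# Methods

This note documents the models, estimators and design choices behind
`biodivgrid`, in the order data flows through the pipeline.

## The analysis grid

The world is an abstract planar grid of square cells (default side
385.9 km), row-major from the north-west corner, with centroids in km.
No map projection is modeled: every downstream computation needs only
cell adjacency, centroids and areas, and defining the analysis on an
abstract grid keeps cartography out of the tested surface. Cells whose
ocean fraction is strictly below 0.5 are excluded from all surfaces; a
cell at exactly 0.5 is retained (the exclusion rule is "ocean area
< 50%", read literally). Ranges given as polygons mark a cell present
on any positive-area intersection with the cell square — a coarse-map
convention chosen because range maps carry no sub-cell information;
boundary contact alone does not count.

## Nucleotide diversity and per-cell GD

For one species with aligned sequences, every unordered pair is scored
by two quantities: the overlap fraction (columns where both sequences
carry an unambiguous A/C/G/T, over alignment length) and the
difference fraction (mismatches over compared columns — an uncorrected
p-distance; no Jukes–Cantor correction is applied because the
aggregated-repository diversity measure this follows is defined on raw
mismatch fractions). Columns with a gap, N or IUPAC ambiguity code in
either sequence are simply not compared: scoring partial matches would
require an arbitrary ambiguity model, and dropping the column is the
conservative choice.

A pair enters the π estimate only if overlap > 0.60 **and** difference
< 0.10, both strict, so ties at the printed thresholds are excluded.
π is the mean difference fraction over surviving pairs. Species with
fewer than `min_sequences` (default 2, configurable because the
robustness analyses vary it) or with no surviving pair yield a flagged
no-estimate record. π is estimated once per species from all of its
sequences, wherever sampled; per-cell GD then averages π over the
species present in the cell (`GD = (1/S) Σ π`). The alternative —
re-estimating π from within-cell sequences only — would confound the
map with local sampling depth and is not implemented.

Sensitivity operations recompute the GD surface under different
`min_sequences` thresholds and at coarser grid resolutions (integer
block aggregation of the base grid; presence of a block is the union
of its base cells). Cross-resolution comparisons project the coarse
surface back onto base cells so the spatially corrected correlation is
evaluated on a common cell set.

## Faith's PD and SES-PD

Faith's PD of a species set is the branch-length sum of the minimal
subtree connecting the set **including the path to the root** — the
rooted include-root convention of the standard community-phylogenetics
implementations — so a single species' PD is its tip-to-root distance.
An `include_root=False` variant (edges below the MRCA only) is
provided. Internally the tree is indexed as a tips × edges boolean
path matrix, making PD a masked sum and the null distributions a
matrix product.

SES-PD standardizes observed PD against a null that shuffles taxa
labels over the species pool. For a fixed pool this null is equivalent
to drawing equal-sized communities uniformly without replacement, and
depends only on community size — so per-cell surfaces compute one null
(default 1000 randomizations) per distinct richness value and share
it, which is exact, not an approximation. The pool is the full set of
presence-matrix species present on the tree (a global, not regional,
pool; the regional alternative is noted but not implemented). A cell
containing the whole pool has a zero-variance null and a flagged,
undefined SES. Species in the range data but absent from the tree are
dropped with a logged count rather than grafted — partial overlap
between the genetic and phylogenetic species sets is expected in
repository-derived data.

Decile classification takes the cells with defined SES, sorts by
(SES, cell id) and labels the lowest and highest ⌊n/10⌋ cells; the
cell-id tie-break makes the classification reproducible, and an
all-equal SES distribution is rejected as degenerate.

## Modified t-test

Pearson's r between two surfaces is computed on their common defined
cells and is never adjusted; only its significance is corrected.
Following the Clifford–Richardson moment estimator with Dutilleul's
small-sample usage, inter-centroid distances are binned into 10
equal-width classes (the bin count is a default, not an inference
about any particular prior analysis); per-class autocorrelations
ρx_k, ρy_k are Moran-type ratios of class autocovariance to variance,
and

    m_eff = n / (1 + 2 Σ_k (n_k / n) ρx_k ρy_k),

clamped to [2, n] (clamping logged). The statistic is
t = r √((m_eff − 2)/(1 − r²)) on m_eff − 2 (possibly fractional)
degrees of freedom. Calibration on a 15 × 15 grid: white-noise
surfaces reject at ≈ 0.05; independent Gaussian-blurred surfaces keep
the corrected test near 0.05 while the naive test rejects at > 0.5
(these rates are recomputed by the test suite and the acceptance
script, not quoted from elsewhere).

## Prioritization

Cells with all three dimensions defined are min–max normalized per
dimension (a constant column maps to zeros with a warning). k-means
uses Lloyd's algorithm with k-means++ seeding, best of 25 restarts
(scikit-learn's `KMeans`), deterministic under seed; silhouette width
over k = 2..10 is available for choosing k, while the reference
analysis fixes k = 6 and takes the top 3 clusters. A cluster's score
is the mean over its member cells of the (by default equally) weighted
mean of the three normalized values — the neutral aggregation when no
weighting is specified; weights are exposed in the API. Score ties
break toward the larger cluster, then the lower cluster index. Cells
missing any dimension can never be priority cells; their count is
logged.

## Effectiveness assessment

A species is "conserved" by a cell set if it occurs in at least one
set cell (no minimum range-fraction threshold). The three coverage
percentages are species coverage (taxonomic), π-weighted species
coverage (genetic: Σπ over covered species / Σπ over all π-estimable
species), and PD of covered tree species over PD of all occurring tree
species (phylogenetic). The π-weighted definition was chosen over the
mean-π-of-covered-species alternative because it is 0 at the empty
set, 100 at full coverage, and monotone under cell-set inclusion —
the alternative is none of these. Denominators use species that occur
in at least one retained cell, so the full cell set always scores
exactly 100.

Accumulation curves draw cells uniformly without replacement (no area
weighting), 1000 replicates per sample size, with percentile
(2.5/97.5) bands; sizes 0 and n are computed exactly. Verdicts for an
observed set are its position relative to the band, with an empirical
two-sided p (twice the smaller tail fraction, capped at 1).

## The synthetic world

The generator emulates the statistical structure of the real inputs:

* **Ranges** grow by a spreading-dye process: a seed cell is drawn
  with weight exp(−hotspot_strength · d/d_max) toward the hotspot
  center, then the range grows through uniformly chosen ocean-valid
  4-neighbors to a lognormal target size. Defaults (20 × 20 grid, 150
  species, log-mean 1.6 / log-sd 0.8 → median ≈ 5 cells ≈ 1% of the
  ocean, hotspot_strength 8) encode the structure the hotspot world
  exists to represent: most species are narrow-ranged and concentrate
  at the hotspot, as range-restricted endemics concentrate in real
  diversity hotspots. With broad ranges or a weak hotspot the
  coverage comparison saturates — scattered random cell sets
  complement one another and match any targeted selection — which is
  the wrong regime for studying prioritization.
* **Tree**: a pure-birth (Yule) tree with birth rate 1.0, tips
  relabeled to the species list.
* **Sequences**: a star model — each sequence mutates independently
  from one ancestral sequence with per-site probability p chosen so
  that the expected pairwise difference equals the species' θ
  (inverting d = 2p − (4/3)p²). θ is uniform on [0.002, 0.02]
  (COI-like intraspecific diversity), multiplied by
  `hotspot_theta_boost` (default 2.0) for species touching the
  hotspot. The boost is a separate knob rather than a function of
  hotspot_strength so that strong spatial concentration cannot push θ
  past the 10% pair-difference filter and silently destroy the GD
  surface. No within-species coalescent topology is simulated: π
  estimation needs only controllable pairwise differences.
* **Coordinates** in FASTA headers are cell-centroid positions with
  uniform within-cell jitter; "lat/lon" are planar km in synthetic
  mode.
* **SST** is a Gaussian bump centered on the hotspot (base 2 °C,
  amplitude 25 °C, length scale 0.35 · d_max) plus white noise
  (sd 0.5 °C) — a warm-tropics gradient correlated with richness.
* **MPA cells** are sampled without replacement with weight
  exp(mpa_hotspot_avoidance · d/d_max), i.e. away from the hotspot,
  emulating protection placed where diversity is not.

One seed makes the world bit-identical across runs (stage-separated
RNG streams); `write_world`/`read_world` round-trip exactly through
plain-text artifacts. What the generator does **not** emulate: real
coastline geometry, geodesic cell areas, coalescent gene genealogies,
sequencing error, taxonomic mis-assignment, and spatially biased
sequence sampling. Passing tests therefore demonstrate the estimators
and the selection logic, not robustness to those real-data pathologies.

## Problem sizes and numerical choices

Tests and the acceptance script run on 15 × 15 to 20 × 20 worlds with
60–300 species, 1000 SES randomizations / curve replicates where the
check is about those nulls, and fewer (50–300) where only surface
shape matters; these sizes put every Monte-Carlo tolerance (3 MC
standard errors) well inside a few seconds of compute. Pipeline stage
seeds are SHA-256 hashes of the stage name under the global seed, so
any stage re-run in isolation reproduces its full-pipeline output.
Degenerate inputs are flagged rather than guessed at: zero compared
columns → undefined p-distance; zero-variance null → undefined SES;
constant feature column → zeros with warning; |r| = 1 → p = 0 with a
degeneracy flag.

## Known limitations

* The "% genetic diversity conserved" definition (π-weighted species
  coverage) is this package's operationalization; other defensible
  definitions exist, and this is the leading interpretive risk when
  comparing against externally published percentages.
* The modified t-test's class count (10) and the equal-width binning
  are defaults, and m_eff is a moment estimate — with very strong
  autocorrelation the corrected df can be small and the test
  conservative.
* SES-PD uses the global species pool; regional pools would yield
  different (typically larger-magnitude) effect sizes.
* Real-world replication (actual coastlines, IUCN/WDPA/MARSPEC data)
  is out of scope; results on the abstract grid are method
  validations, not geographic claims.
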