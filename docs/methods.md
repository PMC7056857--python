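# Methods

This note documents the models and procedures implemented in
`somscape`, the parameters that matter, the design choices that were
genuinely open, and what the synthetic benchmarks do and do not show.

## Shaped lattices

All hexagonal shapes are generated on axial coordinates `(q, r)` with
Euclidean positions `x = q + r/2`, `y = r·√3/2`, enumerated over
`q, r ∈ [−3R, 3R]` for scale `R` and kept when the shape mask holds:

| shape | mask (R = scale) |
|---|---|
| sheet | `|q| ≤ R ∧ |r| ≤ R` (axial window, a rhombic "sheet") |
| hexagon | `|q| ≤ R ∧ |r| ≤ R ∧ |q+r| ≤ R` |
| diamond | `|x|/R + |y|/(R·√3/2) ≤ 1` |
| triangle | `y ≥ 0 ∧ |x| ≤ R·(1 − y/(R√3))` |
| butterfly | union of two diamond masks centred at `(±0.7R, 0)` |
| trefoil | three discs (radius `0.55R`) at distance `0.65R` from the origin at 90°, 210°, 330°, plus a central disc (radius `0.35R`) |
| square | rectangular `(2R+1)²` grid, 4-neighbour adjacency |

Adjacency is exactly the set of node pairs at Euclidean distance 1 (a
tested invariant), nodes are ordered by `(y, x)` so regeneration is
bit-identical, and after masking only the largest connected component
is kept (reported in the lattice metadata) so that downstream region
growing always operates on a connected graph.  These masks are declared
conventions: they reproduce the qualitative geometry the shapes are
named for with deterministic, enumerable node sets.  Frozen node counts
at scale 4 — diamond 37, butterfly 61, trefoil 55 — serve as regression
fixtures.  A float slack of 1e−9 on the Euclidean mask comparisons keeps
boundary membership stable across platforms.

## Batch SOM training

Training is the classical batch scheme.  Per iteration: every row is
assigned to its best-matching unit (BMU; Euclidean distance in feature
space, ties to the lowest node index), then every prototype becomes the
kernel-weighted mean of all rows,

    m_j ← Σ_i h(j, b_i) x_i / Σ_i h(j, b_i),
    h(j, b) = exp(−d_map(j, b)² / 2σ²),

with `d_map` the Euclidean distance between node positions.  Nodes
receiving kernel mass below 1e−12 keep their previous prototype rather
than dividing by ~0.  The width σ decays linearly within each of two
phases; with lattice diameter `D` the defaults are rough `D/4 → D/16`
(10 iterations) and fine-tune `D/16 → 0.5` (20 iterations).  Batch
rather than sequential updating was chosen for determinism (the only
randomness is in initialisation) and speed; the batch step is a descent
step on the kernel-smoothed distortion `Σ_i Σ_j h(j, b_i)·‖x_i − m_j‖²`,
which the test suite asserts over 20 random instances.

Initialisation is PCA-linear by default: prototypes start at the data
mean plus the node's centred map coordinates projected along the top
two principal components, scaled so the map's extremes reach ±2 SD of
the component scores; single-column data falls back to seeded random
row sampling.  Columns are not standardised by default (the measures in
the intended inputs — e.g. −log10 q-values per tissue — share a scale);
a `standardize` flag z-scores them and the scaling is stored on the map
so later assignments are consistent.  Rows with missing values are
rejected; an explicit `impute_mean` flag at load time fills them with
column means and logs the count.

The per-iteration mean row-to-BMU distance (quantization error) is
recorded, with one final evaluation after the last update; the final
value never exceeding the initial one is a tested invariant.

The "2D landscape" view of the columns themselves (e.g. placing
phenotypes by similarity) needs no extra machinery: train a `square`
lattice on the transposed matrix and read each column's BMU position.

## PCA shape hint

`pca_shape_hint` projects rows onto the first two principal components
of the centred data and estimates the number of density centres: the
scores are binned into a 32×32 histogram, smoothed with a
fixed-bandwidth Gaussian filter (2 bins), and modes are smoothed bins
strictly exceeding all 8 neighbours while holding ≥ 5% of the maximum
smoothed density.  The smoothing bandwidth is the operative choice: a
raw histogram of a few hundred points carries many one-count local
maxima, so an unsmoothed scan reports tens of "modes"; 2 bins of
smoothing makes the count track the generative number of centres across
seeds for the mixture scales used here, while the 5% floor discards
stray tail mass.

## Overlay

The overlay of a non-training column through a hit assignment uses the
same Gaussian kernel over map distance, defaulting to the final
fine-tune σ (0.5) so overlaid landscapes have the same smoothness as
trained ones and no node is empty.  `σ = 0` degenerates to the plain
per-BMU mean, with NaN marking nodes that received no rows — never a
silent 0, since for a binary status vector 0 is a meaningful
probability.  Overlay rows unknown to the map are dropped with a logged
count; training rows missing from the overlay simply contribute
nothing.  Three tested properties pin the construction: linearity in
the overlay values (to 1e−10), node values staying within the overlay's
range (weighted means), and per-column Pearson correspondence ≥ 0.95
with the trained codebook when the training matrix is overlaid onto its
own map.  Landscape correspondence is computed per column pair with
pairwise NaN exclusion and requires ≥ 3 jointly defined nodes.

## Region growing on the U-height landscape

The U-height of node `j` is the mean Euclidean distance between its
prototype and those of its lattice neighbours.  Partitioning proceeds
in three deterministic stages:

1. **Steepest descent.**  Each node points to the neighbour minimising
   `(height, index)` if that pair is lexicographically below its own
   (heights compared with a plateau tolerance, relative to the height
   range, default 1e−12); nodes with no lower neighbour are seeds, and
   pointer paths assign every node to a seed's basin.  Pointer paths
   are adjacency paths, so basins are connected by construction.
2. **Plateau merging.**  Basins touching through nodes of equal height
   *at both seeds' level* merge, so a perfectly flat region (e.g. a
   constant codebook) yields one cluster.  The restriction to the
   seeds' level matters: flat ridge interiors also contain equal-height
   contacts, and merging across those would fuse two wells separated by
   a plateau-topped ridge.
3. **Persistence merging.**  A basin whose separating saddle rises less
   than `min_depth` × (height range) above the shallower basin's
   minimum is merged into its deeper neighbour, smallest depth first
   (default `min_depth = 0.15`; set 0 to disable).  This is the
   standard refinement of watershed-style region growing: sampling
   noise in a fitted codebook always carves a few shallow dips into an
   otherwise homogeneous region, and on the benchmark fixtures these
   noise basins show relative depths ≤ ~0.12 while genuine group
   boundaries ride ridges of relative depth ≥ ~0.2 (often 0.4–0.8).
   0.15 sits in the gap between those regimes, removes the noise
   basins, and leaves every real boundary intact; the contiguity
   guarantee is unaffected because only adjacent basins merge.

Clusters are relabelled 1..K by seed index; genes inherit the cluster
of their BMU.  No target K is exposed — the count emerges from the
landscape — but `merge_to_max_clusters` optionally merges the
closest-prototype adjacent pair until a user ceiling is met.

## Fisher-exact enrichment

For each (cluster, set) pair within a universe (default: all genes
carrying a cluster label, i.e. the mapped population), the 2×2 table is
tested with the hypergeometric distribution under fixed margins.
One-tail (`one_greater`) is `P(A ≥ a)`, for enrichment-only screens;
two-tail follows the classical point-probability convention — the sum
of probabilities of all tables at most as probable as the observed one,
with a relative slack of 1e−7 absorbing float noise — and captures
enrichment and depletion symmetrically.  Degenerate margins give p = 1.
The implementation (on `scipy.stats.hypergeom`) is verified against an
independent log-factorial full enumeration for every table with all
margins ≤ 25 (max deviation observed ~4e−14) and against
`scipy.stats.fisher_exact` on random tables.

Odds ratios use the Haldane–Anscombe correction (add 0.5 to every cell)
only when a zero cell exists, and only for the ratio and its Woolf
confidence interval `exp(ln OR ± z·√(Σ 1/cell))`; p-values always use
the raw counts, as the exact test requires.  Multiplicity is controlled
by Benjamini–Hochberg across all cluster–set pairs of a run (one
collection × one tail family); raw p-values are always reported
alongside.  Under label shuffling the two-tail test is conservative, as
exact tests are: the measured fraction of p < 0.05 is ≈ 0.039–0.046
rather than 0.050.

## Synthetic data

`simulate_matrix` draws rows from a Gaussian mixture: `k` groups of
as-equal-as-possible size, centres at the vertices of a regular simplex
with pairwise distance 8 noise-SDs by default (well-separated on the
scale SOMs resolve), isotropic noise SD 1.  `simulate_status` draws an
independent Bernoulli per gene at its group's rate (defaults 0.8 for
the first group vs 0.1 elsewhere — a strongly but not perfectly
correlated binary annotation).  `simulate_genesets` builds planted sets
(a purity fraction of the target group plus a background rate of the
rest, default 0.8/0.05) and uniform decoys.  Default sizes (600 genes ×
4 measures, 2–4 groups) mirror the shape of gene-by-tissue matrices at
a scale where the full pipeline runs in seconds.

What passing on these fixtures shows: the pipeline recovers planted
partition structure (ARI ≈ 1 at separation 8σ), maps distinct density
centres to distinct shaped-map regions, and calls planted enrichments
at the right cluster.  What it does not show: behaviour under
correlated measures, heavy-tailed or zero-inflated values, unbalanced
group sizes, or weakly separated groups — real eQTL and screen matrices
have all of these, and cluster counts and boundaries there will be
sensitive to the persistence floor in ways the clean mixtures are not.

## Numerical and degenerate-input conventions

BMU ties go to the lowest node index; all stage seeds derive
deterministically from one master seed; pipeline outputs are
byte-identical across reruns (tested).  Zero-variance columns in
correspondence give NaN with a warning; empty masks raise; disconnected
custom masks keep the largest component with a warning; a constant
matrix is rejected by the PCA hint ("zero variance"); non-finite values
are rejected at construction everywhere.  Undefined node values are NaN
throughout and excluded pairwise (correspondence) or per cluster
(summaries), with all-NaN clusters reported as NaN.

## Problem sizes in tests and the acceptance script

The Fisher sweep covers all ~82k tables with margins ≤ 25; null
calibration uses 1000 genes × 5 shuffled clusters × 10 sets × 200
permutations; contiguity covers 50 random trained maps across the seven
built-in shapes at scales 2–4; recovery fixtures use 400–600 genes.
These sizes give stable statistics (binomial SE ≈ 0.002 on the null
fraction) while keeping the whole suite under a minute of compute.
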