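# Methods

`nichedomains` detects *climatic niche domains* — groups of climatic
conditions and the species mainly associated with them — from gridded
species occurrences, and projects them back to geography as *climate
regions*. This note documents the model, the numerical choices, and what
the synthetic studies do and do not demonstrate.

## The model

### Niche profiles in a binned climate space

The climate space is two-dimensional: an energy surrogate (e.g. annual
potential evapotranspiration) and a water surrogate (e.g. annual
precipitation). Fine-resolution rasters are block-averaged over the land
pixels of each coarse analysis cell; a coarse cell's climate is the mean
of its fine land pixels, and an all-sea block is nodata. Each axis is
divided into `d` quantile intervals computed from the distribution of
coarse land-cell values over the whole grid, so intervals hold equal
numbers of cells and resolution concentrates where climates are common
(for a skewed axis such as precipitation this automatically refines the
dry end). Intervals are half-open with the last closed; values outside
the edges (possible when edges come from another dataset) clamp to the
end bins with a logged count.

A species' *niche profile* is the vector

w_ij = (occupied cells of species j in bin i) / (occupied cells of j),

so Σ_i w_ij = 1. Occurrences are occupied coarse cells — range-map
semantics, no abundance. Species occupying fewer than `min_range_cells`
(default 5) cells are removed before profiling: too few cells make the
realized-niche estimate unstable.

### The bipartite network and the map equation

Bins and species form the two node sets of a weighted bipartite network
with one link per positive w_ij; the total link weight equals the number
of species. Domains are modules of this network found by minimizing the
map-equation code length: for an undirected network with
link-weight-proportional flow, node visit rates are p_u = s_u / 2W
(s_u the node strength, W the total weight), a module's exit rate is its
boundary-link weight over 2W, and the code length is the entropy of the
index codebook plus the rate-weighted entropies of the module codebooks.
For nested partitions every module owns a codebook whose rates are its
exit rate plus its children's entry rates, and the total recurses down
the tree.

The optimizer is a multi-restart stochastic search: greedy single-node
moves (accepting only strictly improving moves, threshold 1e-12 bits),
module aggregation, and repeated refinement until no move helps; each
restart uses an independent seeded stream, and the best partition over
`n_runs` restarts is returned. The trivial one-module partition is
always a candidate, so clustering never scores worse than not
clustering. With `hierarchical=True`, each module is offered a recursive
sub-split (found by re-running the search on its induced subgraph) that
is kept only when the full hierarchical code length drops by more than
1e-10 bits. Ties between equal-code-length partitions break toward the
lexicographically smallest canonical labelling, which makes detection
deterministic given `(seed, n_runs)`. On networks small enough to
enumerate, the search recovers the exhaustive minimum (the test suite
checks all partitions of networks up to 10 nodes); an external
map-equation optimizer can be substituted behind the same
partition schema, exchanged via bipartite Pajek files.

*Defaults.* `n_runs=50` for detection and `B=20` bootstrap replicates
are working defaults sized to the synthetic studies here; for real
continental datasets the corresponding full-scale settings
(`n_runs=1000`, `B=100`) are a configuration change. "Domains" in all
reports are the finest-level modules; the top level is exported
alongside.

### Choosing the number of divisions

`select_divisions` scores each candidate `d` by the *compression gain*:
the one-module code length minus the optimized code length, in bits. The
selected `d*` is the largest candidate whose marginal gain over the
previous candidate is at least 2% of the cumulative gain at that
candidate — i.e. trailing candidates that add only negligible
compression are discarded. The full (d, gain) curve is always returned
and exported, and the stopping rule is deliberately pluggable: the
"lowest number of divisions maximizing the information gain" admits more
than one operationalization, and any monotone statistic of the curve can
replace the default rule without touching the rest of the pipeline.

### Bootstrap significance clustering

Range maps overstate occupancy and cell means hide within-cell climate
variability. The bootstrap addresses both: per replicate, per species,
per occupied coarse cell, the cell's n fine land pixels are resampled
with replacement (jointly for both axes, preserving the energy-water
covariance of pixels), averaged, and the cell re-assigned to a bin using
the *original* global quantile edges (global climate is not resampled —
only within-range values). Profiles and the network are rebuilt and
re-clustered per replicate. A domain's *support* is the fraction of
bootstrap partitions containing at least one finest-level module whose
Jaccard similarity to the domain's node set (bins ∪ species; a
species-only comparison is a config option) is strictly greater than the
threshold (default 0.5). Nodes absent from a bootstrap network count as
absent from all its modules.

### Geography: regions, specificity, signal

Every coarse cell inherits the domain of its climatic bin — the *climate
region* map. Bins present in the climate but occupied by no species are
labelled unclassified. Three statistics characterize the match between
climate and species:

- **Bin specificity** S_i = Σ_{j∈D} w_ij / Σ_j w_ij for bin i in domain
  D: 1 when the bin connects only to its own domain's species, lower in
  transition zones.
- **Projected vs actual specificity**: a cell q in bin i gets S_q^P =
  S_i verbatim (no smoothing); the actual value recomputes the ratio
  over only the species present in q,
  S_q^A = Σ_{j∈D, j in q} w_ij / Σ_{j in q} w_ij.
- **Geographical signal** G = mean over cells of |S_q^A − S_q^P|, in
  [0, 1]: 0 when each domain's species fill its whole region, large when
  climatically suitable areas lack the domain's species.

Cells hosting no species leave S^A undefined; they are excluded from G
and counted in the report (the alternative — imputing 0 — would
conflate emptiness with mismatch). Regionalizations are compared with
adjusted mutual information, AMI = (MI − E[MI]) / (mean(H_a, H_b) −
E[MI]), with E[MI] under the permutation (hypergeometric) model;
nodata cells are excluded pairwise, and two single-label partitions
(identical by construction) score 1. Max-normalization is available via
an option.

## The synthetic-data generator

Real inputs (range-map rasters, global climate) are replaced by worlds
with known ground truth. Climate fields are white noise convolved with a
Gaussian kernel (`autocorr_scale`, default 6 fine pixels) rescaled into
the configured ranges (defaults loosely follow global PET and AP in
mm/yr); the energy field additionally carries a north-south gradient
(weight 0.55) mimicking the latitudinal organization of energy input.
The land mask thresholds an independent smoothed field at the
`land_fraction` quantile, giving a few contiguous continents. The fine
grid aggregates to coarse cells by an exact integer factor (default 6),
sidestepping the resampling ambiguity of real-world non-integer
resolution ratios.

Species pools are planted as *archetypes*: a climatic optimum, a
per-axis Gaussian breadth (niche width — the overlap lever), a species
count, and a geographic-restriction fraction rho. Each species draws a
target range size uniformly within ±50% of `range_cells` (default 40
coarse cells) and samples that many cells without replacement with
probability proportional to the archetype's suitability kernel.
Geographic restriction keeps the round(rho·n) occupied cells nearest a
randomly chosen anchor cell of the range — a compact patch of the
suitable geography; rho = 1 is the identity. The default study layout
plants four archetypes at the (0.2, 0.8) per-axis quantile combinations
of the realized coarse climate, with breadth a fraction
(`breadth_frac`, default 0.05) of each axis's realized spread — about
20 standard deviations of separation, making the planted truth
unambiguous.

What the generator does **not** emulate: realistic continental geometry,
spatially autocorrelated range shapes (ranges are climate-driven cell
samples, geographically scattered unless restricted), temporal climate,
abundance, or taxonomic error. Passing tests therefore demonstrate that
the machinery recovers *planted* structure under controlled violations —
not that any particular real-world regionalization is correct.

## Study conditions (and why)

- **Planted recovery**: 4 archetypes × 60 species, d = 12, 50 restarts,
  20 bootstrap replicates. Sized so a full pipeline run takes about a
  minute while leaving the planted domains comfortably recoverable.
- **Overlap sweep**: breadth fractions 0.03, 0.06, 0.09, 0.12. Beyond
  ~0.14 the optimizer (correctly) merges overlapping archetypes, and
  mean bin specificity rebounds trivially toward 1 — the
  monotone-erosion prediction presupposes the planted domains persist,
  so the grid stays inside that regime. Support summaries use the
  domains matched to planted archetypes (majority-species rule); the
  specificity-support rank correlation pools all bin-bearing finest
  domains, where single transition-zone bins with S^P near 0 and low
  support carry most of the signal — the synthetic analogue of
  transition zones being both diffuse and unstable.
- **Restriction sweep**: rho ∈ {1.0, 0.6, 0.3} on three matched
  replicate worlds with fragmented climate (autocorr_scale 3) and large
  ranges (80 cells, 40 species/archetype). Restriction only produces a
  geographical signal when a domain's climate occurs in disjoint patches
  some of which lose their species — the same mechanism as a desert
  fauna occupying one continent's desert but not another's. On a single
  world the rho = 0.6 effect is at sampling-noise level (~0.003 in G),
  hence the three-replicate average.

## Numerical choices and degenerate inputs

- Quantile edges use linear interpolation between order statistics with
  integer-exact break positions (an edge at k/d sits at sorted position
  k(n−1)/d computed with integer arithmetic), so edges landing on order
  statistics carry no floating-point jitter and tie-free axes satisfy
  the n/d ± 1 occupancy contract exactly. Duplicate edges from heavily
  tied data collapse, with the effective division count logged.
- Profile rows are validated to sum to 1 within 1e-9; bins with zero
  total weight are dropped from the bin list.
- Degenerate axes (all values identical) and empty filter results are
  errors, not silent passes.
- The code-length move threshold (1e-12 bits) and the split-acceptance
  threshold (1e-10 bits) guard against float-noise oscillation.
- Pajek weights are written with shortest-round-trip `repr`, making the
  write/read cycle bit-stable.
- AMI with a near-zero denominator (both partitions near-degenerate)
  returns 1 if MI equals E[MI] exactly, else 0.

## Known limitations

- The greedy search carries no optimality guarantee beyond the sizes
  where it is tested exhaustively; pathological near-degenerate networks
  could require more restarts.
- E[MI] is computed by the exact hypergeometric sum — quadratic in the
  number of labels with an inner sum over feasible counts; fine for
  dozens of regions, slow for thousands.
- Bootstrap replicates resample within-cell climate only; range
  uncertainty itself (which cells are occupied) is not resampled, so
  support quantifies climate-measurement robustness, not range-map
  error.
- The geographic-restriction model produces compact distance-ball
  patches, not realistic range geometry.
- The support-vs-specificity relationship is asserted as a rank
  correlation on synthetic sweeps; fitting the corresponding regression
  on real data is left to the exported per-domain table
  (`domain_summary.csv`).
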