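# nichedomains

Network-based detection of **climatic niche domains** and the **climate
regions** they define, from gridded species distributions.

Classic climate classifications (Köppen's above all) delimit regions
from expert knowledge of vegetation. This package implements the
complementary, data-driven route for any species pool: characterize each
species' realized climatic niche, cluster niches and climates jointly,
and let the regions emerge from the species themselves.

The pipeline:

1. **Niche profiles.** Fine-resolution energy and water rasters (e.g.
   potential evapotranspiration and annual precipitation) are
   block-averaged to a coarse analysis grid; both axes are divided into
   `d` quantile bins computed from the global distribution of cell
   values. Species j's profile is w_ij, the proportion of its occupied
   cells in climate bin i (species under 5 cells are filtered out).
2. **Bipartite network & domains.** Bins and species form the two node
   sets of a weighted bipartite network with links w_ij. Niche domains
   are modules that minimize the map-equation code length
   (multi-restart greedy search with optional hierarchical splitting,
   implemented in-package and tested against exhaustive enumeration).
3. **Bootstrap support.** Within every occupied cell the fine climate
   pixels are resampled with replacement, cells re-binned with the
   original edges, and the network re-clustered; a domain's support is
   the share of bootstrap partitions containing a module with Jaccard
   similarity > 0.5 to it.
4. **Geography.** Every cell inherits its bin's domain (the region
   map). Bin specificity S_i = Σ_{j∈D} w_ij / Σ_j w_ij flags climatic
   transition zones; comparing its geographic projection S^P with the
   actual specificity S^A recomputed from each cell's resident species
   yields the geographical signal G = mean |S^A − S^P|. Regionalizations
   are compared with adjusted mutual information (permutation-model
   E[MI]).

A synthetic-world generator with planted climate archetypes
(controllable niche overlap and geographic restriction) provides ground
truth for all of the above; see `docs/methods.md` for the model and the
study conditions.

## Worked example

The numbered scripts under `analysis/` run the whole study; each is a
thin driver over the library. The reference world plants 4
well-separated archetypes with 60 species each on a 120×120 fine grid:

```sh
python analysis/01_simulate_and_bin.py
python analysis/02_detect_domains.py
python analysis/03_regions_and_signal.py
```

prints

```
species kept after the 5-cell range filter: 240 (removed 0); divisions per axis: 12
code length: 6.2560 bits over 356 nodes
finest domains: 5
 domain  n_nodes  support  B  jaccard_threshold
      0       93      1.0 20                0.5
      1       85      1.0 20                0.5
      2       87      1.0 20                0.5
      3       89      1.0 20                0.5
      4        2      0.1 20                0.5
...
 domain  n_species  n_bins  n_cells  mean_S_P  bootstrap_support  major
      0         60      33       73  0.982064                1.0   True
      1         60      25       97  0.974118                1.0   True
      2         60      27      100  0.983456                1.0   True
      3         60      29       67  0.983589                1.0   True
      4          0       2        8  0.000000                0.1  False
geographical signal G = 0.0136 over 297 cells (72 excluded: no species present)
```

Read: the four planted archetypes come back as four major domains
(60 species each, bootstrap support 1.0, near-unit specificity), plus
one minor transition-zone module — two bins whose species all belong to
other domains (specificity 0, support 0.1). Without geographic
restriction the signal G is near zero: species fill their domains'
climates wherever they occur.

`analysis/04_overlap_sweep.py` widens the archetypes' niche breadth and
watches specificity erode monotonically (0.97 → 0.81) while
transition-zone modules with low specificity also show low bootstrap
support (rank correlation 0.645); `analysis/05_restriction_sweep.py`
confines each species to a fraction rho of its suitable geography on
fragmented-climate worlds and recovers a growing geographical signal
(mean G: 0.031 at rho = 1.0, 0.036 at 0.6, 0.100 at 0.3). Their tables
land in `results/`.

The same workflow is scriptable via the CLI against a YAML config:

```sh
nichedomains run-all --config run.yaml --out myrun --seed 7
# or stage by stage: simulate / bin / network / domains / bootstrap / regions / signal
```

## Layout

```
src/nichedomains/   library: synthetic worlds, niche space, bipartite
                    network + Pajek I/O, map equation, bootstrap
                    support, geography metrics, pipeline, CLI
analysis/           numbered study drivers (write under results/)
tests/              pytest suite incl. exhaustive-search oracles
docs/methods.md     model, numerical choices, study conditions, limits
```
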