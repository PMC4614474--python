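# colonycomp

Tools for studying **competition for space during bacterial colonization of
a surface**: when scattered founder cells proliferate on an empty surface,
each clonal lineage ends up owning a contiguous patch, and the patches of
neighbouring lineages collide.  Who wins, and why?

The package serves researchers analysing surface-colonization experiments
(e.g. two-colour *E. coli* mixtures on agarose imaged before and after
overnight growth) and anyone studying the equivalent lattice models.  It
provides:

- **`colonycomp.sim`** — a discrete-event simulator of clonal microcolonies
  on a 2-D lattice (one cell per site, Moore-neighbourhood placement, open
  boundaries, optional founder lag times, exponential-area vs perimeter
  growth regimes);
- **`colonycomp.zones`** — Voronoi tessellation of founder positions, patch
  extraction from label maps, patch–zone matching, and the **winner index**

  ```
  WI = A_P / A_V
  ```

  the final patch area `A_P` of a lineage over the area `A_V` of its
  founder's Voronoi zone.  WI = 1 means a lineage colonized exactly the
  space nearest its founder; WI > 1 marks winners, WI < 1 losers.
  Distribution summaries: lognormal coefficient of variation
  `c_v = sqrt(exp(s²) − 1)` (with `s` the SD of ln WI) and the median
  absolute deviation;
- **`colonycomp.shapes`** — closed-boundary tracing and complex Fourier
  descriptors `a_n + i b_n = (1/M) Σ_m (x_m + i y_m) e^(−2πinm/M)`, with
  magnitude normalization giving translation/rotation/scale/start-point
  invariant shape signatures, pairwise shape dissimilarities, and
  patch-vs-zone shape correspondence;
- **`colonycomp.stats`** — non-metric MDS (Kruskal stress-1) and two-group
  PERMANOVA (between/within mean-distance ratio, or Anderson's pseudo-F)
  with permutation p-values;
- **`colonycomp.synth`** — synthetic founder patterns, lag-time models
  (truncated normal or empirical), and ground-truth label maps from an
  additively weighted Voronoi growth model, so the whole analysis chain can
  be exercised against known answers without microscopy data;
- **`colonycomp` CLI** — `simulate`, `synth`, `analyze`, `shapes`, `stats`
  and `pipeline` subcommands with JSON run manifests (seeds, checksums,
  timings) for bit-reproducible runs.

## Worked example

Simulate 400 founders on a 500 × 500 lattice with no lag times
(exponential-area growth), compute winner indices, and test whether
winner and loser Voronoi zones differ in shape:

```sh
colonycomp pipeline --lattice 500 500 --seeds 400 --seed 1 --out-dir demo
```

which logs:

```
simulate: 394258 events, occupancy 1.000, 400 lineages -> demo/sim
analyze: N=327 c_v=0.512 MAD=0.273 -> demo/analysis
shapes: 64 winner/loser zones -> demo/shapes
stats: ratio statistic=1.177 p=0.0010 stress=0.074 -> demo/stats
```

Reading: the lattice filled completely after ~394k division events; 327
lineages were analyzable (the rest touched the open boundary, whose areas
are unknown); even with *no* lag-time differences the winner-index
distribution is broad (`c_v` = 0.51), so boundary "squeezing" alone creates
winners and losers.  The 32 winners and 32 losers (top/bottom 10% by WI)
differ significantly in the *shape* of their founders' Voronoi zones:
mean between-group shape distance is 1.18× the within-group mean, a ratio
reached by none of 999 random relabellings (p = 0.001).  The MDS embedding
of the shape distances (Kruskal stress 0.074) is written to
`demo/stats/embedding.csv` and plotted in `demo/mds.png`.

Running the same pipeline with `--regime perimeter` (growth restricted to
colony perimeters, i.e. no pushing at collision boundaries) produces
near-Voronoi patches and a non-significant shape test — the contrast that
identifies boundary competition as the mechanism.

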