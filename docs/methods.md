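# Methods

This note documents the models, estimators and numerical choices behind
`colonycomp`, and what the synthetic data do and do not establish.

## The lattice colonization model

The habitat is a `width × height` square lattice; each site holds at most
one cell.  Founder cells are placed on distinct uniformly random sites and
assigned either a lag time (the waiting time before their first division)
drawn from a lag model, or — in no-lag runs — an ordinary first division
interval.  The simulation is discrete-event: the earliest scheduled
division is processed, the state is assumed frozen between events, and ties
are resolved first-scheduled-first-served, so a run is a deterministic
function of the config's single RNG seed.

On division, the daughter goes to a uniformly chosen free position of the
mother's Moore (8-connected) neighbourhood.  Positions beyond the lattice
edge count as free: a daughter placed there is counted but not tracked
(open boundary, mimicking a finite microscope field of view), and the
mother is rescheduled normally.  Lineages that ever touch the lattice
border are flagged and excluded from analysis, since their true areas are
unknown.

When the Moore neighbourhood is full, the placement threshold decides the
growth regime.  Each lineage's **perimeter set** — the empty sites
8-adjacent to at least one of its cells — is maintained incrementally
(O(1) amortized per event, with a brute-force recomputation used as a test
oracle).  Perimeter sites within Euclidean distance `threshold` of the
mother qualify for fallback placement:

- `threshold = ∞` (**exponential-area** regime): the daughter appears on a
  uniformly chosen perimeter site, standing in for cells deep in the colony
  pushing it outward.  Every cell keeps dividing, so colony area grows
  exponentially; the area-doubling interval equals the division-interval
  range (default uniform 18–22 min, matching measured microcolony area
  doubling of ~20 min).
- `threshold = √2` (**perimeter** regime): only Moore placements qualify,
  so a fully enclosed mother is retired permanently and growth is
  boundary-limited (sub-exponential; successive area doublings take
  √2-fold longer, as the tests verify at doubling crossings).

Both mother and daughter draw fresh independent division intervals; with a
lag model the *first* division of a founder fires at its lag time (lag is
defined as waiting time before the first division), and all later
intervals come from the division range.  Division times of a
synchronously-seeded population stay partially synchronized for many
generations (interval CV ≈ 0.06), so log-area versus time is a damped
staircase; growth-law tests therefore measure linearity at area-doubling
crossings rather than at every event.

Termination: full occupancy (guaranteed in the exponential-area regime:
any empty site adjacent to a lineage keeps that lineage's cells dividing),
queue exhaustion, or an optional event cap (flagged as truncated).

## Winner index and territory analysis

Founder positions (site centres, or continuous microscopy coordinates)
are tessellated with GEOS Voronoi polygons clipped to the observation
rectangle; pixel (r, c) is treated as the unit cell centred on
(x = c, y = r), so an H × W raster spans [−0.5, W−0.5] × [−0.5, H−0.5]
and zone areas sum exactly to the raster area.  Patches are 8-connected
components per lineage id.  Two pairing modes exist:

- **id pairing** (default for simulated and ground-truth maps, whose pixel
  labels *are* founder ids): exact, with edge-touching patches and
  fragmented lineages discarded;
- **overlap pairing** (for segmented micrographs with no id
  correspondence): each patch goes to the zone of maximal pixel overlap on
  the rasterized tessellation (nearest-founder assignment of pixel
  centres), and patches claiming an already-claimed zone are discarded as
  merged.

Overlap pairing is deliberately not used on simulator output: an extreme
winner's patch can overlap a neighbour's zone more than its own small
zone, and overlap pairing would silently discard exactly the most
informative lineages.

`WI = A_P / A_V` uses the polygon zone area and the pixel-count patch
area; rasterization makes equal-lag ground-truth WI ≈ 1 within about
0.5·perimeter/area, i.e. ~1–3% for zones of a few hundred sites — the
reason interior zones of at least a few hundred sites are used wherever
WI ≈ 1 is asserted.  Distribution width is summarized by the raw median
absolute deviation and by the lognormal coefficient of variation
`c_v = sqrt(exp(s²) − 1)`, `s` = sample SD (ddof 1) of ln WI, appropriate
for WI distributions peaked near 1.  Median-WI-versus-area curves use
equal-count (quantile) bins over `A_V`.  Winners/losers are the top and
bottom `floor(N × fraction)` records (default fraction 0.10) under a
stable (WI, founder id) sort, so ties resolve deterministically.

## Shape descriptors

Boundaries are closed loops: raster patches are traced with
Moore-neighbour contour following (the walk's (position, backtrack) state
is recorded and the first repeated state closes the cycle exactly — this
terminates on any connected mask, including ones where Jacob's classical
stopping rule cycles), polygons are resampled to M points equally spaced
in arc length.  Loops are forced counterclockwise; an odd-length loop gets
its last point duplicated, since the transform assumes even M.

Descriptors are the DFT of the complex boundary signal with 1/M prefactor
and negative exponent; `n = 0` (the centroid) is excluded and magnitudes
are divided by `f_1`, yielding similarity-transform and start-point
invariance.  The transform convention is pinned by two oracles: a circle
of radius r must give `f_1 = r` and nothing else, and total spectral
energy must equal the mean squared boundary radius (Parseval).  Magnitudes
discard phase, so mirror-image shapes are indistinguishable — a documented
consequence, irrelevant when only shape irregularity matters.  The default
descriptor range is n = 1..20 (configurable, capped at M/2 − 1); the
winner/loser results are insensitive to using 10 instead.

Pixel-index parameterization weights diagonal boundary runs √2-fold less
densely than straight runs, which makes raw pixel-loop spectra drift by a
few percent under raster rescaling.  Whenever spectra of *different*
shapes or resolutions are compared (patch-vs-zone correspondence), both
loops are resampled to 256 arc-length-uniform points first; invariance
then holds to ~1e-6 for continuous resampling and ~2% for raster
re-tracing.

## Ordination and permutation testing

Non-metric MDS minimizes Kruskal stress-1 by SMACOF with monotone
(isotonic) regression of embedded distances on dissimilarity ranks.  One
start uses Torgerson classical scaling — exact for Euclidean-realizable
inputs, which makes low-stress solutions reproducible — plus 7 random
restarts by default; the reported stress is recomputed independently of
the optimizer.

PERMANOVA compares winners and losers on the shape-dissimilarity matrix.
The default statistic is the ratio of mean between-group to mean
within-group pairwise distance; Anderson's pseudo-F (from sums of squared
distances) is available as `variant="pseudo-f"` and is cross-checked
against an independent implementation in the tests.  Group labels are
permuted B = 999 times by default and
`p = (1 + #{permuted ≥ observed}) / (B + 1)`, so the smallest attainable
p is 1/(B+1) = 0.001 and the test is exact: under a random-label null the
fraction of p ≤ 0.05 is 0.05 (verified over 1000 trials).

**Statistical power matters here.**  With N analyzable founders, the
winner/loser subset has 2·floor(0.1·N) members.  A 500 × 500 / 400-founder
simulation yields ~56–64 items, and the regime contrast is then decisive:
across 10 replicates the exponential-area regime gives p ≤ 0.002 in 10/10
and the perimeter regime p > 0.05 in 8/10.  A 250 × 250 / 100-founder
simulation (same founder density) yields only ~12 items; with ties among
C(12,6) relabellings the attainable p floor is already ~0.003 and measured
power at p ≤ 0.01 is ~1/10 even though the effect is present (the ratio
statistic exceeds 1 in most replicates).  The replicate-level shape tests
are therefore run at the full 400-founder scale, which this implementation
completes in ~10 s per replicate; small-field runs are reserved for the
directional lag analyses, where the effect is much larger.

## Synthetic ground truth

The generator emulates the analysis inputs, not the images: founder
patterns are Poisson in number, uniform in position with a hard minimum
separation (dart throwing), independently labelled minority/majority at a
1:19 default mix, at densities matching the low- and high-density
experiments (1.5×10⁻⁴ and 7.2×10⁻³ cells µm⁻²).  Lag models: truncated
normal (negatives redrawn, not clipped; at mean 53 / SD 16 the truncation
bias is negligible) or empirical resampling of measured lag lists.  The
heat-shock preset (mean 106, SD 32 min) is a *placeholder* at twice the
exponential-phase values — the measured heat-shock parameters are not
available — and is clearly labelled as such; it is used only for
directional comparisons, never for calibrated values.

Ground-truth label maps assign each site to the founder minimizing
`distance / v + lag` — an additively weighted Voronoi growth model in
which each front starts after its lag and expands at constant radial speed
`v`.  With equal lags this reduces *exactly* to nearest-founder
assignment (tested site-for-site), and shortening one founder's lag grows
its patch monotonically.  The default `v = 0.2` length units/min keeps
lag-induced boundary displacements (v·σ_lag ≈ 3 units) well below typical
founder spacings at the emulated densities, so WI distributions stay
peaked near 1 with moderate dispersion, as in the experiments; at much
larger `v` extreme losers vanish from the map entirely and survivor-biased
summaries become non-monotone in lag breadth.

What the synthetic data do **not** capture: real front speeds are not
constant (colonies grow exponentially before collision), colonies stack
vertically at large sizes (excluded from WI by construction), fluorescence
thresholding and stitching artefacts are absent, and ground-truth patch
boundaries are exactly radial-growth interfaces rather than mechanically
deformed ones.  Passing tests on synthetic maps therefore validate the
*measurement pipeline* (tessellation, matching, WI, shapes, statistics),
not the biological model; the simulator provides the mechanistic claims.

## Problem sizes and defaults used in the shipped analyses

- acceptance script: 150 × 150 ground-truth field for the WI identity;
  100 000 lag draws; one 500 × 500 / 400-founder no-lag simulation with
  B = 999 for the shape-clustering p-value;
- replicate tests: 10 × two regimes at 500 × 500 / 400 founders (shape
  clustering), 10 × two lag conditions at 250 × 250 / 100 founders (WI
  dispersion and lag–success correlation);
- descriptors n = 1..20 on 256-point boundaries; MDS with 8 starts,
  tolerance 1e-9.

## Known limitations

- Off-lattice daughters consume a division slot but are untracked; edge
  lineages are excluded rather than corrected.
- The simulator is single-layer by construction; no vertical stacking or
  nutrient fields.
- Overlap matching discards rather than resolves merged patches.
- Phase information in the descriptors is discarded (mirror ambiguity),
  and descriptor distances are not a metric on shape space beyond the
  chosen order range.
- PERMANOVA is two-group only; multi-group designs are out of scope.
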