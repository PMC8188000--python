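# Methods

## The model

`buteo-abm` implements an individual-based model of territory formation for
common buzzards (*Buteo buteo*) in lowland agricultural landscapes.  The
landscape is a square-pixel categorical raster in which every pixel holds one
of five resource codes: **woodland** (roosting/nesting habitat),
**rough-ground** (sparse grass and shrub hunting habitat), **meadow**
(seasonally-long-grass hunting habitat), **other** (non-resource land) and
**water** (never claimable; also the NODATA convention).

Virtual buzzards settle sequentially.  Each bird:

1. draws a roost uniformly at random among the free, untried woodland
   pixels and defends it;
2. acquires rough-ground: it repeatedly draws a *seed* pixel uniformly at
   random among the free rough-ground pixels whose centres lie within the
   rough-ground search distance `rgr_dist` of the roost centre, and claims
   the entire connected patch of free rough-ground reachable from that
   seed — only the seed is distance-constrained, the claim may extend
   beyond the search radius — until the defended rough-ground area reaches
   the requirement `rgr_area`, or no eligible seed remains;
3. acquires meadow by the same procedure with `mead_area` / `mead_dist`.

A bird that cannot meet a requirement emigrates: everything it defended is
released, except its roost pixel, which is permanently marked *tried*.  The
run stops when no free, untried woodland pixel remains anywhere in the
world; the surviving territory mosaic is the model's prediction of maximum
distribution and abundance for a saturated population.  Time is not
represented: the model asks what the landscape can hold, not how long
colonization takes.

### Assumptions

* Random roost colonization yields the same maximum abundance and
  distribution as any other colonization order (checked empirically by the
  replicate machinery: on constructed landscapes the count is seed-invariant).
* Birds do not avoid non-resource land; patch area is proportional to the
  accessible resource it contains.
* Territories are exclusive: a pixel has at most one owner.
* Birds defend whole patches.  The algorithm claims each patch in full, so
  requirements can be overshot; a configuration switch
  (`SimulationParams.whole_patch=False`) stops a claim mid-patch for
  experiments with minimal-defence variants.

### Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `roost_area_ha` | 0.06 | ha | roost requirement; one 25 m pixel |
| `rgr_area_ha` | 0.56 | ha | rough-ground area requirement |
| `rgr_dist_m` | 500 | m | rough-ground forage search distance |
| `mead_area_ha` | 13.5 | ha | meadow area requirement |
| `mead_dist_m` | 1200 | m | meadow forage search distance |
| `connectivity` | 8 | – | pixel adjacency for patches and flood fill |

The area requirements are field-derived estimates of the minimum area of
each resource-containing category an average bird needs (from radio-tracking
and resource-area-dependence estimation); they are taken as given.  Only the
two search distances are calibration targets (grids 300–500 m and
1150–1350 m at 50 m steps).

### Interpretations where the rules are under-determined

* **Connectivity** is not stated by the source description; the default is
  8-neighbour because diagonally touching field corners form continuous
  cover at 25 m grain.  Both patch labelling and flood-fill claims use the
  same setting (configurable to 4).
* **Failed settlers** must leave a permanent mark, or the stop condition
  ("free woodland exhausted") is unreachable: a failed attempt releases its
  forage claims but blocks its roost pixel forever.  This is an
  interpretation forced by termination, not a stated rule.
* **Seed choice** is uniform over free resource *pixels* (not patches),
  which weights larger patches in proportion to their area, matching an
  encounter-probability reading of random search.
* **Boundary strip**: birds may settle in a strip around the core study
  area; they defend pixels normally but are excluded from abundance.  The
  strip width is configurable (default 2 × `mead_dist` = 2400 m, so no
  outside bird could reach across it into unmodelled terrain).

### RNG protocol

One `numpy.random.Generator` per run, fully determined by the run seed.
Candidate lists (roost pixels; forage seed pixels) are ordered row-major;
each selection consumes exactly one `integers(n)` draw; no other draws are
consumed.  The protocol is part of the engine's contract: the test suite
contains an independent brute-force simulator that consumes the same draws
and must reproduce every claim pixel for pixel.

## Home-range metrics

The core at level *x*% is the convex hull of the ⌈*x*% · *n*⌉ territory
pixel centres nearest the arithmetic-mean centre of all *n* centres — the
classic peeled ("percentage") convex-polygon estimator with a single
ranking from a fixed centre.  The peeling variant (fixed centre, single
ranking) is pinned here because the estimator for virtual birds is
otherwise under-determined; recomputing the centroid between peels is a
documented alternative the package does not use.  The standard profile is
30–80% at 5% steps (11 levels); cores above 85% are excluded from defaults
because such outlines tend to include non-foraging excursions.  Degenerate
hulls (≤ 2 points, collinear) have zero area and an out-and-back perimeter.

Pairwise overlaps are directed by default: for cores A and B with positive
intersection, `(A,B)` reports 100 · area(A∩B)/area(A) and `(B,A)` the same
intersection over B's area.  An intersection-over-union option exists
(`symmetric=True`).  Zero-area cores are skipped.

## Landscape-change scenarios

Meadow plots (8-connected meadow patches) of at least 20 ha — the smallest
economically viable conversion unit, threshold inclusive and configurable —
are drawn uniformly at random without replacement and converted whole to
woodland until the converted area first reaches the target fraction of the
total eligible area.  Plots are indivisible, so the target can be overshot
by at most the largest eligible plot; the realized conversion is reported.
The target fraction applies to eligible *area*, not plot count.

## Calibration

Grid search over (rgr_dist, mead_dist).  Each combination runs six
replicates (six runs per combination were found to give reasonably stable
results at a fraction of the cost of long series); the objective is the L1
distance between the 11-level mean core-area profile of the settled virtual
birds and a reference profile.  Birds are pooled across a combination's
runs with equal weight (a per-run-then-average option exists).  Per-combo
seeds derive from the base seed and the combination's parameter *values*,
so the table is order-invariant and a reference generated by the same
evaluator at a true combination is recovered exactly (objective 0).
Combinations with zero settled birds score +inf.

## Sensitivity analysis

**Morris screening** (local): the four forage parameters are varied around
their reference values by ±70% (`rgr_dist`) and ±67% (the other three).
The variant implemented is *individually randomized OAT*: each trajectory
draws a random base point on a 4-level grid and perturbs each parameter
once, in random order, from that same base (a radial/star design) with the
classic step Δ = p/(2(p−1)) on the unit-scaled range.  A walking-trajectory
classic Morris is available via `scheme="classic"`.  Elementary effects are
Δoutput/Δparameter on ranges scaled to [0, 1]; the report gives the mean
(μ), mean absolute (μ*), and standard deviation (σ) per parameter ×
output.  Six outputs are screened: abundance, mean 80%-core overlap
percentage, 40% and 80% core areas and perimeters.  The simulation
evaluator uses the same run seeds at every parameter point (common random
numbers), so effects measure the parameter, not seed noise.  Defaults of 4
levels and 10 trajectories are package choices.

**Full factorial** (global): meadow area 9.5–17.5 ha step 1 ha × meadow
search distance 800–1600 m step 100 m, 81 cells, fixed per-cell run seeds
shared across cells.  The table reports mean and SD of abundance per cell
plus marginal means.

## Statistics

`mann_whitney` reports W in the smaller-rank-sum convention (midranks for
ties) — the convention must be pinned because a printed statistic alone
cannot disambiguate it — with a two-tailed p that is exact (enumeration)
for m+n ≤ 20 without ties and the normal approximation with tie and
continuity corrections otherwise.  A permutation p is available as a
cross-check.  `summarize` reports n, mean, median, IQR
(linear-interpolation quartiles) and the sign of (mean − median) as a
skewness indicator.

## Synthetic landscapes

The raster the model was developed against (a 25 m categorical land-cover
map of a 22 × 6 km lowland UK study area) cannot be redistributed, so the
package generates synthetic rasters in two modes:

* **Territory kits**: each kit is one woodland roost pixel plus a
  rough-ground blob and a meadow blob of stated sizes grown within the
  stated search radii.  Kits separated by more than 2 × `mead_dist` are
  mutually unreachable, so K exactly-viable kits support exactly K
  territories — constructions with known ground truth, used for exact
  packing and zero-variance replicate tests.
* **Stochastic landscapes**: connected patches are grown from random seeds
  until target cover fractions are reached.  Defaults — 30% meadow, 12%
  woodland, 8% rough-ground, patch sizes log-uniform with meadow fields
  spanning 1–45 ha (straddling the 20 ha conversion threshold) — are a
  one-time choice emulating the mixed pastoral structure of lowland UK at
  25 m grain.

What the synthetic landscapes do *not* emulate: real field geometry
(rectangularity, hedgerow networks), spatial autocorrelation of land cover
beyond patch contiguity, rivers/roads, and the particular meadow size
distribution of any real county.  Passing tests therefore demonstrate the
correctness of the mechanics and the direction of parameter effects, not
quantitative abundance for any real landscape; real predictions require a
real land-cover raster and mapping table.

## Problem sizes and numerical choices

* Analysis-scale runs in the test suite and acceptance script use
  140×140–180×180-pixel stochastic landscapes (12–20 km² at 25 m),
  30 replicates for baseline abundance, 20 per scenario, 30 Morris
  trajectories with 2 runs per evaluation, and 10 runs per factorial cell —
  sizes chosen so the whole analysis reruns from scratch in minutes while
  leaving the observed effects far from their decision thresholds.
* Areas are exact multiples of the pixel area (0.0625 ha at 25 m), so
  requirement comparisons are exact in binary floating point at the default
  parameter values; requirement checks use `>=` with no tolerance.
* Distances are Euclidean between pixel centres; the seed-eligibility test
  compares squared pixel distances against the squared radius.
* Calibration ties break toward the smallest objective, then the
  lexicographically smallest (rgr_dist, mead_dist).
* 95% intervals on replicate means are t-intervals; zero-variance replicate
  sets give zero-width intervals.

## Known limitations

* No demography: no juveniles, dispersal mortality, breeding success or
  inter-annual turnover; the model predicts a saturation ceiling, not a
  trajectory.
* No interspecific interactions (e.g. goshawk competition/predation), which
  would lower realized densities in heavily afforested scenarios.
* Movement is not costed: flights to seeds and between patches take no time
  and no energy; search distances are hard constraints rather than
  energetic trade-offs.
* Whole-patch defence can overshoot requirements substantially on maps with
  very large patches; the mid-patch switch exists but is not the default
  and is not used in any reported result.
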