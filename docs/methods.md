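# Methods

This note documents the statistical models implemented in `pairspace`, the
defaults and why they were chosen, the numerical choices that affect
results at the margin, and what the synthetic-data generator does and does
not emulate.

## Data model

All coordinates are planar meters on a local study grid; no geodesy is
performed anywhere (ranges of interest span tens of meters). Timestamps
are seconds on a shared epoch and must be strictly increasing per
trajectory. A trajectory is one individual's fix stream for one night or
pooled across nights; a dyad series is the time-aligned sequence of
simultaneous (male, female) fixes.

* **Subsampling** (default 300 s for all home-range and dyad analyses) is a
  greedy forward scan: the first fix is kept, and a fix is kept iff it is
  at least the interval after the last kept fix. This is deterministic,
  order-preserving, idempotent, and does not invent a clock grid.
* **Dyad alignment** pairs each fix of one stream with the nearest-in-time
  unused fix of the other within a tolerance, default **150 s** — half the
  5-min analysis grid, so every subsampled fix of one observer can claim at
  most one of the other's. Earlier fixes win ties.

## Kernel home ranges

Fixed bivariate Gaussian kernel on a regular grid, exact (not binned),
renormalized to unit mass on the grid. Defaults:

* **Cell size 2.5 m** — a quarter of the 10-m field grid; a ~0.2-ha range
  (~45 m across) is resolved by ~20 cells, and halving the cell changes
  the 95% area by well under 5% (grid-convergence test).
* **Grid padding 3.5·h** beyond the data extent so isopleth contours close
  inside the grid.
* **Reference bandwidth** `h_ref = sqrt((s_x²+s_y²)/2) · n^(−1/6)` with
  *population* (ddof = 0) SDs, which makes the rule exactly invariant
  under point duplication.
* **Ad hoc bandwidth**: the term is used ambiguously in the home-range
  literature (plain reference rule vs. stepwise contiguity rule). The
  stepwise rule is the default here: scan multipliers c = 1.0, 0.9, …, 0.1
  of `h_ref` and keep the smallest c whose 95% isopleth is a single
  connected region (8-connectivity on the thresholded grid); if even
  c = 1.0 fragments, `h_ref` is returned unchanged. The plain reference
  rule remains available (`bandwidth="reference"`).
* **Isopleth**: cells are ranked by density and the contour is traced
  (marching squares) at the density of the last cell needed for the
  cumulative cell mass to reach the level; rings are assembled into
  shells and holes by even-odd nesting. Area is the summed ring area in
  hectares.
* **Sparse nights**: below 15 fixes a kernel estimate is unstable, so
  per-night ranges fall back to the 100% minimum convex polygon; the
  output records which estimator produced each polygon.
* **No autocorrelation correction** is applied to fixes: kernel home-range
  estimation does not require serial independence, and precision improves
  with more fixes.

Correctness anchor: for a seeded standard-bivariate-normal sample the 95%
isopleth area must match the analytic 95% ellipse, area
`π·χ²₂(0.95)·σ² ≈ 18.8 m²` at σ = 1, within 10%; smoothing inflates the
area by roughly `(1 + h²/σ²)`, about 4% at the reference bandwidth for
n = 10⁴.

## Percent overlap

Directional: `overlap of A by B = 100·area(A∩B)/area(A)`. Multi-ring
isopleths contribute their summed areas before division. "Neighbor"
summaries restrict pairs to polygons within an adjacency distance,
default **50 m** (a configuration knob — adjacency is a study-design
choice, not a fact of the geometry).

## Dynamic interaction

Distance criterion default **d = 15 m** (close enough for visual contact
in the study habitat), group spread default **s = 0** (solitary foragers);
both are flags.

* **Random gas model**: expected encounters per observation period
  `f = (4ρv/π)(2d+s)`. ρ is taken as the inverse of the pair's union
  95%-range area in m² (polygon union, not the sum of areas); v is the
  mean over the two partners of their mean nightly path length.
* **Observed encounter counting**: the gas model predicts a *rate of
  encounters*, not of samples-in-proximity, so the observed side counts
  *entries* into the below-d state (maximal runs of consecutive below-d
  fixes count once; a series that starts below d starts with one entry).
  Because this reading is not the only possible one, the per-fix
  association count is reported alongside in every report.
* **Hutchinson's model**: expected below-d count among N instantaneous
  point samples, `f = Nρπd²`, compared against the pooled association
  count.
* **Doncaster's test**: 2×2 table with rows {N observed simultaneous
  pairings, all N² cross pairings} and columns {≤d, >d}; the observed
  pairings are included in the N² set (the literal "all N² distances
  possible"). χ² test of independence with df = 1, continuity correction
  off by default (switchable). Direction is attraction/avoidance by the
  sign of the observed-vs-cross proportion difference when p ≤ α, else
  none. A configurable minimum of 20 aligned fixes is enforced.
* **Across-pairs inference**: per-dyad observed minus expected values go
  into the exact Wilcoxon signed-rank test.

**Known property**: under study-scale geometry (d comparable to the range
SD) the Doncaster χ² is mildly *conservative*: the N²-row proportion is a
U-statistic over the same points that form the observed row, so the two
rows co-vary positively and the nominal variance overstates the true one.
Measured type-I error over 1,000 independent simulated dyads is ~3% at
α = 0.05 (the acceptance band is 5% ± 2%); direction recovery under strong
coupling is essentially perfect. Users should treat marginal Doncaster
p-values as slightly understated evidence against independence.

Also worth knowing: both the gas and Hutchinson expectations assume
uniform use of the union range. Stationary OU-style space use concentrates
both animals near the shared range center, so *independent* partners
already exceed both expectations (measured obs/exp ≈ 1.2 and ≈ 1.5
respectively on the uncoupled generator). Conclusions of "attraction" from
either model alone therefore deserve caution; the Doncaster comparison,
which conditions on each animal's own marginal space use, does not share
this bias.

## Exact rank tests

Signed-rank: zeros dropped, mid-ranks for tied absolute values, V = sum of
positive-difference ranks. The exact null is computed by subset-sum
dynamic programming over doubled ranks — identical to enumerating all 2ⁿ
sign assignments — for n ≤ 25; beyond that a tie-corrected normal
approximation is used and noted in the result. Two-sided p = 2·min(tail),
capped at 1: for n = 7 one-signed differences this yields 2/128 = 0.015625
(0.02 at two decimals) at either extreme of V. Rank-sum: Mann–Whitney
statistic for the first sample; exact enumeration over all C(n₁+n₂, n₁)
labelings for n₁+n₂ ≤ 20 without ties, otherwise the tie-corrected normal
approximation. The χ² 2×2 test keeps Yates correction off by default so
the Doncaster statistic matches the classical independence formula.

## Social metrics

Agonistic codes (chase, charge, bite, grab, flee, displace, jump-away)
dominate any distance information; grooming or inter-individual distance
≤ 1 m is affiliative; distance ≤ 5 m without either is neutral; beyond
5 m a record is no interaction. Records carrying neither codes nor a
distance, or unknown codes, are rejected rather than guessed. Rates are
events per hour of simultaneous in-sight observation per dyad — these
hours are an input column, since they are a property of the field
protocol, not derivable from the event log. Per-dyad totals are computed
from unrounded counts and then rounded, so a printed total may differ from
the sum of the printed class rates by one unit in the last place.
Sleeping tallies count a tree as shared if both partners ever used it and
a day as simultaneous only if both used the same tree that day;
observation days are days with records for both partners.

## Synthetic data generator

Each animal follows a discrete OU walk toward its own range center with
mean-reversion a per fix interval and Gaussian step noise; within a
perception radius R the step gains η·(unit vector toward partner) — η < 0
is avoidance, η > 0 attraction. The OU choice (over a plain correlated
random walk) is deliberate: it has a stationary range whose 95% area is
analytically `π·χ²₂(0.95)·σ_st²` with `σ_st² = step_sd²/(1−(1−a)²)`,
which the tests verify, and step SDs are derived from requested range
radii through this relation. All randomness flows from a single seed;
per-dyad substreams are derived deterministically, and reruns are
bitwise identical.

Defaults are the study-shaped conditions: 7 dyads, 8 nights per dyad,
10.5-h nights, 60-s raw fixes (5-min subsampling downstream), pair
partners sharing a center, neighboring pairs 80 m apart, a = 0.05 per
60-s step (≈20-min relaxation time). The **"paper" preset** fixes
η = −0.55 with R = 40 m and nominal radii 28.0 m (male) / 20.5 m
(female); the nominal radii sit below the uncoupled analytic values
because kernel smoothing and the mutual repulsion both inflate the
realized range. Under this preset the measured 95% kernel areas are
≈ 0.34 ha (males) and ≈ 0.19 ha (females), partners spend ≈ 4–6% of
aligned time within 10 m and ≈ 22–25% within 20 m, the Doncaster test
flags avoidance for all seven dyads, and pair overlap is high and
female-biased while same-sex neighbor overlap is ≈ 0.

Sleeping records draw one tree per individual per day from a per-dyad
pool of exclusive and shared trees; a simultaneity probability (0 in the
"paper" preset) controls whether partners ever share a tree on the same
day. Interaction events are an independent Poisson process per class
(defaults 0.11 neutral, 0.03 agonistic, 0.005 affiliative per in-sight
hour, ≈ 74 in-sight hours per dyad).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: habitat structure and range shapes that deviate
from isotropic OU ellipses; seasonal changes in movement or coupling;
observation gaps from out-of-sight periods (fix streams are complete);
GPS/triangulation error; behavioral time structure in interactions
(events are homogeneous Poisson); and any feedback between sleeping-site
choice and nocturnal movement.

## Problem sizes and runtime

The default test suite simulates at the study scale (7 dyads × 8 nights ×
~630 fixes per animal per night), uses 1,000 replicates for the Doncaster
type-I experiment (4 nights per replicate, fixes subsampled to one per
hour, N ≈ 44 aligned fixes per dyad — near-independence given the 20-min
relaxation time), 200 replicates per direction for direction recovery,
and 10 × 10,000 paired draws for the uniform-placement check of
Hutchinson's formula. These sizes were chosen to keep Monte Carlo error
comfortably inside each asserted tolerance.

## Degenerate inputs and tie-breaks

All-identical points: bandwidth and KDE raise a degenerate-input error;
collinear fixes make the MCP fallback raise rather than return a zero-area
polygon. Empty trajectories pass through subsampling unchanged; an empty
dyad series yields zero counts but proximity and Doncaster refuse it.
Zero-margin contingency tables and all-zero difference vectors raise
test-undefined errors. In dyad alignment, ties between equally near fixes
go to the earlier fix; in the isopleth threshold, the contour is traced at
the density of the last cell that brings cumulative mass to the level, so
the enclosed mass is at least the requested level.
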