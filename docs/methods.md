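# Methods

This note documents the modeling assumptions, conventions and numerical
choices behind `cjindex`, and what the synthetic validation does and does
not establish about real data.

## Indicator system and normalization

Two fixed schemas describe the spatial units.  Linear (street) spaces
carry nine indicators — sky view factor, street canyon ratio, green view
index and land surface temperature (distributive); population aggregation,
proportion of sensitive population and housing prices (recognition);
indoor cooling facilities and medical facilities (procedural).  Areal
(park/square) spaces carry seven — vegetation coverage and land surface
temperature (distributive), the same recognition triple, and the same
procedural pair.  Each schema stores reference per-dimension weights from
the original Fuzhou case study as fixtures; they are used only when a run
explicitly requests fixed weights or when the synthetic generator
backfills indicator columns.

Polarities are not part of any published tabulation, so the package fixes
defaults from the physical reading of each indicator: sky view factor,
green view index, vegetation coverage, housing prices and both facility
counts are *positive* (more of them means a cooler or better-served
space); street canyon ratio, land surface temperature, population
aggregation and proportion of sensitive population are *negative* (streets
with low sky view and high enclosure trap heat; crowding and demographic
sensitivity raise risk).  All polarities are overridable per run.

Normalization is min-max per column, reversed for negative polarity, so
every normalized value lies in [0, 1] with 1 = most just.  A column with
zero range carries no ordering information; it is mapped to all zeros,
flagged, and (through entropy weighting) receives zero weight.  By default
the bounds are the empirical column extrema; the caller may instead supply
explicit reference bounds.  The explicit-bounds mode exists because
empirical min-max is an affine shrinkage of any externally defined scale:
when the generating ranges of synthetic data are known, scoring against
them is the only way the reconstruction can be exact (see *Synthetic
validation* below).

## Entropy weighting

Weights are estimated independently within each (space type, dimension)
group, mirroring how composite-indicator weight tables are reported per
criterion block; a whole-table mode (estimate jointly, renormalize within
groups) is available for sensitivity analysis.  Conventions:

* 0·ln 0 ≡ 0 in the entropy sum (the standard limit convention);
* an all-zero column gets entropy 1, hence weight 0;
* if *every* column in a group is degenerate, the group falls back to
  uniform weights with a `degenerate` flag so downstream aggregation never
  divides by zero;
* a single-unit table is rejected (ln m = 0 makes entropy undefined).

Entropy weighting is purely dispersion-driven: a nearly-constant but
informative indicator gets little weight, and the estimated weights are a
property of the sample, not of the indicator system.  This is visible in
the reference scenarios: weights estimated from a simulated population
differ from the weights that generated it, which in turn perturbs scores
and slightly degrades typology recovery relative to injecting the true
weights (adjusted Rand ≈ 0.94 instead of ≈ 0.98 on the linear scenario).

## Composite index

The three criterion indices are combined linearly, CJI = α·DJ + β·RJ +
γ·PJ.  The dimension weights default to 1/3 each — the neutral choice when
no substantive argument ranks the dimensions — and are constrained to be
nonnegative and sum to 1 so the composite stays in [0, 1] and level
classifications are comparable across runs.  Alternative aggregations
(geometric mean, minimum) are deliberately out of scope.

## Jenks classification

Scores are classified per space type and per score vector (each criterion
index and the CJI separately) into k = 5 levels labeled Low / Lower /
Medium / Higher / High, "Low" meaning least justice.  The partition is the
exact optimum of the within-class sum of squared deviations (SDCM),
computed by Fisher's dynamic program over the *distinct* values with
multiplicities — running the DP on distinct values guarantees that heavy
ties can neither straddle a class boundary nor empty a class.  Because
Jenks implementations differ in conventions, the package states its own:
class intervals are right-closed (a value equal to a break belongs to the
lower class), and SDCM ties are broken toward the partition whose first
class is smallest.  An exhaustive-enumeration oracle (n ≤ 15) verifies
optimality in the test suite.  Values outside the fitted range are clamped
to the end classes with a warning.  If a score vector has fewer distinct
values than k (noise-free synthetic data collapses each cluster to a
point), the pipeline reduces k for that vector and logs it; the library
function itself treats that as an error, per its contract.

## Deficit typology

K-means with k = 4 (the number of recurring deficit configurations in the
reference scenarios; silhouette-based selection can be layered on by the
caller), k-means++ initialization, 50 restarts, and a fixed default seed
(20250101) runs on the raw (DJ, RJ, PJ) triples — they are already on a
common [0, 1] scale, so re-standardization is off by default but available.
Clusters are renumbered in descending size order with deterministic
tie-breaks so typology tables are stable; recovered centroids are reported
as member means on the original score scale.

One-way ANOVA per dimension validates the partition: F = (SSB/(k−1)) /
(SSW/(m−k)) with p from the F(k−1, m−k) distribution.  Degenerate cases
are defined explicitly: SSW = 0 with SSB > 0 reports F = +∞, p = 0 (with a
warning); all groups identical reports F = 0, p = 1.  No post-hoc
correction is applied.

Deficit labels derive from centroids: a dimension is *deficient* when its
centroid falls below a threshold θ (default 0.5 on the score scale;
configurable per dimension, or relative to the across-cluster column mean).
All three deficient → "Systemic Justice Deficit"; none → "All-Dimension
Justice Fulfilled"; otherwise the deficient dimensions are named.  A single
fixed threshold cannot reproduce every verbal typology in the literature —
e.g. a cluster centered at DJ ≈ 0.41 may be called "balanced" while one at
DJ ≈ 0.36 is called "deficient" — so the rule is explicit configuration
rather than a claim of canonical labeling; with θ = 0.5 it reproduces the
systemic, fulfilled, and single-dimension reference labels.

## Synthetic validation

The generator emulates the statistical structure the analysis assumes:
two populations (linear: four planted clusters of 108/84/76/19 units;
areal: 13/11/11/19), per-unit score triples drawn as planted centroid +
independent Gaussian noise (sd 0.05 by default), clipped to [0, 1], with
exact planted cluster sizes so count-based checks are deterministic.  (The
published linear typology that these presets mirror is internally
inconsistent — its per-cluster counts sum to 287 while its stated total is
279; the presets follow the per-cluster counts.)  The `null` preset is a
single homogeneous cluster used to calibrate the ANOVA rejection rate.

`backfill_indicators` inverts the scoring chain: for each unit and
dimension with target score C it sets every normalized indicator in the
group to C (whose weighted sum is C for any weights on the simplex), adds
optional jitter confined to the weight vector's zero-sum directions and
scaled to stay inside [0, 1] (units at the boundary keep the unjittered
solution, with a warning), then inverts the polarity-appropriate
normalization over configured plausibility ranges (e.g. land surface
temperature 28–45 °C) to produce raw columns.  Re-scoring the backfilled
table with the injected weights and the configured bounds reproduces the
planted scores to ≤ 1e-9 (observed ≈ 1e-16), which validates the entire
load → normalize → weight → score chain end to end.

What passing these checks does **not** show: real indicator tables have
spatially autocorrelated, non-Gaussian, cross-correlated indicators and no
ground-truth clusters; entropy weights estimated from real data need not
resemble the reference fixtures; and the clipped-Gaussian noise model
slightly biases cluster means near the [0, 1] boundary (≈ 0.004 at a
centroid of 0.95 with sd 0.05).  Recovery statistics on synthetic data are
therefore a correctness floor, not a field-performance estimate.  In
particular the smallest planted cluster (19 units) has a per-coordinate
sampling sd of ≈ 0.0115 in its own sample mean, so recovered centroids are
compared per seed against the planted-label *sample means* and only on
average (over 20 seeds) against the planted population centroids.

## Determinism and problem sizes

All randomness flows through explicit integer seeds (`numpy`
`default_rng`; the k-means restart schedule is seeded through
scikit-learn's `random_state`).  Output CSVs use 17-significant-digit
floats (exact binary round-trip); JSON reports are written with sorted
keys and no timestamps, so re-running a configuration reproduces artifacts
byte for byte.

The validation suite runs at the scenario sizes above (m = 287 and 54),
with 200 random 5×3 matrices for the weighting oracle, 100 random
instances (n ≤ 12, k ≤ 4) for the Jenks oracle, 1000 replicates for the
ANOVA null calibration, and 20 seeds for typology recovery — sizes chosen
so every property is exercised at the reference scale while the whole
suite completes in seconds.

## Known limitations

* Entropy weights are sample-dependent; comparing scores across datasets
  requires either fixed injected weights or shared normalization bounds.
* Min-max normalization is sensitive to outliers in the column extrema;
  no winsorization is applied.
* Geometry handling is pass-through (GeoJSON in, GeoJSON with result
  properties out); no CRS transforms, areal weighting or spatial
  statistics.
* Deriving the raw indicators themselves (remote sensing, street-view
  segmentation, POI harvesting) is out of scope; the pipeline starts at
  the indicator table.
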