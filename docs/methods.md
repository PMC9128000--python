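# Methods

This note records the models, algorithmic choices and defaults behind
`foragedecomp`, including the places where the procedure was genuinely open
and a choice had to be made.

## Arena model and zones

The arena is a circular platform of radius 17.5 cm (35 cm diameter) entered
from below through one of five 5.5 cm holes; the other four hold sand pots
(pot radius 2.75 cm). Pot zones extend 1.7× the pot radius (4.675 cm); the
Tunnel Zone shares that radius. Three concentric rings partition the
platform: the Center ring's radius is half the Intermediate ring's outer
radius, and the Intermediate outer radius passes through the hole centers.
Five sectors are bounded at the angular midpoints between holes.

Dimensions the source description leaves open, fixed here as configurable
defaults: the hole-circle radius is 12.0 cm; the five holes are equally
spaced at 72°, tunnel at 270°; the Wall ring is the annulus between the
Intermediate outer radius and the wall. Boundary points belong to the inner
region (half-open convention), making zone assignment deterministic. A point
within 1.0 cm of the tunnel center is In Tunnel and counts as off-platform
(the animal is in or over the hole). Layouts serialize to an `arena:` YAML
block (cm, degrees).

## Tracking, alignment, segmentation

Tracking tables are 30 frames/s records of time, position (cm) and speed
(cm/s); validation enforces strictly increasing time, uniform frame spacing
and non-negative speeds. Sessions are aligned by a least-squares similarity
transform (rotation, uniform scale, translation — the Umeyama solution) on
≥ 3 non-collinear landmark pairs, then translated so the tunnel center maps
to the origin; speeds are rescaled by the fitted scale factor.

An excursion runs from the last In-Tunnel frame before an exit to the first
In-Tunnel frame after the return; its interior lies entirely on the
platform. Trips still open at the end of the analysis window (default the
first 25 min) are discarded. Coordinate dropouts of ≤ 5 frames are linearly
interpolated; longer dropouts invalidate any excursion spanning them. Zone
flags are recomputed from geometry by default (an `in_tunnel` column can be
used instead), so segmentation is invariant to the alignment transform.

## Measure battery

58 named measures per excursion, computed on the interior frames: x/y
min/max/mean/median/sd/range; radial statistics; radius-weighted mean
direction components; total distance, summed and mean heading change,
tortuosity (path length over maximal radial extent); duration; speed
mean/sd/max; fractions of frames per velocity class; velocity-bout counts
and durations; per-zone occupancy fractions and debounced visit counts
(center, intermediate, wall, pots 1–4, tunnel zone); latencies to the center
and each pot; first pot visited; sectors visited.

Velocity classes use the stated half-open bands — slow v ≤ 5, medium
5 < v ≤ 15, fast v > 15 cm/s (units taken as cm/s) — and a bout is a
maximal same-class run longer than 3 frames (≥ 4).

Three measure-design decisions matter for clustering stability and are
deliberate:

- **Visit debouncing.** A zone exit shorter than 5 frames does not end a
  visit. Raw 30 fps boundary flicker otherwise turns visit counts into
  high-variance noise; commercial tracking software applies equivalent
  filters.
- **Angular placement** is reported as radius-weighted mean direction
  components (mean x and mean y over mean radius). Normalized centroid
  directions, or per-frame angles, flip sign arbitrarily for angularly
  symmetric trajectories; the weighted components go smoothly to zero
  instead.
- **Latency to a never-visited zone** is a fixed cap (300 s), not the
  excursion duration. Using the duration would alias duration variance into
  every latency column for non-visiting excursions. No speed median is
  included: per-frame speed distributions are multimodal (stops vs runs),
  where a median is a knife-edge statistic.

Measures are z-scored across excursions (ddof = 1); constant columns are set
to 0 and flagged. Keystone features are normalized by dividing time, visit,
sand and food measures by total time in arena (per-bin measures by the
bin's own TTA), subtracting the platform-entry latency (LEP) from pot
latencies, passing LCAE and percentage measures through, and excluding
platform and tunnel time as redundant with TTA; rows with TTA = 0 are
flagged and dropped.

## Module discovery

**Measure selection.** Pairwise Pearson correlations; while any off-diagonal
|r| exceeds the cutoff, the member of the most-correlated pair with the
larger mean absolute correlation to the other retained measures is dropped
(ties keep the earlier column). The cutoff grid is 0.50–0.95 in 0.05 steps;
the selected cutoff maximizes the resulting cluster count (ties prefer the
larger cutoff, i.e. least pruning).

**Clustering.** Ward's minimum-variance method on Euclidean distances
(scipy's `ward`, equivalent to hclust Ward.D2).

**Hybrid adaptive tree cut.** The reference implementation of the published
hybrid dynamic tree cut is not available here, so the cut is this package's
own adaptive branch decomposition. Walking the merge sequence bottom-up, a
branch is *locked* as a cluster at the merge that consumes it when it
(1) has ≥ `min_cluster_size` members, (2) separates cleanly — its relative
height gap (join height minus branch height, over join height) is at least
a `deep_split` threshold, (3) is internally tight — its mean internal merge
height, relative to 0.99× the tree height, is at most a `deep_split`
threshold — and (4) the join is prominent, i.e. happens high enough in the
tree (protects the interior of tight clusters from being shredded). The
deepSplit 0–4 mapping (min gap 0.60 → 0.05, max scatter 0.40 → 0.95, min
join prominence 0.70 → 0.20) was calibrated once on simulated single-blob
versus separated-blob dendrograms in ≥ 8 dimensions, then frozen. Points
never locked are unassigned; if nothing locks, the data form one cluster.
Study parameters follow the source: deepSplit 4, minimum cluster size 20.
At deepSplit 4, structureless data shred into many minimum-size clusters —
the property the cluster-count null relies on.

**Cluster-count null.** Each of N iterations permutes values independently
within each column (preserving marginals, destroying joint structure),
re-clusters, re-cuts and counts clusters; p = (1 + #{null ≤ observed}) /
(N + 1), lower-tailed, since real structure yields *fewer* clusters than
shuffled data.

**Partition and IGP.** A balanced train/test split stratifies on genotype ×
sex × phase (fraction 0.5, round-half-up per stratum, seeded). Training
clusters give centroids (member means). Each test point is assigned to the
nearest centroid (Euclidean; ties to the lowest index) and the in-group
proportion of cluster k is the fraction of its assigned test points whose
nearest test-set neighbor (excluding self; ties to lowest index) is also
assigned to k; clusters with < 2 assigned points score 0.

**IGP permutation null.** The null replaces the test matrix with a
within-column shuffle of itself (the same scheme as the cluster-count null),
keeps the centroids fixed, recomputes assignments and nearest neighbors in
the shuffled data, and recomputes each cluster's IGP;
p = (1 + #{null ≥ observed}) / (nperm + 1). A uniform-box
random-replacement-centroid null was evaluated first and rejected: in
strongly clustered data a random centroid frequently captures an entire
coherent blob, so its null IGP ties the observed value and the test has no
power precisely where clusters are best. The shuffle null is exactly
calibrated when the test data have independent columns and loses power only
through whatever marginal structure shuffling preserves.

**Modules and annotation.** Storey q-values across cluster p-values; modules
are clusters with q < 0.1. Every excursion (train and test) is annotated
with its nearest significant-module centroid; ties go to the lower module
id. With fewer than ~20 clusters the smoother is unreliable, so pi0 defaults
to 1 (pure Benjamini–Hochberg) below 20 tests.

## q-values

pi0(λ) = #{p > λ} / (m(1 − λ)) on λ = 0.05…0.95 (step 0.05), smoothed by a
cubic polynomial fit; the estimate is the mean of the fitted curve over
λ ≥ 0.5, clipped to (0, 1]. Averaging the fitted curve rather than reading
its right endpoint avoids the endpoint's high variance (the fitted value at
λ = 0.95 extrapolates tail-count noise and dips below 0.8 on ~5% of all-null
draws at m = 1000). q-values are the pi0-scaled step-up values,
q(i) = pi0 · min over j ≥ i of m·p(j)/j, monotone in p; with pi0 = 1 this is
exactly Benjamini–Hochberg.

## Poisson GLMs and effect classes

Counts per module are modeled with log-link Poisson GLMs (statsmodels).
Analysis of deviance is sequential (Type I), matching R's `anova.glm`:
terms enter in the order cross, genotype, cross:genotype, and each term's p
is the chi-square tail of its deviance drop at its df. Goodness of fit is
the upper-tail chi-square of the residual deviance at the residual df
(pass iff p > 0.05). Effects classify as: *putative imprinting* —
significant interaction; otherwise *generalized parental* — significant
cross main effect; *genetic* — significant genotype main effect. An empty
cross × genotype cell makes the interaction inestimable; the fit drops to
main effects and is flagged. All-zero counts flag a degenerate fit (p = 1).

Fisher's exact test: 2×2 tables are exact two-sided (sum of hypergeometric
probabilities ≤ the observed table's); larger tables use Monte Carlo over
margin-preserving tables (Patefield sampling via scipy's `random_table`,
default 10⁵ iterations, seeded) with the add-one estimator — exact
enumeration over hundreds-of-rows profile tables is infeasible. Keystone
post-tests are het-vs-wildtype contrasts from a one-way genotype OLS within
each sex × cross subset, Bonferroni-adjusted over the mutant genotypes in
that subset (the adjustment family). Module → keystone links are simple
regressions, reported as Pearson r, slope sign and p (significance 0.05).

## Transitions

Per mouse and phase, expressed modules ordered by excursion start time give
consecutive pairs; counts pool across mice but never across mice or phases.
A pseudo-count α = 0.5 is added to every cell before row normalization, so
the probability matrix is strictly positive and ergodic even when the
empirical chain is reducible. The stationary distribution solves
(Pᵀ − I)π = 0 with Σπ = 1 by least squares; the fixed-point residual is
checked against 1e-10. Group comparison: observed statistic =
‖π_A − π_B‖₂; the null reassigns whole per-mouse sequences between groups
(preserving sizes), keeping within-mouse dependence intact — reshuffling
individual module tokens is available behind `unit="token"` but the
per-mouse unit is the default and the honest exchangeability unit.
Note the statistic only sees stationary distributions: two chains with the
same π (e.g., any two doubly stochastic chains) are indistinguishable to it
no matter the sample size.

## IEN and region scoring

Imprinting signal: maternal − paternal expression per replicate (alleles
already parent-resolved from the reciprocal-cross orientation). Pearson r
against each marker's expression across replicates (≥ 3 replicates;
zero-variance markers skipped and reported). Signs are tallied per cell-type
category (r = 0 excluded and counted) and tested by chi-square without
continuity correction; Pearson residuals (obs − exp)/√exp localize the
enrichment; a warning notes expected counts < 5. Cell-type mean profiles are
plain means over labeled cells; imprinted-gene grouping is Ward.D2 on
Euclidean distances of those profiles, cut at a fixed group count
(default 24).

Region scoring from reciprocal-cross reporter images: per region and
channel, a 2×2 Fisher compares dominant-image frequency between crosses
(minimum 8 images per cross); the score is −log10 p, signed positive when
dominance comes from the maternal-copy channel of each cross; a region is
called maternally imprinted only when both channels are independently
significant (p < 0.05) in the maternal direction.

## Synthetic data

The generator is the package's definition of the study conditions, not a
tuning surface.

**Trajectories.** Six excursion templates are waypoint paths over arena
anchors with a velocity class per segment: direct-to-food (fast to pot 4,
dwell, medium home), loop-explore (medium tour pot 1 → center → pot 2 →
pot 3), wall-follow (fast full-perimeter wall tour), dig-at-pot (long slow
dwell at pot 2), center-dart (fast out-and-back with a center dwell),
short-peek (slow, barely past the tunnel zone). Segments are piecewise
linear with speeds drawn inside the class band (slow 2–4.2, medium 7–12,
fast 17–24 cm/s); dwells are mean-reverting slow wiggles; per-excursion
waypoint jitter is 0.5 cm and per-frame jitter 0.005 cm; dwell anchors at
pots are pulled 1.5 cm inside the ring boundary the pots sit on, and speeds
continue from the actual previous frame, so velocity classes and zone
engagement are consistent *within* a template — between-template contrasts,
not boundary flicker, carry the signal. Sessions alternate In-Tunnel blocks
with excursions; per-frame speed is recomputed from displacements, so the
velocity column is self-consistent.

**Cohorts.** Per-mouse module counts are Poisson with per-cell rates: base
rates × optional (genotype, cross) multipliers (planted interactions) ×
optional per-sex multipliers (the default biases female usage toward the
first modules, so male and female chains differ in stationary
distribution). Expression order follows the sex's transition chain
restricted to the remaining multiset. All randomness descends from one
SeedSequence, spawned per mouse, so any mouse regenerates in isolation.
Truth records carry every planted rate, multiplier and chain.

**Allelic replicates.** The focal gene's bias b_r = μ + σz_r (defaults
μ = 5, σ = 2 on a base expression of 50, 18 replicates emulating a 9 + 9
reciprocal design); maternal/paternal = base ± b/2. Markers of the positive
category are ρ·z + √(1−ρ²)·noise (category two with −ρ), so the planted
marker–signal correlation is exactly ρ in expectation.

**What passing tests show, and what they do not.** The templates are far
better separated than real excursion types, tracking has no identity swaps
or dropout bursts, counts are exactly Poisson, and replicate noise is
Gaussian and independent. Recovery of 6/6 modules at purity ~1.0 therefore
validates the machinery (segmentation, measures, selection, cut, IGP, FDR,
GLMs) — it does not predict module counts or purity on real tracking data,
where cluster structure is weaker and measure noise is heavier-tailed.

## Validation studies (experiments module)

Sizes chosen for stable rates in minutes on one CPU: oracle equivalence
(50 IGP instances vs a pure-Python O(n²) brute force, 200 Fisher tables vs
hypergeometric enumeration, 50 two-state chains vs the closed form
π₁ = p₂₁/(p₁₂+p₂₁)); recovery over 10 cohorts (8 mice, ~480 excursions,
~80 per template; null test 200 iterations, IGP 200 permutations);
calibration at α = 0.05 with 200–500 permutations (150 replicates for the
discrete cluster-count null — its permutation p is conservative under ties,
so the data shape, 300 × 10, was chosen so null counts disperse; 100
replicates elsewhere); power at the planted effect sizes (rate-ratio 2.0 at
25 mice/cell; ρ = 0.8; stationary-distinct chains at 30 mice/group).

## Known limitations

- The hybrid tree cut is a behavioral re-design, not a port; on dendrogram
  shapes far from those it was calibrated on (e.g., 2-D data, chained
  clusters, moderate separation) its deepSplit mapping will differ from the
  published implementation's.
- The IGP permutation null assumes within-column shuffling destroys the
  relevant structure; test data with strong non-cluster correlation
  structure would make it anti-conservative.
- The stationary-distribution group test cannot see differences in
  transition structure that leave π unchanged.
- Monte Carlo Fisher p-values carry sampling error ~1/√iterations; seeds
  are recorded so results are reproducible.
- The cluster-count null statistic is a small integer, so its permutation
  p-value is conservative under ties: the measured type-I rate at α = 0.05
  sits near 0.02 rather than 0.05 across the data shapes examined. The test
  never exceeds its nominal level.
- Poisson GLMs assume equidispersion; cohorts mixing heterogeneous rates in
  one modeled cell (e.g., pooling sexes when usage is sex-biased) fail the
  GOF check, by design — the analysis drivers fit within sex.
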