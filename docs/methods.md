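# Methods

This note documents the models, conventions and numerical choices behind
`lesionnet`, in the order the pipeline runs them.

## Synthetic cohorts and what they do (and do not) emulate

The generator produces everything the analysis consumes: per-subject ROI
time series, motion traces, lesion-overlap fractions, demographics and raw
cognitive scores, for a cohort of patients and individually matched
controls (matched on sex, education category, and age within 3 years).

**BOLD model.** Subject time series are stationary multivariate Gaussian
draws whose covariance is the inverse of a constructed precision matrix.
This choice is deliberate: the downstream estimator (partial correlations
from the inverse sample covariance) is then exactly consistent, so
parameter recovery is a meaningful acceptance surface rather than a
modelling accident. Temporal smoothness is emulated by an AR(1) filter
x_t = φ x_{t−1} + √(1−φ²) ε_t with ε_t ~ N(0, Σ) and default φ = 0.3; this
preserves the stationary covariance (hence the planted partial
correlations) exactly while reducing the effective number of independent
volumes by roughly (1−φ)/(1+φ). The generator does **not** model
hemodynamics, scanner noise spectra, band-pass filtering, nuisance
regression, or spatial structure; conclusions from passing tests are about
the analysis pipeline, not about fMRI preprocessing.

**Defaults as study conditions.** 50 patients + 50 controls, 78 regions,
450 volumes, AR coefficient 0.3, motion-spike rate 0.02/volume, unilateral
contiguous lesions over 4 regions with overlap fractions uniform in
[0.3, 0.95] (patients only), and an 8-hub planted network.

**Planted-hub network.** `make_hub_recovery_network` designs its weight
template directly in partial-correlation space and sets the precision to
P = I − s·W with s = 0.9/λ_max(W); the implied partial-correlation matrix
is then exactly s·W, and the uniform scale s preserves every ordering the
quantile-based hub criteria use. The template gives each non-hub node a
structural role that can earn at most one of the four hubscore points:

- *heavy dyads* — highest non-hub strength, but peripheral (no shortest-
  path traffic, long paths) and triangle-closed (nonzero clustering);
- *bridges* — each the sole connector of two leaf nodes, hence high
  betweenness, but modest strength and mid-range paths;
- *leaves* — degree-1 nodes, the only zero-clustering nodes, with the
  longest paths and lowest strength;
- *fast lanes* — one strong edge into a hub, hence short paths, but low
  strength;
- *ring* — a weighted cycle attached to hubs; local cycle traffic keeps
  ring betweenness positive (avoiding a degenerate all-zero quantile) but
  far below bridge betweenness.

Planted hubs interconnect and attach to most of the network, earning
strength, betweenness and path-length points simultaneously. This
structure is what makes *exact* recovery of the planted hub set possible:
with 78 nodes, any top-20% criterion admits ~16 nodes, so ~8 non-hubs
always earn each single criterion point; recovery fails only if some
non-hub earns two, which the role separation rules out by construction. A
generic degree-skewed random network (`simulate_ground_truth_network`,
also provided) does not have this property — its strength and betweenness
extremes overlap — and is used where only a strength contrast is needed.
All weights carry ±3% multiplicative jitter so quantile thresholds never
sit on exact ties.

**Cognition generator.** Raw score = intercept + age·slope_age +
education·slope_edu + Σ coef·(graph metric) + N(0, σ), with defaults
intercept 50, slope_age −0.3 per year, slope_edu +2 per education
category, σ = 5, and a metric link of ∓40 × whole-brain clustering into
the proxy-IQ and executive tests (computed on each subject's true
lesion-masked network). Tests with a timed/error raw scale are stored
sign-flipped so the instrument orientation is realistic; the orientation
table is configuration.

**Seeding.** One master seed is split with numpy `SeedSequence.spawn` into
independent child seeds per subject (and per null-ensemble draw), so any
subject is reproducible in isolation and whole cohorts are byte-identical
across reruns.

## Connectome construction

Volumes are flagged when FD ≥ 0.5 mm, any |translation| ≥ 1.5 mm, or
DVARS exceeds its own mean + 3 sample standard deviations (n−1
denominator); flagged volumes are deleted, not interpolated. A scan fails
the quality gate when the scrubbed fraction strictly exceeds 0.2 (so
exactly 20% passes). Partial correlations come from the inverse sample
covariance; if inversion fails numerically, a Ledoit–Wolf shrinkage
covariance is substituted and the fallback recorded in the output
metadata. Edge weights are absolute values of the partial correlations.
The lesion rule is applied literally: edges between regions with overlap
fraction strictly greater than 0.5 and all other regions are zeroed;
edges *within* the affected set are retained. Floating nodes are regions
whose row is entirely zero after masking.

## Graph metrics

Connection length is 1/weight (absent edges are infinite). Distances use
Dijkstra; unreachable pairs are excluded from path-length averages (the
excluded fraction is reported) and contribute 0 to efficiency. Clustering
is the Onnela geometric-mean form with weights normalized by the
network-wide maximum; c_i = 0 below degree 2. Local efficiency is the
cube-root weighted variant: neighbour-pair terms (ŵ_ij ŵ_ih)^{1/3} / d_jh,
with d_jh the shortest path *within the neighbour subgraph* computed on
cube-rooted lengths. Betweenness is Brandes accumulation with fractional
counting of degenerate shortest paths, reported in unordered-pair counts.
Assortativity is the edge-weighted Pearson correlation of excess endpoint
strengths (s_i − w_ij); the nodal decomposition assigns each directed
edge's covariance contribution to its source node, making Σ_i a_i equal
the global coefficient to machine precision — a testable conservation law
standing in for a nodal assortativity definition the literature leaves
open. A perfectly regular graph has undefined (NaN) assortativity, never
silently 0. Whole-brain aggregates exclude floating nodes entirely, so
they equal the metrics of the graph with those nodes removed.

## Null normalization

"Equivalent random graphs" preserve the node count and the exact multiset
of connectivity values: each draw is a uniform permutation of the
upper-triangle weights (zeros included). Degree and strength sequences are
deliberately *not* preserved — the null asks what the weight distribution
alone implies. Observed metrics are divided by the per-metric (per-node,
positional) ensemble median; medians rather than means so single extreme
draws cannot distort the scaling. A null median of 0 flags the normalized
value as undefined rather than dividing. Default ensemble size is 1,000;
tests and the acceptance script use 50–200, where the median is already
stable to a few percent.

One consequence worth knowing: for *sparse* graphs (e.g. the zero-noise
synthetic connectome) most nodes' null clustering/betweenness medians are
0, so normalized hubscores are undefined there. The exact-recovery check
therefore scores raw metrics (quantile criteria are scale-free, so this
changes nothing about the ranking logic), while the noisy, dense-estimate
path uses the default normalized scores.

## Hub classification

Per subject, the four thresholds are linear-interpolation quantiles over
nodes with defined values (80th percentile for strength and betweenness,
20th for path length and clustering); ties at a threshold all qualify.
Floating nodes are excluded from the quantiles and cannot earn path or
betweenness points. Cohort labels use strict majorities over the reference
(control) subjects: hub ⇔ score ≥ 2 in > 50%, nonhub ⇔ score = 0 in
> 50%, else intermediate.

## Cognition

Normative models are per-test OLS regressions of (orientation-corrected)
raw score on age and numeric education (the 1–7 ordinal treated as
linear), fitted on controls only, with residual SD using an n−3
denominator. On the fitting sample, mean w is exactly 0 (OLS residual
property) and the SD of w is exactly 1 under the same n−3 convention. A
test whose control scores are an exact function of age and education has
no normative spread and is rejected rather than producing infinite
w-scores. Domains are unweighted means of member-test w-scores; the
test→domain map is configuration. Impairment: ≥ 2 w ≤ −1.5 or ≥ 1 w ≤
−2.0.

## Statistics

Mann–Whitney U is exact by enumeration for tie-free samples up to n = 20
per group, otherwise the tie-corrected normal approximation (measured null
rejection rate 0.0485 at α = 0.05, n = 50/50). Chi-square on 2×2 tables
is Pearson's without continuity correction (flag available); a zero margin
is undefined. The mixed-design ANOVA (pingouin) reports between, within
and interaction effects; when Mauchly's test rejects sphericity at p <
0.05 and the within factor has > 2 levels, within and interaction p-values
use Greenhouse–Geisser ε-adjusted degrees of freedom (ε = 1 exactly for
two levels). Partial eta squared is graded small < 0.060 ≤ moderate ≤
0.140 < large. Non-normal metric distributions (Shapiro–Wilk p < 0.05)
are natural-log transformed first, with a half-minimum offset when zeros
are present. Pearson correlation grids carry explicit Bonferroni family
sizes (4 for the whole-brain tests; the whole-brain × 6-domain grid uses
24). McNemar's test uses the exact binomial below 25 discordant pairs and
χ² = (b−c)²/(b+c) otherwise.

## Problem sizes and tolerances

Oracle-equivalence checks run on hundreds of random graphs of ≤ 12 nodes
(≤ 8 for exhaustive path enumeration), at 1e−10 for formula oracles and
1e−12 for Dijkstra-vs-Floyd–Warshall (the two algorithms sum identical
edge lengths in different orders, so agreement is to float associativity,
~4e−15 observed). Conservation laws hold to 1e−12. The noiseless hub
cohort uses 50 subjects; the noisy condition uses 20 subjects at 450
volumes with 50 null graphs per subject — chosen so the full verification
sweep completes in about a minute on one CPU while every stage still runs
at the 78-region scale. Type-I calibration uses 10,000 null replicates so
the Monte-Carlo standard error (~0.002) is small against the ±0.01
acceptance band. Slope-recovery checks average 10 independent 200-control
cohorts because a single cohort's education-slope standard error (~0.11
under the generator's noise) is as large as the ±0.1 recovery band.

## Known limitations

- The generator's Gaussian/AR(1) model omits physiological noise,
  drift and motion-signal coupling; scrubbing is exercised against clean
  injected spikes only.
- The weight-permutation null is the weakest "equivalent random graph"
  notion consistent with preserving the value distribution; strength- or
  topology-preserving nulls would give different normalized values and are
  intentionally out of scope.
- Education as a numeric predictor is a linearity assumption;
  categorical coding is possible but not the default.
- Exact hub recovery is a property of the purpose-built planted network;
  on generic random networks the four hubscore criteria necessarily admit
  non-planted nodes among their top-20% sets.
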