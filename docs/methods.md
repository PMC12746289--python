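# Methods

This note documents the statistical procedures `betascape` implements,
the choices made where conventions differ between tools, and what the
synthetic benchmark does and does not establish.

## Data model

A `CommunityTable` is a validated samples × features abundance matrix
(ASV counts, CPM gene profiles, or taxon-family counts) with a
normalization tag (`raw`, `rarefied`, `relative`, `cpm`). Rarefaction is
exact multivariate-hypergeometric subsampling to a common depth;
samples below depth are dropped with a logged warning rather than
raising, matching standard practice. Bray–Curtis dissimilarity
`D = Σ|x_i − x_j| / Σ(x_i + x_j)` is the default community metric.
Geographic distance defaults to great-circle (haversine, Earth radius
6371 km) so distance–decay slopes have per-km units; a `planar` flag
gives literal Euclidean distance in decimal degrees for strict
comparability with analyses that used raw coordinates. Shannon diversity
is reported in nats (configurable base), the dominant convention in
ecological software.

## Dispersion (homogenization) testing

The dissimilarity matrix is embedded by principal coordinates: Gower
double-centering of −D²/2 followed by an eigendecomposition. Bray–Curtis
matrices are generally non-Euclidean, so negative eigenvalues occur;
their axes are retained as "imaginary" coordinates and a sample's
squared distance to its group centroid is computed as the real-axis
squared distance minus the imaginary-axis squared distance. The rare
negative squared distances this can produce are clamped to zero and
logged (reference implementations differ between clamping and absolute
value; clamping guarantees a real result). Centroids are arithmetic
means in the embedded space.

Two grouping schemes are reported together: regional (groups = land
use, all replicate cores) and local (groups = site × land use, with the
per-sample distances pooled across sites within each land use before
comparison). The default comparison is the two-sided Wilcoxon rank-sum
test with tie correction; a PERMDISP-style permutation-F (labels
permuted on the distances) is available. The regional comparison uses
all replicate samples by default; note that replicate cores within a
plot are not independent, so when between-site structure is strong the
per-sample rank-sum test should be read descriptively and the
permutation test, or site-mean aggregation, preferred for strict
inference.

## Spatial statistics

**DDR.** Similarity (1 − D) is regressed on raw geographic distance by
OLS over all unordered within-group pairs, per land use ("linear
regression" on the untransformed axis; a log-distance variant is behind
a flag). Pair-level regression p-values are reported but
anti-conservative — pairs sharing a sample are not independent — so the
inferential surface for "is the AS slope steeper?" is a permutation test
that reshuffles land-use labels over samples and recomputes both slopes
(999 permutations by default).

**PCNM.** The truncation threshold is the longest edge of the minimum
spanning tree of the geographic distance matrix; larger distances are
replaced by 4× the threshold; positive-eigenvalue principal-coordinate
axes of the truncated matrix, normalized to unit norm, are the spatial
predictors. Moran's-I screening of individual eigenvectors is omitted:
positive-eigenvalue retention plus forward selection is the
pipeline's filter.

**Forward selection.** RDA on Hellinger-transformed counts (square root
of relative abundance — the standard transformation that makes
count RDA well behaved; the choice is recorded in output). At each step
the candidate with the largest partial F enters if a permutation test is
significant; the permutation statistic is the *maximum* partial F over
all remaining candidates, which corrects the best-of-k selection bias
(with a naive per-candidate test, a pure-noise candidate pool of size
five is "selected" from roughly a quarter of the time; with the max-F
test, at the nominal rate). Selection stops at p > α (default .05), when
the selection's adjusted R² reaches the global model's (the double
stopping rule), or when no candidate improves the criterion.

**Variation partitioning.** Adjusted R²
(`1 − (1 − R²)(n − 1)/(n − p − 1)`) for the environment-only,
spatial-only, and joint RDA models gives fractions a (pure
environmental) = joint − spatial, c (pure spatial) = joint − env,
b (shared) = env + spatial − joint, d (residual) = 1 − joint; the four
sum to one identically.

**PERMANOVA.** Classical partition of squared dissimilarities
(pseudo-F from among- vs within-group sums of d²/n), p by free label
permutation. A sequential (type-I) multi-term variant on the
Gower-centered matrix handles the two-factor main-effects case; the
interaction structure of a crossed design is not modelled.

## Assembly statistics

**Sloan neutral model.** N is fixed at the mean sample depth, the
detection limit at one read (1/N), and only the migration rate m is fit,
by bounded scalar least squares of observed occurrence frequency against
`1 − BetaCDF(1/N; Nmp, Nm(1−p))`. R² = 1 − SSE/SST can be negative for
strongly non-neutral data. Wilson score intervals (not the normal
approximation, which misbehaves near frequencies of 0/1) at the realized
sample count give the 95% envelope that partitions taxa into
above/within/below. Fits with fewer than 10 taxa at intermediate
frequency are rejected as unidentifiable. A joint (N, m) fit is not
attempted: at desk-scale sample sizes the two are poorly separable.

**Levins niche breadth.** `B_j = 1/Σ_i P_ij²` with `P_ij` the share of
taxon j's total abundance found in sample i; `Bcom` is the unweighted
mean over taxa by default (an occupancy-weighted flag exists; the
unweighted mean is the common convention).

**NST.** The null model (named "PF" in outputs) preserves each sample's
richness and depth: occupied taxa are drawn without replacement with
probability proportional to occupancy frequency, each receives one read,
and the remaining reads are multinomial with probability proportional to
the group's mean relative abundances. The expectation `E_ij` is the mean
null Bray–Curtis over `n_null` draws (default 1000; reducible from the
CLI), and the normalized index is `NST_ij = D_ij/E_ij` when
`D_ij ≤ E_ij`, else `(1 − D_ij)/(1 − E_ij)` — equal to 1 when observed
matches the null exactly and falling toward 0 as the observation departs
from it in either direction, with 50% as the conventional
deterministic/stochastic boundary. Pairs with degenerate expectation
(E = 0 or 1) are excluded with a warning. The null model is pluggable
and its name, draw count, and RNG seed appear in every output.

## Networks

Pearson correlations are computed on relative abundances after the
standard filter (mean relative abundance > 0.01%, prevalence ≥ 25%),
and edges kept at |r| > 0.7 and raw P < .01 — both correlation signs are
retained (with the sign stored), and no multiple-testing correction is
applied by default because the stated filter is a raw-P threshold; a
positive-only mode and a BH-corrected mode are flags. Modules come from
greedy modularity maximization (deterministic; the algorithm name is
recorded). Zi is the within-module degree z-score (population SD;
zero-SD modules get Zi = 0, logged) and Pi = 1 − Σ_s (k_is/k_i)²; roles
use the 2.5 / 0.62 thresholds (module hub, connector, network hub when
both exceeded, else peripheral). Ranking-based "network hubs" are the
top 5% (ceiling) of nodes by the mean of z-scored degree and betweenness
centrality; the union with Zi/Pi module hubs forms the hub set used for
targeted removal.

Stability metrics, since figure-level definitions vary across the
literature: robustness at removal fraction f is the fraction of
*remaining* nodes that keep at least one link (largest-component
fraction is available by flag), averaged over random removal orders or
computed on the hub-score order; vulnerability is
`max_i (Eff − Eff_−i)/Eff` with Eff the global efficiency of the largest
component; natural connectivity is `ln((1/n) Σ e^{λ_i})` over adjacency
eigenvalues, tracked along the removal order.

## Y-A-S profiling

Category shares are computed over mapped genes only — share of
CPM-normalized abundance per category divided by total mapped abundance
— with coverage (mapped fraction) reported, because trait maps cover a
minority of genes and an all-genes denominator would conflate coverage
with biology. Shares are invariant to per-sample rescaling by
construction. The gene → {Y, A, S} map is an input contract; the
upstream HMM search that produces it is out of scope. Environmental
screens report per-feature Pearson or Spearman correlations with BH
q-values by default (raw-p mode by flag; both logged).

## The synthetic generator

`simulate_paired_design` builds per-feature log intensities

    log λ = log(metacommunity) + site_effect(site, land_use)
            + landuse_effect − s·(env − optimum)² + N(0, δ_land_use)

and draws multinomial counts at fixed depth. The metacommunity is
lognormal (σ = 1.5). Site effects per land use come from a Gaussian
process along the transect whose covariance is an independent-site
nugget (SD 5.0) plus a spatially structured exponential term (SD 2.0,
range 250 km), scaled by a per-site lognormal distinctiveness multiplier
(SD 0.5) shared by the two paired plots of a site. The nugget + multiplier
give sites heterogeneous distinctiveness — without it, Bray–Curtis
saturates at nearly equal between-site distances and the regional
dispersion test becomes pathologically sensitive to within-plot noise —
while the structured term supplies the distance decay that the DDR,
PCNM, and variation-partitioning analyses measure. The spatial
autocorrelation range is a free parameter rather than a fixed constant.
Defaults (27 sites × 2 land uses × 5 replicates over 900 km; depth 2000;
δ_AS = 0.3 < δ_NS = 1.0) encode the survey layout and the
local-scale-homogenization regime. Environmental covariates (pH, TC) are
linear in latitude plus noise, mirroring the role of pH and carbon as
dominant drivers in temperate soil surveys. Sites lie on a 1-D transect
by default (the sampling spans of such surveys are roughly linear); a
2-D option exists.

`simulate_neutral` draws each sample's latent relative abundances from a
Dirichlet with concentration N·m·p — marginally the
Beta(Nmp, Nm(1−p)) stationary approximation the Sloan fit assumes — and
allocates N reads to the taxa above the 1/N detection limit (one
guaranteed read each plus a multinomial remainder). The thresholded
allocation makes a taxon's occurrence frequency *exactly* the beta
formula; with plain multinomial sampling the detection step is smoothed
(P(detect) = E[1 − (1 − π)^N]) and the fitted migration rate is biased
upward by roughly 25%, which would test the approximation error rather
than the estimator.

## Calibration and test scale

Null calibration of the dispersion, PERMANOVA, and DDR slope-difference
tests is assessed under the structure-free null — equal within-plot
noise, no site, spatial, or land-use effects, no selection — where all
samples are exchangeable and all three p-values are Uniform(0,1)
(Kolmogorov distance ≤ 0.05 over 500 simulations in the test suite).
With between-site random effects present, replicate cores are clustered
and neither the rank-sum test nor free permutation is exactly
calibrated; this is a property of the tests, not of the implementation,
and is why the equal-noise scenario in the pattern tests is checked for
pattern direction rather than exact size.

Test and acceptance runs use scaled-down designs chosen once: 10–12
sites × 3 replicates, 100–150 features, depth 500–1000 for the
dispersion/pattern/null suites; 100 samples × 300 taxa at depth 1000 for
neutral-model recovery; 30 samples × 200 taxa at depth 2000 with 200
null draws for stochasticity-ratio checks. The generator validates the
*machinery* — estimator consistency, test calibration, threshold
behavior, invariances. It does not emulate phylogenetic structure,
compositional correlation between taxa, read-level error, or the
taxon-richness (tens of thousands of ASVs) of real surveys, so passing
tests certify the statistics, not any empirical claim about a particular
soil system.

## Known limitations

- The NST implementation uses the single named null model; phylogenetic
  null models (βNTI-style) are out of scope.
- PERMANOVA multi-term support is sequential main effects only.
- Rank-sum dispersion comparisons on replicated designs inherit the
  pseudo-replication caveat above.
- Family-level input tables are accepted as either counts or relative
  abundances (both are valid Bray–Curtis inputs); kingdom-wise analyses
  require a feature → kingdom map from the caller.
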