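# Methods

This note documents the statistical models implemented in `taxadecay`, the
choices made where conventions genuinely diverge, what the synthetic data
generator does and does not emulate, and the numerical details a user would
need to reproduce or audit a run.

## The distance-decay model

Community similarity is modelled as a power law of geographic distance,

    S(d) = c · d^(−2z),

where `S = 1 − BC` is one minus the Bray-Curtis dissimilarity and `z` is the
spatial turnover exponent. On log-log axes the model is linear, and `z` is
estimated as

    z = −slope / 2

from an ordinary least-squares fit of `ln S` on `ln d` over all usable sample
pairs. `z` is invariant to the logarithm base (slopes of log-log fits are),
and to rescaling all distances by a constant (only the intercept moves);
natural logarithms are used throughout. Pairs with `S ≤ 0` (completely
disjoint communities) or `d = 0` (coincident plots) carry no log-log
information; they are excluded and counted in `n_dropped` rather than offset
by a pseudo-value, which would inject an arbitrary constant into the slope.

**Bootstrap significance.** The slope is tested against zero by resampling
the vectorized pair list with replacement `B` times (default 9,999),
refitting the slope in each replicate, and applying a one-sample t test to
the replicate slopes:

    t = boot_mean / (boot_sd / √B),   df = B − 1.

Two properties of this form deserve emphasis. First, `|t|` grows as `√B`, so
at `B = 9,999` even modest decays produce `|t|` in the hundreds or thousands;
the scale-free ratio `boot_mean / boot_sd` is reported alongside as a
B-independent effect measure. Second, sample pairs are not independent (each
sample participates in `n − 1` pairs), so pair-level resampling understates
the true sampling variability. A sample-level bootstrap (resampling rows of
both matrices jointly) is available via `unit="sample"` for users who prefer
inference that respects the dependence structure; pair-level resampling is
the default because it is the only reading consistent with the magnitude of
published test statistics for this test form. On noiseless data every
replicate refits the identical slope; this degenerate case is flagged, `t`
reported as signed infinity and `p` as the resolution floor `1/(B+1)`.

## Regression on distance matrices (MRM)

Distance matrices enter regression through their vectorized strict lower
triangles (row-major, `i < j`). Coefficients are ordinary least squares;
inference is by a Mantel-style permutation null in which the *response*
matrix has its rows and columns permuted jointly — permuting the response
preserves the internal dependence of the predictors and is the canonical
scheme of MRM implementations. P-values use the add-one estimator
`p = (#{permuted ≥ observed} + 1) / (B + 1)`, which counts the identity
permutation and bounds `p ∈ [1/(B+1), 1]`. Coefficient tests are two-sided on
`|coefficient|` by default (one-sided available). Scalar covariates
(elevation, PC scores, plant diversity) enter as absolute-difference matrices
`|x_i − x_j|`, the only construction that makes a per-sample scalar
commensurable with distance predictors. For single-predictor fits the
descriptive F statistic `F = (n_pairs − 2) R² / (1 − R²)` is reported; since
pairs are dependent its nominal F distribution does not apply, and
significance always comes from the permutation p.

## Ordination

**PCA** centres the (optionally log-transformed) table, scales variables to
unit variance by default (environmental variables mix units — pH against
precipitation), and decomposes by SVD. Eigenvalues are component variances;
variance fractions sum to one over all axes. Constant columns are an error
under standardization rather than a silent drop.

**Correspondence analysis** decomposes the chi-square standardised residuals
`(P − rcᵀ) / √(rcᵀ)` of the relative-frequency table by SVD; eigenvalues are
squared singular values (summing to the total inertia) and row scores are
reported in principal coordinates, whose per-axis weighted variance equals
the eigenvalue.

**DCA.** CA of a single strong gradient produces the arch effect: axis 2 is
an artifactual quadratic in axis 1. Detrending follows Hill's
method-of-segments: axis 1 is the plain CA axis; each later axis is extracted
by reciprocal averaging in which every iteration first removes, within each
of `n_segments` (default 26) equal-count segments of every previously
extracted axis, the weighted segment mean of the trial scores. Iteration
stops at score convergence (tolerance 1e-10) or 30 iterations. The nonlinear
axis-rescaling half of classic DECORANA is deliberately not implemented:
the analyses here use only score configurations (cluster structure), which
rescaling does not alter structurally; axis units therefore differ from
DECORANA's half-change units. Axes beyond the table rank, or collapsed to
zero by detrending, are flagged in `notes` rather than silently filled.

## Community preprocessing

Singleton OTUs are defined globally — pooled count across all samples equal
to one — the standard convention after pooled OTU clustering; per-sample
singletons with larger pooled totals are retained. Rarefaction draws a single
multivariate hypergeometric subsample per sample (exact without-replacement
draw via `numpy`) at a default depth of 20,000 reads; samples below depth are
dropped and reported, never partially kept. A single seeded draw (rather than
an average over draws) is the default because downstream dissimilarities are
computed on realized counts; the draw is deterministic given the seed.
Default order is singleton removal, then rarefaction. Shannon diversity
`H = −Σ p ln p` is reported in nats; observed-richness bounds (`0 ≤ H ≤ ln
richness`) are enforced by construction.

## Geographic distance

Great-circle (haversine) distance on a sphere of radius 6371.0 km.  At the
scale of a field transect spanning ~17° of latitude this is within ~0.5% of
ellipsoidal distance and requires no datum choice. Plot-to-plot distances are
the default; site-centroid distances can be had by collapsing the metadata
before building the matrix.

## Functional gene array processing

Three fixed steps, in a fixed order:

1. **Detection filter** — within each site group of 10 samples, a probe
   detected (non-missing, positive) in fewer than 6 of them is masked to
   missing throughout that group. Groups of a different size get a
   proportionally rescaled threshold `ceil(6/10 · n)` and a warning. Probes
   left without any detection are dropped.
2. **Mean normalisation** — each spot is divided by its sample total and
   multiplied by the across-sample mean total, removing per-sample scaling
   artifacts (labelling/hybridisation efficiency) while preserving intensity
   units; every sample ends at exactly the mean total.
3. **Category sums** — detected intensities are summed per sample within
   each of the 18 registered gene categories (3 carbon fixation, 7 carbon
   degradation, 5 nitrogen, 3 phosphorus); missing spots contribute zero but
   are never converted to measured zeros.

The order is material (filtering first means normalisation totals reflect
only reliably detected signal) and is asserted by test. Undetected spots are
a distinct missing marker end to end: the filter counts detections, the
normaliser skips them. The filter operates at probe level; a gene-level
variant (aggregating probes first) would require a probe→gene map and is out
of scope for v1.

## Synthetic data generator

The generator emulates the *statistical structure* the analyses assume, not
any real dataset: 24 sites × 10 plots along a ~23–40°N latitudinal gradient
(~108–112°E), ~2,000 OTUs at 26,026–93,786 reads per plot, a 540-probe
functional array over the 18 categories, and environmental variables from a
low-rank latent-factor model in which factor 1 tracks latitude.

Ground-truth decay is controlled two ways, deliberately:

* **Similarity-level** simulation draws pairwise similarities directly from
  `S = c·d^(−2z)` with optional lognormal noise — an exact harness for
  estimator unit tests, at the price of not being generated by any community
  mechanism.
* **Count-level** simulation gives each OTU a Gaussian niche along latitude
  (centre uniform over an extended gradient, width `niche_width /
  (turnover_rate × phylum multiplier)`) and draws multinomial counts. Here
  the realized exponent is *measured*, not set — count-level data cannot hit
  an arbitrary target z exactly — so tests assert ordering and limit
  properties (zero turnover → flat; doubled turnover → steeper; a phylum
  with a larger multiplier → larger realized z). Default phylum multipliers
  (1.21, 1.16, 0.93, 0.84 for the four dominant phyla) stagger the realized
  exponents in a fixed order.

The functional array generator holds true category means constant across
sites (functional convergence) by default; `geochip_site_effect_sd > 0`
breaks convergence with per-site, per-category lognormal effects, half of
which follow the latitudinal gradient — so divergence, when simulated, is
detectable both as site clustering and as spatial signal. Per-sample
multiplicative lognormal scaling (sd 0.3), per-spot lognormal noise (sd
0.15) and independent detection dropout (10%) emulate the array's main
artifacts.

What the generator does **not** emulate: real taxonomic composition and
richness distributions, phylogenetic structure, spatial autocorrelation of
environment beyond the single latitude factor, correlated (non-independent)
dropout, or probe cross-hybridisation. Passing tests therefore demonstrate
that the estimators recover known structure under the model's assumptions;
they say nothing about robustness to real-data pathologies outside those
assumptions.

## Problem sizes and replication defaults

Library defaults match survey-scale analysis: 9,999 bootstrap replicates and
9,999 permutations. The orchestrated end-to-end runs used by the test suite
and the acceptance script use `AnalysisConfig.fast()` (B = 199 bootstrap, 99
permutations) and, where many seeds are replicated, the reduced
`scaled_config()` design (8 sites × 5 plots, 300 OTUs, depth 3,000–6,000);
estimates are identical in expectation and the p-value resolution floor
(1/200, 1/100) is ample for the qualitative contrasts asserted. The
acceptance script runs the full 240-plot, 2,000-OTU design with B = 999
bootstrap and 199 permutations.

## Degenerate inputs and tie-breaks

* All-zero count rows are an error for Shannon and Bray-Curtis (named
  sample), not a silent NaN.
* Distance matrices are validated (symmetry to 1e-12, zero diagonal,
  nonnegativity, Bray-Curtis ≤ 1) at construction and symmetrised exactly so
  vectorization is well defined.
* Equal-count segment splits in DCA use a stable argsort, making detrending
  deterministic under ties.
* The bootstrap degenerate case (`boot_sd ≤ 1e-12·(1+|mean|)`) is flagged
  rather than producing a spurious astronomically large t.
* Collinear or zero-variance predictors are an error naming the offending
  matrix, before any permutation work is spent.

## Known limitations

* DCA lacks nonlinear rescaling; axis units are not half-change units.
* Pair-level bootstrap inference ignores pairwise dependence (see above);
  the sample-level alternative is provided but slower.
* The taxa-area interpretation of z rests on the distance-decay regression
  alone; no area-based (nested quadrat) estimator is implemented.
* BIOM support covers the JSON 1.0 dialect only (dense and sparse), not
  BIOM 2.x HDF5.
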