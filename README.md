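# taxadecay

Biogeography statistics for soil microbial community surveys: distance-decay
exponent estimation with bootstrap significance, regression on distance
matrices with permutation tests, PCA/CA/DCA ordination, diversity and
rarefaction, functional gene array (GeoChip-style) signal processing, and a
study-shaped synthetic data generator so every stage can be exercised
against known ground truth.

## Who this is for

Microbial ecologists analysing amplicon surveys along environmental
gradients — an OTU count table, a sample metadata sheet with GPS
coordinates and environmental covariates, and optionally a functional gene
array — who want the standard biogeography toolkit (spatial turnover
exponents, Mantel-style matrix regression, detrended ordination) as tested,
scriptable Python instead of a chain of one-off scripts.

## The statistics at the core

**Distance decay.** Community similarity `S = 1 − BC` (Bray-Curtis) is
modelled as a power law of geographic distance, `S = c·d^(−2z)`. The
turnover exponent is `z = −slope/2` from an OLS fit of `ln S` on `ln d`
over sample pairs; significance comes from a one-sample t test on bootstrap
replicates of the slope (`t = mean/(sd/√B)`, pair-level resampling,
B = 9,999 by default).

**MRM.** Regression of a distance matrix on distance-matrix predictors via
vectorized lower triangles, with Mantel-style joint row/column permutation
of the response; `p = (#{perm ≥ obs} + 1)/(B + 1)`. Scalar covariates enter
as `|x_i − x_j|` matrices.

**Ordination.** PCA (SVD of the standardized table), correspondence
analysis (SVD of chi-square standardized residuals), and DCA (Hill's
detrending-by-segments, 26 segments, no nonlinear rescaling).

**Functional array processing.** Three fixed steps: mask probes detected in
fewer than 6 of a site's 10 samples, rescale each sample to the mean total
intensity, sum detected intensities within 18 registered gene categories
(carbon fixation/degradation, nitrogen, phosphorus cycling).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a reduced survey (8 sites × 5 plots, 300 OTUs), preprocess, and
estimate the spatial turnover exponent:

```python
import warnings; warnings.filterwarnings("ignore")
from taxadecay import *
from taxadecay.synthetic import scaled_config, study_preset

otu, frame, signals = study_preset(seed=7, config=scaled_config())

otu2, _ = rarefy(remove_singletons(otu), depth=3000, seed=7)
frame2 = frame.select_samples(otu2.sample_ids)
geo = haversine_matrix(frame2)
bc = bray_curtis(otu2)

fit = fit_distance_decay(geo, bc)
print(f"z = {fit.z:.4f}  slope = {fit.slope:.4f}  "
      f"r2 = {fit.r_squared:.3f}  pairs = {fit.n_pairs}")

boot = bootstrap_decay_test(geo, bc, n_boot=999, seed=7)
print(f"t = {boot.t_statistic:.1f}  p = {boot.p_value:.3g}")

res = single_matrix_regression(bc, geo, n_permutations=999, seed=7)
print(f"MRM spatial: R2 = {res.r_squared:.3f}  p = {res.p_r_squared:.3g}")
```

prints

```
z = 0.0616  slope = -0.1231  r2 = 0.352  pairs = 780
t = -674.6  p = 0.001
MRM spatial: R2 = 0.980  p = 0.001
```

Reading this: similarity between plots falls off as `d^(−2·0.0616)` — a
measurable spatial turnover (`z > 0`) whose log-log regression explains 35%
of pair-level variance; the bootstrap slope is overwhelmingly non-zero (the
t statistic scales as √B, hence its magnitude; p is at the floor `1/(B+1)`),
and spatial distance alone accounts for 98% of the variance in community
dissimilarity under the permutation test. The same API runs on real tables
read with `read_otu_table` / `read_sample_frame` / `read_signal_table`.

The command line mirrors the library:

```sh
taxadecay simulate --preset small --seed 3 --out data/
taxadecay decay --otu data/otu_table.tsv --meta data/metadata.tsv \
    --phyla Acidobacteria,Proteobacteria --n-boot 9999 --seed 17
taxadecay geochip --signals data/signals.tsv --meta data/metadata.tsv --log
taxadecay run-endemism --otu data/otu_table.tsv --meta data/metadata.tsv \
    --depth 3000 --out report/
```

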