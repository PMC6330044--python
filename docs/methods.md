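# Methods

## Scope and model of the data

The package treats a species' Grinellian (climatic) niche as a set of
continuous univariate traits — one per bioclimatic variable — measured as the
suitability-weighted mean of the variable over the species' modeled
distribution (the PNO-weighted mean). All phylogenetic analyses assume a
rooted, ultrametric, time-calibrated tree; branch lengths are in consistent
time units (the docs use MY). Habitat-suitability surfaces are consumed as
given (any bounded [0, 1] output such as MaxEnt cloglog); fitting the niche
models themselves is out of scope, as are phylogeny inference and divergence
dating.

## Phylogenetic covariance and model transforms

Under Brownian motion, trait covariance among tips is `σ²C` with
`C_ij` the shared root-to-MRCA path length. The four trait models are
implemented as transforms of `C` (`trees.transform_vcv`):

- **λ** multiplies off-diagonals (diagonal unchanged), `λ ∈ [0, 1]`;
- **δ** raises every entry to `δ > 0`. No tree-height rescaling is applied:
  a constant rescale of `C` is absorbed exactly into the ML rate `σ̂²` and
  leaves every likelihood and likelihood difference unchanged, so results
  agree with either convention of the literature;
- **EB** maps `t → (e^{rt} − 1)/r` with decay `r ≤ 0` (identity at `r = 0`);
- **OU** uses the root-conditioned covariance
  `C'_ij = e^{−2α(T−t_ij)}(1 − e^{−2αt_ij})/(2α)` on an ultrametric tree of
  depth `T`; the BM matrix is its `α → 0` limit. Note that `σ²` then scales
  `C'`, so the stationary variance is `σ²/(2α)`.

For every model, the root state `z₀` and rate `σ²` are profiled in closed
form by GLS; `σ̂²` uses the pure-ML `1/n` denominator so log-likelihoods are
comparable across models and match the likelihood-ratio machinery. Shape
parameters are optimized deterministically: a 21-point grid plus bounded
refinement for λ (tolerance 1e−8), and a fixed 5-point start grid with
bounded quasi-Newton refinement for α, r, δ. Default bounds are
`α ∈ [1e−8, 50/T]`, `r ∈ [−10/T, 0]`, `δ ∈ (1e−3, 3]`; a boundary-pinned
estimate (δ̂ = 3 is common on real data) is flagged, not an error. The
"white noise" model is deliberately absent — it is indistinguishable from OU
with very strong attraction and adds nothing to the comparison.

AICc uses `n` = number of tips carrying trait data, reported explicitly in
all outputs. ΔAICc categories follow the fixed thresholds 2 / 7 / 10.
Multi-optima OU with reversible-jump MCMC is a documented stub
(`evomodels.fit_multi_optimum_ou`); single-optimum OU is the supported model.

## Phylogenetic signal

Blomberg's K is the variance-ratio statistic normalized by its BM
expectation; the permutation test shuffles tip labels and counts permutations
whose phylogenetic MSE is ≤ the observed (signal lowers the MSE), observed
included, so p ∈ (0, 1] and is never exactly 0. Pagel's λ is searched on
[0, 1]; the LRT against λ = 0 uses the χ²₁ upper tail. Both statistics were
verified against an independent reference implementation
(phytools `phylosig`) to 5–6 significant digits on a frozen fixture, as was
the phylogenetic PCA (phytools `phyl.pca`, covariance mode) and the BM
ancestral-state estimator (ape `ace`).

## Overlap and the age–range correlation

Suitability surfaces are normalized to probability distributions over the
cells valid in *all* compared species, then `D = 1 − ½Σ|p−q|` and
`I = 1 − ½Σ(√p−√q)²`; `I ≥ D` always. ARC aggregates overlap at each
internal node by nested averaging — each daughter clade contributes ½
regardless of size, giving cross-pair weights `(½)^d` with `d` the count of
intervening internal nodes — and regresses node overlap on node age (OLS,
overlap as response; the regression direction is stated in the output since
the field's phrasing is ambiguous). The null jointly permutes rows and
columns of the overlap matrix (preserving exchangeability); two-tailed
p-values include the observed statistic. Warren's `I` is the default ARC
statistic; `D` is available.

## PNO profiles and ancestral tolerances

A PNO profile evaluates the climate variable at `n_bins` equally spaced
points spanning the layer's valid range (default 50, the convention of the
reference implementation) and assigns each cell's suitability to the nearest
evaluation point, normalizing to unit mass. Per variable, all species share
one bin grid (global min/max) so profiles are comparable and overlayable.
The species trait value for downstream analyses is the profile's weighted
mean; a raw occurrence-mean alternative exists
(`extract_values` + averaging) but the weighted mean is the default.

Ancestral tolerances: each of `n_iter` (default 1000) iterations draws one
climate value per species from its PNO and applies the GLS/BM
ancestral-state operator (a precomputed linear map, so the whole Monte Carlo
is one matrix product); nodes are summarized by mean and 80% central
interval, tips by their own PNO mean and 80% central density.

## Disparity through time and MDI

Disparity is the mean squared pairwise difference (equivalently twice the
sample variance); relative disparity divides by the whole-tree disparity, so
DTT is invariant to affine trait changes. The curve starts at (0, 1) for the
root and adds one point per internal-node event (oldest first), valued at
the mean relative disparity of every lineage crossing the tree immediately
after that event, single tips contributing 0. The BM null simulates
`n_sim` datasets at the ML rate estimated from the data; the envelope is the
pointwise CI (default 95%). MDI integrates observed − null *median* by
trapezoid over relative time up to the last internal-node event (the median
is the robust default; the mean-centred value is also reported). Clade-level
MDI refits the subtree extracted at the clade's MRCA and re-estimates the
rate from the subset.

## Partial ROC

Suitability values are discretized to 100 threshold classes (the bin count
is a documented choice; published tools do not state theirs). For descending
thresholds this yields a monotone curve of sensitivity against proportion of
area predicted present. The partial AUC is integrated (trapezoid, with the
crossing point interpolated) over the region where sensitivity ≥ 1 − E
(default E = 0.05) and divided by the chance-diagonal area over the same
region. Each of `n_boot` (default 1000) bootstrap replicates resamples
`boot_frac` (default 50%) of the test points with replacement; significance
is a one-sided Z-test on the replicate ratios (the bootstrap proportion of
ratios ≤ 1 is reported alongside). A constant surface yields ratio exactly 1.

## Data preparation

Occurrence thinning enforces a minimum great-circle separation (haversine on
a 6371-km sphere, default 0.5 km) and at most one record per raster cell;
removal is randomized under the seed, the two passes can run in either order
(distance-first by default), and the operation is idempotent. Layer pruning
is a greedy scan in a user-supplied priority order (default: input order,
so ecologically preferred layers should be listed first): a layer is kept
iff its Pearson |r| over jointly valid cells with every already-kept layer
is below the threshold (default 0.75).

## Synthetic data

The generator emulates the study design the pipeline targets: a
crown-conditioned pure-birth tree rescaled to a chosen depth (default 20
species, 10 MY); smooth climate layers (planar gradient of unit amplitude
plus a Gaussian random field smoothed at σ = 5 cells, amplitude 0.2, on a
100 × 100 grid — enough structure for correlation pruning and extraction
tests without real spatial autocorrelation); per-species Gaussian niche
responses whose optima evolve on the tree under any of the four models and
are mapped affinely into the central 60% of the layer range (affine, so the
optima remain draws from the same model class); breadth τ = 0.15 of the
layer range; and 200 suitability-proportional, within-cell-jittered
occurrence points per species. Everything derives from one seed via spawned
sub-seeds, so scenarios are byte-reproducible.

What passing on synthetic data does **not** show: real bioclim layers are
strongly spatially autocorrelated and cross-correlated, real occurrence data
carry sampling bias, and real suitability surfaces are not Gaussian in any
single variable — so calibration and recovery results here demonstrate
correctness of the statistics, not field-data performance.

## Problem sizes and determinism

Stochastic defaults (1000 permutations / bootstraps / simulations / MC
iterations, 95% envelopes, 80% tolerance density) follow standard practice
and are all exposed in `RunConfig`. The test suite scales Monte-Carlo
studies to the smallest sizes that keep the checked quantities stable
(e.g. 500 simulations for signal calibration, 50 runs × 200 null simulations
for MDI centering, 15 scenario replicates for end-to-end recovery). Every
stochastic routine takes a seed; the pipeline derives independent per-stage
sub-seeds by hashing stage names, so any stage can be reproduced in
isolation.

## Known limitations

- λ is bounded at 1 (some implementations allow λ slightly above 1 when the
  tree permits); estimates at 0 are reported as exact zeros.
- OU fitting assumes an ultrametric tree and a root at the optimum;
  non-ultrametric input is rejected where ages are required.
- GeoTIFF rasters are not read; use ESRI ASCII grids.
- The ARC permutation null treats species as exchangeable; phylogenetic
  pseudo-replication in the overlap matrix is only partly accounted for.
- MDI integrates to the last speciation event, not the present; curves for
  trees with many near-simultaneous events contain duplicate time points
  (zero-width trapezoids, harmless).
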