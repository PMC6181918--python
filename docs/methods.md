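# Methods

## Input model and quality filters

The unit of data is a localization table: `(frame, x_nm, y_nm, photons,
precision_nm)` per detected appearance of a blinking fluorophore.
Upstream peak fitting (turning camera frames into localizations) is out of
scope; the canonical CSV schema plus a dialect layer (e.g. ThunderSTORM
headers, micron-to-nm scaling) is the entry point.

Three filters run in a fixed order, each appending one entry to the table's
audit log:

1. **Photon cut** (default ≥ 700 photons): removes dim, poorly localized
   detections. Inclusive at the threshold.
2. **Precision percentile cut** (default 98th percentile): discards the
   worst 2% of precisions. The threshold is the linear-interpolation
   quantile of the *input* table — a self-referential cut, applied per
   acquisition (whether the original workflow applied it per coverslip or
   per ROI is not determinable; per acquisition is the conservative
   reading).
3. **Density filter** (default 70 nm radius, 50 counts): removes
   localizations with more than 50 neighbors within 70 nm, an artifact
   signature (e.g. fluorescent debris) far above biological cluster
   densities (a 3-molecule cluster with 3× blinking contributes ~9
   localizations). Neighbor counts are computed once on the input and all
   removals applied simultaneously; whether the original filter removed
   single localizations or whole regions is ambiguous, so per-localization
   removal is used with both parameters exposed.

Binarization floors positions onto a square grid (default 1.6 nm). Multiple
localizations in one pixel collapse to a single on-pixel; the collision
loss fraction is reported and is ~0.5% on simulated 360 locs/µm² data
(the 1.6 nm default was chosen in the source workflow to keep this ≲1%).

## Density quantification

Square ROIs (default 20 µm², half-open membership so tiles partition
points) are placed on a grid over the signal mask, keeping tiles with ≥80%
coverage, or supplied explicitly. Detected density is

    density = n_localizations / (α · area)   [molecules/µm²],

with α the mean appearances per label. The pipeline counts on-pixels of the
binarized ROI, folding the small collision loss into the estimate.

**α estimation.** On a sparse control (molecules ≫ grouping scale apart,
~4 molecules/µm²), localizations are grouped by spatiotemporal single
linkage: distance ≤ group radius AND frame gap ≤ maximum dark time,
transitively. α is the mean group size. Two defaults matter:

- *Group radius = 4× mean precision.* Two appearances of one molecule are
  separated by a Rayleigh(√2 σ) distance; a 2σ radius would cut that
  distribution at its ~63rd percentile and fragment roughly a third of
  two-appearance molecules (simulations recover λ̂ ≈ 2.1 instead of 3),
  while 4σ keeps >98% of same-molecule pairs linked and recovers λ̂ ≈ 3.00.
- *Maximum dark time = 250 frames* (2.5 s at 10 ms exposure). The value is
  not fixed by the source workflow; it is a config parameter.

Because a molecule with zero appearances is unobservable, group sizes
follow a zero-truncated Poisson; the estimator optionally inverts
m = λ/(1−e^(−λ)) to report the underlying Poisson mean (for λ = 3 the
observed mean is 3.157).

**Split-robustness test.** Per study unit, ROI densities are shuffled with
a seeded RNG, split into ⌈n/2⌉ vs the rest, and compared by a one-tailed
Welch t-test (direction: first group mean greater — arbitrary under the
null). Homogeneous ROI sets give p ≥ 0.1 for ~90% of splits by
construction (p is uniform under the null); all-equal degenerate inputs
report p = 1 with a warning.

## Pair correlation and the composite fit

g(r) is estimated on the binary image as
radially averaged [FFT-autocorr(image) / FFT-autocorr(mask)] / ρ_loc²,
with the mask autocorrelation evaluated analytically for full rectangular
supports and by FFT otherwise; the zero-lag (self-pair) term is excluded.
Radial bins are 5 nm wide to 500 nm — at least three bins below any
plausible cluster radius (17–40 nm). Correctness is pinned by an
independent O(n²) pair-counting oracle in the test suite: both estimators
agree bin-wise to well within 5% on random and clustered instances.

The measured curve is fit (bounded nonlinear least squares, A ∈ [0, 10³],
ξ ∈ [1, 500] nm, start A = g(first bin)−1, ξ = 30 nm) with

    g_meas(r) = 1 + g_stoch(r) + [A e^(−r/ξ)] ⊛ G,

where g_stoch(r) = e^(−r²/4σ̄²)/(4πσ̄²ρ_mol) is the blinking
self-correlation of a label localized with mean precision σ̄,
ρ_mol = ρ_loc/α, and G is the normalized Gaussian pair-resolution kernel of
width √2 σ̄ (the convolution is evaluated by Bessel-I₀ quadrature).
Residuals are weighted by √(per-bin pair count), the statistical weighting
for a count-based estimator. Config alternatives: skip the convolution, or
exclude r < r_min (default 25 nm) instead of modeling the blinking peak.

Derived quantities:

- **Molecules per cluster**: n = 1 + 2πAξ²ρ_mol — one reference protein
  plus the integrated excess correlation ρ_mol∫(g−1)d²r. Because
  convolution with a normalized kernel preserves this integral, n is robust
  to the resolution broadening; on simulated data it recovers the
  generative occupancy mean (~3.2–3.35 vs a generative 3.16 for the
  BT-474-like preset; the small excess comes from the exponential's shape
  mismatch to the disc-overlap correlation).
- **Clustered verdict**: the exponential model must beat the flat (A = 0)
  model by small-sample-corrected AIC, the 95% CI of A (Gauss–Newton
  covariance) must exclude zero, and ξ must fall in [5, 200] nm. Random
  patterns (monomer simulations) are classified `random`; the clustered
  presets are detected in ≳95% of ROIs.

**Known limitation — ξ vs disc radius.** The simulator places molecules
uniformly on discs of radius R. The pair correlation of such clusters is
the disc self-overlap profile, whose least-squares exponential decay length
is ≈0.55·R, so the fitted ξ systematically underestimates the generative
disc radius (ξ̂ ≈ 13 nm for R = 24 nm). Dropping the resolution
deconvolution would inflate ξ̂ to ≈R, but only by absorbing the σ̄
broadening, and it overestimates molecules per cluster by ~25% — the
composite fit is kept as the default because it recovers the physically
meaningful occupancy integral. "Cluster radius" in fitted output therefore
means the exponential correlation length, not the disc radius; the two
coincide only for cluster shapes whose correlation is near-exponential.

## Cluster occupancy

For ROIs with a `clustered` verdict: localizations are grouped into
molecules (single linkage, radius 4× mean precision, dark time as above),
then molecule centroids are linked at ≤ 2ξ (the cluster diameter, inclusive
at the boundary). Components of ≥3 molecules are clusters;

    fraction_clustered = (Σ sizes of components ≥ 3) / n_molecules.

Unclustered ROIs short-circuit to fraction 0 with a `skipped` flag. On
clustered simulations the mean fraction lands in the 0.4–0.7 band measured
for HER2-overexpressing cell lines (49%/59%). It does *not* reach the
generative fraction of molecules in ≥3-occupancy clusters (~0.8), because
the linkage distance 2ξ̂ inherits the downward ξ bias above — a propagated
limitation, not an independent one.

## Monte Carlo simulator

Emulates clustered dSTORM data for one square ROI (default 20 µm²):

| parameter | default / presets | notes |
|---|---|---|
| localization density | 360 (BT-474) / 230 (SK-BR-3) / 12 (monomer control) locs/µm² | target count jittered by U(0.8, 1.2) |
| blinking mean α | Poisson(3), resampled ≥ 1 | zero-truncated mean 3.157 |
| precision σ | Normal(12, 2) nm, truncated > 0 | per-localization isotropic error |
| photons | Poisson(2000), resampled ≥ 700 | matches the photon filter floor |
| occupancy | truncNormal(3 or 2, 0.75) on [1.5, 4.5], rounded ≥ 1 | distribution shape not fixed by the source; truncated Normal chosen |
| cluster radius | truncNormal(20 or 24, 3) on [18, 32] nm | same caveat |
| placement | uniform on the cluster disc | Gaussian (sd R/2) available via config |
| frames | 20,000; appearances on consecutive frames from a uniform onset | minimal temporal model so dark-time logic is exercised; real dye kinetics (on/off rates, multiple dark states) are not modeled |

Clusters are created until the expected localization count (occupancy ×
truncated blinking mean, accumulated) reaches the jittered target; molecule
draws falling outside the ROI are re-drawn, and localization errors that
leave the ROI are dropped (~0.3% at 20 µm²). Everything is reproducible
from a single seed, and every table ships with ground truth (per-molecule
positions, cluster ids, appearance counts, per-localization molecule
labels).

What the simulator does **not** emulate: camera-frame rendering and PSF
fitting, drift, z-dimension, structured backgrounds, label stoichiometry
variation, dye photophysics beyond the Poisson appearance count, and
spatially varying density within an ROI. Passing recovery tests therefore
demonstrates correctness of the estimators under this generative model, not
performance on raw experimental data.

## Study-level statistics

- **Pearson correlation** by product-moment sums; 95% CI by Fisher
  z-transform; two-sided p from the t statistic with n−2 df; OLS line of
  copy number on the imaging quantity (the orientation consistent with the
  reported slopes). Simulated coverage of the CI at known ρ is 93–97%.
- **Density threshold**: the copy-number-on-density line inverted at the
  clinical cutoff (copy number 6 → ~22 molecules/µm² for the embedded
  patient table); ROI fractions above threshold use strict inequality.
- **NMI** between two result distributions: samples paired by quantile
  rank, discretized with a common Freedman–Diaconis binning on the pooled
  values, scored by mutual information normalized by the arithmetic mean of
  marginal entropies, clipped to [0, 1]. Identical distributions score 1;
  degenerate/disjoint cases score 0 with a warning. Because a monotone rank
  map preserves mutual information, the score is mostly sensitive to shape
  and support mismatch rather than pure location shifts within a common
  support.
- **Summaries**: SEM with sample sd (n−1); CV = 100·sd/mean (%), undefined
  (with warning) at zero mean.

The embedded patient table carries the printed per-patient summary values
(FISH copy numbers, densities, receptors per cluster, cluster radii,
clustered fractions, precisions, ROI counts, split p-values) for patients
P1–P7; correlations computed from it use these rounded values.

## Problem sizes and tolerances

Recovery checks use 100 simulated ROIs per preset (the validation-scale
batch), a 330 µm² sparse field (~1300 molecules) for α recovery, 300
dataset+seed pairs for the split-test null, and 1000 replicates for CI
coverage. Numerical tie-breaks: quantiles by linear interpolation; linkage
distances inclusive; binarization floors coordinates; fits that fail to
converge return an `unknown` verdict and negative-amplitude optima clamp to
A = 0 with verdict `random`.
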