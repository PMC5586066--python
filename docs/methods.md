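# Methods

`mammospat` quantifies the *spatial organisation* of breast tissue on
mediolateral-oblique (MLO) mammograms and relates it to case–control
status.  The chain is: preprocessing → four-class tissue segmentation →
pairwise forces histograms → functional PCA → adjusted logistic
association with optimism-corrected validation.  A synthetic phantom and
cohort generator with known ground truth stands in for real image data.

## Preprocessing

Intensities are rescaled to [0, 1].  Digitised-film images are denoised
with a pixelwise adaptive Wiener (local linear MMSE) filter over a
5×5 window, with the noise variance estimated as the mean of the local
variances; digital raw images skip denoising (their signal-to-noise ratio
makes it unnecessary).  Contrast is enhanced with the logarithmic map
`log(1 + c·x) / log(1 + c)`, `c = 9` by default — a strictly increasing
bijection of [0, 1] that brightens the dim skin-line pixels.

The breast profile is found by a three-class Otsu multi-threshold of the
256-bin histogram (exhaustive search over all threshold pairs, ties to
the lexicographically smallest pair): the two brightest classes are the
candidate foreground, the largest 8-connected component is kept, and the
mask is smoothed by morphological closing/opening with a disk of radius
1% of the image width plus hole filling.  The Wiener window, `c` and the
disk radius are conventional defaults, exposed in the configuration; they
are not claimed to match any particular prior implementation.

Pectoral-muscle removal is a deliberately simple straight-line cut:
within the pectoral corner (auto-detected as the brighter top corner),
pixels above a two-class Otsu threshold whose component touches both the
top edge and the chest wall are taken as muscle; the outermost candidate
column per row — the strongest oriented intensity edge — is fit by least
squares, and everything on the corner side of the line is removed.  This
is *not* a texture-gradient pectoral segmentation; downstream analysis
only needs a pectoral-free mask, and on phantoms the cut removes ≥ 90% of
the muscle while sacrificing ≤ 5% of breast pixels.

## Tissue segmentation

Breast pixels are clustered on intensity alone into four classes — fatty,
semi-fatty, semi-dense, dense — by fuzzy C-means with the conventional
fuzzifier `m = 2`, tolerance 1e-6 on the centroid shift, at most 300
iterations, and deterministic initialisation at the 12.5/37.5/62.5/87.5
intensity percentiles (seeded random initialisation is available).  The
membership/centroid updates are the standard alternating scheme; the
objective `Σ u^m d²` is non-increasing and its trace is stored.  Labels
are the arg-max memberships, indexed 1..4 by ascending centroid, ties to
the lower class.  An empty hardened class is allowed (very fatty breasts)
and logged; its forces histograms are zero by convention.

Clustering uses the **denoised, un-enhanced** intensities by default
(`cluster_on="denoised"`).  The log enhancement compresses the bright end
of the scale, which can make the (population-heavy) semi-fatty class
split while dense and semi-dense merge; on the raw scale the four
intensity strata are equidistant and recovered almost perfectly
(≥ 99% pixel agreement on phantoms at noise 0.02).  Clustering the
enhanced image remains available as a configuration switch.

Label maps are resampled to a common physical grid (0.25 mm/pixel) by
nearest neighbour before spatial analysis, which preserves the label set
exactly; upsampling is refused.

## Forces histograms

For two regions A and B and a direction θ, the image is swept by the
family of parallel digital lines along θ; on each line every ordered pair
(a ∈ A strictly ahead of b ∈ B) contributes `1/d²`, and the line weights
sum into bin θ.  Repeating over 180 directions (step 2°, covering
[0°, 360°)) gives the histogram; the six unordered class pairs of a
four-class map give six histograms per image.

Discretisation choices:

* **Rasterisation.**  For |tan θ| ≤ 1 lines are indexed by the rounded
  row intercept `r − ⌊c·m + 0.5⌋` with one pixel per column (transposed
  otherwise), so the line family partitions the grid — every pixel lies
  on exactly one line, which is what makes the brute-force oracle
  well-defined.
* **Positions and distances.**  A pixel's position on its line is its
  scalar projection onto the unit direction vector; `d` is the
  difference of projections, in pixel units of the 0.25 mm grid.  Angles
  are measured counter-clockwise from the +x (column) axis with +y up.
* **Direction convention.**  Bin θ of FH_ij accumulates pairs whose
  region-i pixel is ahead of the region-j pixel along θ.  This yields the
  exact symmetry law FH_ij(θ) = FH_ji(θ + 180°), which the tests check to
  1e-12.
* **No normalisation** by default: histogram mass scales with region
  sizes (and hence breast size); size is handled downstream by covariate
  adjustment, not by rescaling the descriptor.  A sum-to-one option
  exists.

Because the line family is anchored to the pixel grid, the histogram is
exactly invariant under object translations aligned with the family
(e.g. any shift at θ ∈ {0°, 90°, 180°, 270°}) and only approximately
invariant otherwise (total mass stable to ~2% for interior objects on a
48-px canvas; individual near-empty bins can switch on or off).  The same
discretisation makes a pixel pair contribute to a few neighbouring bins
around its exact direction, not to a single bin.

The production kernel (numba) accumulates all ordered label pairs in a
single sweep per angle, O(a · n√n) overall; a pure-Python enumeration of
every line and pixel pair serves as the independent oracle in tests
(agreement ≤ 1e-12 bin-wise).

## Functional PCA

Each FH family across images is a sample of curves on the regular
180-point angle grid, so sparse-data functional estimators reduce to
plain discretised PCA: subtract the mean curve, eigendecompose the
sample covariance (divisor n − 1, uniform quadrature weights), fix
eigenfunction signs by positive first grid value (positive sum on ties),
and retain the smallest K whose eigenvalues reach 85% of the total
variance.  Scores are grid inner products of centred curves with the
eigenfunctions, standardised to zero mean and unit variance (ddof 1)
over the training images; new curves (a validation study) are scored
with the training mean, basis and standardisation via `project`.

Modes of variation `V = μ(θ) ± α√λ_k·φ_k(θ)` and the dominant angles of
|φ_k| (largest circular local maxima, with signs) are used to interpret
components.  With a noise-free single-component sample the eigenfunction
is recovered to 1e-8; with several components the span is exact and the
individual eigenfunctions are recovered up to the finite-sample rotation
inherent to PCA.

## Association analysis

Case–control status is modelled by maximum-likelihood logistic
regression (Newton/IRLS, tolerance 1e-10; separation and rank deficiency
raise dedicated errors).  The adjustment set is age, BMI, √PD, the
combined parity/age-at-first-birth five-category variable (reference
Nulliparous) and HRT use (reference Never); breast area and
breastfeeding are optional extra terms.  √PD is the default PD scale,
with raw and five-category ([0,5), [5,10), [10,20), [20,40), [40,100])
codings available.  Category dummies for levels absent from a given
sample are dropped.

The primary inference is the global likelihood-ratio test of the
adjusted model with all retained fPC scores against the adjusted model
without any; its degrees of freedom equal the number of fPC columns.
The unadjusted categorical LRT from a printed count table is the
contingency-table G-statistic `2ΣO·ln(O/E)`, an identity the tests check
on random tables.

The spatial-relations score is the coefficient-weighted sum of the fPC
values from the full fit.  Its per-SD odds ratio is `exp(β·sd)`.  AUCs
use the Mann–Whitney statistic with half tie credit; correlated AUCs are
compared with DeLong's placement-value z-test.

**Optimism correction** follows Harrell's bootstrap.  For each of B
resamples the supervised steps are refit: the full logistic model on the
resample defines a score; the *apparent* index is measured on the
resample and the *test* index by carrying the frozen score to the
original data; optimism is the mean excess, and honest = apparent −
optimism per index.  Concretely, the per-SD effect of a trained score on
evaluation data is the coefficient of the (frozen) score in an adjusted
logistic refit on those data, times the score's SD there; the AUC
indices use the trained full and adjustment-only linear predictors
evaluated on the data at hand.  The fPC basis is fit without outcome
labels and is therefore held fixed across resamples (a configuration
choice; refitting it would only add unsupervised noise to the optimism
estimate).  Separation in more than 5% of resamples aborts with a
diagnostic.  Stepwise selection over fPC terms is bidirectional AIC
(adjustments always kept, deterministic column-order scans, strict
improvement required).

## Synthetic data

The phantom idealises an MLO view: a breast half-ellipse flush with the
chest-wall edge (default semi-axes 0.45·rows and 0.82·cols), a bright
right-triangle pectoral region covering 28% of the image height by
default, a thin skin-line intensity fall-off (outer 1.5% of the ellipse
radius), and four tissue classes.  Class assignment is a deterministic
arg-max over interpretable spatial scores: a fatty rim near the skin
line plus a lower-quadrant fatty tilt controlled by
`lower_quadrant_fat_weight`; a uniform semi-fatty background; Gaussian
dense islands at the polar `dense_blob_centers` with semi-dense halos
(halo scale twice the blob σ).  Pixel intensities are the four
`tissue_levels` (defaults 0.25/0.45/0.65/0.85) plus Gaussian noise
(default sd 0.02), clipped to [0, 1].  Percentage density of a synthetic
subject is defined from ground truth as the percentage of breast pixels
in the two densest classes, preserving the confounding between PD and
the spatial parameters.

The cohort generator draws age ~ N(63.1, 6.5), BMI ~ N(25.1, 3.7), PD
from a truncated normal (16.7 ± 14.0 on [0.5, 85]), HRT with
probabilities (0.73, 0.06, 0.21) and the parity/AFB five-category
variable with (0.117, 0.287, 0.295, 0.230, 0.071) — the pooled key
characteristics of the main case–control study.  Latent spatial
parameters are standard normal: `z_dense_angle` shifts one dense island
along the lower/retromammary arc (315° + 20°·z, clipped to the
half-ellipse) and `z_lq_fat` scales the lower-quadrant fat weight
(`exp(0.5·z)`).  Case status is Bernoulli with logit `intercept + β·x`;
covariate coefficients default to the adjusted estimates of the main
study's full model and the latent spatial coefficients default to zero,
so the default cohort is null for spatial effects and a "planted" effect
is a single explicit β.  The intercept is calibrated by root finding so
the expected case fraction matches the request, then subjects are
sampled by status to exact counts.

What the generator does *not* emulate: parenchymal texture within
classes, compression and projection physics, scanner artefacts and
labels, laterality, or the continuous gradation of real tissue — so
passing tests demonstrate that the pipeline recovers planted spatial
structure from images with this geometry, not clinical performance on
real mammograms.

## Problem sizes and numerical notes

* Tests and the acceptance script run the end-to-end planted-effect
  study at 2000 phantoms of 128×128 pixels (0.25 mm/pixel, so no
  resampling step) with a dense-location log-odds of 1 per SD; the
  global LRT p-value is far below 0.05 (~1e-20 at seed 1).  Unit and
  smoke tests use 64×64 phantoms and cohorts of 60–600.
* Bootstrap validation uses B = 200 in tests and the acceptance script
  (B = 1000 is the production default of the method description).  The
  null-calibration check (fully null cohort, 13 noise components,
  n = 600) shows the correction removing the bulk of the overfitting:
  the apparent AUC of ~0.59–0.63 drops to an honest value near 0.5.
  The simple optimism bootstrap is known to retain a small positive
  bias when many pure-noise predictors are fit (a few hundredths of
  AUC at these sizes — an independent minimal implementation of the
  same procedure behaves identically), so honest null values scatter
  slightly above 0.5 rather than centring exactly on it.
* FCM on heavily discrete data can place coincident percentile
  initial centroids; these are spread across the distinct values.
  Membership of a pixel exactly at a centroid is 1 by the d → 0 limit.
* Eigenvalues below 1e-12 of the leading one are treated as zero in
  fPCA; a retained component with zero score variance is an error.
* Chi-square upper tails come from the regularised incomplete gamma
  function (scipy); p-values are reported in full precision and can be
  displayed at one significant figure below 1e-3.

## Known limitations

* The pectoral cut assumes a roughly straight muscle edge reaching the
  top corner; unusual geometries fall back to "no candidate, mask
  unchanged" with a warning.
* The FH is computed on hard labels; fuzzy-landscape variants and other
  force exponents are out of scope.
* Discretised fPCA assumes densely, regularly observed curves — true
  for FH families, not for sparse functional data.
* The synthetic planted effect enters through two latent parameters
  only; real tissue organisation is higher-dimensional.
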