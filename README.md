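# mammospat

Spatial organisation of breast tissue on mammograms, and its association
with breast cancer case–control status.

Mammographic percentage density (PD) — the fraction of the breast area
occupied by radiodense fibroglandular tissue — is an established breast
cancer risk factor, but it ignores *where* dense and fatty tissue sit in
the breast.  `mammospat` implements a full pipeline for quantifying that
spatial layout on mediolateral-oblique (MLO) mammograms and testing
whether it carries risk information beyond PD and the classical
epidemiological covariates.  It is aimed at researchers in mammographic
epidemiology and medical image analysis who want a tested, reproducible
reference implementation; because the underlying case–control imaging
data are not public, the package ships a synthetic phantom/cohort
generator with known ground truth so every stage is verifiable.

## Method

1. **Preprocessing** — intensities rescaled to [0, 1], adaptive Wiener
   denoising (digitised film), log contrast enhancement
   `log(1 + 9x)/log 10`, three-class Otsu thresholding, largest
   connected component + morphological smoothing for the breast mask,
   and a straight-line pectoral-muscle cut.
2. **Tissue segmentation** — fuzzy C-means (m = 2) on breast-pixel
   intensities into four classes: fatty (1), semi-fatty (2), semi-dense
   (3), dense (4), ordered by intensity.
3. **Forces histograms (FH)** — for each ordered region pair (i, j) and
   each of 180 directions θ (step 2°), parallel digital lines sweep the
   0.25 mm/pixel label map; each pair of pixels on a common line with
   the region-i pixel ahead of the region-j pixel contributes the
   inverse squared distance:

       FH_ij(θ) = Σ_lines Σ_{a∈i, b∈j, a ahead of b} 1 / ‖a − b‖²

   Six histograms (the 4-choose-2 pairs) describe one image.
4. **Functional PCA** — each FH family across images is a functional
   sample; discretised fPCA yields mean μ(θ), eigenfunctions φ_k(θ),
   eigenvalues λ_k, and per-image scores, retaining the smallest K
   reaching 85% cumulative variance.  Scores fPC_ij^k are standardised;
   modes of variation V = μ ± α√λ·φ and the dominant angles of |φ_k|
   interpret the components.
5. **Association** — logistic regression of case–control status on the
   fPC scores, adjusted for age, BMI, √PD, parity/age-at-first-birth
   and HRT; a global likelihood-ratio test over all fPC terms; a
   spatial-relations score Σ β_k·fPC^k with per-SD odds ratio
   exp(β·sd); AUCs with DeLong's test for correlated models; Harrell's
   optimism bootstrap for honest (overfitting-corrected) estimates; and
   bidirectional AIC stepwise selection of the key components.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

Recover the tissue classes of a synthetic phantom
(`examples/01_phantom_and_segmentation.py`):

```text
breast area: 8931 px (558 mm^2 at 0.25 mm/px)
FCM centroids (fatty -> dense): [0.248 0.449 0.649 0.839]
class areas (px): {1: 2461, 2: 4523, 3: 1490, 4: 457}
percentage density (classes 3-4): 21.8%
pixel agreement with ground truth: 0.992
```

The centroids land on the phantom's four tissue intensity levels
(0.25/0.45/0.65/0.85) and 99.2% of breast pixels get their true class.

Unadjusted likelihood-ratio tests recomputed from the published cohort
count tables (`examples/05_published_tables.py`):

```text
main study, parity & age at first birth: LRT = 34.015 on 4 df, p = 7.4e-07
validation study, parity & age at first birth: LRT = 6.094 on 4 df, p = 0.192
validation study, HRT use: LRT = 3.443 on 2 df, p = 0.179
```

A full synthetic case–control study of 600 subjects with a planted
dense-location effect (`examples/04_cohort_association.py`) runs
images → FH → fPCA → adjusted global test → honest validation:

```text
global LRT: statistic 46.83 on 8 df, p = 1.65e-07
stepwise-selected components: ['fpc12_1', 'fpc13_1', 'fpc14_1', 'fpc24_2']
spatial-relations score, per-SD OR: apparent 3.69, honest 2.59
AUC (full model): apparent 0.719, honest 0.683
```

The planted spatial effect is recovered through the whole image
pipeline after adjustment for PD and the other covariates, and the
honest (optimism-corrected) estimates sit below the apparent ones.
The other examples demonstrate the FH descriptor and fPCA modes in
isolation.

A thin CLI mirrors the library (`mammospat simulate | preprocess |
segment | fh | fpca | associate | run-all | validate-transfer`).

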