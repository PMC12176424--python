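# Methods

`conjradiomics` implements a color-free ("monochromatic") radiomic analysis
of conjunctiva photographs for anemia screening, together with a synthetic
conjunctiva-phantom generator that makes the whole chain testable at desk
scale. This note records the models, the parameters that matter, the
numerical conventions, and the limits of what the phantom experiments can
show.

## The analysis chain

Photographs with aligned binary ROI masks (palpebral or bulbar conjunctiva)
enter a fixed sequence:

1. **Grayscale conversion** — a single intensity per pixel as a weighted
   combination of R, G, B. The default is the balanced combination
   (1/3, 1/3, 1/3); ITU-R BT.601 luma weights are available through
   `grayscale_weights`. Color information is deliberately discarded: the
   premise is that spatial/textural microvascular structure, not pallor
   hue, carries the anemia signal, which sidesteps device- and
   light-dependent color calibration.
2. **Intensity standardization** — within-ROI min-max mapping to [0, 255],
   applied to the whole frame. A constant ROI maps to 128. All images are
   treated as 8-bit provenance, hence the fixed 255 range.
3. **Filtered images** — Laplacian-of-Gaussian responses at sigma = 1, 2, 3
   px (band-pass blob/edge emphasis at those scales) and a single-level
   undecimated Haar wavelet decomposition. `Wavelet-L` is the LL
   (approximation) subband and `Wavelet-H` the HH (diagonal detail)
   subband; LH/HL are computed on request but off by default. All filters
   run on the full frame with mirror padding before masking, so
   filtered-image features may depend on pixels within the filter support
   of the ROI boundary — this is intended and asserted in tests. The LoG
   kernel is truncated at 4 sigma and recentred to exactly zero sum so
   constant and affine images produce exactly zero response.
4. **Discretization** — within-ROI intensities are binned into Ng = 32
   equal-width levels spanning the ROI [min, max] (top edge inclusive;
   constant ROI occupies level 1). Because the edges rescale with the
   data, quantization is invariant to increasing affine intensity maps.
   Ng is configurable; the feature inventory size depends on it only
   through feature values, not count.
5. **Texture matrices and features** — per image type, first-order
   statistics (16) plus four matrix families: GLCM (23 features, distance
   1, four 2-D angles, symmetric accumulation, features averaged over
   angles), GLRLM (16, maximal equal-level runs in four directions,
   averaged), GLSZM (16, 8-connected equal-level zones, orientation-free),
   and GLDM (14, dependence counts with tolerance alpha = 0 over the
   8-neighborhood). With the default six image types (original, three LoG
   scales, two wavelet subbands) the inventory is 510 features per photo.
   Shape features are never computed: conjunctival outline depends on how
   the eyelid is everted, not on physiology.
6. **Preprocessing** — Z-score standardization (train-fitted), kNN
   imputation (k = 5, distances on min-max-scaled features so no single
   feature dominates; test rows are imputed from training neighbors only),
   then min-max scaling to [0, 1] (train-fitted; test values outside the
   train range are preserved, not clipped, and flagged). Both
   normalizations are kept, in this order, because each serves a
   different stage (comparability across photos, then equal contribution
   ranges for selection and the network); either can be disabled.
7. **Stability feature selection** — for each of `n_seeds` seeds a random
   forest is fitted to the training rows (anemia as target) and features
   are ranked by mean decrease in impurity (Gini importance). A feature is
   *stable* if it reaches the top `top_k` in at least `threshold x
   n_seeds` fits; the 20 stable features with best median rank are kept
   (ties by median rank, then name). Defaults: n_seeds 20, top_k 30,
   threshold 0.8, 100 trees. Forest bootstraps depend on row order, so
   rows are sorted lexicographically before fitting, making selection
   invariant to row permutations. If fewer than 20 features are stable the
   threshold is halved once, then an error reports the stability
   histogram.
8. **Classifier** — a fully connected network with 20 inputs, two hidden
   layers of 50 rectified-linear units, and a sigmoid binary output
   trained with cross-entropy under ADAM (the single-sigmoid head is the
   standard binary parametrization of a 2-way softmax). SMOTE balances
   the training classes (each synthetic row is x + u (x_nn - x) for a
   minority row and one of its 5 minority nearest neighbors, u ~ U(0,1));
   SMOTE never touches tuning-holdout or test rows. Optional randomized
   hyperparameter search draws 20 candidates from {learning rate 1e-2,
   1e-3, 1e-4} x {batch 32, 64, 128} x {epochs 50, 100, 200} and scores
   them by AUC on a participant-level 20% holdout of the training set.
9. **Evaluation** — ROC/AUC as the Mann-Whitney rank statistic (ties count
   one half) with the DeLong structural-component standard error and Wald
   95% CI truncated to [0, 1]; the paired DeLong test for two models on
   the same rows (covariance included) and an unpaired variant (sum of
   variances) for disjoint subgroups; Kruskal-Wallis with tie correction
   over bootstrap AUC replicates (200 per group, seeded) when three or
   more groups are compared; chi-square or, for 2x2 tables with an
   expected cell below 5, Fisher's exact test; and multivariate
   association models — linear regression of hemoglobin on the selected
   features within each class, and logistic regression of anemia on all
   selected features jointly with Wald CIs on the odds-ratio scale
   (perfect separation falls back to an L2-penalized fit, flagged, without
   CIs).

ROC units default to photos; because photos of one participant share
latent anatomy, photo-level scores are clustered and the photo-level
DeLong variance understates sampling noise. The pipeline therefore also
reports participant-level results (scores averaged over a participant's
photos), which are the calibrated unit for cross-model comparisons, and
the null-safety checks use them.

WHO anemia labels use strict `hgb < cutoff` with cutoffs 11.5 g/dL (ages
5-11), 12.0 (12-14), and at 15, 12.0 for females and 13.0 for males. The
source bands overlap at age 11; the implemented reading assigns 11 to the
lower band.

## The resolution estimator

Device spatial resolution is estimated by the edge method: the mean
profile across a step-edge target gives the edge spread function (ESF);
its finite difference is the line spread function (LSF, samples at
half-integer positions); a cubic spline locates the half-maximum
crossings sub-pixel, and the FWHM times the pixel pitch is the
resolution. Finite differencing convolves the true LSF with a unit
boxcar, which would bias a coarse-grid half-maximum reading by several
percent at sigma ~ 1 px; the spline upsampling keeps recovery within 2%
of 2.3548 sigma for sigma in {1, 2, 3} px. An estimation error is raised
when no single dominant monotonic edge is present (net excursion below
half the profile's total variation). Unblurred edges hit a 1 px
discretization floor.

## The phantom cohort

The generator emulates the structure of a school-age screening cohort:
565 participants by default, ages uniform on 5-15, 53% male, anemia
prevalence 56%. Hemoglobin is drawn from class-conditional normals
(anemic 9.1 +/- 1.1, nonanemic 11.8 +/- 1.0 g/dL) and redrawn until the
WHO label agrees, which reproduces an overall mean near 10.3 +/- 1.7
g/dL while keeping labels and hemoglobin jointly consistent. Photos per
participant default to 2 eyes x 3 devices x 4 = 24, mirroring a ~22
photos/participant acquisition.

Each photo is a smooth bright background (planar illumination gradient)
with dark curvilinear vessel strokes inside an elliptical lid-shaped
(palpebral) or scleral (bulbar) ROI. Vessels are random-walk centerlines
with Gaussian cross-profiles of width 1-4 px — capillaries near the
resolution limit of a ~100-200 um/px camera. The class effect is the
ground truth the pipeline must recover: anemic participants have sparser
(6 vs 14 strokes per 1000 ROI px) and fainter (22% vs 42% contrast)
vessels, i.e. pallor as loss of visible microvascular texture. Each
participant holds latent density/contrast values (between-participant SDs
1.5 and 0.04) around which photos vary; the defaults put the class gaps
at several SDs — a strong, clearly recoverable effect, chosen because no
quantitative anemic-vs-nonanemic microvascular difference is established
to calibrate against. Device profiles add Gaussian PSF blur, resolution
loss (down/up-resampling), a gamma tone curve and additive read noise.
Everything is bit-identical under a fixed seed.

What the phantom does *not* emulate: specular reflections, eyelashes,
motion blur, segmentation error (masks are exact by construction), skin
pigmentation (irrelevant to the conjunctiva), vessel branching topology,
and any physiologic coupling between hemoglobin level and vessel
appearance beyond the binary class. Passing the end-to-end checks
therefore demonstrates that the *pipeline machinery* recovers a planted
microvascular texture signal and stays null-safe — not that real
conjunctiva photos carry such a signal.

## Orchestration and reproducibility

The pipeline runs the palpebral and bulbar regions over a shared cohort
and a shared participant-level split (so cross-region DeLong comparisons
are paired), but keeps feature tables, selection and models strictly
separate per region. Splitting is at participant level, stratified by
anemia, redrawn within the seed stream until the train/test prevalence
gap is at most 3 percentage points; for cohorts so small that one
participant moves the test prevalence by more than that, the
best-balanced draw is used. 565 participants at 70/30 split into exactly
395/170. A master seed fans out to per-stage seeds by a fixed counter
scheme so any stage reruns identically in isolation; the manifest records
the config hash and per-stage checksums, and an access log records which
participant ids each fitting stage touched (test ids appear only at
evaluation — asserted in tests).

## Problem sizes used in tests and the acceptance script

End-to-end checks run 200-participant cohorts at 64x64 px with one photo
per eye per device (1200 photos per region), selection with 5 seeds and
50-tree forests, and 100 training epochs; these sizes give stable AUC
estimates for a strong planted effect while keeping a full run in tens of
seconds after extraction. Null-safety replicates permute anemia labels at
participant level and rerun everything downstream of extraction 20 times.
Statistical calibrations use 1000 null replicates (DeLong, Kruskal-
Wallis) and 200 replicates at n = 5000 for logistic CI coverage. The
per-run medians reported for null AUC aggregate over replicates because a
single 60-participant test set determines a null AUC only to within ~0.08
(participant-level sampling), while the median over 20 replicates is
stable to ~0.02.

## Known limitations

- The feature inventory (510 per photo with defaults) depends on the
  filter/level configuration; no attempt is made to reproduce any
  particular historical inventory size.
- GLCM/GLRLM features are aggregated by per-direction averaging; merged-
  matrix aggregation is exposed in config but not the default.
- Probability calibration of the network is out of scope; scores are used
  only through ROC ranks.
- The logistic fallback under perfect separation reports penalized point
  estimates without CIs.
- Photo-level Wald CIs ignore within-participant clustering; use the
  participant-level outputs for inference across models or subgroups.
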