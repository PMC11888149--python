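# Methods

## Problem and model

Wireless capsule endoscopy (WCE) produces tens of thousands of frames per
study, many of which show mucosa obscured by bile, bubbles, debris or food
residue.  `wceclean` segments each frame into *clean* and *contaminated*
pixels and summarises visualisation quality as the clean-pixel fraction.

The classifier is a two-class Gaussian Bayes (quadratic discriminant)
model over raw RGB intensities.  Each pixel is an observation
x = (r, g, b) in [0, 255]^3.  For class k in {clean, contaminated}:

    p(x | y=k) = N(x; mu_k, Sigma_k)          (tri-variate, full covariance)
    p(y=k)     = N_k / (N_clean + N_cont)     (training-pixel share)
    p(y=k | x) ∝ p(x | y=k) p(y=k)

and the label is the posterior argmax.  The model has 26 learned numbers
(2 priors, 2 means of length 3, 2 symmetric 3x3 covariances stored densely),
so it fits on 20 annotated frames and needs no GPU.

Assumptions: pixels are conditionally independent given their class; each
class's color distribution is a single Gaussian on the raw intensity scale
(no normalisation to [0, 1]).  Spatial context, texture and shape are
deliberately not used.

## Representative-frame selection

Annotating pixels is expensive, so only K = 20 frames are labelled.  To
make those 20 frames span the corpus's color variability, every frame is
summarised by a 3-D CIELAB histogram (8 bins per channel, 512 bins,
fixed absolute ranges L: [0, 100], a/b: [-128, 127], L1-normalised) and the
corpus is clustered by K-means (k-means++ init, 10 restarts, max 300
iterations, seeded).  One frame per cluster is drawn uniformly at random;
the complement is the evaluation set.  Fixed absolute bin ranges keep
features comparable across frames; L1 normalisation keeps corpora with
mixed resolutions comparable.  The repeated-trial protocol
(`evaluation.run_trials`, 5 trials by default) re-runs clustering and
selection with a fresh derived seed per trial and reports per-metric
mean ± sample std.

## Estimators and numerics

- Covariances use the unbiased 1/(N-1) estimator (switchable to 1/N); at
  the pixel counts involved the difference is negligible.
- Every covariance receives a ridge `epsilon * I` (default epsilon = 1e-3
  intensity^2) so degenerate annotations (e.g. a constant-color class)
  still yield a positive-definite matrix.
- All density evaluation runs in log space through a Cholesky
  factorisation; the explicit inverse and determinant are never formed.
  Posteriors are normalised by log-sum-exp, so the evidence is computed
  implicitly and the returned p(clean | x) map is a genuine probability,
  usable directly for AUROC.
- Exact posterior ties label the pixel clean, keeping recall of the
  positive (clean) class the conservative direction.
- A circular field-of-view (FOV) mask is available because real capsule
  frames have dark, non-informative corners; it is OFF by default and all
  fitting/evaluation functions accept it as an option.

## Degradation scenarios

Six parametric corruptions emulate common WCE acquisition problems.  None
of them displaces pixels, so ground-truth masks carry over unchanged.

| scenario       | parameters (defaults)                                   |
|----------------|---------------------------------------------------------|
| fog            | intensity in [0.25, 1] scales disk density; per-disk alpha 0.05 |
| gaussian_noise | zero-mean, variance in [5, 300] per channel (a milder [5, 50] range is configurable) |
| defocus        | soft-edged disk PSF, radius in [1, 8] px                |
| motion_blur    | anti-aliased line kernel, angle on the 15° grid, length in [1, 25] px |
| brightness     | power law S = r^(1/gamma), gamma in [0.75, 1.25] (gamma > 1 brightens under this exponent convention) |
| color_jitter   | HSV shifts in [-5, 5] 8-bit units; hue on the 0–179 half-degree scale, wrapping |

Choices made where the knobs were genuinely open: the defocus radius range
[1, 8] px spans mild-to-severe blur at ~336 px frames; fog is rendered as
Poisson-placed soft disks whose expected count scales with intensity and
frame area; the hue unit is the half-degree 8-bit convention.  Blur kernels
are normalised to sum to one, so constant images are exact fixed points and
the global mean is preserved up to clipping.  `corrupt_dataset` derives one
child seed per (frame, scenario) pair, making corrupted sets bit-identical
across runs and platforms.

## Synthetic scenes

The generator produces frames with the statistical structure the
classifier models: two tri-variate Gaussian color populations arranged as
spatially coherent regions (unions of random rotated ellipses, redrawn
with an adaptive size factor until the contaminated fraction inside the
circular FOV is within ±0.05 of its target) on black out-of-FOV corners.

Default palettes are package defaults chosen for qualitative realism —
clean mucosa pinkish (mean (185, 115, 110)), contamination yellow-green
(mean (150, 140, 70)), correlated covariances with per-channel SD ~10–14 —
not measurements of any real corpus.  Their Mahalanobis separation is ~6,
i.e. near-zero Bayes risk, so segmentation on default scenes should be
near-perfect; `overlapping_palettes()` provides a deliberately harder pair
(separation ~3, Monte-Carlo Bayes risk ~6%) for error-calibration studies.
Means sit ≥ 3 SD from 0 and 255, so clipping bias on sampled intensities
is negligible.

Colors are sampled i.i.d. per pixel given the class.  Real mucosa has
spatial color correlation, specular highlights, bubbles with ring
highlights and smooth illumination gradients; the generator has none of
these.  Passing tests on synthetic scenes therefore demonstrate
correctness of the estimators, the decision rule and the metrics — and
that observed error matches the analytic Bayes risk of the generating
mixture — but they do not certify performance on real endoscopy data.

`bayes_risk_monte_carlo` estimates the irreducible mixture risk by
classifying samples with the optimal rule under the true generating
parameters, evaluated through `scipy.stats.multivariate_normal`
(independent of the classifier's own likelihood code).

## Metrics

Clean is the positive class.  Per frame: accuracy, precision, specificity,
sensitivity, DSC = 2TP/(2TP+FP+FN), IOU = TP/(TP+FP+FN), and rank-based
(Mann–Whitney, midrank ties) AUROC of the clean posterior.  Any 0/0 ratio
or single-class AUROC is an undefined marker (NaN), excluded from
aggregation and counted.  Aggregation is per-frame mean ± sample std
(ddof = 1); the pooled-pixel alternative was rejected because per-frame
spread is the quantity a reader compares across trials.  Agreement between
predicted and annotated clean fractions is Pearson's r.

## Problem sizes

The test suite and `scripts/acceptance.py` run the full protocol —
2000-frame corpus, K = 20 selection leaving 1980 evaluation frames, six
corruption scenarios (12 000 corrupted frames) — at reduced frame sizes
(32–224 px sides depending on the check) as the package's own choice of
desk-scale problem size; every count law, estimator property and metric
identity is size-invariant.  Statistical checks use 10^6 pixels per class
(parameter recovery to ±0.5 counts and 2% Frobenius error; Bayes-risk
agreement to ±1.5% absolute).

## Known limitations

- Two classes only; no multi-class extension (e.g. bubbles vs bile).
- Single-Gaussian class conditionals cannot represent multi-modal
  contamination colors; a mixture would need more than 26 parameters.
- Color-only features make the model sensitive to chromatic shifts (the
  color-jitter scenario is its weakest case) though robust to blur.
- The synthetic generator's realism gap above: results on it bound, but do
  not equal, behaviour on clinical frames.
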