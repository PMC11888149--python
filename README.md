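# wceclean

Segmentation of clean vs. contaminated mucosa in wireless-capsule-endoscopy
(WCE) frames, for gastroenterologists and imaging researchers who need an
objective, lightweight small-bowel visualisation-quality score.  Much of a
capsule study shows mucosa obscured by bile, bubbles, debris or food
residue; `wceclean` labels every pixel as clean or contaminated and reports
the clean-pixel fraction as the cleanliness score.

## Model

A two-class Gaussian Bayes (quadratic discriminant) pixel classifier over
raw RGB intensities.  Each pixel x = (r, g, b) is scored by

    p(y = k | x) ∝ N(x; μ_k, Σ_k) · p(y = k),    k ∈ {clean, contaminated}

with class means μ_k, full 3×3 covariances Σ_k and priors p(y = k)
estimated from annotated training pixels — 26 learned parameters in total,
so the model fits in seconds on 20 annotated frames.  The 20 fitting frames
are chosen by clustering the corpus's 3-D CIELAB color histograms (8 bins
per channel, 512-bin features) with K-means (K = 20) and drawing one frame
per cluster, which covers the corpus's color variability on a tiny
annotation budget.

The package also ships six parametric image degradations (fog, Gaussian
noise, defocus, motion blur, power-law brightness, HSV color jitter) for
robustness studies, a pixel-level evaluation suite (accuracy, precision,
specificity, sensitivity, AUROC, DSC, IOU, clean-fraction Pearson
agreement), and a synthetic-scene generator with known ground truth so the
whole pipeline is testable without any dataset download.  See
`docs/methods.md` for the full model description.

## Worked example

```python
import wceclean as wc

# 100 synthetic 96x96 frames with ground-truth masks (known palettes)
scenes = wc.generate_scenes(100, height=96, width=96, seed=0)
images = [s.image for s in scenes]
masks = [s.mask for s in scenes]

# repeated-trial protocol: cluster, select 10 fitting frames, fit, evaluate
reports = wc.run_trials(images, masks, n_trials=2, k=10, seed=0)
print(reports[0].mean)

# score one held-out frame
model = wc.fit(images[:10], masks[:10])
pred, p_clean = wc.segment(images[20], model, fov=scenes[20].fov)
print(wc.clean_fraction(pred, scenes[20].fov))
```

This prints, for the first trial,

```
{'accuracy': 0.998, 'precision': 0.986, 'specificity': 0.998,
 'sensitivity': 1.0, 'auroc': 1.0, 'dsc': 0.993, 'iou': 0.986}
0.3344
```

meaning: on the 90 held-out frames the classifier labels 99.8% of pixels
correctly, overlaps the true clean region with Dice 0.993, and scores this
frame as 33.4% clean (ground truth: 33.0%).  The default synthetic
palettes are well separated (Mahalanobis distance ~6), so near-perfect
scores are the expected behaviour; `wc.overlapping_palettes()` provides a
harder regime whose error rate matches the mixture's Bayes risk.

A CLI mirrors the library:

```bash
wceclean simulate --n 100 --size 96 --seed 0 --out-dir fixtures/
wceclean select-frames --manifest fixtures/manifest.csv --k 10 --seed 0 --out selection.json
wceclean fit --manifest fixtures/manifest.csv --selection selection.json --out model.json
wceclean segment --model model.json --image fixtures/scene_00020.png --out-mask pred.png
wceclean corrupt --manifest fixtures/manifest.csv --scenario all --seed 0 --out-dir corrupted/
```

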