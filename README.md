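# matpercept

Analysis toolkit for a translucency-perception psychophysics workflow:
binary translucent/opaque classification agreement, six-point semantic
attribute ratings, material categorization, and the associated image
colorimetry — driven either by response tables on disk or by a seeded
synthetic observer simulator, so the entire pipeline is testable offline.

## What it does

- **core_data** — panel data model (binary votes, Likert ratings, category
  choices per observer x image x condition) with strict validation and
  CSV round-tripping.
- **agreement** — percent agreement, 60%-threshold T/U/O image labels and
  label flips between color and grayscale, normalized-Hamming RDMs,
  pairwise Cohen's kappa with agreement-level binning, one-sided
  Mann-Whitney U region comparisons.
- **rating_stats** — per-image rating distributions (add-one smoothing),
  KL divergence of grayscale from color with the D_KL > 1 rule, skewness
  shift between conditions, Kendall tau-b correlations, and the
  Bonferroni-corrected (alpha = 0.05/10 = 0.005) attribute correlation
  matrix.
- **perceptual_space** — PCA of mean ratings, per-observer PCA on
  polychoric correlations (two-step pairwise ML), per-observer 3-fold
  stratified-CV logistic prediction of the observer's own binary labels
  with Wald-test attribute significance, t-SNE embedding.
- **categorization** — 18-name category vocabulary, regrouping into 8
  major categories (chalk/wood discarded), misjudgment counts against
  ground truth, food vs non-food binarization, person-by-person
  categorical RDMs.
- **colorimetry** — CIELab-lightness decolorization (D65), CIELCh
  lightness/chroma extraction, CIE u'v' saturation vs luminance Pearson
  correlation, and a saturation-luminance blending transform that
  preserves hue, luminance, and the saturation mean/SD.
- **synthetic** — seeded generators for observer panels (latent
  translucency continuum, grayscale signal attenuation + noise inflation,
  category confusion with extra food/non-food flips in grayscale) and
  Beer-Lambert cube stimuli with negative saturation-luminance
  correlation.
- **pipeline** — runs all stages in order and emits one JSON report.

## CLI

```bash
matpercept simulate --out sim/ --seed 3          # synthetic panels + cube.png
matpercept validate sim/color --condition color
matpercept agreement sim/color sim/grayscale --out agreement.json
matpercept ratings sim/color sim/grayscale
matpercept space sim/color sim/grayscale --seed 0
matpercept categories sim/color sim/grayscale
matpercept image cube.png gray.png --op gray     # also: lch, satlum, blend
matpercept run --out report_dir/ --seed 0        # full pipeline
```

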