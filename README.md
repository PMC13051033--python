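# morphgaze

Tools for studying which facial features drive social impressions
(attractiveness, dominance, sexual dimorphism) with three complementary
lenses on one data substrate:

1. **Geometric morphometrics** — faces digitized as 52 main landmarks (plus
   87 semi-landmarks for smooth imaging) are superimposed by generalized
   Procrustes analysis; the aligned coordinates are regressed on impression
   ratings, significance is assessed by permutation, and the fitted slope
   field generates morphed stimulus images at ±k SD of the rating via dense
   thin-plate-spline warping.
2. **Eye tracking** — gaze sample streams are parsed into fixations,
   saccades and blinks (30 °/s velocity and 8000 °/s² acceleration
   thresholds); duration-weighted fixation heatmaps are contrasted across
   morph conditions per pixel with Benjamini–Hochberg FDR control, and
   ratings are modelled with a crossed-random-intercepts linear mixed model.
3. **CNN attention** — a six-convolution regression network (batch norm
   after every convolution, max-pool after every second, linear scalar
   output) is trained to predict ratings from images; Grad-CAM extracts the
   image regions driving its predictions, and those attention maps are
   compared with human fixation maps via Kullback–Leibler divergence and
   per-AOI correlation.

A synthetic-face module generates every input with known ground truth —
landmark populations with a planted shape–score displacement field,
schematic face renders, ratings from a known mixed model, and gaze streams
from AOI-weighted fixation mixtures — so each stage of the pipeline can be
validated quantitatively.

## The core models

**Shape regression.** After Procrustes alignment (translation, scale and
rotation removed; reflections disallowed), each face is a point
`x_i ∈ R^{2k}`. The model is per-coordinate least squares on the centered
score `s_i`:

    x_i = μ + β (s_i − s̄) + ε_i

with variance explained `SS_model / SS_total` on the Procrustes sum of
squares and permutation p-values from refitting under score shuffles. A
morph at level `m` (in SD units) is `μ + β · m · sd(s)`, mapped back through
each face's stored similarity transform and rendered by backward TPS
warping.

**Rating mixed model.** `rating ~ morph × image_sex × participant_sex` with
crossed random intercepts for participants and stimuli (sexes coded −0.5 /
+0.5), fitted by profiled restricted maximum likelihood.

**Attention vs. gaze.** Both map families are normalized to probability
grids (`+ε`, sum 1) and compared by `D(fixation ‖ attention) = Σ p log p/q`
(direction labelled, both directions reported) and by correlating per-AOI
mass vectors over eight landmark-derived facial regions.

## Worked example

```python
import numpy as np
from morphgaze import synth, shape_core, impression

cfg = synth.SyntheticWorldConfig(n_faces=300, seed=2)
faces, scores, truth = synth.sample_population(cfg)
aligned = shape_core.gpa_align(faces)
labels = [impression.ImpressionLabel(image_id=f.image_id, trait="dominance",
                                     score=float(s))
          for f, s in zip(faces, scores)]
model = impression.fit_shape_regression(aligned, labels)
p = impression.permutation_test(aligned, labels, n_perm=999, seed=0)
r = np.corrcoef(model.slopes.ravel(), truth["beta_true"].ravel())[0, 1]
print(f"variance explained: {model.variance_explained_pct:.1f}%")
print(f"permutation p:      {p:.4f}")
print(f"slope recovery r:   {r:.3f}")
```

prints

```
variance explained: 99.1%
permutation p:      0.0010
slope recovery r:   0.998
```

With the default generator the planted eyebrow-raising field dominates the
small landmark noise, so the regression explains almost all Procrustes
variance, the permutation test is maximally significant (p = 1/(n_perm+1)),
and the estimated slope field is essentially the planted one. Real face
samples sit in a very different regime (a rating explains a few percent of
shape variance at most); the generator's `landmark_noise_sd` controls this.

The command line mirrors the library:

```bash
morphgaze make-world world/ --n-faces 20 --n-participants 6 --n-trials 30
morphgaze run-all world/ out/ --epochs 10
```

`run-all` executes the three analysis stages and writes a manifest of every
artifact with content hashes and seeds.

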