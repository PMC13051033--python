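# Methods

This note documents the models, the numerical choices, what the synthetic
world does and does not emulate, and the known limitations. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Landmark geometry

Faces are digitized as 52 anatomically homologous main landmarks plus 87
semi-landmarks carried along contours for smooth imaging. All shape
statistics use only the main landmarks; semi-landmarks are transported by
the thin-plate spline fitted on the main landmarks whenever a shape is
deformed. No semi-landmark sliding (bending-energy or perpendicular
projection) is performed.

**Generalized Procrustes analysis.** Each configuration is centered, scaled
to unit centroid size, and rotated to the evolving mean by the optimal
proper rotation (SVD of the cross-covariance with the determinant forced
+1 — faces must never mirror). The mean is re-estimated and renormalized to
unit size each sweep; iteration stops when the mean moves less than 1e-8
RMS (at most 100 sweeps; deterministic initialization from the first
shape). Because the iteration's frame would otherwise inherit the first
shape's orientation, the converged solution is re-oriented into a canonical
frame computed from the mean shape itself (the baseline from landmark 0 to
its farthest landmark is rotated onto +x). This makes the output invariant
under similarity transforms of any input, which the test suite checks to
1e-8. The returned mean shape is the exact coordinate-wise average of the
aligned sample (its centroid size is slightly below 1; it is not
renormalized). Tangent-space projection is available
(`AlignedShapeSet.tangent_projected`) but off by default: face-shape
variation is small enough that Procrustes residuals serve directly as the
regression's dependent variables.

**Thin-plate splines.** The exact interpolant with kernel U(r) = r² log r²
(U(0) = 0), solved from the standard bordered system. The system is formed
in centered, unit-RMS-scale coordinates — the TPS interpolant is invariant
under similarity transforms of the frame (given the side conditions), and
normalization keeps the bordered matrix well conditioned even for dense
pixel-scale control sets; without it, ~150 control points in raw pixel
coordinates produce visible oscillation between control points. Bending
energy is the quadratic form of the kernel weights (reported in normalized
units; zero iff the map is affine). Degenerate systems are detected by the
control-point residual, not by a condition-number heuristic.

## Shape-on-score regression

Single-predictor least squares of every aligned coordinate on the centered
impression score, fitted separately per trait and per face sex. Variance
explained is `SS_model / SS_total` on the Procrustes sums of squares. The
score SD uses the population convention (divisor n), matching the "±k SD"
framing of morph levels; this is configurable. The permutation test
shuffles scores across faces (default 10,000 draws; the identity is not
forced into the set) and uses the add-one convention
p = (1 + #{perm ≥ obs}) / (1 + n_perm), so p is never zero. The permuted
statistic is computed by a closed form (‖residᵀ s_perm‖²/‖s‖²), which makes
500-dataset calibration runs cheap.

Morph targets displace the mean shape (or a single face's aligned shape) by
`slopes × level × SD`; per-face targets return to the face's own pixel
frame through its stored similarity transform, so pixel displacement scales
with the face's Procrustes scale.

## Image morphing

Dense warps use backward mapping: a TPS is fitted from the target landmark
set to the source set (main + transported semi-landmarks jointly), sampled
at every output pixel center, and the source is bilinearly interpolated.
Eight stationary anchors (corners + edge midpoints) prevent edge collapse.
Samples within half a pixel of the border take the edge value; genuinely
out-of-source samples are filled with the background colour (default
mid-grey). Oval clipping fits an axis-aligned ellipse to the main-landmark
bounding box with 5% padding. Composites warp every face to a reference
shape and average pixels.

## Gaze statistics

**Event parsing.** Blinks are maximal invalid runs. Velocity is computed by
central differences within each valid run (the two-sample span is the only
smoothing — this keeps detected event boundaries within one sample of an
instantaneous jump); acceleration is the central difference of that
velocity. Samples above 30 °/s or 8000 °/s² are saccade samples; remaining
runs of at least 50 ms are fixations (duration-weighted centroid), and
shorter residual runs are absorbed into the saccade class so the three
event classes exactly partition the trace.

**Fixation maps.** Each fixation deposits its duration at its centroid
pixel; condition sums are convolved with an isotropic Gaussian (default
0.5° of visual angle, converted through px_per_deg; the right kernel width
is an empirical choice and the pixel-contrast calibration uses ~0.6° —
narrower kernels leave too little pooled evidence per pixel for a
48–64 px raster).

**Pixel-wise contrasts.** The full per-pixel mixed model of the
condition contrast is simplified to its paired core: within each
participant, the mean map over positive-morph trials minus the mean over
negative-morph trials; per pixel, a one-sample two-tailed t across
participants; Benjamini–Hochberg step-up across pixels at q = 0.05.
Participants observed in only one cell are dropped with a warning. Sign
convention: beta > 0 where gaze is heavier on the positive-SD side.
Constant pixels yield p = 1. Note the knife-edge behaviour inherent in BH
on spatially smoothed maps: as the signal cluster's minimum p crosses the
step-up threshold, the admitted cluster grows discontinuously.

**Rating mixed model.** rating ~ morph × image_sex × participant_sex with
crossed random intercepts for participants and stimuli; sexes coded −0.5
(male) / +0.5 (female). The fit is profiled REML: with V = σ²(I + θ_p Z_p
Z_pᵀ + θ_s Z_s Z_sᵀ), fixed effects and σ² are profiled out analytically
through the Woodbury identity (all linear algebra on the (participants +
stimuli)-dimensional inner matrix), leaving a 2-parameter Nelder–Mead
search over the log variance ratios. A fit at the default design scale
(35 × 240) takes ~40 ms, which is what makes 100-replicate coverage checks
routine. Fixed effects are reported as estimate / SE / t without
denominator-df p-values (df conventions for crossed designs differ between
packages). The implementation is cross-checked in the test suite against
statsmodels' variance-components MixedLM on a small design. All-constant
ratings return zero slopes with a singular flag; variance ratios at the
boundary also set the flag.

## CNN scorer and Grad-CAM

The scorer is six 3×3 convolutions (same padding), each followed by batch
normalization and ReLU, with 2×2 max-pooling after every second
convolution, then a single linear output unit on the flattened features.
Default filters (32, 32, 64, 64, 128, 128); default input 96×96×3, with
64×64 used throughout the validation battery for speed. Training is
mini-batch Adam (lr 0.001, batch 16) on mean-squared error with a fixed
epoch schedule and no early stopping; all shuffling and initialization is
seeded. Forward and backward passes are written directly in NumPy (im2col
convolutions), which keeps inference deterministic and gives Grad-CAM exact
gradients.

Two choices matter for attribution hygiene:

- **Zero-initialized readout.** The final linear layer starts at zero, so
  readout weight accumulates only on features whose gradients correlate
  with the labels during training. With a random readout, features that
  never influence learning retain arbitrary weight and contaminate
  gradient-based attribution maps.
- **Sign disambiguation (`sign="auto"`).** Grad-CAM rectifies the
  gradient-weighted activation sum. For a class logit the positive
  direction is privileged; a regression output has no such privilege —
  evidence may legitimately drive the score down, and the raw rectification
  can then discard the informative side of the field wholesale. The default
  therefore keeps the side of the field carrying the larger energy;
  `sign="positive"` restores the classification-style convention, and the
  two agree whenever the field is predominantly positive.

Even with both, localization of a *planted* signal is imperfect: Grad-CAM
weights whole channels by their mean gradient, so every location where a
signal-carrying channel activates receives credit. On schematic faces whose
label signal is a sub-pixel eyebrow displacement, the measured share of
mean attention mass inside the dilated eyebrow region varies with
initialization (roughly 0.3–0.7 across seeds in our experiments; the
validation battery reports the value measured at its seed). This is a
genuine property of channel-global gradient attribution at coarse feature
resolution, not of the training accuracy, which is consistently near 1 in
the memorization regime.

Attention significance uses a per-pixel one-sample t-test (one-tailed
"greater" for rectified maps; two-tailed for signed difference maps) with
BH FDR. The 0–255 view of a map is for rendering only; statistics always
use the unscaled rectified map, because per-image min-max scaling would
distort cross-image averages.

## Comparing attention with gaze

Maps are normalized to probability grids by adding ε = 1e-8 to every cell
and dividing by the total (ε recorded for audit). KLD is Σ p log(p/q) in
nats; the default direction is D(fixation ‖ attention) and both directions
plus the symmetrized mean are always reported, since the divergence is
asymmetric. AOIs (eyes, eyebrows, glabella, nose, mouth, cheeks, chin,
forehead) are landmark-derived convex hulls dilated by a configurable
radius; an `exclusive` mode resolves overlapping pixels to the nearest
feature, which matters for mass correlations — overlapping masks couple the
mass vectors structurally. With only eight AOIs, a single condition's mass
correlation has a null |r| around 0.3 purely from small-n; the
pooled-across-conditions form is the statistically meaningful one.

## The synthetic world

The generator mirrors the emulated study design: 80 base faces, impression
scores on the 1–7 scale (mean 3.5, SD 0.7), 35 raters (16 male / 19 female)
rating 240 trials each over 3 traits × 5 morph levels (−3, −1.5, 0, +1.5,
+3 SD), 5000 ms of viewing per trial, gaze sampled at 1000 Hz with
~35 px/degree. Rating-model defaults: morph slope 0.12 per SD level,
image-sex effect 0.14, participant and stimulus intercept SDs 0.5 and 0.3,
residual SD 1.0; ratings are rounded and clipped to 1..7.

The score-linked displacement field raises the eyebrows by 0.012 face-box
units per score unit. By default the field is projected off the similarity
subspace at the template (translation/scale/rotation components removed):
a displacement with a net translation component would be partially absorbed
by the superimposition, and the projected field is the one a shape analysis
can actually recover. For image-localization experiments the unprojected,
strictly-eyebrow-local variant is used instead so that rendered ground
truth is exact. Landmark noise defaults to 10% of the RMS signal
displacement at one score SD.

Gaze streams alternate fixations (AOI drawn from the weight table, position
Gaussian around the AOI center with 0.6° scatter, duration
truncated-normal 250 ± 80 ms, floor 100 ms) with 30 ms saccade transits;
5% of transits are replaced by 150 ms blink gaps. Re-fixations closer than
a 2° amplitude floor extend the ongoing fixation instead of creating an
unresolvable micro-event, keeping generator truth commensurate with what a
velocity-threshold parser can see.

What the world does **not** emulate: photorealistic texture, identity
variation beyond landmark noise, appearance cues uncorrelated with shape,
race and age structure, head pose, calibration drift, or pupillometry.
Passing tests therefore demonstrate the statistical machinery's
correctness and calibration — not that the pipeline's effect sizes
generalize to real face photographs.

## Validation battery sizes

The battery (`morphgaze.validation`, driven by `scripts/acceptance.py`)
uses: 1000 random TPS warps; 20 GPA sets; 500 null datasets of 20 faces at
199 permutations; 300 faces for slope recovery; 100 replicates at 35 × 240
for the rating model; 200 simulated gaze trials; 50 null pixel-contrast
simulations plus one planted-effect run (20 participants, 10 trials per
cell, eye-region weight +0.40); one CNN run of 200 faces at 64×64 (40
epochs); 1000 random distribution pairs and 100 paired ordering simulations
for KLD; 1000 random p-vectors for the FDR oracle. These sizes were chosen
so the whole battery reruns in minutes on a single core while leaving each
check statistically meaningful.

## Known limitations

- The pixel-contrast simplification (paired t over participants) does not
  model stimulus crossed effects within pixels; iMap-style cluster
  enhancement is out of scope.
- The mixed model is Gaussian; ordinal 1–7 ratings are treated as metric,
  as is conventional for 7-point impression means.
- Grad-CAM localization instability for regression outputs is documented
  above; per-element attribution methods would localize better but are
  different estimators, not the one implemented here.
- TPS warps are exact interpolants: with badly inconsistent landmark sets
  they will fold; no diffeomorphic regularization is applied.
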