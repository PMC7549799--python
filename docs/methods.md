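# Methods

This note records the models, parameter choices and numerical decisions
behind `finid`, and what the synthetic benchmark does and does not show.

## Problem setting

Blue whale photo-identification assigns a photograph of a dorsal fin to one
of six shape classes: {falcate, hooked, triangular} × {right, left flank}.
The fin outline is the identifying structure; pigmentation is deliberately
ignored (it changes with molt, temperature and salinity).  The pipeline is
a reduced SIFT feature extractor feeding a nearest-centroid classifier,
chosen for portability: every stage is simple arithmetic on small rasters.

## Scale space and statistical pruning

The ROI is smoothed with Gaussians at σᵢ = σ₀·kⁱ, σ₀ = 1.6, k = √2, in a
single octave — no downsampling pyramid, so all DoG layers share one raster
shape and one pooled statistic is well defined across them.  Six levels are
used (five DoG layers, three of them interior and therefore searchable for
3×3×3 extrema).  Five levels would leave only two interior layers and
measurably fewer, less stable keypoints; six is the classic
three-scales-per-octave configuration.

The pruning threshold is the pooled population standard deviation of the
DoG stack about its per-pixel mean across the scale index,

    sigma_D = sqrt( sum_m sum_xy (D_m(x,y) - Dbar(x,y))^2 / (n_layers * n_pixels) ),

dividing by the total number of scalar samples.  A per-level variant (one
sigma per DoG layer) is available via `scale_space.pooling: per_level`.

The comparison `D <= sigma_D` supports two readings, and the package ships
both:

* `abs_le` (default): the comparison identifies **redundant** samples —
  anything with |D| ≤ σ_D is eliminated, keeping the salient minority.  On
  synthetic fins σ_D ≈ 0.007 while genuine extrema have |D| ≈ 0.05–0.10,
  so this prunes ~18% of samples and ~18% of extremum candidates with no
  measurable change in end-to-end accuracy — the data-reduction behaviour
  the method is designed around.
* `signed_le`: the comparison read literally as a retention rule (keep
  D ≤ σ_D).  This keeps strong negative responses but discards strong
  positive ones; it is retained as a config option and in tests, but it
  measurably degrades accuracy and is not the default.

## Keypoints

Candidates are strict 26-neighbor extrema among retained samples on
interior DoG layers, excluding a 4-pixel border.  Localization solves
ẑ = −H⁻¹∇D with finite-difference derivatives in (x, y, scale), stepping
to the neighboring sample while any offset component exceeds 0.5 (at most
5 iterations).  The linear solve uses a pseudo-inverse with a residual
consistency check: a Hessian that is exactly singular along a flat
direction (common on separable or planted inputs) gets a zero offset in
that direction, while genuinely inconsistent systems are rejected.
Rejections also cover non-convergence, out-of-bounds refinement and
refined contrast |D(ẑ)| < 0.03 (on [0, 1] luminance; the classic value).
Principal-curvature (edge-response) filtering is off by default — fin
contours are edges, and discarding edge keypoints would discard the
signal — but can be enabled via `features.edge_response_threshold`.

Gradients use unnormalized central differences (M = 2 on a unit ramp) with
replicate border padding, and full-circle orientations from atan2.
Orientation assignment histograms gradient angles into 36 bins over a
Gaussian window (σ = 1.5 × keypoint scale, radius 3σ), magnitude- and
distance-weighted; every bin reaching 80% of the peak spawns an oriented
keypoint copy (`peak80`).  A `literal_mean` mode thresholds bins at
0.8 × the plain window mean of the angle values instead; the rule mixes an
angle average with histogram mass and is dimensionally odd, but it is kept
as a faithful alternative reading of the 80% criterion.

Descriptors sample a 16×16 grid with spacing equal to the keypoint scale,
rotated into the keypoint frame, accumulating bilinearly interpolated
gradient magnitudes into 4×4 spatial cells × 8 relative-orientation bins
with trilinear soft assignment, weighted by a Gaussian of σ_G = half the
window width (`half_window`; `half_scale` = 0.5 × keypoint scale is a
config alternative).  Vectors are L2-normalized, clamped at 0.2 and
renormalized.  Descriptor length is fixed at 128.

## Classifier

Training pools all descriptors of all training images of a class and takes
the elementwise mean (default) or median — the "median estimation"
aggregate — as the class centroid.  The sample-to-class distance is the
sum over sample descriptors of the squared Euclidean distance to the
centroid; the prediction is the arg-min over the six classes, ties
breaking toward the declared class order (right/left falcate, hooked,
triangular).  With one training image per class this reduces exactly to a
minimum-distance nearest-exemplar classifier.  The K-NN baseline scores a
training image by the sum over sample descriptors of the minimum squared
distance to that image's descriptors, takes the K nearest images and
majority-votes (vote ties resolve by smallest summed distance).

## Evaluation

Image-level six-class results are evaluated one-vs-rest: each class in
turn is positive, yielding TP/TN/FP/FN and Sp = TN/(TN+FP),
Se = TP/(TP+FN), Acc = (TP+TN)/N per class — the layout in which per-class
triplets are always defined.  Metrics with a zero denominator are reported
as explicit `None` markers, never silently zero.  Cross-class dispersion
is the population standard deviation of the six accuracies (consistent
with the divide-by-n convention used for the scale threshold).

ROC curves need a per-class score.  The raw summed distance is confounded
by descriptor count — an image with many descriptors is far from every
centroid — which empirically inverts one-vs-rest rankings.  The report
therefore ranks by the classifier's decision margin per descriptor,
(min over other classes of the distance − class distance) / n_descriptors:
a monotone function of the decision rule (positive exactly when the class
wins) and comparable across images.  The `roc_curve` operation itself is
generic (any scores, threshold sweep with tie grouping, trapezoidal AUC;
scikit-learn provides the sweep, and tests cross-check the AUC against
all-pairs counting).

## Synthetic fins

The generator emulates the six classes with a two-Bézier outline over a
straight base.  Choices, and why:

* **tip_curl bands** — triangular [0, 0.15], falcate [0.35, 0.6], hooked
  [0.75, 1.0] — map one scalar to the three families: trailing-edge
  concavity grows linearly with curl, and the tip droops into an overhang
  once curl passes 0.55.
* **Backward rake** (tip offset (0.38 + curl) × base width): real dorsal
  fins lean toward the tail, so even a triangular fin is chiral; without
  rake, low-curl fins are bilaterally symmetric and the left/right
  distinction is unlearnable in principle.
* **Class-banded base widths** (falcate 0.58–0.68, triangular 0.50–0.60,
  hooked 0.42–0.52 × fin height) reflect the field taxonomy: falcate blades
  are long-based, hooks narrow-based.
* **Back ridge**: a one-sided band at the base, receding and sloping down
  behind the fin, as the whale's back appears in real ROIs.  It is the
  strongest chirality cue after rake.
* **Dome shading**: interior luminance rises linearly with distance from
  the outline (0.15 at the edge to 0.60 on the medial ridge).  Fins are
  three-dimensional; a flat silhouette would give the difference-of-
  Gaussians nothing to respond to inside the outline, and the shading
  iso-contours follow the class-specific shape.
* **Pose jitter**: rotation uniform in ±15°, scale uniform in [0.8, 1.25]
  (ROI cropping roughly normalizes fin size), per-sample seeds derived as
  base_seed × 10000 + index; no global random state.
* **Noise and background**: zero-mean Gaussian pixel noise (σ = 0.02 for
  the standard benchmark) over a flat bright background by default;
  `sea_texture` mixes three low-frequency sinusoids to emulate sea-surface
  shading for low-contrast stress tests.
* **Ground truth**: the one-pixel outline of the noise-free silhouette,
  and the exact mirror construction of left-flank classes (left renders
  are bitwise flips of right renders).

What passing the synthetic benchmark shows: the pipeline recovers shape
classes separated by outline geometry and shading under moderate pose
jitter and noise, and the statistical pruning does not destroy that
signal.  What it does not show: robustness to real-sea clutter, partial
occlusion by waves, motion blur, specular highlights, variable lighting
direction, or fin marks and notches — real photographs are substantially
harder, and reported benchmark numbers should not be read as field
performance.

## Problem sizes and determinism

The standard study is 6 classes × 20 training + 20 test images at
160×160 px, noise σ = 0.02 — small enough to run end to end in well under
a minute while keeping ≥ 100 test images.  All stages are deterministic
given the configuration and seeds; descriptor order is fixed by
(level, y, x, orientation).  Artifacts (descriptor files, models) are
versioned JSON carrying a SHA-256 hash of the extraction configuration,
and classification refuses a model whose hash does not match the active
settings.

## Known limitations

* Single octave: very large or very small fins relative to the ROI shift
  keypoints across the fixed σ range rather than into other octaves; crop
  ROIs reasonably tight.
* The centroid classifier summarizes each image by (effectively) its mean
  descriptor; it cannot exploit descriptor correspondence or geometry, by
  design (portability).  K-NN partially compensates at higher cost.
* `literal_mean` orientation thresholding and `signed_le` pruning are
  faithful alternative readings kept for comparison, not recommended
  defaults.
* The contour extractor is a generic gradient-threshold / largest-component
  stand-in, adequate for high-contrast fins; it is not a learned or
  model-based segmenter.
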