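# Methods

This note documents the models and procedures implemented in `landloc`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic experiments do and do not show.

## Problem setting

Anatomical landmark localization (ALL): predict the pixel coordinates of
L = 37 named skeletal points in a 2-D hand radiograph. Deep heatmap
regression solves most of the problem, but rare far-off-target predictions
("outliers") are disproportionately harmful to downstream clinical use, so
the toolkit's focus is explicit anatomical constraints that filter
anatomically infeasible predictions — during inference and, where the
refiner is differentiable, during training.

## Metric layer

Images carry no physical resolution; each image j gets a scale
`s(j) = 50 / ||l2(j) − l6(j)||` (mm per pixel), i.e. the wrist pair is
defined to span 50 mm. The point-to-point error of a prediction is
`PE = s(j) · ||p − t||`. Aggregates are the median, mean, and standard
deviation of PE plus counts/percentages of predictions strictly farther
than r ∈ {2, 4, 10} mm from their targets. Choices:

- SD is the sample standard deviation (ddof = 1); at the n > 10⁴ sizes of
  the three-fold protocol the population/sample distinction is negligible,
  and the sample convention is the comparison-literature standard.
- The outlier comparison is a strict `>`: an error exactly at the radius
  is not an outlier.
- Percentages are reported at two decimals (three where the value is
  below a hundredth of a percent); full precision is kept internally.
- The metric layer treats every supplied error equally; masking of
  invisible landmarks is the caller's decision, and the occlusion
  protocol deliberately does not mask.

## Heatmap codec

Targets are image-sized grids, zero except for a blob of peak γ = 1000 at
the annotation: `γ·exp(−d²/2σ²)` (Gaussian, σ = 3 px default) or
`γ·exp(−d/σ)` (Laplacian option). Blobs are evaluated over the whole frame
(no truncation radius). Decoding:

- `decode_argmax`: integer pixel of the maximum, ties broken to the first
  in row-major order (deterministic tests need a rule).
- `soft_argmax_dsnt`: rectify to non-negative, normalize to unit sum, take
  the expectation of the coordinate grid. The default rectifier is
  `max(x, 0)`: it is exact on the codec's contract cases (a one-hot map
  decodes to that pixel, two equal masses to their midpoint, a uniform map
  to the frame centre) and makes the decoded point the exact centroid of a
  non-negative map. A Softplus rectifier is available when strictly
  positive gradients are needed, but its floor ln2/β contributes
  appreciable background mass on large frames and biases the expectation
  toward the centre — measurably wrong for blob decoding, which is why it
  is not the default. A `softmax` rectifier (`exp(βx)` weights) serves
  log-energy maps, whose background is negative; the refiner uses it with
  β = 5, matching its energy-domain rectifier.
- Coordinate convention everywhere: 0-based, (u, v) = (column, row),
  pixel centres at integers.

## Localizer

A U-Net with per-level double convolution blocks (3×3, stride 1 → batch
normalization → leaky rectifier slope 0.1 → dropout), 2×2 average pooling
down, fixed bilinear upsampling up, and skip concatenation (the first
decoder convolution of a level sees twice the base width). The head is a
linear 3×3 convolution to L full-resolution heatmaps. Same-padding with
zeros keeps every level's spatial size; weights are Kaiming fan-in
initialized under a fixed seed. Training: MSE on heatmaps with
visibility masking (landmarks warped out of the frame contribute neither
loss nor gradient), Adam at lr 10⁻³, batch 8, a fixed epoch count with no
early stopping. Reference configuration: 4 levels × 128 channels at
256×256 input.

The package's numerical engine is a small reverse-mode automatic
differentiation library over numpy arrays (`landloc.nn`): elementwise ops,
stable softplus/log-softplus, reductions, im2col-based convolution, fixed
linear resampling expressed as cached interpolation matrices, and an
FFT-based large-kernel convolution. Gradient correctness is pinned by
finite-difference and brute-force tests rather than symbolic derivation.
Float32 is used throughout the engine.

## Conditional priors

For each ordered pair (i, j ∈ N_i) required by the graph, every training
annotation contributes `centre + (l_i − l_j)` on a grid of twice the
image resolution (doubling keeps all displacements on-grid after the
translation that moves l_j to the centre). Each training image is sampled
three times under spatial augmentation only — intensity changes do not
move coordinates and occlusions do not move landmarks. Gaussian mixtures
with 1..10 components are fitted (scikit-learn, k-means init, fixed
seed); the component count minimizing the mean of AIC and BIC is kept,
ties toward fewer components. The selected density is evaluated at pixel
centres with no normalization to unit sum: the grids are used as energies
and as convolution-kernel initializations, where a global scale is
absorbed. A covariance ridge of 10⁻³ px² guards degenerate clusters.

## The sum-product refinement layer

The landmark MRF has a vertex per landmark; every pixel is a candidate.
One sum-product iteration in log-energy space refines the heatmaps:

    mê_i = me_i + Σ_{j∈N_i} log( SP_β(p_i|j) ∗ SP_β(p_j) + SP_β(b_j→i) + ε )
    me_i = log SP_β(p_i + ε),   SP_β(x) = (1/β) log(1 + e^{βx})

with β = 5, ε = 10⁻⁶, `∗` true convolution with the double-size prior
kernel, and b_j→i a learnable per-message bias grid initialized to ε.
N_i is the union of the graph neighbours of i and a fixed global set
(wrist pair, MCP row, fingertips; 12 landmarks) minus i itself — the
global messages are what keeps an occluded region placeable. The result
stays in log space; exponentiating back would not move the maximum.
Coordinates are decoded with the softmax soft-argmax and trained with MSE
on coordinates; with a localizer attached the total loss is
`heatmap MSE + λ·coordinate MSE`, λ set once from the first batch so both
terms start at the same magnitude, then frozen.

Numerical realization:

- Messages run at a bicubically downsampled working resolution
  (down-factor 4 by default: 256 → 64 work, 128-sized kernels); the summed
  message energy is bicubically upsampled back before the addition with
  the full-resolution me_i, which preserves the localizer's accuracy.
- Prior kernels are stored a further factor (default 2) below the kernel
  extent and bicubically restored each forward pass, reducing learnable
  parameters; both factors are configurable, and setting both to 1 makes
  the layer bit-compatible with a literal nested-loop transcription of the
  energy update (the oracle test uses exactly that).
- The convolution is evaluated in Fourier space (zero-padded linear
  convolution cropped to the "same" centre window; circular wrap-around
  would leak energy across the image and is rejected). The kernel origin
  is its exact centre pixel, the single alignment rule, verified by a
  delta-shift test.
- Batch normalization (per-channel, affine) is applied to the incoming
  heatmaps to speed convergence; inference uses running statistics.
- Priors and biases are learnable (the priors initialize the kernels); a
  freeze flag supports ablation.

## Comparison refiners

**Graphical model (external, non-differentiable).** Candidates per
landmark are Laplacian-of-Gaussian blob peaks (scales σ ∈ {2, 3, 4} px,
matching the blob rendering), ranked by peak intensity; the top 25 are
kept and normalized peaks below 0.015 discarded. Pairwise costs on each
graph edge combine (a) a location-scale t distribution fitted to training
distances (scale floored at 10⁻² px) and (b) ratio terms against the
three reference edges with the smallest fitted scale: d_e is rescaled by
μ_f/d_f and scored under edge e's own distribution, averaged over the
references — invariant to global image rescaling. The exact ratio formula
and the unary/pairwise weighting are under-specified in the source
method; both are conventions here, isolated behind one function, with the
two cost families rescaled once per image to matched empirical ranges.
Inference is synchronous sum-product LBP in the log domain with damping
0.5, at most 100 iterations, convergence at 10⁻⁶ maximum message change;
non-convergence returns current beliefs with a warning. Marginals are
exact on trees (tested against exhaustive enumeration).

**SpatialConfiguration head (implicit).** The local heatmaps are average-
pooled to a coarse resolution, passed through three successive 7×7
convolutions (128 maps, batch normalization before each activation, no
internal downsampling), bilinearly upsampled, and multiplied elementwise
with the local heatmaps. The product is trained with the same heatmap MSE.

## Augmentation and occlusion training

Order: resize → spatial → intensity → occlusion. Spatial: uniform
translation ±10 px, rotation ±0.2 rad about the centre, elastic field
from a 5×5 control grid of ±20 px displacements under cubic-spline
interpolation, applied as a backward warp (stable resampling); landmark
coordinates go through the exact forward map, with the elastic part
inverted by fixed-point iteration, and landmarks leaving the frame are
flagged invisible. Intensity: min–max normalization to [−1, 1] (constant
images map to zero), one random shift in ±0.15 per image (a per-pixel
switch exists; the per-image reading was chosen as the more common
augmentation practice), then `v_new = v_old(1+v)` with one v per image.
Occlusion boxes: one rectangle covering 1–15% of the pixels, aspect ratio
in [0.5, 2] (unspecified by the source; avoids degenerate slivers),
position uniform, identical placement for every image of the batch,
filled with i.i.d. uniform noise over each image's intensity range.
Targets are never modified — the model must infer occluded landmarks.

## Occlusion test protocol

Fingers are five ordered chains (thumb 4 joints, others 5; 24 occludable
landmarks). Each finger enters with probability 1/5; a selected finger
loses a uniformly chosen contiguous distal suffix of its joint pairs
(possibly empty — a selected finger may stay intact). Each selected pair
(l_i, l_{i+1}) is erased by filled circles of radius r (10 px at 256,
scaled proportionally): with v = l_i − l_{i+1} and c = ⌊||v||/r⌋, centres
sit at l_{i+1} + k·v/c for k = 0..c. The floor rounding guarantees circle
spacing ≤ r·(1+1/c) so the strip is connected, and including k = 0 and
k = c covers both joints (a deliberate superset of "circles between the
joints": full-joint occlusion). Endpoints closer than r get a single
circle at the midpoint. Circle interiors become zero plus Gaussian noise
(σ = 0.02). Because plans are random, metrics are averaged over repeated
runs (30 per fold at full scale): outlier counts averaged, percentages
from averaged counts, everything reproducible under one seed.

## Synthetic hands

The generator emulates the dataset geometry needed by every stage: a
hand-designed 37-landmark template on a 256² frame (five finger chains,
carpal points, wrist pair at exactly 50 px so s ≈ 1 mm/px), per-image
global affine (rotation ±0.15 rad, scale 0.9–1.1, translation ±10 px),
per-landmark jitter (σ = 1.5 px), bone-like capsule ridges and joint
bumps, and Gaussian background noise (σ = 0.05). It does not emulate
radiographic texture, soft tissue, age-dependent ossification, or
annotation error; passing tests therefore demonstrate the machinery
(priors are learnable, refinement filters implausible peaks, occlusion
robustness from global messages) and not clinical-grade accuracy on real
radiographs.

## Scaled experiment sizes

The repository's end-to-end benchmark (`landloc.experiments`) runs the
full pipeline at a desk scale chosen so a run completes in a few minutes
on one CPU core: 60 synthetic images at 64×64, a 3-level × 16-channel
U-Net with dropout 0.1, blob targets σ = 2 / γ = 100, Adam at lr 3·10⁻³,
60 localizer epochs followed by 15 joint epochs with the refiner attached
(λ balancing at the first joint batch), priors from the training
annotations (mixtures capped at 3 components — the synthetic displacement
clouds are unimodal), refinement at down-factor 4, and an occlusion
evaluation with selection probability 0.2 averaged over 10 runs. The
lower γ and higher learning rate compensate for the two-orders-smaller
step budget of the scaled run: with a few hundred optimizer steps the
head cannot traverse the parameter distance that a γ = 1000 target scale
implies at lr 10⁻³, while the full-scale defaults (kept in the library
configs) assume tens of thousands of steps. Occlusion-box training is
disabled in this benchmark to isolate the refiner's contribution: the
comparison of interest is localizer-alone versus refined output under
occlusion.

## Known limitations

- The elastic warp inverts the backward field by four fixed-point
  iterations; for extreme control-point displacements (≫ 20 px on 256)
  image/landmark consistency degrades below the tested 1 px bound.
- The refiner's memory and time scale with |Σ N_i| messages (≈ 500 for
  the default graph at 37 landmarks); every added global landmark adds a
  message to every other landmark.
- `stats.t.fit` can be slow or flat for near-constant distances; the
  scale floor handles rigid datasets, but dof estimates are then
  arbitrary.
- Batch-normalization inference statistics come from training batches;
  evaluating on distributions very unlike training (e.g. unnormalized
  intensities) is unsupported — inputs are min–max normalized per image
  at prediction time.
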