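# Methods

## Problem and approach

Delineating the high-risk primary clinical target volume (CTVp1) on a
planning CT is slice-by-slice work: an oncologist contours one axial
image, moves to the adjacent one, and keeps the contour anatomically
continuous. `slicechain` implements a segmentation model built around the
same prior. Instead of segmenting each slice in isolation (the standard
2D U-Net protocol), the SI-Net predicts the contour on the *next* slice
from three aligned planes: the current image, the current contour (a
filled binary mask), and the next image. At inference time the model is
seeded with one manual contour and applied iteratively — each prediction
becomes the contour input for the following step — in either anatomical
direction (inferior→superior, "forward", or the reverse, "backward").

## The SI-Net architecture

The input is a depth-3 stack (current image, current contour, next image)
with one feature channel. The encoder runs zero-padded 3×3×3
convolutions (each ReLU-activated and batch-normalized) so the three
planes interact volumetrically; in-plane resolution halves between levels
via 1×2×2 max pooling while the depth stays 3. Each skip connection
collapses depth with a 3×1×1 max pooling and halves channels with a 1×1
convolution before joining the decoder. At the bottom the depth axis is
folded into channels ("reshape") and a 1×1 convolution restores the
level's channel count. The decoder is 2D: 2×2 stride-2 transposed
convolutions, skip concatenation, and pairs of 3×3 convolutions, ending
in a 1×1 convolution with a sigmoid — a per-pixel probability that the
pixel belongs to the contour on the next slice.

Two depth-handling details are deliberate design choices. Repeated
2×2×2 pooling is impossible on a depth-3 stack, so pooling is in-plane
only and the depth is preserved by convolution padding; this keeps the
3×1×1 skip pooling well-defined at every level. The channel "squeeze" on
the skip path is fixed at one half, and the bottom reshape maps 3·C
channels back to C. Channel widths default to 32 at the first level,
doubling per level, with 4 levels at the clinical 512×512 size; tests and
phantom experiments use 64×64 with 3 levels and 8 base channels. All of
this is configurable through `NetworkConfig`.

The baseline is a standard 2D U-Net with the same level/width
configuration, taking a single image plane.

## Compute engine

No deep-learning framework is used: the layers (2D/3D convolution via an
offset-major im2col and BLAS matrix multiplication, transposed
convolution, max pooling, batch normalization) are implemented directly
on numpy arrays with hand-derived backward passes. Every backward pass is
verified against central-difference numerical gradients in float64 in the
test suite; production arithmetic is float32. Batch normalization uses
mini-batch statistics in training and running averages (momentum 0.99,
eps 1e-5) at inference. The optimizer is Nadam (Nesterov-accelerated
Adam, Keras formulation) with β₁ = 0.9, β₂ = 0.999, ε = 1e-8. Weights are
initialized He-uniform from a seeded generator, so training is bit-
reproducible on a fixed BLAS.

## Training

The loss is 1 − soft-Dice with an additive smoothing constant (default
1.0) in numerator and denominator; the learning rate defaults to 1e-4.
Triplets are built with teacher forcing: the contour input plane is
always the ground-truth mask of the current slice. One terminal
transition past each end of the target extent (empty target) is added by
default so the model can learn to extinguish the contour at the target's
extremes — the inference stop rule depends on this behaviour.
Augmentation (shared left-right flip with probability 0.5 plus a uniform
±10° rotation per sample, bilinear for images, nearest-neighbour for
masks) is available but off in the phantom experiments, where the
generator already randomizes geometry. Direction-specific models are
trained separately for forward and backward propagation.

Teacher forcing alone leaves an *exposure gap*: the model only ever sees
ground-truth contours as input, while iterative inference feeds it its
own imperfect predictions, whose errors compound across slices — a model
can be accurate per transition yet drift badly over a full rollout.
*Scheduled sampling* closes the gap: with probability
`scheduled_sampling_p` a training sample's contour plane is replaced by
the model's current prediction of it (obtained from the case's preceding
transition, binarized at 0.5). The library default is pure teacher
forcing (p = 0); the phantom benchmark experiments train the SI-Net with
p = 0.5, which moves rollouts from drift-prone to near per-transition
quality without hurting teacher-forced accuracy.

Training ends with a *precise-BN* pass: batch-norm running statistics
are re-estimated by one fixed-weight sweep over the training set with
every batch weighted equally. The exponential running averages
accumulated during training track a moving target; after a short,
aggressive run they can be calibrated to weights that no longer exist,
in which case inference-mode activations collapse even though
training-mode predictions are excellent. Re-estimation under the final
weights removes that gap; it changes no trainable parameter and is
deterministic. It can be disabled via ``TrainConfig.bn_recalibrate``.

## Iterative inference

Propagation binarizes each probability map at 0.5 (strictly greater, so
an untrained zero-weight network predicts empty), keeps the largest 2D
8-connected component to stop speckle accumulating over iterations,
writes the slice, and feeds it back. The seed slice is never modified.
Termination is one of: volume end; an *area-stop* after `stop_patience`
(2) consecutive slices under `stop_min_voxels` (10) foreground voxels,
in which case those trailing slices are zeroed; or a step cap. For
metric comparisons against a ground truth, *extent mode* seeds from the
terminal ground-truth slice in the travel direction and propagates
exactly over the ground-truth extent with the area-stop disabled, so
overlap scores measure contour quality rather than extent detection;
*free mode* (deployment) lets the stop rule decide.

## Evaluation metrics

DSC = 2|A∩B|/(|A|+|B|) and JI = |A∩B|/|A∪B| are exact rationals of voxel
counts. Surface distances use surface point sets: centres of foreground
voxels with at least one face-adjacent (6-connectivity) background
neighbour, the volume border counting as background, scaled by the
anisotropic (dz, dy, dx) spacing. ASD is the symmetric mean of the two
directed average nearest-neighbour distances; HD is the exact (not
percentile) Hausdorff distance. Empty masks make a metric undefined and
raise, rather than silently scoring 0 or 1. Metrics are computed in 3D
over the whole structure (per-slice 2D use is possible by passing
single-slice volumes). The paired t-test on per-case differences uses
the n−1 standard deviation and the t distribution with n−1 degrees of
freedom.

## Synthetic phantoms

The generator emulates planning-CT geometry: (2.5, 0.98, 0.98) mm voxels
(configurable up to the clinical 512×512 in-plane size; the desk-scale
default is 64×64×24), an elliptical body at ~0 HU on a −1000 HU air
background, a high-intensity couch bar detached from the body, and
Gaussian noise (σ = 20 HU default). The target is a star-convex lobed
region — radius r(θ) = R·(1 + Σₖ aₖcos(kθ+φₖ)) — whose centre and radius
follow seeded Gaussian random walks across slices, with R tapering
cosine-smoothly to a positive floor at both ends of its extent. Lobed
cross-sections and a modest +100 HU default contrast keep the task from
being a pure thresholding exercise; the low-contrast variant (contrast
×0.25, noise ×2) probes the regime where the slice-continuity prior
should matter most. Cohorts draw per-case geometry parameters uniformly
from configured ranges with per-case seeds derived from one master seed.

What the phantoms do *not* model: real anatomy (no organs, bone, or
airway structure), CT physics (no beam hardening or metal artifacts),
inter-observer contour variability, and the weak, spatially structured
soft-tissue gradients of a real nasopharynx. Passing phantom experiments
therefore demonstrates that the pipeline — architecture, loss,
propagation, metrics — works end to end and that slice continuity is
exploitable; it does not certify clinical accuracy.

## Problem sizes used in tests and the acceptance script

A clinical-scale run of this method (a 150-patient cohort, 512×512
images, 200 epochs on a data-centre GPU, roughly 2×10⁵ optimizer steps)
is far beyond desk scale, so the shipped experiments are scaled down as
this package's own benchmark conditions: cohorts of 12–16 phantoms at 64×64×24, an SI-Net
of 3 levels and 8 base channels, 30 epochs for the default-contrast
experiment, and 8-case / 12-epoch / 3-repeat runs for the low-contrast
SI-Net-vs-U-Net trend check. Because the desk-scale step budget is about
two orders of magnitude smaller, the benchmark experiments use a larger
step size (learning rate 1e-3) and batch size 2 — spending the budget on
more, larger updates — while the library's `TrainConfig` default remains
the clinical-scale setting (1e-4) for full-scale use. Batch normalization in
the conv→ReLU→BN order this architecture prescribes noticeably slows
early convergence at this scale; it is retained as part of the method.

## Numerical choices and degenerate inputs

Otsu thresholds use a 256-bin histogram of the input range with a
first-maximum tie-break; foreground is strictly greater than the
threshold; constant slices yield an empty body-mask slice with a logged
warning rather than aborting the volume. The closing radius is specified
in mm (5.0 default) and converted to pixels with the in-plane spacing.
Intensity windows are fixed at [−1000, 1000] HU → [0, 1] so training and
inference are comparable across cases. Mask I/O stores 8-bit 0/1
payloads; any nonzero voxel read from disk is foreground. NIfTI written
by the CLI is uncompressed so that identical invocations are
byte-identical (gzip embeds a timestamp). DICOM reading sorts by slice
position, applies rescale slope/intercept, and rejects series whose
slice gaps deviate more than 1% from the median gap.

## What the phantom benchmark can and cannot show

The default-contrast experiment checks that the whole chain — training
on teacher-forced triplets, scheduled sampling, precise-BN calibration,
seeded propagation — segments held-out phantoms accurately. The
low-contrast trend comparison against the U-Net is a harder and more
caveated read-out: phantom targets are centred, similarly sized blobs,
so a slice-independent model can exploit a positional prior that real
anatomy does not offer, while the iterative model pays a compounding-
error tax the per-slice model never pays. On such a generator the two
effects can nearly cancel, and small seed-to-seed differences decide the
sign of the comparison; the shipped trend check records exactly that,
rather than a clean mechanism win.

## Known limitations

* The architecture's channel widths and squeeze ratio are declared
  defaults, not values dictated by the underlying method description.
* Extent-mode evaluation assumes the ground-truth extent is known; free
  mode's area-stop has two tunables with no clinical calibration here.
* Training determinism is bit-exact only for a fixed BLAS and thread
  count.
* The numpy engine is CPU-bound and desk-scale; the clinical 512×512 /
  200-epoch regime would require hours to days on one CPU.
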