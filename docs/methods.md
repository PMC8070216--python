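# Methods

## Problem and model

`osteoseg` detects and classifies bone tumors on knee radiographs. Given a
grayscale image `X`, the system predicts

* an image-level class `ŷ ∈ {normal, benign, malignant}`,
* a per-pixel tumor segmentation `Ŷ_seg ∈ [0,1]^{H×W×2}`, and
* a per-pixel *multi-level distance* field `Ŷ_dist ∈ [0,1]^{H×W×5}`.

All three heads share one encoder–decoder trunk (a Seg-Unet): a VGG-style
contracting path whose 2×2 max-pool layers record their argmax indices, and
an expanding path that unpools into those indices (the SegNet mechanism) and
concatenates the same-level encoder feature map (the U-Net mechanism) before
two conv–batch-norm–ReLU blocks. The classifier head applies global average
pooling to the bottleneck feature followed by a dense layer and softmax; the
two pixel heads are 1×1 convolutions with per-pixel softmax. The three tasks
are trained jointly so that the global geometric context (classification),
the lesion extent (segmentation) and the texture of the peri-lesional
"high-risk" region (distance field) regularize each other.

The network and its training loop are implemented directly in NumPy
(`osteoseg.nn`): im2col convolution whose input gradient is computed as a
convolution with the flipped, channel-transposed kernel; batch normalization
with running statistics; max-pool/-unpool index plumbing; analytic
softmax+cross-entropy gradients; Adam and SGD; reduce-on-plateau and early
stopping. Gradient correctness was established against central finite
differences on a tiny network.

## Multi-level distance labels

A binary tumor mask is converted to a categorical field with labels
0 = background, 1 = tumor, and 2/3/4 = nested shells at normalized distance
(0, t1], (t1, t2], (t2, t3] from the nearest tumor pixel, with thresholds
(0.25, 0.5, 0.75) by default. Choices that the underlying idea leaves open,
resolved here:

* **Metric.** Chebyshev by default — shells of a compact lesion are then the
  concentric *rectangles* seen in qualitative examples of the approach;
  Euclidean is selectable.
* **Normalizer.** `max(H, W)` ("fraction of image size" is ambiguous);
  `min(H, W)` and the diagonal are selectable.
* **Source set.** Distance is measured from the tumor *pixel set*, not a
  bounding box, so arbitrary shapes and multi-lesion masks are well defined;
  shells derive from the union (nearest lesion wins).
* **Ties.** Shell intervals are half-open `(lo, hi]`, so every pixel gets
  exactly one label; a pixel exactly at a threshold joins the nearer shell.
* **Patches.** For patch training the map is computed at full resolution and
  cropped, never recomputed from the cropped mask — shells near a patch
  border still reflect lesions outside the patch.
* An empty mask yields an all-zero map (there is nothing to measure from).

## Two-stage training and fusion

* **Global stage** — whole images resized to the network input size
  (nearest-neighbor for label fields; the distance map is regenerated from
  the resized mask). Adam, lr 0.001.
* **Patch stage** — the same architecture initialized with the global
  weights (the trunk is fully convolutional, so the weights run unchanged at
  the patch input size) and fine-tuned on balance-sampled crops. SGD,
  lr 0.0004. Crops inherit the image label only when they actually contain
  tumor (foreground ≥ `min_tumor_pixels`); tumor-free crops are labeled
  normal.
* Both stages: 80/20 stratified split, lr halved after 5 stale validation
  epochs, early stop after 20, best-validation weights restored.
  Augmentation (horizontal flip, ±15° rotation, center-crop-zoom 0.8–1.0,
  each with probability 0.5) transforms image and labels identically.
* **Balance random sampling** — rejection sampling with a target
  tumor-patch fraction (default 0.5). Normal patches must be tumor-free
  (below `min_tumor_pixels`) *and* bright (mean intensity at or above a
  percentile of the image, default 50th) to keep them on bone. No bone mask
  exists, so brightness stands in for "bone region". `min_tumor_pixels`
  defaults to 64 at patch size 416, scaled with patch area; at desk scale
  the pipeline sets it to 16 explicitly because the proportional value
  degenerates to 1 px.
* **Inference** — global: forward at input size, probabilities upsampled
  bilinearly and renormalized per pixel. Patch: overlapping tiles (stride =
  half the patch size; edge tiles clamped, never padded), probability fields
  stitched by per-pixel arithmetic mean (a convex combination, so simplexes
  are preserved), class simplexes aggregated per-class by max (default;
  maximally sensitive to a single malignant tile), mean or top-k-mean, then
  renormalized.
* **Fusion** — the patch model decides malignancy (argmax, or a probability
  threshold when configured); otherwise the global model decides
  normal-vs-benign by argmax restricted to those two classes. A global
  malignant argmax is therefore deliberately overridden — the division of
  labor is that the texture-sensitive patch route owns that call.
  Segmentation fields are combined as `w_g·P_g + w_p·P_p` with default
  weights (0.5, 0.5).

## Synthetic data generator

The clinical dataset behind the original study is private, so the generator
emulates its statistical structure: a bright stylized long bone (vertical
shaft + elliptical condyle, cortical rim, low-amplitude trabecular texture)
on a dark soft-tissue background; 1–8 lesions per image confined to the
bone; per-lesion bounding boxes drawn from a configured size range
(clamped per dimension to the shaft width); three classes with one label per
image; additive Gaussian noise (sd 0.02 in [0,1] intensity units); 16-bit
images. Benign lesions are single smooth bright ellipses with sharp margins;
malignant lesions are connected unions of ≥3 overlapping small ellipses with
blurred margins and strong internal speckle — the texture-statistics
separation is intentional so that the classification task carries a
learnable signal analogous to real tumor-matrix patterns. Lesions are placed
with a 2-px halo so separate lesions stay 8-disconnected, making
connected-component counts a meaningful oracle.

Defaults are desk-scale: 128×128 canvases with 10–36 px lesions (the same
~8–30 % of image side that 100–1500 px lesions occupy on ~1000–4000 px
radiographs); the end-to-end experiment uses 64×64. What the generator does
**not** emulate: anatomy, pose variety, acquisition heterogeneity,
periosteal reaction, soft-tissue masses, pseudo-tumors. Passing tests
therefore demonstrate that the machinery is correct and that the pipeline
can learn this class of signal — not clinical performance.

## Scaled-down experiment

The reference experiment (run by `scripts/acceptance.py` and the end-to-end
test) uses 90 images (30/class, 64×64, lesions 8–24 px, counts 1–4), the
desk model (input 64, depth 3, base filters 8, ~135 k parameters), batch 4,
≤50 epochs per stage, patch stage on 32×32 crops (8 per image, tumor
fraction 0.5, `min_tumor_pixels` 16), tiling stride 16. These sizes are the
package's chosen desk-scale conditions; on one CPU the whole run takes a few
minutes. Per-stage seeds are derived from the single run seed by hashing, so
every stage is independently reproducible and all derived seeds stay below
2^31.

## Numerical choices and degenerate inputs

* float32 throughout the network; BN eps 1e-5, momentum 0.1; He
  initialization; probabilities clipped at 1e-12 inside log.
* Softmax is computed with max-subtraction; stitched/upsampled fields are
  renormalized so channel sums are 1 within 1e-6.
* Validation: non-binary masks, non-increasing thresholds, out-of-range
  labels, color images, undersized images vs. patch size, incompatible
  transfer weights and uncovered stitching pixels all raise descriptive
  errors rather than propagating garbage.
* An image smaller than the patch size at inference falls back to a single
  resized tile with a warning. An image whose every bright crop contains
  tumor falls back to an all-tumor draw for that image (logged); the strict
  sampling-exhausted error remains the contract of `sample_patches` itself.

## Known limitations

* No GPU path; paper-scale configuration (416×416, depth 4, base 64) is
  constructible but impractical to train in this NumPy implementation.
* Exact-reproducibility claims hold for single-threaded execution.
* The classifier-free ablation (segmentation only) decides tumor presence
  from the mask, so its "classification" collapses normal-vs-tumor.
* Fusion strictly delegates malignancy to the patch route; when the patch
  model under-detects, fused classification can trail the global model —
  visible occasionally at desk scale and consistent with the failure modes
  the approach is known for.
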