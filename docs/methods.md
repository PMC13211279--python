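# Methods

This note documents the models and procedures implemented in `cropstress`,
the defaults they ship with, and the reasoning behind the choices that were
genuinely open.

## Problem setting

The package segments six-band UAV multispectral orthomosaics of crop fields
into five classes — soil (0), low water stress (1), high water stress (2),
healthy vegetation (3), rust disease (4) — and summarizes the predictions as
georeferenced stress zones. Two task-specific label spaces feed a harmonized
five-class space: the water-stress task is four-class (soil/low/high/healthy)
and the rust task three-class (soil/rust/healthy); harmonization keeps the
water IDs, maps rust-task healthy to the common healthy class, and appends
rust as the fifth class.

## Synthetic scenes

Because no public orthomosaics ship with the package, a seeded generator
produces scenes with known ("planted") class layouts:

* **Spectral model.** Each class has a fixed mean reflectance per band
  (Blue, Green, Red, RedEdge, NIR, and a duplicated-NIR sixth band whose
  identity is carried as metadata). The table encodes the field contrasts
  the method relies on: soil is the brightest class in Red with a small
  NIR−Red gap; vegetation NIR decreases with stress severity
  (healthy 0.55 > low 0.42 > high 0.36 > soil 0.30); rust has depressed
  NIR and RedEdge and a simple ratio NIR/Red (≈4.2) far below healthy
  (≈11). Pixels get their class mean plus i.i.d. Gaussian noise, clipped
  to [0, 1].
* **Geometry.** Vegetation lies on vertical row stripes (8 px rows,
  4 px gaps). Water-stress severity is the quantile-thresholded level set
  of a smoothed Gaussian random field over the vegetation pixels, giving
  diffuse, spatially continuous stress patches; rust grows as compact
  disk clusters seeded on the rows, giving localized clusters — the
  qualitative contrast between abiotic and biotic stress in real fields.
  Quantile assignment makes the planted water fractions exact; rust
  clusters stop once the requested fraction is reached.
* **Noise level.** `noise_sd = 0.02` (2% reflectance) is the default —
  the order of residual noise in radiometrically calibrated reflectance
  products. The generator is deliberately simple: no illumination
  gradients, no mixed pixels, no co-registration error, no texture
  within classes. Tests passing on these scenes show the pipeline's
  machinery is correct, not that the thresholds would transfer to real
  orthomosaics.
* A NoData border (default 8 px) exercises validity masking; invalid
  pixels carry the sentinel −9999 and the reserved ignore label 255.

## Vegetation indices and rule-based labeling

Five indices are computed on valid pixels only (eps = 1e−6 stabilizes all
denominators; SAVI soil-brightness factor L = 0.5):
SAVI, NDRE, NDVI, GCI, SR.

**Water chain.** Otsu's threshold on SAVI separates soil from vegetation; a
second Otsu threshold on NDRE splits vegetation into healthy and
stressed candidates; 2-means clustering of the standardized (NDVI, GCI)
features splits the stressed candidates, the cluster with higher mean NDVI
becoming low stress. Our Otsu implementation returns the *bin edge* of the
between-class-variance-maximizing cut (256 bins over the observed range):
returning a bin center — as some library implementations do — can flip
`value < threshold` for values inside the argmax bin, which matters on
quasi-discrete index distributions.

**Rust vote.** Soil splits off at the midpoint of the two 1-D k-means
centers on SAVI (the threshold bounding the smaller, soil-like cluster);
on the plant region each of NDRE, NDVI, SR casts one vote where the pixel
falls below that index's plant-region median, and two or more votes flag
rust. Medians are computed on the initial plant region, before cleaning.
The rust support is then cleaned by binary opening (disk radius 1) and
removal of 8-connected components under 16 px; removed pixels revert to
healthy. K-means uses a fixed seed, making both chains deterministic.

## Auxiliary targets

* **Edge target**: union over classes of the morphological gradient
  (3×3 dilation − erosion) of each class's support — the two-pixel
  transition band at class boundaries.
* **Signed distance target**: exact Euclidean distance to the inner
  boundary ring of the combined non-soil foreground (4-connected ring, so
  it stays one pixel thin and boundary pixels read exactly 0), positive
  inside and negative outside, divided by τ = 20 px and clipped to
  [−1, 1]. The single-channel union-of-classes choice trades per-class
  geometry for cost; τ is a scale choice, not fitted.

## WF-UNet++

A UNet++ lattice of Conv–BatchNorm–ReLU double-conv blocks: encoder nodes
X(i,0) at 2× downsampling steps (max-pool), nested nodes
X(i,j) = block(concat(X(i,0..j−1), up(X(i+1,j−1)))) with bilinear 2×
upsampling followed by a 1×1 projection. Defaults: depth L = 4, base 32
filters doubling per level (≈8M parameters; the reduced benchmark model
uses L = 3, base 16, ≈0.5M). Three heads read the final full-resolution
node: 1×1 conv + softmax (K = 5 segmentation), 1×1 conv + sigmoid (edge),
and a 3×3 conv–BN–ReLU + 1×1 conv + tanh regression head (signed
distance, matching the clipped target range).

**Wavelet enhancement.** Each block input is augmented with its
single-level 2-D Haar detail sub-bands. Concatenating all 3C per-channel
bands would quadruple every block's input width, so the three bands are
channel-averaged and appended as three extra channels (C+3) — explicit
high-frequency structure at marginal parameter cost. The mechanism is a
design choice; nothing in the task pins a unique form.

The network and its training run on a small reverse-mode autograd engine
(`cropstress.nn`) written on numpy: im2col convolutions, pooling,
bilinear/nearest resampling, batch normalization, and the elementwise and
shift operations the FPDE path needs. Every operation's gradient is
verified against central finite differences in the test suite.

## FPDE refinement

Class probability maps are refined by an edge-stopping diffusion update
applied independently per channel:

    u ← u + λ Σ_{m=1..M} w_m(α) Σ_d c(|δ_d^m u|) δ_d^m u

where δ_d^m is the finite difference at offset m in the four axis
directions (edge-replicated, i.e. zero-flux boundaries), and
c(g) = exp(−(g/κ)²) (or 1/(1+(g/κ)²)). The scale weights
w_m = m^{−α} / Σ m'^{−α} are our discretization of fractional order:
α = 2 concentrates weight on the classical nearest-neighbour Perona–Malik
update (M = 1 reduces to it exactly — the anchoring requirement), while
smaller α spreads weight to longer-range differences, emulating the
non-local behaviour of a fractional Laplacian. After every iteration the
channels are clipped to [0, 1] and renormalized per pixel, so the simplex
constraint holds exactly.

Defaults: α = 1.3, T = 2 iterations, κ = 0.1 on the probability scale,
λ = 0.15, M = 3 scales, exponential conductivity. Because the scale
weights are normalized, explicit four-neighbour stability requires only
λ ≤ 1/4 regardless of M; the config enforces that bound. Clipping uses a
straight-through gradient so refinement stays differentiable inside the
training forward pass.

## Curriculum gating and losses

The refinement is phased in by the epoch gate g(e): 0 before `e_start`,
linear over `e_ramp` epochs, then 1; the training output is the convex
blend (1−g)·raw + g·refined (defaults e_start = 20, e_ramp = 20, so the
gate saturates at the midpoint of an 80-epoch run).

Total loss: λ_seg (L_WCE + L_Dice) + λ_edge L_BCE + λ_sdt L_L1 with
λ_seg = 1, λ_edge = λ_sdt = 0.5 (auxiliary heads weighted below the main
task). Class weights are inverse pixel frequencies over the training
split, normalized to mean 1. Dice uses ε = 1 smoothing with sums over
pixels and classes jointly. Ignore-labeled pixels are excluded from every
average.

Training: Adam at 0.002, batch 4, up to 80 epochs, reduce-on-plateau
(×0.5 after 10 flat epochs, floor 1e−6), no early stopping, no weight
decay, no augmentation; the checkpoint is the epoch with the best
validation mIoU. Batches are drawn with PatchBalance (each draw comes
from the above-median foreground-ratio pool with probability 1/2, so
foreground-bearing patches make up at least half the stream) and
BalancedMix (the source — water or rust — is drawn uniformly first), both
seeded and reshuffled per epoch. These two rules are named components of
the method whose exact mechanics were open; the implementations above are
the simplest rules with the stated sampling guarantees.

## Inference and metrics

Orthomosaics are scanned with a boundary-flushed tile/stride grid
(defaults 224/96) and per-pixel probabilities are the arithmetic mean of
all covering windows (blending in probability space); FPDE refinement, if
enabled, is applied per window before blending. Labels are per-pixel
argmax with ties to the smaller class index. Note that with stride 96 and
tile 224 the per-axis coverage alternates between 2 and 3 windows (96
does not divide 224), so interior pixels are covered by 4, 6 or 9
windows, 9 being the maximum.

Metrics come from the K×K confusion matrix: IoU_k = TP/(TP+FP+FN), mIoU
the unweighted mean, FG-IoU the mean over the non-soil classes
{1, 2, 3, 4}, and Dice/F1 via D = 2I/(1+I). Classes absent from both
prediction and ground truth are excluded from the means and flagged. The
foreground set resolves "ignoring the background classes" to {soil}: it
is the unique reading under which the published per-class IoUs reproduce
the published FG-IoU (0.8439) and macro Dice (0.9250).

## Stress zones

A class's support is closed with a disk (radius 5 px) to bridge small
gaps, 8-connected components are labeled, and components under 1 m² are
dropped. Area counts only original predicted pixels (closing serves
grouping, not area — the conservative choice), centroids are
geotransformed mean pixel coordinates, and IDs are RR/WL/WH plus a
3-digit ordinal in descending area order.

## The benchmark and what it shows

`cropstress.experiments.run_synthetic_benchmark` (also driven by
`scripts/acceptance.py`) runs the study at desk scale: 512×512 scenes,
64×64 patches on a 96-px stride (≈47 patches after foreground filtering,
25% validation), a depth-3/base-16 network trained 15 epochs. The run
reports:

* noise-free labeling recovery of the planted layouts (water ≈ 1.00,
  rust ≈ 0.99 — the rust deficit is the morphological cleaning of true
  single-pixel cluster fringes);
* validation mIoU of the trained network with and without FPDE
  refinement, and the change in fragmentation (8-connected components of
  the stress classes over the predicted maps).

The network in the benchmark is supervised by the planted reference
masks. Supervising it by the rule-generated labels of the noisy scenes
instead caps mIoU near 0.67 regardless of training length: the water
low/high split thresholds noisy indices, so its labels are
pixel-speckled near class boundaries, and a convolutional predictor
smooths exactly the speckle it is scored on. Clean planted supervision
isolates what the benchmark is meant to measure — that the network can
recover a separable five-class mapping — while rule-label quality is
measured separately by the recovery figures. The rule-label training
path remains available (`build_patch_dataset(labels_from="rule")`, and
the CLI always trains on whatever masks it is given).

## Known limitations

* The synthetic scenes omit illumination gradients, mixed pixels, texture,
  and georeferencing error; thresholds and accuracies do not transfer to
  real data.
* Patch-level train/validation splitting is spatially correlated when
  stride < tile; a block-wise split is the honest protocol for real
  orthomosaics.
* The numpy training loop is single-core and suits small studies, not
  full-scale training.
* The wavelet enhancement and the FPDE scale weights are reasonable
  concretizations of under-specified components, not uniquely determined
  forms.
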