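# Methods

## Problem setting

The package targets closed-set individual recognition from face images:
K known individuals (classes), a few hundred images per individual
extracted from video, and a classifier that assigns each new face image
to one individual. Video-derived data has two properties the pipeline is
built around: heavy near-duplication (consecutive frames are almost
identical) and scarcity after curation (hence offline augmentation).

## Dataset curation

**Difference hashing.** Each image is converted to grayscale with BT.601
luma weights (0.299 R + 0.587 G + 0.114 B) and resized to a 9-column ×
8-row thumbnail; bit (r, j) is 1 iff thumbnail pixel (r, j) strictly
exceeds its right neighbor (r, j+1), giving 8 bits per row and 64 bits
per image, row-major. The 9 × 8 orientation is the one under which
row-wise adjacent differences produce exactly 8 values per row; the
strict-greater convention is the common dHash choice. All resizing in
the package (thumbnails and network input alike) uses one documented
convention: separable bilinear interpolation with half-pixel centers,
clamped borders, no antialiasing pre-filter, computed in the lerp form
`a + f(b − a)` so constant regions are preserved exactly.

**Deduplication** is a greedy first-wins scan in input order: an image is
removed iff its hash is within Hamming distance < t (default 5) of any
already-kept image. The rule is deterministic, O(n²) with packed 64-bit
popcount comparisons, idempotent, and guarantees all kept pairs are ≥ t
apart.

**Augmentation.** The default offline recipe expands each original into
itself plus ten variants: one horizontal mirror; four pans (±dx, ±dy at
10% of width/height, edges replicated); three brightness scalings
{0.7, 1.3, 1.6} (clipped to [0, 255]); two Gaussian blurs (σ = 1, 2).
The 1+4+3+2 decomposition realizes an exact 11× expansion using all four
operation families; counts and parameters are configurable through
`AugmentRecipe`. Augmenting an already-augmented record is an error, so
transforms cannot compound.

**Splitting.** Stratified 70/15/15 by default: within each class,
records are shuffled with the split seed, then floor-allocated by
fraction with the remainder assigned to the training split (20 images
per class → 14/3/3; 10 per class → 8/1/1). To avoid leakage the intended
protocol is split first, then augment the training split only.

## The fusion module

For adjacent pyramid maps F_i (deeper, upsampled ×2) and F_j (shallower):

    F̂ = (1 + Att[concat(F_i, F_j)]) ⊙ (Φ[concat(F_i, F_j)] + F_j)

with att = sigmoid(D) element-wise. Design choices where the formula
leaves the architecture open:

- **Φ** is conv3×3 → BN → ReLU → conv3×3 → BN → conv1×1, projecting to
  F_j's channel count — forced by the `+ F_j` skip. He-normal init.
- **D** is a learned 1×1 convolution of the concatenated map to F_j's
  channel count, zero-initialized (weights and bias), so training starts
  at the neutral gate att ≡ 0.5 and the fused output at 1.5 × R. A
  parameter-free variant (`attention="raw"`, D = F_j's slice of the
  concatenation) is selectable for comparison; the learned form is the
  default because a gate with no parameters cannot adapt to the task.
- **`1 + Att` is literal**: the fused output is R + att ⊙ R, i.e. the
  residual features plus their attention-enhanced copy — a residual
  attention form that bounds the gate's effect to [1×, 2×] and keeps
  gradients flowing through the ungated path.
- **Downscale**: a stride-2 residual block (3×3 stride-2 conv + BN on
  the main path, 1×1 stride-2 conv + BN on the shortcut, summed, ReLU)
  halves the side inside every module; it can be disabled per block.
  Even input sides are required; all pyramid sides in supported
  configurations are even at fusion time.

## Cascade and classifier

Backbones expose a four-level pyramid at sides input/4 … input/32
(56/28/14/7 at 224). Tap points: VGG16 — after pooled conv blocks 2–5;
ResNet50 — after stages conv2_x–conv5_x; GoogLeNet — after the conv2
block and inception groups 3/4/5; these are the standard layers with the
required sides. The cascade reading adopted here is shallow-to-deep:
stage k upsamples level k+1 by 2, fuses it with the running map, and the
module's stride-2 path returns the result at level k+1's native side.
After three stages the map is at the deepest side and is summed
pixel-wise with the backbone's last feature layer (channel counts agree
by construction: each stage's output channels equal the next level's
channel count, ending at the last layer's). This is the only wiring
under which all four stated pyramid sides appear and the final sum is
shape-consistent; the stage wiring is data-driven so alternates can be
configured. Head: global average pooling + one linear layer for every
family; cross-entropy loss.

The `tiny` family (16/32/64/128 channels, two stride-2 stem convs plus
three stride-2 stages) exists to make training-loop and contract tests
cheap; it obeys the same halving law and accepts any input side
divisible by 32.

## Training protocol

Adam (lr 1e-4, batch 16, cross-entropy), a fixed epoch budget (default
200), per-epoch train/val accuracy trace, and the state dict of the best
validation epoch retained. The k-fold variant uses stratified folds
(delegated to scikit-learn's StratifiedKFold) with the lr 1e-5 preset
and a fresh model per fold. Training is fully deterministic given the
model init seed and the config seed (pure numpy, seeded generators).
Batches with fewer than two samples are skipped because batch
normalization needs batch statistics. An optional `target_train_acc`
lets harnesses stop once a training-accuracy target is reached; it is
off by default, matching the fixed-epoch protocol. Transfer learning is
supported as warm-starting from a local checkpoint; no pretrained
weights ship with the package.

**Metrics.** Per-class one-vs-rest TP/FP/FN; precision, recall, F1 in
percent (rounded to 2 decimals for reporting, exact values retained);
summary figures are macro averages — the unweighted class mean — chosen
because single-figure summaries without a stated scheme are conventionally
macro; micro accuracy (ΣTP / n) is also reported as a cross-check. A
class never predicted gets precision 0 with a degenerate flag rather
than an error. Cost is wall-clock seconds per single-image prediction,
Tn/n, after 10 warm-up predictions; it is hardware-dependent and only
reported, never asserted against reference figures.

## Synthetic data

The generator stands in for an unreleased enrollment dataset. Each class
is a procedural face — elliptical head, two eye blobs, muzzle patch —
with class-specific geometry, base color (hue spread around the color
wheel), and an oriented background gradient; each image perturbs the
class face by ±5° rotation, ±2 px translation, ±10% brightness, and
additive Gaussian noise (σ = 3). Classes are linearly well separated by
color and geometry, which is intentional: it makes training-sanity
checks fast and sharp. What it does **not** emulate: photorealistic
texture, occlusions (mud, tear stains), illumination extremes, class
imbalance, or label noise — so passing tests demonstrate the
correctness of the machinery, not field-grade recognition accuracy.

Burst generation emulates frame-grab redundancy. Frames differ from
their base by a spatially smooth illumination field (consecutive video
frames shift in lighting, not in per-pixel noise), calibrated in a
bounded loop (amplitude decays 0.9× per retry, ≤ 100 attempts) until the
frame's hash is within ⌊t/2⌋ bits of the base; bases are redrawn until
pairwise ≥ t + 2⌊t/2⌋ bits apart. By the triangle inequality every
within-burst pair is then < t and every cross-burst pair ≥ t, so
deduplication at threshold t must keep exactly the bases — asserted at
generation time, not assumed.

## Numerical choices

- float32 throughout the network engine; float64 for image resampling
  and hashing arithmetic.
- Fusion-formula agreement between the module and an entry-wise
  reference evaluation is checked at 1e-5 relative tolerance
  (accumulation order differs between the two routes at float32).
- BN uses biased batch variance for normalization, unbiased for running
  stats, eps 1e-5, momentum 0.1.
- Sigmoid is evaluated in the numerically stable split form; attention
  values are therefore strictly inside (0, 1).
- Max-pool ties break toward the first maximal element (argmax).
- Weight init: He-normal for convolutions and linear layers; zeros for
  the attention convolution.

## Problem sizes

Tests and the acceptance script run at deliberately small scales chosen
as the package's own test-design choice: 224-input forwards for pyramid
geometry (single images), side-64 inputs for per-family unit tests,
the tiny family at side 32 for training checks (4 classes × 50 images,
≤ 50 epochs, 5 seeds), 8 classes × 20 images for the end-to-end
benchmark, and 5 × 10-frame bursts for deduplication. Full-scale
replication of a 200-epoch transfer-learning study on real enrollment
data is out of scope.

## Known limitations

- No pretrained backbone weights; transfer learning requires a local
  checkpoint.
- The numpy engine is single-threaded per op (BLAS aside) and intended
  for correctness and small-scale experiments, not GPU-scale training.
- Reported parameter totals reflect the canonical architectures as
  implemented here and are not calibrated to any published totals.
- GoogLeNet's auxiliary classifiers are omitted (they only affect
  training of the original at scale, not the pyramid contract).
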