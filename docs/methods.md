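# Methods

`cryopick` implements set-prediction particle picking for cryo-EM
micrographs: a residual convolutional backbone feeds an encoder–decoder
transformer whose learnable particle queries each emit one candidate
(box + particle/no-particle probabilities), trained end-to-end with a
bipartite-matching (Hungarian) loss, followed by percentile-based
confidence filtering and STAR-file export.  This note records the model,
the choices that were genuinely open, and what the synthetic benchmark
does and does not demonstrate.

## Model

**Backbone.** Standard residual networks (depths 18/34 with basic
blocks, 50/101/152 with bottleneck blocks) reduce a 3-channel image
(grayscale replicated) to a C×H/32×W/32 activation map, C = 512 or 2048
by block type.  Normalization inside the backbone is *group
normalization* (8 groups) rather than batch normalization.  This is a
deliberate design choice: group statistics are independent of batch
composition and deterministic in evaluation, and — computed mask-aware
over each image's valid region — they make predictions computed inside a
zero-padded batch *exactly* equal to unbatched predictions.  Running-mean
batch normalization cannot give that guarantee.  Padding correctness is
maintained by tracking each image's valid extent through every stage,
zeroing features outside it, and masking attention keys; the test suite
asserts batched-vs-unbatched agreement to 1e-4.

**Transformer.** The activation map is projected to width d by a 1×1
convolution and flattened to H·W tokens.  Fixed 2-D sine/cosine
positional encodings (normalized to each image's valid extent, in
(sin, cos) pairs per frequency; learnable encodings behind a flag) are
added to the attention inputs of every layer, not only the first.  The
decoder transforms N learnable particle queries (N = 600 at full scale);
post-norm layers with dropout after each attention/FFN block.  Each
query ends in a shared 3-layer ReLU perceptron for the box — squashed by
a sigmoid to guarantee normalized (cx, cy, w, h) in [0,1] — and a linear
softmax head over {particle, ∅}.  ∅ ("no particle") plays the role of a
background class so the fixed-size prediction set can represent any
particle count ≤ N.

**Matching and loss.** Ground truth is conceptually padded with ∅ to
size N.  The matching cost of truth i against slot j is
−p̂_j(particle) + λ_L1·‖b_i − b̂_j‖₁ + λ_iou·GIoU(b_i, b̂_j); padding
pairs cost 0.  The optimal one-to-one assignment is found with SciPy's
linear-sum-assignment solver (ties broken by solver order; only the
optimal cost is contractual, and tests verify it against brute-force
enumeration for N ≤ 7).  The Hungarian loss then sums over all N slots
the classification negative log-likelihood — multiplied by 0.1 for ∅
slots, i.e. down-weighted by a factor of 10 against class imbalance —
plus the λ-weighted L1+GIoU box terms over matched true pairs.  The
matching cost deliberately uses the raw probability while the loss uses
the log-probability; the asymmetry is part of the method.  Defaults
λ_iou = 2, λ_L1 = 5 follow the detection-transformer convention.
Degenerate predicted boxes are clamped to 1e-6 side length before GIoU.

**Optimization.** AdamW (transformer 1e-4, backbone 1e-5, weight decay
1e-4), Xavier-initialized weights, dropout 0.1, 300 epochs with both
learning rates divided by 10 at epoch 200 — the full-scale recipe.  The
training objective normalizes the per-image loss sum by the number of
true particles in the batch so gradient scale is density-independent;
global gradient-norm clipping (default 0.1) guards the early phase.
Auxiliary supervision of intermediate decoder layers is available behind
a flag (`aux_loss`) and is used in the scaled-down runs, where it
speeds convergence substantially.  An optional `freeze_backbone` mode
holds the backbone at its initialization and caches its features, which
makes desk-scale CPU training practical; `freeze_backbone_early` freezes
only the stem and first stage.

The whole network is written against `autograd.numpy`; convolution and
max-pooling are custom autograd primitives (strided patch extraction +
BLAS tensordot) with hand-written vector-Jacobian products, verified
against finite differences in the tests.

## Denoising chain

Gaussian blur (σ=1) → z-score normalization → linear 8-bit grayscale →
fast non-local means (h=10 on the 8-bit scale, template 7, search 21) →
5×5 Wiener → CLAHE (clip limit 2% of the tile histogram, 8×8 tiles) →
guided filter (radius 8, ε=0.01) using the CLAHE output as guide and the
Wiener output as input, then back to float and re-normalization.  Every
stage is independently toggleable; "raw" inputs in the ablation keep
only the z-score (optimization needs a sane numeric scale either way).
The stage order is fixed; parameters are config-exposed defaults chosen
from each filter's common conventions.  Constant images pass through to
a constant (the Wiener variance guard maps 0/0 to 0).

## Synthetic scenes

The generator composes: dark soft-edged particles (disk/annulus/ellipse;
sigmoidal 1-px edge), rejection-sampled centers with a minimum pairwise
separation and a half-diameter image margin (10,000 attempts per
particle before an explicit infeasibility error), optional soft ice
blobs (Gaussian intensity offsets, radius 12–25% of the image),
an optional carbon-edge sigmoidal ramp, additive Gaussian noise, and
optional Poisson shot noise.  Default contrast: background 1.0, particle
depth 0.45, noise σ 0.3 — a modest-SNR regime where denoising visibly
helps but detection remains learnable at desk scale.  It deliberately
omits CTF, 3-D projection structure, correlated noise, and real ice
texture, so passing benchmarks here demonstrates that the pipeline and
losses work, not that the model generalizes to EMPIAR data.

## Scaled-down benchmark conditions

CPU-scale experiments use 64×64 scenes with ~15 particles of diameter 10
(separation ≥ 12, noise σ 0.3, one ice blob), 200 training and 50
held-out scenes, and a tiny model (depth-18 backbone, d=64, 2+2 layers,
8 heads, N=20 queries).  The training recipe for this scale: frozen
backbone with cached features, auxiliary decoder losses, dropout 0,
AdamW at 1e-3 (transformer) for 150 epochs, batch 32, learning-rate drop
at epoch 120.  Dropout is disabled because at this width it measurably
prevents convergence; the full-scale defaults keep 0.1.  Evaluation
matches predicted to true centers one-to-one within half a particle
diameter.

What this configuration can and cannot show: it trains stably (the
matching loss falls several-fold; denoised inputs train to a lower loss
than raw ones, the expected direction) and the full pipeline runs
micrograph-in, STAR-file-out, but held-out accuracy sits far below what
the full-scale method targets.  The gap is structural, not a tuning
artifact: a 64×64 image yields only four 1/32-scale feature tokens for
~15 particles, and with the backbone held at random initialization the
features never adapt.  In side experiments, end-to-end backbone
training at this image size converges far too slowly on a CPU to close
the gap within any practical time, dihedral augmentation (the
`augment` flag) reduces overfitting and helps longer frozen runs, and
input upsampling or higher learning rates do not help.  Competitive
picking accuracy requires the full-scale regime: large micrographs
(hundreds of tokens), the 600-query model, and GPU-scale end-to-end
training.

## Metrics

A pick is a true positive when a maximum-cardinality one-to-one matching
pairs it with a truth at distance ≤ 0.5 × that particle's diameter (the
tolerance is config-exposed; the assignment formulation is verified
against exhaustive matching for small instances).  Precision, recall and
F1 follow; undefined precision (no picks) is reported as 0 with a flag.
The Dice score is computed on rendered disk masks (radius = ground-truth
diameter/2 around both center sets), which is intentionally different
from set-level F1.  Dataset averages are unweighted (macro) means of
per-micrograph rows.

## Known limitations

- CPU-only: full-scale (600-query, ResNet-152, 1024² micrograph)
  training is out of reach; the implementation is exercised end-to-end
  at reduced scale and verified by contracts, oracles and closed forms.
- The frozen-backbone desk recipe relies on random convolutional
  features; trainable-backbone behavior is implemented and tested for
  gradient flow but not trained to convergence here.
- STAR output uses a single documented dialect (MicrographName,
  CoordinateX, CoordinateY, optional AutopickFigureOfMerit) with
  top-left 0-based pixel coordinates; downstream y-flips are the
  importer's responsibility.
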