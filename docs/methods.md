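# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, the numerical conventions, what the synthetic
data does and does not exercise, and known limitations. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Numerical core

No deep-learning framework is used: the package carries its own
reverse-mode autograd over float32 numpy arrays (`enetcaem.nn`). Forward
convolution uses an im2col view (stride tricks) contracted with einsum;
the input gradient is accumulated per kernel tap into the padded input,
vectorised over space. Supported primitives are exactly those the model
needs: grouped/dilated 2-D convolution, 1-D convolution over a channel
sequence, batch norm, max/average pooling, elementwise ops, reductions
(max gradients route to the first argmax), matmul, and a numerically
stable log-softmax (constant max shift). Adam implements bias-corrected
moments with β = (0.9, 0.999), eps 1e-8. Every layer takes an explicit
`numpy.random.Generator`; builds from the same seed are bit-identical, and
all stochastic modules (dropout, drop-path) draw from per-module streams
spawned from one seed, so training runs are bit-reproducible.

Correctness is established in the suite by (a) nested-loop oracle
implementations of every convolution/pooling path, written with explicit
sums and no shared code, compared at 1e-5 relative tolerance on inputs up
to 2×8×16×16, and (b) central-difference numerical gradients for conv,
batch norm, pooling and reductions.

## Architecture

Baseline: standard EfficientNet-B0 (stem 3×3/2 → 32 ch; seven MBConv
stages with repeats 1,2,2,3,3,4,1, widths 16–320, SE with hidden width a
quarter of the block input; 1×1 → 1280 head; FC). With an 8-class head
this build has 4.02 M trainable parameters — matching the published
figure — and 0.3845 G MACs at 224×224.

Reduced model: 13 improved MBConv blocks. Block order: 1×1 expand → BN →
Swish → depthwise → BN → Swish → [CCM in the three middle stages] →
multi-scale ECA (+ spatial attention) → 1×1 project → BN; identity
residuals pass through learnable drop-path. Head: 1×1 → 1280 expansion
(retained; see calibration), LightASPP, global mixed pooling, dropout 0.2,
FC.

Conventions fixed where the source description is open:

- **Multi-scale fusion** is the arithmetic mean over the three 1-D conv
  branches. A printed prefactor of 1/k is dimensionally inconsistent with
  three scales and is read as 1/n, n = 3. The alternative "dynamic weight
  fusion" mentioned in prose is available as learned softmax branch
  weights (`eca_fusion: learned`) but is off by default — the equation is
  implemented, the prose exposed as an option.
- **Spatial attention output** is one channel (7×7 conv maps the
  2-channel pooled stack to 1); a printed 2-channel weight map cannot
  broadcast-multiply the feature map and is treated as a typo.
- **1-D channel convolutions** use a single input/output channel over the
  length-C sequence, with bias, padding (k−1)/2 — the ECA convention.
- **CCM** reduction ratio is unstated; r = 16 (SE convention), hidden
  width floored at 1. Its 1×1 convolutions carry no bias (each is
  followed by BN). Placement: after the depthwise conv, before ECA.
- **Mixed pooling** in the head is global (it feeds the FC directly); λ is
  stored as a logit and squashed by a sigmoid so it stays in [0, 1],
  initialised to 0.5. Note a structural fact: when the pooled window is a
  single pixel, max equals average and λ has zero gradient — at 32×32
  input the top feature map is 1×1, so λ only trains at ≥ 64×64 input.
- **Learnable drop-path** uses p = σ(θ)·p_max with p_max = 0.2; the
  gradient reaches θ through the 1/(1−p) rescaling of kept samples. This
  is the simplest differentiable relaxation consistent with a per-block
  learnable drop probability. Per-block initial probabilities ramp
  linearly 0 → 0.1 with depth.
- BN momentum 0.1, eps 1e-5; Swish means x·σ(x); convolutions followed by
  BN carry no bias; SE and the attention convolutions that are not
  followed by BN carry bias.

### Calibration of the under-determined knobs

The published description fixes 13 total blocks, CCM in stages 4–6, rates
{3, 6, 9} and a 128-channel global branch, but not (i) which three repeats
are removed, (ii) the dilated-branch width, or (iii) whether the 1×1→1280
expansion survives in the head. The only constraints are the printed
totals: 6.55 M parameters and 0.461 G FLOPs.
`scripts/calibrate_architecture.py` enumerates all repeat profiles
(three repeats removed, every stage keeps ≥ 1) × branch widths 48–256 ×
both head variants using a closed-form layer walk, keeps combinations
whose parameter count rounds to 6.55 M (five exist), ranks them by MAC
closeness to 0.461 G, and verifies the winner against a real build. The
frozen default is repeats (1, 1, 2, 3, 1, 4, 1), branch width 94,
expansion retained: 6.55 M parameters, 0.454 G MACs.

### Complexity accounting

Parameters: sum of trainable tensor element counts. FLOPs: MACs of one
batch-1 forward at the configured input size over convolution, depthwise
and linear layers only; BN, activations and pooling are excluded. This is
the convention under which compact CNNs are normally quoted (B0 ≈ 0.39 G).
Note the published baseline figure of 0.410 G is not reproducible under
this convention — the faithful build counts 0.3845 G, verified against an
independent closed-form walk — so the published counter evidently included
non-MAC operations. The reduced model's 0.454 G sits within 2% of the
published 0.461 G.

## Data pipeline

Augmentation transforms and their ranges: rotation −45°…45° (bilinear,
black corner fill), horizontal flip, random 200×200 crop (uniform over
valid positions) resized to 224×224, Gaussian blur radius 0.5–1.5,
additive Gaussian noise σ = 10 (8-bit units, clipped), brightness
0.7–1.3×, contrast 0.8–1.2×, saturation 0.6–1.4×. Each augmentation cycle
samples 2–3 of these eight transforms without replacement and produces two
versions per source image; everything is a pure function of (input, seed).
Balancing resamples per class — with replacement up, without replacement
down — to explicit targets (default: the median class size; the
non-uniform per-class totals of the original study follow no stated rule,
so targets are an argument, not a constant). Splitting is stratified 8:1:1
with per-class largest-remainder rounding, so the three parts always
partition each class exactly. Splitting an already-augmented tree risks
leaking augmented copies of one source across splits; the CLI warns and
the supported order is split-then-augment.

## Training recipe

Adam, batch 32, 200 epochs by default, cosine annealing
lr(t) = lr_min + ½(lr_max−lr_min)(1 + cos(πt/T)) evaluated per epoch.
Unstated pieces fixed as: lr_max 1e-3 (configurable; the desk-scale runs
below use 5e-3), lr_min 0, weight decay 0, no early stopping; the best
checkpoint is the highest validation accuracy with ties to the earlier
epoch. Label smoothing uses the uniform-mixture convention
q = (1−ε)·onehot + ε/K with ε = 0.1 (the dominant convention; the
ε/(K−1) variant distributes mass only off the true class and is not
used). With ε > 0 the loss is bounded below by H(q) > 0; the suite
asserts this floor.

## Synthetic data

The generator emulates the study's eight-way task: leaf-green or
fruit-red backgrounds (vein-like shading, radial highlight) with
class-specific lesions — angular brown patches, small purple spots,
white powdery speckle, large dark rot spots, gray mold — plus two
lesion-free healthy classes, Gaussian pixel noise (σ = 8 by default), and
a lesion-scale multiplier for scale-series experiments. Separability is
guaranteed by construction: diseased images carry ≥ 10% lesion coverage,
palettes sit in distinct, quantisation-stable cells of a 4×4×4 joint RGB
histogram, and powder masks are binary so lesion pixels never blend into
background-adjacent hues. The suite verifies that leave-one-out 1-NN on
joint colour histograms reaches accuracy 1.0 at zero noise.

What this shows and does not show: passing tests demonstrate that the
blocks compute their contracts, gradients flow to every parameter, and the
assembled network can fit a task whose classes are unambiguous. The data
has none of the hard properties of field photographs — no background
clutter, occlusion, lighting variation, inter-class visual similarity or
label noise — so nothing here predicts accuracy on real disease images.

## Desk-scale problem sizes

CPU-sized runs use `ArchitectureConfig.enet_caem_small()`: the same 13
blocks and every block type, widths 12–96, expansion capped at 4, CCM in
the middle stages, LightASPP with 32-channel branches, at 32×32 input
(~0.38 M parameters). The learnability check trains it on 8 × 50
synthetic images (8:1:1 split) for 30 epochs with lr_max 5e-3 and requires
final validation accuracy > 0.90; the recorded run reaches 0.97.
Bit-reproducibility is asserted by running a 3-epoch configuration twice
and comparing trajectories exactly. Cross-validation and CLI tests use
1–2 epochs on a few dozen images: they exercise bookkeeping, not
convergence.

## Known limitations

- The numpy engine is single-threaded apart from BLAS; full-resolution
  training is out of scope (a 224×224 forward of the full model takes
  ~1.5 s), and no mixed precision or multi-device support exists.
- Bilinear upsampling is implemented only for the 1×1 → H×W case the
  LightASPP global branch needs (a constant fill, which is exact there).
- Max-pooling gradients follow the first-argmax convention on ties.
- Checkpoints are .npz with the config embedded as JSON; there is no
  interchange format with other frameworks.
- The ablation variants of the original study (attention-only models with
  a reported 1.97 M parameters, far below the 4.02 M baseline) imply an
  undocumented head removal and are not reproduced; only the baseline and
  final configurations are built.
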