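# Methods

## Model

The network is an encoder–decoder for binary lesion segmentation of
256×256 RGB dermoscopy images (any input side divisible by 32 is
supported; the model is built for a fixed size because the frequency
filters are sized per pyramid level).

**Encoder.** The default backbone is a visual state-space model in the
VMamba-tiny family: 4×4 patch embedding to 96 channels, four stages of
depths (2, 2, 9, 2) at widths (96, 192, 384, 768), 2×2 patch-merging
between stages. Each block is pre-norm residual around an SS2D mixer:
input projection to 2× the inner width (expansion ratio 2), a 3×3
depthwise convolution with SiLU, a four-directional cross-scan (row-major
and column-major, forward and reversed), a selective state-space scan with
state size N = 16 per direction, scan merging, layer norm, gating by the
SiLU of the second projection half, and output projection. The recurrence
uses zero-order-hold discretisation for the state transition
(`exp(Δ·A)`) and Euler for the input, with Δ produced by a low-rank
projection (rank 3C/16) through softplus, `A = −exp(A_log)` initialised to
−(1…N), and a skip `D` initialised to 1.

The backbone's citation chain fixes the channel tuple and, by convention,
depths and patch size, but not the expansion ratio or Δ-projection rank.
We set expansion 2 (the standard choice for this family) and rank 3C/16,
the pairing consistent with the published parameter budget of the full
model (30.26 M); the common ceil(C/16) rank would undershoot it by ~11 %.
All of this is exposed in `EncoderConfig`. No pretraining is used
(none is mentioned for the original model): projections are initialised
truncated-normal (std 0.02), convolutions with fan-in scaling, from a
single seeded generator (`sgnet.nn.init.seed_all`).

A second encoder variant (`test_conv`, strided convolutions) satisfies the
identical pyramid contract at ~1/30 the cost and is used throughout the
fast tests; contract equivalence of the two variants is itself tested.

**DDBE.** Each level is unified to 96 channels (1×1 conv → batch norm →
GELU) and split evenly: channels 0–47 feed a 3×3 conv spatial branch,
channels 48–95 a frequency branch that multiplies the 2D spectrum by a
learnable per-channel complex half-spectrum filter (shape 48×H×(W/2+1)),
implemented with the conjugate-symmetric full-spectrum extension so a unit
filter is an exact identity. Filters are per level (spatial dims differ)
and initialised to 1+0i so training starts from an identity branch. The
branches are concatenated, fused by a grouped 3×3 conv (groups 4) → batch
norm → GELU → 1×1 conv, and added residually to the unified feature. The
even 48/48 split is the only one consistent with a 48-channel frequency
input and 96 total.

**STFU.** The shallow member of each adjacent pair is 2×2 average-pooled
(average preserves texture statistics better than max) and both are passed
through 1×1 conv → batch norm → ReLU; the concatenated pair is reduced to
96 channels before triplet attention (the attention is shape-preserving,
and downstream fusion is defined at 96 channels). Triplet attention uses
the standard rotate / Z-pool (max‖mean) / 7×7 conv / sigmoid design with
the three branch outputs averaged. CoupleConv uses K = 3 branches with
kernels {1, 3, 5} — mirrored from the refiner's explicit kernel set — and
groups = 4. Both the branch weights α and the residual weights ω are
stored as unconstrained logits and softmax-normalised at every forward
pass, so Σα = 1 and ω₁+ω₂ = 1 hold by construction after any optimiser
step. The three STFU instances share no parameters.

**SAGM.** Per-input 3×3 conv alignment; bilinear upsampling of the two
deeper features to the stride-8 grid; a boundary gate from two cascaded
3×3 convs (96→48→1, minimal cascade) and sigmoid; global guidance by
global average pooling → 1×1 conv → spatial broadcast; additive fusion;
then exactly three ConvTranspose stages (kernel 4, stride 2, padding 1 —
an alias-free ×2) with channels 96→64→32→1 and batch norm + ReLU between
stages. The output is a logit map; sigmoid is applied only where
probabilities are required (refiner guidance, loss).

**GMSR.** Stages run deepest-first (stride 32 → 16 → 8), the first guided
by the coarse map. The attention extractor is sigmoid(p) ⊕ feature → 3×3
conv (97→48) → ReLU → 3×3 conv (48→3) → sigmoid. Scale branches are plain
convolutions with kernels {1, 3, 5}; the fusion bottleneck reduces
288→36→3 (reduction 8, squeeze-excitation practice). The guidance residual
is added on logits (not probabilities) for training stability; the final
prediction is the bilinear upsampling of the last stage's guidance to full
resolution.

**Loss.** All five supervised maps (final, coarse, three stage maps) are
bilinearly upsampled to the mask resolution and each contributes
BCE + soft Dice (smoothing 1e-5) with equal weight 1.

**Ablations.** Three toggles mirror the module-contribution study. A
disabled DDBE leaves channel-unifying 1×1 projections; a disabled STFU
uses a non-adaptive pool-concat-project fusion (so every level still
contributes and shapes are preserved); disabled SAGM+GMSR uses a plain
conv head on the finest fused feature with light auxiliary heads standing
in for the stage maps.

## Training recipe

AdamW, initial learning rate 1e-3, cosine annealing to 1e-6 over the full
schedule, batch size 16, 100 epochs, BCE-Dice — the published recipe.
Unstated details chosen here: weight decay 1e-2 (the AdamW default),
checkpoint selection by best validation DSC, augmentation restricted to
flips and right-angle rotations so masks remain exactly binary. All
randomness (init, shuffling, augmentation) derives from one seed; the
forward pass contains no stochastic kernels, so repeated runs are bitwise
identical — determinism is structural rather than a mode flag.

## Metrics

The overlap metrics implement the foreground-count formulas exactly as
printed in the segmentation literature this model belongs to; note that
"mIoU" there is foreground IoU, and the two-class mean is available behind
`mean_over_classes=True`. Dataset aggregation defaults to global
confusion-count pooling (sum, then divide), with a per-image mean behind a
flag. Undefined ratios return 1.0; both-empty masks score mIoU = DSC = 1.

HD95 uses 8-connected border pixels (mask minus its 3×3 erosion), exact
Euclidean distance transforms, and pools both directed distance sets
before taking the 95th percentile — symmetric by construction; the
max-of-directed-percentiles variant is behind a flag. Conventions: 0 for
two empty masks, the image diagonal when exactly one mask is empty.
Binarisation threshold is 0.5 on sigmoid probabilities.

## Synthetic data

The generator emulates the canonical dermoscopy challenge cases:
lesions are rotated ellipses (semi-axes uniform in 12–40 % of the image
side) deformed by low-order radial harmonics; skin is a warm base tone
with smoothed Gaussian texture and mild vignetting; lesion-to-skin
contrast defaults to 0.18 intensity units (deliberately low); boundaries
are blurred with σ = 2 px in the image only — the mask is the pre-blur
support; 0–12 dark cubic-Bézier hair strokes (1–3 px) are drawn over the
image but never into the mask. Every sample is a pure function of
(seed, index) via a `SeedSequence` spawn.

What it does not emulate: real lesion colour distributions and
dermoscopic structures (networks, globules), specular highlights, ruler
and gel artefacts, annotation noise, or the scale statistics of clinical
archives. Tests passing on this generator therefore demonstrate that the
architecture, optimisation and evaluation machinery are correct and that
the model can fit lesion-like structure — not clinical-grade accuracy,
which requires the public dermoscopy benchmarks (supported via the
ISIC-style folder reader, `<split>/{images,masks}` with
`<stem>_segmentation.png` pairing, bilinear image / nearest mask resize to
256², mask binarisation at 127).

## Numerical choices and problem sizes

The engine computes in float32 for training (float64 in gradient-check
tests). Batch norm uses eps 1e-5 / momentum 0.1; layer norm eps 1e-6.
Bilinear resizing uses half-pixel (align_corners=False) mapping realised
as two small dense matrix contractions, making its adjoint exact. The FFT
filter's backward pass is the analytic adjoint of the full-spectrum
extension, verified against central differences. The selective scan saves
its state history for the reverse-time adjoint only when gradients are
enabled. FLOP accounting counts multiply-accumulates of convolutions,
projections and the scan (one MAC = one FLOP), not normalisation,
activations or FFTs — the convention of common profilers.

Desk-scale sizes used by the test suite, chosen to exercise every code
path on one CPU: training tests run the `test_conv` backbone on 64×64
synthetic images (single-batch overfit: 8 images, 200 steps; short runs:
64 training samples, 3 epochs); full-size checks (256², state-space
backbone) are confined to shape contracts and the parameter/FLOP profile.

## Known limitations

* numpy-based training is single-device and orders of magnitude slower
  than GPU frameworks; the package targets correctness and desk-scale
  experiments, not benchmark-scale training runs.
* The model is fixed-resolution per instantiation (per-level frequency
  filters); changing resolution means rebuilding.
* Exact parameter parity with the published figure depends on backbone
  hyperparameters the original description leaves open; the chosen
  configuration lands within 1 % but is not guaranteed identical
  layer-by-layer.
* The scan's Python-level time loop makes the state-space backbone's
  forward pass ~20 s at 256² — fine for profiling and contract tests,
  impractical for full training, which is what the `test_conv` variant is
  for.
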