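# sgnet — structure-guided skin-lesion segmentation

Automatic delineation of skin lesions in dermoscopic images is a core step
in computer-aided melanoma diagnosis, and a hard one: lesions are
low-contrast, irregularly shaped, blurred at the boundary and frequently
occluded by hair. `sgnet` implements a structure-guided hybrid CNN /
visual-state-space segmentation network for this problem, together with the
full metric suite used in the field, a synthetic dermoscopy generator so
every part of the pipeline is testable without dataset downloads, and a
small CLI. It is aimed at researchers who want a transparent, dependency-
light reference implementation of this architecture family.

The entire network runs on a self-contained numpy autograd engine
(`sgnet.nn`) — reverse-mode autodiff, im2col convolutions, a differentiable
FFT filter, the selective state-space scan, AdamW — so the package needs no
deep-learning framework and trains on a plain CPU at desk scale.

## The model

An input image `X ∈ R^{H×W×3}` passes through five components:

1. **Encoder** — a VMamba-style visual state-space backbone (4×4 patch
   embedding, stage depths [2,2,9,2], patch-merging downsampling) producing
   a pyramid `X_i ∈ R^{H/2^{i+1} × W/2^{i+1} × C_i}`, `C_i ∈ {96,192,384,768}`.
   Each block serialises the feature map along four traversal orders
   (cross-scan) and applies the input-dependent linear recurrence
   `h_t = exp(Δ_t A) h_{t-1} + Δ_t B_t x_t`, `y_t = C_t h_t + D x_t`.
   A strided-conv `test_conv` variant satisfies the same pyramid contract
   for fast experiments.
2. **Dual-Domain Boundary Enhancer (DDBE)** — per level: unify channels to
   96, split 48/48 into a spatial 3×3-conv branch and a frequency branch
   `X_freq = IRFFT(RFFT(X_f) ⊙ W_f)` with a learnable complex filter
   `W_f(u,v)` per channel, fuse with grouped convolutions, add residually.
3. **Semantic-Texture Fusion Unit (STFU)** — aligns each adjacent pair of
   enhanced levels, applies triplet attention, then multi-kernel grouped
   convolutions fused by softmax weights:
   `F_multi = Σ_k α_k Conv_k(F_attn)` (Σα_k = 1), and
   `F_out = F_multi + ω_1 X'_i + ω_2 X'_{i+1}` (ω_1 + ω_2 = 1).
4. **Structure-Aware Guidance Module (SAGM)** — boundary attention
   `F_out1^enh = F_out1 ⊙ A_bnd`, broadcast global context `F_glo`, additive
   fusion, then exactly three stride-2 transposed convolutions to emit a
   full-resolution coarse logit map.
5. **Guided Multi-Scale Refiner (GMSR)** — three coarse-to-fine stages; each
   gates kernel-{1,3,5} branches with prediction-guided attention, fuses
   them with channel-semantic softmax weights
   `Ŵ = Softmax(W_2 σ(W_1 g))`, `F̂ = Σ_s Ŵ_s F^s`, and updates the
   guidance residually. All intermediate maps are deeply supervised with a
   summed BCE + soft-Dice loss.

Evaluation implements `mIoU = TP/(FP+TP+FN)`, `DSC = 2TP/(FP+2TP+FN)`,
ACC, SE, SP and HD95 (95th-percentile symmetric boundary distance with
exact Euclidean distance transforms).

## Worked example

Train a small model end-to-end on synthetic data
(`examples/03_train_tiny_model.py`, ~1 minute on CPU):

```text
epoch   1  loss 6.3850  val mIoU 0.4004  val DSC 0.5718
epoch   2  loss 5.0788  val mIoU 0.6011  val DSC 0.7509
epoch   3  loss 4.7686  val mIoU 0.5870  val DSC 0.7398

loss fell from 6.385 to 4.769; best val DSC 0.751
```

The loss is the sum of BCE+Dice over five supervised maps (≈ 5·(ln 2 + 1) ≈
8.5 for an uninformative predictor), so three epochs of a 13 M-parameter
model on forty 64×64 synthetic images already cut it by a quarter and reach
a validation Dice of 0.75. Metric evaluation on a toy pair
(`examples/04_evaluate_metrics.py`):

```text
TP=784 FP=0 TN=3072 FN=240
mIoU 0.7656  DSC 0.8673  ACC 0.9414  SE 0.7656  SP 1.0000
HD95 2.106 px
```

The other examples synthesise data (`01`), demonstrate the learnable
Fourier filter's identity and DC-suppression limits (`02`), and profile the
architecture (`05`).

The CLI mirrors the library:

```bash
sgnet synth --n 64 --seed 0 --out-dir data/synth
sgnet train --synthetic-n 32 --epochs 3 --encoder test_conv --input-size 64
sgnet predict --checkpoint sgnet_checkpoint.npz --images data/synth/images --out-dir preds
sgnet eval --pred-dir preds --mask-dir data/synth/masks
sgnet profile --encoder vmamba_tiny
```

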