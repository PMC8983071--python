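# Methods

## Problem and model

Clinical chest CT resolves ~0.5–0.6 mm voxels; micro-CT of resected lung
specimens resolves ~50 μm, an order of magnitude finer, and reveals
micro-anatomy (bronchiole walls, septa, tumour margins) that clinical CT
cannot. Because a living patient cannot be scanned at micro-CT resolution
and resected specimens deform too much to register against in-vivo scans,
no aligned (LR, HR) training pairs exist; super-resolution across this
modality gap must be learned from *unpaired* image collections.

`microsr` implements SR-CycleGAN for this setting. Two generators are
trained jointly: `G1` maps an n×n clinical patch to a 2^k·n × 2^k·n
micro-CT-scale patch, and `G2` maps a micro patch back down to n×n.
Relative to a conventional CycleGAN generator, `G1` drops the stride-2
downblocks (a 32×32 input would be crushed to 4×4 feature maps, destroying
the spatial detail SR must preserve) and appends k sub-pixel-shuffle
upsampling stages; `G2` keeps the downblocks. Two PatchGAN discriminators
(`D1` on the micro domain, `D2` on the clinical domain) drive the
adversarial terms. Only `G1` is used at inference.

The total objective is

    L = λ1·L_S(x, f↓(x_SR)) + λ2·L_S(y, f↑(y_LR))
      + λ3·L_D(x, x_SR)     + λ4·L_U(y, y_LR)
      + λ5·L_GAN(x_SR)      + λ6·L_GAN(y_LR) + λ7·L_cyc

with x a clinical patch, x_SR = G1(x), y a micro patch, y_LR = G2(y),
f↓ non-overlapping average pooling, f↑ nearest-neighbour upsampling.
The first four terms are the multi-modality super-resolution (MMSR) loss:
`L_S` = 1 − SSIM across resolutions, `L_D` = mean squared error between x
and the pooled SR image, `L_U` = mean squared error between y and the
upsampled y_LR. They tie images of *different sizes* (and modalities)
together; without them the unpaired adversarial objective is free to emit
images unrelated to the input. Default weights: λ = (1, 1, 0.7, 0.3, 1, 1, 1).

Interpretation choices a reimplementation must make, and ours:

* SSIM in the loss uses **global per-image moments** (one μ, σ per image),
  in the standard Wang et al. form with 2·μaμb in the numerator so that
  SSIM(x, x) = 1. Constants C1 = (0.01·L)², C2 = (0.03·L)² with data range
  L = 2 for [−1, 1] images. The evaluation metric is the separate
  **windowed** SSIM (11×11 Gaussian window, σ = 1.5); both are reported by
  the evaluation module.
* Adversarial terms are least-squares GAN (the CycleGAN-lineage default):
  discriminator ½·mean((D(real)−1)²) + ½·mean(D(fake)²), generator
  mean((D(fake)−1)²). Binary cross-entropy is available via
  `gan_mode="bce"`.
* Squared ℓ2 norms are averaged per pixel, so λ weights are independent of
  patch size.
* The λ1–λ4 inside the MMSR loss are the same symbols as in the total
  objective; they are applied once.

## Architecture

`G1`: Conv(1→C, k1)+Norm+ReLU; Conv(C→C, k2)+Norm+ReLU; `n_resblocks`
residual blocks at C channels (two 3×3 convs, norm, ReLU after the first,
additive skip); k stages of Conv(C→4C, 3×3) + sub-pixel shuffle(2) + ReLU;
Conv(C→1, tail kernel) + tanh. Defaults (full scale): k1, k2 = 3, 7;
tail 7; C = 64; 9 resblocks; batch norm; reflection padding. `G2` replaces
the shuffle stages with k stride-2 convolution downblocks placed after the
head. Discriminators are 70×70-receptive-field PatchGANs (stride-2
Conv+Norm+LeakyReLU stages, 64→512 channels, 1-channel score conv, zero
padding); for small inputs the number of stride-2 stages shrinks so a
spatial score map remains. Weights are Gaussian(0, 0.02) from a seeded RNG.

The convolutions feeding each sub-pixel shuffle use **ICNR
initialization** (Aitken et al. 2017): the r² channels of each sub-pixel
group start identical, so at initialization the shuffle acts as nearest
upsampling. Without it, naive sub-pixel convolution injects
checkerboard-patterned high-frequency noise that the pooling-based MMSR
terms cannot see (pooling averages it away), and short training runs can
converge to outputs that satisfy the pooled losses while remaining noisy
at full resolution.

Ablation variants are first-class configurations: `downblocks` keeps the k
downblocks in `G1` (bottlenecking 32×32 to 4×4 at k=3, requiring 2k
shuffle stages), and `upblocks` is a conventional CycleGAN generator with
k deconvolution upblocks appended. Channel widths through the network are
not published; we pin the CycleGAN convention (constant 64 through the
resblocks), so published parameter-count totals are not reproduced.

## Optimization

Adam (β = 0.5, 0.999), learning rate constant for the first half of
training and decaying linearly to zero over the second half (full-scale
default: 1e-5 flat to epoch 100, zero at epoch 200; mini-batch 4). Each
step updates both generators jointly on the total objective, then each
discriminator once on pooled fakes (a 50-image history pool, disableable).
Every random draw (init, shuffling, pooling) flows from explicit seeds;
identical configuration reproduces identical loss logs and byte-identical
checkpoints, and a resumed run reproduces the uninterrupted trajectory
(checkpoints embed optimizer state, pool contents and the RNG state).

## Intensity handling

Clinical CT is windowed to [−1000, 2500] H.U. (air to bone), micro-CT to
[0, 15000] scanner units (air to cancer tissue); both are affinely
compressed to [−1, 1]. The maps are monotone and exactly invertible on the
clipped range. Lung masking of clinical volumes: connected components of
the < −400 H.U. threshold with components touching the in-plane borders
removed (outside air), then per-slice morphological hole filling so
vessels inside the lung stay in the mask; equivalent to region growing
from every interior low-intensity seed. Patch extraction samples top-left
corners uniformly across axial slices and, when a mask is supplied,
accepts a patch only when ≥50% of its pixels are inside the mask.

Bicubic resampling — used by the evaluation protocol — is the Keys
cubic-convolution kernel (a = −0.5) applied separably with reflect
boundary handling and the pixel-area coordinate convention; each interior
output sample is a weighted sum of a 4×4 source neighbourhood, and
constant and linear images are reproduced exactly. It is implemented
in-package because the evaluation contract pins this exact kernel.

## Synthetic phantoms

No real clinical or micro-CT data ships with the package; a seeded phantom
family provides both domains with the statistical structure the method
assumes.

* **Micro-domain HR phantoms** (default 256×256; 64×64 at desk scale):
  granular alveolar background built from correlated Gaussian noise split
  into a tissue mode (≈ +0.45) and an air mode (≈ −0.55), plus 2–5 bright
  vessel disks (≈ +0.75) and 1–3 bronchi (bright annulus ≈ +0.65, dark
  lumen ≈ −0.65). The histogram concentrates in the upper normalized
  range, as in specimen micro-CT.
* **Clinical-domain LR images** come from a forward model: Gaussian blur
  (σ = 1 HR px, the scanner PSF) → average pooling by the scale factor →
  monotone affine intensity remap 0.32·v − 0.70 → additive Gaussian noise
  (σ = 0.03), clipped to [−1, 1]. The remap gain and offset are derived
  from the reported tissue intensities of the two modalities: a blood
  vessel sits at ≈ 0 H.U. (≈ −0.43 after clinical normalization) but at
  ≈ 15000 scanner units (≈ +0.88) on the micro scale, and air at
  −1000 H.U. (−1) versus ≈ 0–1000 (≈ −0.9); the affine map through those
  two tissue anchors gives gain ≈ 0.32, offset ≈ −0.70. The two domains'
  pixel histograms are decisively separated (two-sample KS statistic
  > 0.2) — the premise that makes the multi-modality loss necessary, and
  the reason plain bicubic upsampling is a weak baseline here: it inherits
  the clinical intensity scale wholesale.
* Unpaired training sets draw the two domains from **disjoint seed pools**
  (no hidden pairing). Registered pairs, where the LR image *is* the
  degraded HR phantom, exist only for evaluation.

What the phantoms do not emulate: CT reconstruction physics (beam
hardening, ring artifacts, streaks), anatomical shape realism, specimen
deformation between in-vivo and ex-vivo states, and non-monotone
modality-specific contrast reversals. Passing desk-scale tests therefore
demonstrates that the training machinery and loss design function as
specified under the assumed statistical structure — not clinical
performance on real scanner data.

## Desk-scale study configuration

CPU-sized runs (the `tiny` preset and the estimator defaults) use scale
4× (LR 16×16 → HR 64×64), 8 base channels, 2 resblocks, all-3×3 kernels,
instance norm, discriminator width 8, Adam at 2e-4, batch 4, 31 epochs of
16 steps (496 steps), pool 16. Three departures from the full-scale
defaults, and why:

* **Instance norm instead of batch norm**: with mini-batch 4 and a few
  hundred steps, batch-norm running statistics are poorly calibrated at
  inference and we observed non-convergence; instance norm behaves
  identically in train and eval modes. Batch norm remains the full-scale
  default, matching the published configuration.
* **Learning rate 2e-4** (the CycleGAN-lineage magnitude) instead of
  1e-5: the published rate is tied to a ~500k-step budget; at a few
  hundred steps nothing moves at 1e-5.
* **All-3×3 kernels**: the 7×7 head/tail kernels are disproportionately
  expensive at these sizes and add receptive field the 64×64 phantoms do
  not need.

The end-to-end check trains on 64 + 64 unpaired phantoms and evaluates on
24 held-out registered pairs per repeat, comparing mean PSNR (data range
2.0, identical images capped at 100 dB) and mean windowed SSIM against
(a) bicubic upsampling of the LR input and (b) the same network trained
with λ1–λ4 = 0 (no MMSR loss). Problem sizes were chosen so one repeat
(two trainings plus evaluation) takes ~2 minutes on one CPU.

## Numerical choices

* The training stack (autodiff tensors, layers, Adam) runs in float32;
  imaging operators, losses on plain NumPy inputs, and metrics run in
  float64.
* Zero-MSE PSNR is reported as a 100 dB cap so means stay finite.
* Average pooling uses non-overlapping blocks with stride = factor — the
  only choice that makes f↓ an exact 1/n resize and f↓∘f↑ the identity.
* Tiled whole-slice inference blends overlapping SR tiles with linear
  feathering; blend weights are normalized to sum to exactly 1 at every
  output pixel, so constant-preserving generators produce seam-free
  output and pixel-local stubs reproduce the untiled result exactly.
* Checkpoint archives store raw `.npy` members with fixed zip timestamps,
  so identical training state yields byte-identical files.

## Known limitations

* The desk-scale GAN equilibrium is seed-sensitive: with tiny networks and
  a few hundred steps, a minority of seeds converge to visibly worse
  optima. The acceptance-style check therefore uses the majority direction
  over three seeded repeats, mirroring how the comparison is defined.
* Full-scale (8×, 64-channel, 200-epoch) training is supported by the same
  code paths but is intended for GPU-class budgets elsewhere; on one CPU a
  single full-scale epoch over 10,000 patches is impractical.
* Published parameter counts and absolute PSNR/SSIM scores on the
  private clinical–micro-CT dataset and the public COVID-19 CT dataset are
  out of scope (private or external data; GPU-scale training); the package
  reproduces the printed structural constants and the ordering claims.
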