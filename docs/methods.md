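# Methods

## Problem and model

The package segments surgical instruments in endoscopic RGB frames as a
two-class dense prediction problem (background k=0, instrument k=1). The
segmentation network is an enhanced U-Net: a contracting encoder and an
expanding decoder with skip pathways, modified in four ways relative to
the plain U-Net,

1. **Deep contextual encoder.** The two deepest encoder levels use dilated
   3×3 convolutions (default schedule 1, …, 1, 2, 4), widening the
   analytic receptive field without extra downsampling or parameters.
   `receptive_field(config)` computes the exact size via the recurrence
   rf' = rf + (k_eff − 1)·jump, k_eff = k + (k−1)(dil−1).
2. **Residual skips.** Encoder features pass through a learned 1×1
   projection and are *added* to the matching decoder stage, instead of
   the U-Net's channel concatenation.
3. **Adaptive feature fusion.** Optionally, a gate
   g = σ(conv1×1([enc, up])) combines the two streams convexly,
   g⊙enc + (1−g)⊙up, per channel and position. This is the minimal
   learned-gate realization of adaptive weighting; with the gate saturated
   the block degenerates to either pure skip or pure decoder path.
4. **Depthwise separable convolutions.** Each 3×3 convolution is replaced
   by a per-channel spatial convolution plus a 1×1 pointwise mix
   (k²·C_in + C_in·C_out parameters versus k²·C_in·C_out).

Downsampling is 2×2 max pooling; upsampling is nearest-neighbour followed
by a 3×3 convolution; every convolution is followed by group
normalization (batch-size independent, so evaluation needs no running
statistics) and a ReLU. The `baseline-unet` variant switches all of the
above off (plain convolutions, concatenation skips, dilation 1).

The numerical backend is a small reverse-mode autodiff engine on float32
numpy arrays (`eugnet.nn`): convolution is im2col + BLAS matmul, and the
whole-model gradient is verified against central finite differences in the
test suite. Weights are He-initialized from a seeded generator, so builds
are bit-reproducible.

## GridMask

GridMask erases a periodic lattice of squares from the input:
X̃ = X ⊙ M with M ∈ {0,1}^{H×W}. A mask is determined by
(r, d, δx, δy): the plane is tiled with d×d units, each unit drops the
square of side s = round((1−r)·d) at its origin, and the pattern is
translated by (δy, δx). The convention "first intact unit begins at
(δy, δx)" is equivalent to translating the drop lattice by the offsets;
the asymptotic kept fraction is 1 − (1−r)², and exactly
1 − (round((1−r)d)/d)² when d divides both sides and the offsets vanish.
Rotated masks are generated on a ⌈√2·max(H,W)⌉ canvas, rotated with
nearest-neighbour interpolation (values stay exactly binary) and
center-cropped, which leaves no unmasked corner artifacts.

During training a policy samples d uniformly from `d_range`, offsets
uniformly from [0, d), and a rotation from [0, 360) when enabled, and
applies the mask with probability `apply_prob` (default 0.5, constant over
training). Defaults: r = 0.6; d_range = (24, 64) for 576-px frames,
scaled proportionally to (8, 24) for the 64-px synthetic scenes. These are
configuration choices, not empirical claims. GridMask acts on the
normalized image (intensities already in [0, 1]), after the standard
augmentations.

**Label masking.** `mask_labels` defaults to OFF: the ground truth keeps
the full tool extent so the network is trained to predict tool pixels
through the erased regions — erasure then behaves like simulated
occlusion. Turning it on multiplies the label by M as well, which instead
teaches the network to reproduce the holes; both behaviours are exposed
because practice varies, but the default is the occlusion-robustness
reading.

## Standard augmentation

Rotation, flips, isotropic scaling, translation, elastic deformation and
cropping are applied with identical parameters to image and label (label
resampled nearest-neighbour, so it stays binary); brightness shift and
additive Gaussian noise touch the image only, clipped to [0, 1].
Out-of-bounds regions are filled with black/background. Elastic
deformation uses a Gaussian-smoothed random displacement field (amplitude
`elastic_alpha` px, smoothing `elastic_sigma` px). The order is geometric
→ photometric → GridMask. All ranges are configuration with identity
defaults; the study conditions (below) use ±15° rotation, flips
(p=0.5/0.25), brightness ±0.1 and noise σ=0.02.

## Loss, class balance and optimization

The loss is pixel-averaged weighted cross-entropy with class weights
w_k ∝ 1/max(freq_k, ε) normalized to Σw_k = K (ε = 1e−6 caps the weight
of absent classes). Dataset-level frequencies are computed once before
training (default); batch-level or unit weights are selectable. With unit
weights the loss reduces exactly to mean cross-entropy (ln 2 per pixel at
uniform two-class scores).

Optimization is SGD with momentum 0.9 under a triangular cyclical
learning rate between (1e−4, 1e−2), cycle length two epochs by default.
CLR was designed around SGD, hence the optimizer choice. The schedule
attains its bounds exactly at cycle starts and half-cycles and never
leaves them.

## Evaluation

Predictions are per-pixel argmax. Per class,
IoU_k = TP/(TP+FP+FN) and DSC_k = 2TP/(2TP+FP+FN), averaged over the
K = 2 classes; balanced accuracy (foreground) is (TPR + TNR)/2 with the
instrument class positive. A class with an empty union contributes 1
(a frame with no foreground and no false alarms is perfect, not 0/0).
The headline report aggregates micro (pixel counts summed over all frames
before ratios); per-frame macro averages of the same quantities are
reported alongside (`macro_*`). The identity DSC = 2·IoU/(1+IoU) holds
per class and implies mean DSC ≥ mean IoU.

## Synthetic scenes

The generator emulates the statistics of endoscopic instrument footage:
a smoothly correlated reddish tissue background; 0–n elongated metallic
tools entering from the borders (biased to the bottom corners) as
capsule-shaped shafts with an articulated tip and an optional specular
streak; optional tissue-coloured occluders overlapping the tools (never
removed from the label) and red splash-like blobs. Default 64×64 scenes
with two 4–8 px wide tools give a foreground fraction of roughly 0.05–0.35
(mean ≈ 0.19), reproducing the class imbalance that motivates the
weighted loss. `occluded_variant` adds occluders until a target fraction
of each scene's tool pixels is covered, leaving labels untouched.

What the generator does **not** emulate: real tissue texture statistics,
specular highlights from wet surfaces, motion blur, smoke, camera
vignetting, and — importantly — tools whose colour distribution overlaps
the background's. Colour is a strong cue in these scenes, so segmentation
quality here overstates what the same architecture would reach on real
surgical video; passing the end-to-end checks demonstrates that the
pipeline trains, generalizes across scene draws and survives occlusion,
not clinical performance.

## Study conditions and problem sizes

`eugnet.presets` fixes the desk-scale conditions used by the end-to-end
experiments: 64×64 scenes with two tools; the depth-4, 8-base-channel
enhanced U-Net (~22k parameters); batches of 8; 10 epochs; the
augmentation and GridMask policies above. The main experiment trains on
200 scenes with a 20 % held-out split; the occlusion A/B trains one
GridMask arm (apply_prob 0.5) and one plain arm (apply_prob 0) per seed
on 120 scenes for three seeds and evaluates both on a common 40-scene
test set with 35 % of tool pixels occluded. These sizes were chosen as
the smallest at which training is clearly converged and arm differences
are stable across seeds.

## Numerical choices and edge cases

* float32 throughout the network; metrics in float64/integers.
* round((1−r)·d) uses banker's rounding (Python `round`), making the
  dropped side 0 at r = 1 and d at r → 0.
* Nearest-neighbour resampling snaps affine coefficients below 1e−12 to
  zero so right-angle rotations map the pixel grid onto itself exactly.
* Group counts divide the channel count (largest divisor ≤ 8).
* Checkpoints are .npz containers holding every named parameter plus the
  generating configuration.
* All randomness flows from numpy Generators; one root seed is split per
  component, so any stage reproduces in isolation, including written file
  bytes.

## Known limitations

* Single-modality RGB only; no fusion of depth/kinematics streams.
* CPU-bound numpy backend: practical up to roughly 128×128 inputs and
  ~10^5 parameters; no GPU path.
* Binary segmentation only (K = 2 wired into balanced accuracy); the
  IoU/DSC machinery itself is K-class.
* Inference-time benchmarking is out of scope; no timing claims are made.
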