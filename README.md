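# eugnet

Surgical-instrument segmentation in endoscopic video frames with an
enhanced U-Net trained under **GridMask** structured-erasure augmentation —
a complete, CPU-only pipeline for researchers studying occlusion-robust
tool segmentation: synthetic surgical scenes with pixel-exact ground
truth, paired standard augmentation, GridMask, the network, class-balanced
training with a cyclical learning rate, and confusion-matrix evaluation.

## The method

Instruments occupy a small, elongated fraction of an endoscopic frame and
are routinely occluded by tissue, blood and other tools. GridMask attacks
exactly this failure mode: the training image is multiplied by a binary
lattice mask, X̃ = X ⊙ M, where M drops a square of side
round((1−r)·d) from every d×d unit of the plane, translated by offsets
(δx, δy) and optionally rotated. Unlike Cutout-style erasure the removed
regions are disconnected and uniformly spread, so the network must learn
to infer tool extent from context — the same skill real occlusion demands.

The segmentation network is a U-Net variant with a dilated deep encoder
(wider receptive field at no extra cost), additive residual skips, an
optional learned gate g⊙enc + (1−g)⊙up fusing skip and decoder features,
and depthwise separable convolutions. Training uses
frequency-balanced cross-entropy (w_k ∝ 1/freq_k, Σw_k = K) against the
background/instrument imbalance, SGD with momentum 0.9, and a triangular
cyclical learning rate between 1e−4 and 1e−2. Evaluation reports mean
IoU, mean DSC (DSC = 2·IoU/(1+IoU) per class) and balanced accuracy with
the instrument class positive.

Everything runs on numpy — the package ships its own small reverse-mode
autodiff backend (`eugnet.nn`) — so the full pipeline is reproducible
bit-for-bit on a single CPU.

## Worked example

```python
import numpy as np
import eugnet as eg
from eugnet import presets

# 200 synthetic 64x64 surgical scenes, two instruments each
dataset = eg.generate_dataset(presets.study_scene(seed=100), 200)

# tiny enhanced U-Net: depth 4, 8 base channels
model = eg.build_model(presets.study_model(), seed=0)

# 10 epochs with standard augmentation + GridMask (r=0.6, d in [8,24])
history = eg.train(model, dataset, presets.study_train(seed=0, epochs=10))
print(f"held-out mean DSC after training: {history[-1]['mean_dsc']:.3f}")

# evaluate on fresh scenes with 35% of tool pixels occluded
test = eg.generate_dataset(presets.study_scene(seed=90_000), 40)
occluded = eg.occluded_variant(test, 0.35, np.random.default_rng(7))
report = eg.evaluate(model, occluded)
print(f"occluded test: mean IoU {report.mean_iou:.3f}, "
      f"mean DSC {report.mean_dsc:.3f}, "
      f"balanced accuracy (fg.) {report.balanced_accuracy_fg:.3f}")
```

prints (about a minute on one CPU):

```
held-out mean DSC after training: 0.948
occluded test: mean IoU 0.769, mean DSC 0.862, balanced accuracy (fg.) 0.858
```

The held-out DSC says the model segments unoccluded synthetic scenes
nearly perfectly; the occluded-test numbers show how much a 35 % tool
occlusion costs, the robustness gap GridMask training is designed to
close. The label masks are untouched by every erasure, so these scores
always measure recovery of the *full* tool extent.

The same pipeline is scriptable from the shell:

```sh
eugnet synth --n 200 --size 64 --seed 100 --out data/
eugnet train -c run.yml --out runs/gridmask/
eugnet eval --checkpoint runs/gridmask/model.npz --data data/
eugnet augment-preview data/images/000.png --r 0.6 --d 16 --rot 20
```

See `eugnet.config` for the YAML run-file schema.

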