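# limbfuse

Continuous estimation of sagittal lower-limb joint angles (hip, knee,
ankle) during walking, by fusing two asynchronous sensor streams: nine
channels of surface electromyography (sEMG, 1111 Hz) and depth video
(30 fps).  sEMG leads mechanical motion by tens of milliseconds
(electromechanical delay) but is noisy and non-stationary; depth-based pose
estimation is geometrically accurate but slow, and degrades under occlusion.
The package implements a dual-branch estimator that exploits both, plus a
seeded synthetic gait-capture simulator so every stage is testable without
recorded data.  It is aimed at researchers in neuromuscular signal
processing, gait analysis and human–machine interfacing who want a fully
reproducible, desk-scale reference implementation.

## Method

Each depth frame's timestamp triggers three co-terminating trailing sEMG
windows of lengths T, 2/3·T and 1/3·T (T = 300 samples), keeping the two
streams synchronous without sliding-window bookkeeping.  The model is:

- **sEMG branch** — band-pass (20–450 Hz) filtering, then a multi-scale
  convolutional autoencoder: temporal ("single-kernel") convolutions, a
  channel shuffle mixing muscle groups, 2D ("multi-kernel") convolutions,
  and a per-scale linear head to a 32-d latent `z_s`; conv weights are
  shared across scales.  A mirrored transposed-conv decoder provides a
  reconstruction error used as an auxiliary loss.
- **Vision branch** — a small residual CNN over the depth frame producing
  one softmax heatmap per skeleton joint (19 joints, localized by
  soft-argmax and back-projected through the pinhole intrinsics) and a
  pooled feature vector `v`.
- **Fusion** — the highest-temporal-resolution latent gates the vision
  features, `ṽ = σ(W z_{1/3}) ⊙ v`, then a 3-row feature image
  `[z_s ‖ ṽ]` passes through seven 3×3 conv layers (stride 2 and channel
  doubling in layers 1–4), with global-average-pooling taps at layers 1, 4
  and 7 concatenated into the fused feature.
- **Regression** — an LSTM over fused-feature sequences with a linear head
  yields per-frame angles; training minimizes
  `MSE(θ̂, θ) + λ · MSE(x̂, x)` jointly over all four submodules.

The simulator generates Fourier-series joint trajectories (knee spanning
0–65° per cycle), phase-locked wrapped-Gaussian muscle activations that
lead motion by 0.05 cycle, activation-modulated band-limited sEMG clipped
at ±11 mV, and rendered stick-figure depth frames with optional ground
occluders.  See `docs/methods.md` for assumptions and limitations.

## Worked example

```python
import numpy as np
from limbfuse import (GaitProfile, SimConfig, TrainConfig, make_dataset,
                      train_full, predict_dataset, rmse_per_joint)

profile, config = GaitProfile(), SimConfig(duration_s=10.0, seed=1)
dataset = make_dataset(profile, config)       # 291 synchronized records
model, history = train_full(dataset, TrainConfig(epochs=50, seed=0))
pred = predict_dataset(model, dataset)
print(rmse_per_joint(pred, dataset.angles))
```

Output (about two minutes on one CPU):

```
{'hip': 0.8449659148668275, 'knee': 2.258576338831233, 'ankle': 0.8736014025552552}
```

Each value is the root-mean-square error in degrees between the model's
per-frame angle predictions and the simulator's ground truth over the 291
records: the fused model tracks the hip and ankle to within about one
degree and the knee — whose 0–65° range is by far the largest — to about
two degrees.  Training the same configuration with `modality="semg"` or
`modality="vision"` (the other branch's features zeroed) gives knee RMSEs
of 2.43° and 3.59° respectively, reproducing the expected ordering: fusion
is at least as good as either sensor alone, and the sEMG branch keeps the
estimate usable when the camera view degrades.

The same pipeline is scriptable from the shell:

```sh
limbfuse simulate --seed 1 --out data.npz
limbfuse train    --data data.npz --seed 0 --out model.ckpt.npz
limbfuse eval     --model model.ckpt.npz --data data.npz --report report.json
limbfuse ablation --data data.npz --seed 0 --out-dir runs/
limbfuse occlusion --model runs/fused.ckpt.npz --report occlusion.json
```

Every command writes a JSON sidecar with the config echo, package version
and seed; identical seeds reproduce artifacts bit-for-bit in
single-threaded mode.

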