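# Methods

## Problem and model

`limbfuse` estimates continuous sagittal lower-limb joint angles (hip, knee,
ankle; degrees) during walking from two asynchronous sensor streams: nine
channels of surface EMG (sEMG) sampled at 1111 Hz and a depth camera at
30 fps.  The estimator is a dual-branch network:

1. **sEMG branch.** The raw recording is band-pass filtered (20–450 Hz,
   4th-order Butterworth, zero-phase) — the only preprocessing applied.
   Each depth frame's timestamp triggers three co-terminating trailing
   windows of 300, 200 and 100 samples (scales T, 2/3·T, 1/3·T; ~270 ms at
   1111 Hz).  Fixed frame-triggered windows, rather than a sliding window,
   keep the two sensor streams synchronous by construction.  A convolutional
   autoencoder compresses each scale's window (time × 9 muscles, treated as
   a one-channel image): two temporal ("single-kernel", 7×1 and 5×1, stride
   2) convolutions, a group-3 channel shuffle so later layers mix muscle
   groups, per-scale average pooling to a common temporal length of 25,
   two 3×3 ("multi-kernel") convolutions, and a per-scale linear map to a
   32-dimensional latent.  The convolutional weights are shared across the
   three scales (the per-scale pooling factors 3/2/1 absorb the length
   differences); the latent heads are per-scale.  A mirrored
   transposed-convolution decoder with independent parameters reconstructs
   the windows; its mean-squared reconstruction error is an auxiliary
   training objective that anchors the latent code to the signal.
   The encoder's activation is configurable per task
   (`EncoderSpec.activation`): the joint regressor uses ReLU — rectification
   is the canonical sEMG envelope readout, and joint angles follow the
   envelope — while standalone reconstruction uses tanh, because the sEMG
   waveform is zero-mean and sign-symmetric and rectifiers discard exactly
   the sign information reconstruction needs.  When the autoencoder is
   trained on its own (`fit_autoencoder`), each training window is
   additionally circularly time-shifted by a random seeded offset every
   epoch — the band-limited correlation structure the code should capture
   is translation-invariant while individual noise realizations are not, so
   the augmentation prevents the network from memorizing a finite window
   set and lets held-out reconstruction error drop below the
   per-channel-mean constant predictor.
2. **Vision branch.** Depth frames (millimeters; desk-scale default 64×64,
   a pinhole model with configurable intrinsics standing in for a
   1280×720 sensor) pass through a small residual network: initial average
   pooling, a two-convolution block (3×3, batch norm, ReLU), an identity
   residual block, pooling, a 1×1 channel transition, a second residual
   block, and pooling — with two heads: a 19-channel softmax heatmap (one
   per skeleton joint) and a 32-dimensional pooled feature vector.  Joints
   are localized by soft-argmax, read out against the depth map (median of
   the 3×3 patch), and back-projected to camera-frame meters.
3. **Fusion.** The shortest-scale (highest-temporal-resolution) sEMG latent
   drives a sigmoid gate over the vision feature vector, element-wise.  The
   gated vision vector is copied next to each scale's latent to form a
   3-row feature image, processed by seven 3×3 conv layers (batch norm,
   leaky ReLU): layers 1–4 use stride 2 and double the channel count each
   time, layers 5–7 refine at stride 1.  Global average pooling taps at
   layers 1, 4 and 7 are concatenated, giving tap dimensions
   (2c, 16c, 16c) for base channel count c (default 4, fused length 136).
4. **Regression.** A single-layer LSTM (hidden size 64) over fused-feature
   sequences with a linear head yields per-frame angles.

Joint training minimizes `MSE(angles) + λ_recon · MSE(reconstruction)` with
Adam over all four submodules (λ_recon = 0.1, lr 1e-3, 50 epochs by
default).  Angle targets are z-scored per joint during optimisation;
predictions are mapped back to degrees.  A two-stage variant (autoencoder
pre-training) is available via `pretrain_ae_epochs` / `--pretrain-ae`.

### Angle conventions

Defined once and used identically by the simulator and the geometry module:
knee flexion = 180° − ∠(knee→hip, knee→ankle), 0° = straight; hip flexion =
signed angle between the trunk-down axis (spine→pelvis) and hip→knee,
positive forward, with the sign taken about the body's own hip-to-hip
lateral axis (making it rigid-transform invariant); ankle dorsiflexion =
∠(ankle→knee, ankle→foot) − 90°.

## Synthetic gait capture

No public dataset pairs sEMG with depth video of the same strides, so the
package carries a seeded generator emulating a treadmill session:

- **Kinematics.** Each joint angle is a 2–3 harmonic Fourier series in gait
  phase.  Default coefficients were fit once to canonical normal-walking
  curves and scaled so the knee spans exactly 0–65° per cycle; cadence
  defaults to 0.9 strides/s.  The left leg runs the same trajectory shifted
  half a cycle.
- **Muscle activations.** Per muscle, a sum of wrapped-Gaussian bumps in
  phase, clipped to [0, 1].  Default bump centers lead the corresponding
  joint motion by 0.05 of a cycle, a stand-in for electromechanical delay —
  the physiological property that makes sEMG predictive of motion.  The
  0.05 value is a simulator default, not an empirical estimate.
- **sEMG.** Per channel: activation × gain (1.5 mV) × a unit-variance
  20–450 Hz Gaussian carrier, plus a 3 µV-RMS noise-floor carrier, clipped
  to ±11 mV (the emulated acquisition range).
- **Depth.** A 19-joint stick figure (segment lengths scaled from a 1.74 m
  stature by standard anthropometric fractions) rendered side-on as
  constant-width bars (radius 0.05 m) by a pinhole camera at 2.5 m;
  nearer surface wins, background pixels carry depth 0.  An optional ground
  occluder of configurable height overwrites all pixels whose line of sight
  falls below its top edge and flags joints below that height invisible —
  emulating ground obstacles that hide the ankle and foot.
- **Labels.** The pelvis height is calibrated so the lowest foot-joint
  excursion touches the floor; stance is labeled wherever the driven foot
  joint is below 0.02 m, which crosses exactly twice per stride under the
  default profile.  Stance onsets define stride cycles for per-cycle error
  statistics.

What the generator does **not** emulate: inter-subject variability, sensor
placement drift, sEMG non-stationarity over time, cluttered backgrounds,
camera noise, soft-tissue artifact, and true musculoskeletal dynamics (the
EMG–angle link here is exact phase-locking plus noise).  Passing tests
therefore demonstrate that the pipeline's mechanics are correct and that
fusion behaves as designed under controlled degradation; they do not
establish accuracy on real recordings.

## Evaluation designs

- Per-joint RMSE (degrees) between predicted and ground-truth series.
- Per-phase mean ± std of |error| within stance and swing.
- Per-cycle maximum |error|, summarized mean ± std across strides.
- **Modality ablation:** sEMG-only, vision-only and fused models trained
  under identical settings (the inactive branch's features are identically
  zero).
- **Occlusion sweep:** the test capture is regenerated (same seed) with
  occluders of heights 0.05/0.15/0.25/0.35 m plus the unoccluded baseline,
  and the knee error of the fused and vision-only models is compared.

## Numerical and design choices

- All networks run on an in-package reverse-mode autodiff core over numpy
  arrays (float32 parameters); convolutions are computed as a loop over
  kernel taps in channels-last layout (block copies + GEMM), and gradients
  are validated against central-difference oracles in the test suite.
- Desk-scale problem sizes keep every experiment single-CPU friendly: the
  default benchmark is a 10 s capture (~290 synchronized records), 64×64
  depth frames, 50 training epochs, non-overlapping 30-frame LSTM
  sequences, batch 6.  The reconstruction objective is estimated on an
  evenly spaced subsample of at most 60 windows per step; the regression
  term always uses the full batch.
- Window triggers map to the last sEMG sample at or before the frame
  timestamp (no interpolation); early frames without a full 300-sample
  history are skipped, not zero-padded — padding would fabricate signal the
  autoencoder is then asked to reconstruct.
- "300 cycles of the sEMG capture period" is read as 300 samples (~270 ms);
  a duration-based reading differs by ~11% at 1111 Hz and can be obtained
  by passing a different `base_len`.
- The decoder's stride-2 transposed convolutions use output padding 1,
  which makes the mirrored shapes exact for even scale lengths; the
  encoder spec validates this at construction.
- Soft-argmax (not hard argmax) localizes joints so the vision branch is
  differentiable end to end and achieves sub-heatmap-pixel precision;
  heatmap peaks below twice the uniform level mark a joint invisible.
- Seeds: every stochastic component (carriers, initialisation, shuffling,
  splits) derives its generator from a `SeedSequence` keyed by the global
  seed and a fixed per-purpose constant, so a single integer reproduces a
  run bit-for-bit in single-threaded mode.

## Known limitations

- The simulator's EMG→angle relationship is far more deterministic than
  real physiology, so absolute error levels are optimistic and the margin
  between fused and sEMG-only models is smaller than it would be on real
  data (both branches see a nearly noiseless encoding of gait phase).
- Stance defined by the foot-joint height threshold covers a narrower
  fraction of the cycle (~11%) than physiological stance (~60%), because
  only the toe marker dips to the floor in the Fourier kinematics.
- The occlusion model is a vertical screen in front of the subject; it does
  not model partial limb self-occlusion or depth noise at object edges.
- Online/continual adaptation of the autoencoder at inference time is not
  implemented as a default behaviour; the optional autoencoder pre-training
  flag is the only two-stage variant exposed.
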