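"""Pyramid fusion of multi-scale sEMG latents with gated vision features.

The shortest-scale (highest-temporal-resolution) sEMG latent drives a
sigmoid gate over the vision feature vector, so muscle activity decides how
much weight each visual feature receives — the mechanism that keeps the
estimate stable when the camera view degrades.  The gated vision vector is
then copied next to each scale's latent to form a 3-row feature image, and
a seven-layer convolutional trunk (3x3 kernels, batch norm, leaky ReLU;
stride 2 with channel doubling at layers 1-4, stride 1 at layers 5-7)
downsamples it.  Global average pooling taps after layers 1, 4 and 7
preserve shallow, mid and deep semantics; their concatenation is the fused
feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm2d, Conv2d, Linear, Module, Tensor, concat, no_grad)
from .semg_encoder import LatentFeatures

__all__ = ["FusionSpec", "FusedFeature", "FusionNet", "gate_vision", "fuse"]

_TAPS = (0, 3, 6)  # 0-based indices of the 1st, 4th and 7th conv layers


@dataclass
class FusionSpec:
    latent_dim: int = 32
    vision_dim: int = 32
    base_channels: int = 4   # layer i output channels: base * 2**(i+1), i<4
    n_scales: int = 3

    @property
    def row_width(self) -> int:
        return self.latent_dim + self.vision_dim

    @property
    def layer_channels(self) -> tuple:
        c = self.base_channels
        chans = [2 * c, 4 * c, 8 * c, 16 * c]        # stride-2, doubling
        chans += [16 * c, 16 * c, 16 * c]            # stride-1 refinement
        return tuple(chans)

    @property
    def tap_dims(self) -> tuple:
        ch = self.layer_channels
        return tuple(ch[i] for i in _TAPS)

    @property
    def fused_dim(self) -> int:
        return sum(self.tap_dims)


@dataclass
class FusedFeature:
    vector: np.ndarray
    tap_dims: tuple

    def __post_init__(self):
        if len(self.vector) != sum(self.tap_dims):
            raise ValueError("fused vector length must equal sum of tap dims")
        if not np.isfinite(self.vector).all():
            raise ValueError("fused feature must be finite")


def _gap(x: Tensor) -> Tensor:
    return x.mean(axis=(2, 3))


class FusionNet(Module):
    """Gating + seven-layer pyramid trunk with GAP taps at layers 1, 4, 7."""

    def __init__(self, spec: FusionSpec = FusionSpec(), seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF5]))
        self.gate = Linear(rng, spec.latent_dim, spec.vision_dim)
        in_ch = 1
        for i, out_ch in enumerate(spec.layer_channels):
            stride = 2 if i < 4 else 1
            setattr(self, f"conv{i}", Conv2d(rng, in_ch, out_ch, 3,
                                             stride=stride, pad=1))
            setattr(self, f"bn{i}", BatchNorm2d(out_ch))
            in_ch = out_ch

    def gate_vision_batch(self, short_latent: Tensor, vision: Tensor) -> Tensor:
        """weights = sigmoid(linear(shortest-scale latent)); out = w * vision."""
        if vision.shape[-1] != self.spec.vision_dim:
            raise ValueError(f"vision dim {vision.shape[-1]} != "
                             f"{self.spec.vision_dim}")
        w = self.gate(short_latent).sigmoid()
        return w * vision

    def fuse_batch(self, latents: list, gated_vision: Tensor) -> Tensor:
        """latents: three [B, latent] Tensors -> fused [B, fused_dim]."""
        if len(latents) != self.spec.n_scales:
            raise ValueError(f"expected {self.spec.n_scales} sEMG latents, "
                             f"got {len(latents)}")
        rows = [concat([z, gated_vision], axis=1) for z in latents]
        b = rows[0].shape[0]
        x = concat([r.reshape(b, 1, 1, self.spec.row_width) for r in rows],
                   axis=2)  # [B, 1, 3, latent+vision]
        taps = []
        for i in range(len(self.spec.layer_channels)):
            x = getattr(self, f"bn{i}")(getattr(self, f"conv{i}")(x)) \
                .leaky_relu(0.01)
            if i in _TAPS:
                taps.append(_gap(x))
        return concat(taps, axis=1)


def gate_vision(emg_latents: LatentFeatures, vision_vec: np.ndarray,
                model: FusionNet) -> np.ndarray:
    """Gate a vision feature vector by the shortest-scale sEMG latent."""
    model.eval()
    with no_grad():
        out = model.gate_vision_batch(
            Tensor(np.asarray(emg_latents.shortest, np.float32)[None, :]),
            Tensor(np.asarray(vision_vec, np.float32)[None, :]))
    return out.data[0].astype(np.float64)


def fuse(emg_latents: LatentFeatures, gated_vision: np.ndarray,
         model: FusionNet) -> FusedFeature:
    """Fuse per-scale latents with the gated vision vector (inference)."""
    model.eval()
    with no_grad():
        out = model.fuse_batch(
            [Tensor(np.asarray(v, np.float32)[None, :])
             for v in emg_latents.vectors],
            Tensor(np.asarray(gated_vision, np.float32)[None, :]))
    return FusedFeature(out.data[0].astype(np.float64), model.spec.tap_dims)
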