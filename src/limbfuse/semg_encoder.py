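"""Multi-scale convolutional autoencoder for windowed sEMG.

Each scale's window (time x 9 muscles, treated as a one-channel image) passes
through a single-kernel stage (temporal-only convolutions), a channel
shuffle that interleaves grouped feature channels so later layers mix
information across muscle groups, a multi-kernel stage (2D convolutions over
time and muscle), scale-specific temporal average pooling down to a common
pre-latent size, and a per-scale linear map to the latent vector.  With
``shared=True`` the convolutional weights are shared across the three scales
(the pooling strides absorb the length differences); the per-scale latent
heads are never shared.  The decoder mirrors the encoder with transposed
convolutions and carries its own, independent parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Adam, Conv2d, ConvTranspose2d, Linear, Module, Tensor,
                 avg_pool2d, channel_shuffle, no_grad)
from .windowing import MultiScaleWindowSet

__all__ = ["EncoderSpec", "LatentFeatures", "MultiScaleAutoencoder",
           "encode", "decode", "reconstruction_loss", "fit_autoencoder"]


@dataclass
class EncoderSpec:
    latent_dim: int = 32
    n_emg_channels: int = 9
    base_len: int = 300
    single_kernel_widths: tuple = (7, 5)      # both applied with temporal stride 2
    single_channels: tuple = (8, 12)
    multi_kernel_shapes: tuple = ((3, 3), (3, 3))
    multi_channels: tuple = (16, 16)
    shuffle_groups: int = 3
    shared: bool = True
    pooled_len: int = 25
    # "relu" rectifies, which is the natural envelope readout for angle
    # regression; "tanh" is sign-symmetric, which waveform reconstruction
    # needs (rectifiers discard the sign of the zero-mean sEMG trace)
    activation: str = "relu"

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.base_len % 6:
            raise ValueError("base_len must be divisible by 6 (scales and stride)")
        if self.single_channels[-1] % self.shuffle_groups:
            raise ValueError("shuffle_groups must divide the channel count "
                             "at the shuffle point")
        if self.activation not in ("tanh", "relu"):
            raise ValueError("activation must be 'tanh' or 'relu'")
        for ln, post in zip(self.scale_lens, self.post_conv_lens):
            k1, k2 = self.single_kernel_widths
            l1 = (ln + 2 * (k1 // 2) - k1) // 2 + 1
            if (l1 - 1) * 2 - 2 * (k1 // 2) + k1 + 1 != ln or \
               (post - 1) * 2 - 2 * (k2 // 2) + k2 + 1 != l1:
                raise ValueError(
                    f"scale length {ln} is not reachable by the mirrored "
                    "stride-2 decoder; use even scale lengths")
            if post % self.pooled_len:
                raise ValueError(
                    f"scale length {ln} is incompatible with pooled_len "
                    f"{self.pooled_len}")

    @property
    def scale_lens(self) -> tuple:
        b = self.base_len
        return (b, 2 * b // 3, b // 3)

    @property
    def post_conv_lens(self) -> tuple:
        """Temporal lengths after the two stride-2 single-kernel convs."""
        k1, k2 = self.single_kernel_widths
        out = []
        for ln in self.scale_lens:
            l1 = (ln + 2 * (k1 // 2) - k1) // 2 + 1
            out.append((l1 + 2 * (k2 // 2) - k2) // 2 + 1)
        return tuple(out)

    @property
    def pool_factors(self) -> tuple:
        return tuple(post // self.pooled_len for post in self.post_conv_lens)

    @property
    def flat_dim(self) -> int:
        return self.multi_channels[-1] * self.pooled_len * self.n_emg_channels


@dataclass
class LatentFeatures:
    """One compressed feature vector per timescale (full, 2/3, 1/3)."""

    vectors: list                      # three [latent_dim] numpy arrays
    scale_ids: tuple = (0, 1, 2)

    def __post_init__(self):
        for v in self.vectors:
            if not np.isfinite(np.asarray(v)).all():
                raise ValueError("latent vectors must be finite")

    @property
    def shortest(self) -> np.ndarray:
        """The 1/3-scale latent: the highest-temporal-resolution feature."""
        return np.asarray(self.vectors[-1])


class _EncoderConvs(Module):
    """The scale-independent convolutional trunk of the encoder.

    The per-scale average pooling sits between the single-kernel and
    multi-kernel stages, so the (optionally shared) 2D convolutions always
    operate at the common pooled temporal length.
    """

    def __init__(self, rng, spec: EncoderSpec):
        super().__init__()
        k1, k2 = spec.single_kernel_widths
        c1, c2 = spec.single_channels
        self.sk1 = Conv2d(rng, 1, c1, (k1, 1), stride=(2, 1), pad=(k1 // 2, 0))
        self.sk2 = Conv2d(rng, c1, c2, (k2, 1), stride=(2, 1), pad=(k2 // 2, 0))
        m1, m2 = spec.multi_channels
        (kh1, kw1), (kh2, kw2) = spec.multi_kernel_shapes
        self.mk1 = Conv2d(rng, c2, m1, (kh1, kw1), pad=(kh1 // 2, kw1 // 2))
        self.mk2 = Conv2d(rng, m1, m2, (kh2, kw2), pad=(kh2 // 2, kw2 // 2))
        self.groups = spec.shuffle_groups
        self.act = spec.activation

    def forward(self, x: Tensor, pool_factor: int) -> Tensor:
        act = Tensor.tanh if self.act == "tanh" else Tensor.relu
        x = act(self.sk1(x))
        x = act(self.sk2(x))
        x = channel_shuffle(x, self.groups)
        if pool_factor > 1:
            x = avg_pool2d(x, (pool_factor, 1))
        x = act(self.mk1(x))
        x = act(self.mk2(x))
        return x


class _DecoderConvs(Module):
    """Mirror of the encoder trunk with transposed convolutions.

    The per-scale unpooling module (a learned transposed conv whose kernel
    equals the encoder's pooling factor) is passed in by the owner, since it
    is never shared across scales.
    """

    def __init__(self, rng, spec: EncoderSpec):
        super().__init__()
        k1, k2 = spec.single_kernel_widths
        c1, c2 = spec.single_channels
        m1, m2 = spec.multi_channels
        (kh1, kw1), (kh2, kw2) = spec.multi_kernel_shapes
        self.mk2 = ConvTranspose2d(rng, m2, m1, (kh2, kw2),
                                   pad=(kh2 // 2, kw2 // 2))
        self.mk1 = ConvTranspose2d(rng, m1, c2, (kh1, kw1),
                                   pad=(kh1 // 2, kw1 // 2))
        self.sk2 = ConvTranspose2d(rng, c2, c1, (k2, 1), stride=(2, 1),
                                   pad=(k2 // 2, 0), output_padding=(1, 0))
        self.sk1 = ConvTranspose2d(rng, c1, 1, (k1, 1), stride=(2, 1),
                                   pad=(k1 // 2, 0), output_padding=(1, 0))
        self.groups = spec.shuffle_groups
        self.act = spec.activation

    def forward(self, x: Tensor, unpool) -> Tensor:
        act = Tensor.tanh if self.act == "tanh" else Tensor.relu
        x = act(self.mk2(x))
        x = act(self.mk1(x))
        x = act(unpool(x))
        # inverse of the encoder's shuffle: transpose with swapped factors
        b, c, h, w = x.shape
        x = (x.reshape(b, c // self.groups, self.groups, h, w)
              .transpose(0, 2, 1, 3, 4).reshape(b, c, h, w))
        x = act(self.sk2(x))
        return self.sk1(x)


class MultiScaleAutoencoder(Module):
    """Shared-weight (optional) three-scale convolutional autoencoder."""

    def __init__(self, spec: EncoderSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xAE]))
        n_trunks = 1 if spec.shared else 3
        self.enc_trunks = [_EncoderConvs(rng, spec) for _ in range(n_trunks)]
        self.dec_trunks = [_DecoderConvs(rng, spec) for _ in range(n_trunks)]
        for i, m in enumerate(self.enc_trunks):
            setattr(self, f"enc_trunk{i}", m)
        for i, m in enumerate(self.dec_trunks):
            setattr(self, f"dec_trunk{i}", m)
        # per-scale unpooling (transposed conv with kernel = pool factor) and
        # latent heads: never shared, absorbing the per-scale geometry
        c2 = spec.single_channels[-1]
        for s, f in enumerate(spec.pool_factors):
            setattr(self, f"enc_head{s}", Linear(rng, spec.flat_dim, spec.latent_dim))
            setattr(self, f"dec_head{s}", Linear(rng, spec.latent_dim, spec.flat_dim))
            setattr(self, f"unpool{s}",
                    ConvTranspose2d(rng, c2, c2, (f, 1), stride=(f, 1)))

    def _trunk(self, trunks, s: int):
        return trunks[0 if self.spec.shared else s]

    def encode_batch(self, xs: list) -> list:
        """xs: three arrays/Tensors [B, T_s, C] -> three Tensors [B, latent]."""
        zs = []
        for s, x in enumerate(xs):
            x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, np.float32))
            b, t, c = x.shape
            x = x.reshape(b, 1, t, c)
            feat = self._trunk(self.enc_trunks, s)(x, self.spec.pool_factors[s])
            z = getattr(self, f"enc_head{s}")(feat.reshape(b, self.spec.flat_dim))
            zs.append(z)
        return zs

    def decode_batch(self, zs: list) -> list:
        outs = []
        mc = self.spec.multi_channels[-1]
        for s, z in enumerate(zs):
            z = z if isinstance(z, Tensor) else Tensor(np.asarray(z, np.float32))
            b = z.shape[0]
            x = getattr(self, f"dec_head{s}")(z)
            x = x.reshape(b, mc, self.spec.pooled_len, self.spec.n_emg_channels)
            x = self._trunk(self.dec_trunks, s)(x, getattr(self, f"unpool{s}"))
            t = self.spec.scale_lens[s]
            outs.append(x.reshape(b, t, self.spec.n_emg_channels))
        return outs

    def n_conv_parameters(self) -> int:
        """Parameters of the encoder convolutional trunk(s) only."""
        return sum(m.n_parameters() for m in self.enc_trunks)


def encode(ws: MultiScaleWindowSet, model: MultiScaleAutoencoder) -> LatentFeatures:
    """Compress one window set to per-scale latent vectors (inference)."""
    exp = model.spec.scale_lens
    got = tuple(w.shape[0] for w in ws.windows)
    if got != exp:
        raise ValueError(f"window lengths {got} do not match spec scales {exp}")
    model.eval()
    with no_grad():
        zs = model.encode_batch([w[None, :, :] for w in ws.windows])
    return LatentFeatures([z.data[0].copy() for z in zs])


def decode(z: LatentFeatures, model: MultiScaleAutoencoder) -> tuple:
    """Reconstruct the three windows from latent vectors (inference)."""
    for v in z.vectors:
        if np.asarray(v).shape != (model.spec.latent_dim,):
            raise ValueError("latent dimension does not match spec")
    model.eval()
    with no_grad():
        outs = model.decode_batch([np.asarray(v)[None, :] for v in z.vectors])
    return tuple(o.data[0] for o in outs)


def reconstruction_loss(x, xhat):
    """MSE averaged over scales, channels and time.

    Accepts triples of arrays (returns float) or Tensors (returns a Tensor
    participating in autodiff).
    """
    if len(x) != len(xhat):
        raise ValueError("scale count mismatch")
    terms = []
    tensor_mode = any(isinstance(a, Tensor) for a in list(x) + list(xhat))
    for a, b in zip(x, xhat):
        ad = a if isinstance(a, Tensor) else Tensor(np.asarray(a, np.float32))
        bd = b if isinstance(b, Tensor) else Tensor(np.asarray(b, np.float32))
        if ad.shape != bd.shape:
            raise ValueError(f"shape mismatch {ad.shape} vs {bd.shape}")
        terms.append(((ad - bd) ** 2).mean())
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    total = total * (1.0 / len(terms))
    return total if tensor_mode else float(total.data)


def fit_autoencoder(model: MultiScaleAutoencoder, windows: tuple,
                    epochs: int = 50, batch_size: int = 16, lr: float = 1e-3,
                    seed: int = 0, val_windows: tuple | None = None,
                    augment_shifts: bool = True) -> dict:
    """Train the autoencoder on stacked window arrays ([N,T_s,C] per scale).

    With ``augment_shifts`` each training window is circularly shifted in
    time by a random (seeded) offset every epoch: the band-limited
    correlation structure the code should capture is translation-invariant,
    while the individual noise realizations are not, so the augmentation
    stops the network from memorizing the finite training set.

    Returns a history dict with per-epoch train loss (and val loss when
    validation windows are given).
    """
    n = windows[0].shape[0]
    if n < 1:
        raise ValueError("no training windows")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF17]))
    opt = Adam(model.parameters(), lr=lr)
    hist = {"train_loss": [], "val_loss": []}
    model.train()
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for i0 in range(0, n, batch_size):
            idx = order[i0:i0 + batch_size]
            if augment_shifts:
                xs = []
                for w in windows:
                    batch = w[idx].astype(np.float32, copy=True)
                    shifts = rng.integers(0, batch.shape[1], size=len(idx))
                    for k, s in enumerate(shifts):
                        batch[k] = np.roll(batch[k], int(s), axis=0)
                    xs.append(Tensor(batch))
            else:
                xs = [Tensor(w[idx].astype(np.float32)) for w in windows]
            zs = model.encode_batch(xs)
            rec = model.decode_batch(zs)
            loss = reconstruction_loss(xs, rec)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        hist["train_loss"].append(float(np.mean(losses)))
        if val_windows is not None:
            model.eval()
            with no_grad():
                xs = [Tensor(w.astype(np.float32)) for w in val_windows]
                rec = model.decode_batch(model.encode_batch(xs))
                hist["val_loss"].append(float(reconstruction_loss(xs, rec).data))
            model.train()
    model.eval()
    return hist
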