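"""Neural-network layers built on the autodiff core.

A ``Module`` owns named parameters (and non-trainable buffers such as
batch-norm running statistics) and can recursively collect them from
sub-modules, which gives checkpointing and optimisation a flat
name -> array view of any model.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, avg_pool2d, conv2d, conv_transpose2d

__all__ = [
    "Module", "Linear", "Conv2d", "ConvTranspose2d", "BatchNorm2d",
    "LSTM", "channel_shuffle",
]


class Module:
    """Base class: tracks parameters, buffers, sub-modules, train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def add_param(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(array, dtype=np.float32), requires_grad=True)
        self._params[name] = t
        object.__setattr__(self, name, t)
        return t

    def add_buffer(self, name: str, array: np.ndarray) -> np.ndarray:
        a = np.asarray(array, dtype=np.float32)
        self._buffers[name] = a
        object.__setattr__(self, name, a)
        return a

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        seen = set()
        for name, t in self._params.items():
            if id(t) not in seen:
                seen.add(id(t))
                yield prefix + name, t
        for mname, mod in self._modules.items():
            for name, t in mod.named_parameters(prefix + mname + "."):
                if id(t) not in seen:
                    seen.add(id(t))
                    yield name, t

    def named_buffers(self, prefix: str = ""):
        for name in self._buffers:
            yield prefix + name, self._buffers[name]
        for mname, mod in self._modules.items():
            yield from mod.named_buffers(prefix + mname + ".")

    def n_parameters(self) -> int:
        return sum(int(t.data.size) for t in self.parameters())

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for t in self.parameters():
            t.grad = None

    # -- checkpointing -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: t.data.copy() for name, t in self.named_parameters()}
        for name, b in self.named_buffers():
            d["buffer:" + name] = b.copy()
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for name, arr in d.items():
            if name.startswith("buffer:"):
                self._set_buffer(name[len("buffer:"):], arr)
            else:
                if name not in params:
                    raise KeyError(f"unknown parameter {name!r}")
                if params[name].data.shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: "
                        f"{params[name].data.shape} vs {arr.shape}")
                params[name].data = arr.astype(np.float32).copy()

    def _set_buffer(self, path: str, arr: np.ndarray):
        mod = self
        parts = path.split(".")
        for p in parts[:-1]:
            mod = mod._modules[p]
        mod._buffers[parts[-1]][...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape)


class Linear(Module):
    def __init__(self, rng, in_dim: int, out_dim: int, zero_init: bool = False):
        super().__init__()
        w = np.zeros((in_dim, out_dim)) if zero_init else \
            _kaiming(rng, (in_dim, out_dim), in_dim)
        self.add_param("weight", w)
        self.add_param("bias", np.zeros(out_dim))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, kernel, stride=1, pad=0):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else tuple(kernel)
        self.stride = (stride, stride) if isinstance(stride, int) else tuple(stride)
        self.pad = (pad, pad) if isinstance(pad, int) else tuple(pad)
        self.add_param("weight", _kaiming(rng, (out_ch, in_ch, kh, kw),
                                          in_ch * kh * kw))
        self.add_param("bias", np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class ConvTranspose2d(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, kernel, stride=1, pad=0,
                 output_padding=0):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else tuple(kernel)
        self.stride = (stride, stride) if isinstance(stride, int) else tuple(stride)
        self.pad = (pad, pad) if isinstance(pad, int) else tuple(pad)
        op = output_padding
        self.output_padding = (op, op) if isinstance(op, int) else tuple(op)
        self.add_param("weight", _kaiming(rng, (in_ch, out_ch, kh, kw),
                                          in_ch * kh * kw))
        self.add_param("bias", np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, self.stride,
                                self.pad, self.output_padding)


class BatchNorm2d(Module):
    """Batch norm over (B, H, W) per channel with running statistics."""

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.add_param("gamma", np.ones(n_ch))
        self.add_param("beta", np.zeros(n_ch))
        self.add_buffer("running_mean", np.zeros(n_ch))
        self.add_buffer("running_var", np.ones(n_ch))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + \
                m * mu.data.reshape(-1)
            self.running_var[...] = (1 - m) * self.running_var + \
                m * var.data.reshape(-1)
            xn = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = self.running_mean[None, :, None, None]
            var = self.running_var[None, :, None, None]
            xn = (x - mu) * ((var + self.eps) ** -0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xn * g + b


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """Interleave grouped channels: reshape (g, c/g) -> transpose -> flatten.

    For 6 channels, groups=3 the permutation is (0, 2, 4, 1, 3, 5).
    """
    b, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"channels {c} not divisible by groups {groups}")
    return (x.reshape(b, groups, c // groups, h, w)
             .transpose(0, 2, 1, 3, 4)
             .reshape(b, c, h, w))


class LSTM(Module):
    """Single-layer LSTM; input [B, T, D] -> hidden states [B, T, H]."""

    def __init__(self, rng, in_dim: int, hidden_dim: int):
        super().__init__()
        self.hidden_dim = hidden_dim
        k = np.sqrt(1.0 / hidden_dim)
        self.add_param("w_ih", rng.uniform(-k, k, (in_dim, 4 * hidden_dim)))
        self.add_param("w_hh", rng.uniform(-k, k, (hidden_dim, 4 * hidden_dim)))
        self.add_param("bias", np.zeros(4 * hidden_dim))

    def forward(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        hd = self.hidden_dim
        h = Tensor(np.zeros((b, hd), dtype=np.float32))
        c = Tensor(np.zeros((b, hd), dtype=np.float32))
        outs = []
        for step in range(t):
            xt = x[:, step, :]
            gates = xt @ self.w_ih + h @ self.w_hh + self.bias
            i = gates[:, 0 * hd:1 * hd].sigmoid()
            f = gates[:, 1 * hd:2 * hd].sigmoid()
            g = gates[:, 2 * hd:3 * hd].tanh()
            o = gates[:, 3 * hd:4 * hd].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h.reshape(b, 1, hd))
        from .tensor import concat
        return concat(outs, axis=1)
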