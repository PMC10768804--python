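"""Neural-network building blocks on top of :mod:`cpifusion.autodiff`.

Layers follow the usual Module/Parameter pattern: a module owns named
parameters and submodules, `parameters()` walks the tree, and optimizers
update any parameter whose ``frozen`` flag is not set (the flag is how
the encoder-freezing utility of the fine-tuning stage is realized).

Initialization is explicit: every module takes a ``numpy.random.Generator``
so that model construction is reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Parameter", "Module", "Linear", "Embedding", "LayerNorm",
    "Conv1d", "Conv2d", "CrossAttention", "SGD", "Adam",
]


class Parameter(Tensor):
    __slots__ = ("name", "frozen")

    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True)
        self.name = name
        self.frozen = False


class Module:
    """Base class; submodules and Parameters are discovered via __dict__."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for k, v in self.__dict__.items():
            key = f"{prefix}{k}"
            if isinstance(v, Parameter):
                out.append((key, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{key}.{i}", item))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Parameter(_glorot(rng, in_dim, out_dim, (in_dim, out_dim)), "weight")
        self.bias = Parameter(np.zeros(out_dim), "bias")

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    """Learnable lookup table mapping integer indices to rows of a matrix."""

    def __init__(self, n_entries: int, dim: int, rng: np.random.Generator):
        self.table = Parameter(rng.normal(0.0, 0.1, size=(n_entries, dim)), "table")

    def __call__(self, indices: np.ndarray) -> Tensor:
        indices = np.asarray(indices, dtype=np.intp)
        return self.table[indices]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Parameter(np.ones(dim), "gain")
        self.bias = Parameter(np.zeros(dim), "bias")
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gain + self.bias


def _same_pad_indices(length: int, kernel: int) -> np.ndarray:
    """Index map (length, kernel) into a zero-padded axis of size length+kernel-1."""
    half = (kernel - 1) // 2
    return np.arange(length)[:, None] + np.arange(kernel)[None, :] + (half - (kernel - 1) // 2)


class Conv1d(Module):
    """'Same' convolution over (channels, length) via gather + matmul."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        self.weight = Parameter(
            _glorot(rng, in_ch * kernel, out_ch, (in_ch * kernel, out_ch)), "weight")
        self.bias = Parameter(np.zeros(out_ch), "bias")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel

    def __call__(self, x: Tensor) -> Tensor:
        c, length = x.shape
        k = self.kernel
        pad_l = (k - 1) // 2
        pad_r = k - 1 - pad_l
        xp = concat([Tensor(np.zeros((c, pad_l))), x, Tensor(np.zeros((c, pad_r)))], axis=1)
        idx = np.arange(length)[:, None] + np.arange(k)[None, :]
        patches = xp[:, idx]                      # (c, L, k)
        patches = patches.transpose(1, 0, 2).reshape(length, c * k)
        return (patches @ self.weight + self.bias).transpose(1, 0)  # (out_ch, L)


class Conv2d(Module):
    """'Same' 2D convolution over (channels, H, W)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        self.weight = Parameter(
            _glorot(rng, in_ch * kernel * kernel, out_ch,
                    (in_ch * kernel * kernel, out_ch)), "weight")
        self.bias = Parameter(np.zeros(out_ch), "bias")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel

    def __call__(self, x: Tensor) -> Tensor:
        c, h, w = x.shape
        k = self.kernel
        pl = (k - 1) // 2
        pr = k - 1 - pl
        data = x
        # pad height then width with zero tensors
        zh = Tensor(np.zeros((c, pl, w)))
        zh2 = Tensor(np.zeros((c, pr, w)))
        data = concat([zh, data, zh2], axis=1)
        zw = Tensor(np.zeros((c, h + k - 1, pl)))
        zw2 = Tensor(np.zeros((c, h + k - 1, pr)))
        data = concat([zw, data, zw2], axis=2)
        ih = np.arange(h)[:, None] + np.arange(k)[None, :]          # (h, k)
        iw = np.arange(w)[:, None] + np.arange(k)[None, :]          # (w, k)
        patches = data[:, ih[:, None, :, None], iw[None, :, None, :]]  # (c, h, w, k, k)
        patches = patches.transpose(1, 2, 0, 3, 4).reshape(h * w, c * k * k)
        out = patches @ self.weight + self.bias                     # (h*w, out_ch)
        return out.reshape(h, w, self.out_ch).transpose(2, 0, 1)


def max_pool1d(x: Tensor, size: int) -> Tensor:
    """Non-overlapping max pooling over the last axis; zero-pads to a multiple.

    Intended for post-ReLU activations (nonnegative), where zero padding
    cannot create a spurious maximum on windows containing real data.
    """
    c, length = x.shape
    rem = (-length) % size
    if rem:
        x = concat([x, Tensor(np.zeros((c, rem)))], axis=1)
    return x.reshape(c, (length + rem) // size, size).max(axis=2)


def max_pool2d(x: Tensor, size: int) -> Tensor:
    c, h, w = x.shape
    rh = (-h) % size
    rw = (-w) % size
    if rh:
        x = concat([x, Tensor(np.zeros((c, rh, w)))], axis=1)
    if rw:
        x = concat([x, Tensor(np.zeros((c, h + rh, rw)))], axis=2)
    hh, ww = (h + rh) // size, (w + rw) // size
    return x.reshape(c, hh, size, ww, size).max(axis=4).max(axis=2)


class CrossAttention(Module):
    """Multi-head cross attention: queries from one modality, keys/values from another.

    Scores are ``softmax(Q K^T / sqrt(C/h))`` per head; heads are concatenated.
    A residual connection on the (projected) query path plus layer norm
    stabilizes training. Padded key rows are excluded via an additive mask.
    """

    def __init__(self, q_dim: int, kv_dim: int, embed_dim: int, n_heads: int,
                 rng: np.random.Generator, identity_init: bool = False):
        if embed_dim % n_heads != 0:
            raise ValueError(
                f"embed_dim {embed_dim} not divisible by n_heads {n_heads}")
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.f_q = Linear(q_dim, embed_dim, rng)
        self.f_k = Linear(kv_dim, embed_dim, rng)
        self.f_v = Linear(kv_dim, embed_dim, rng)
        self.norm = LayerNorm(embed_dim)
        if identity_init:  # used by tests that need hand-checkable projections
            for lin in (self.f_q, self.f_k, self.f_v):
                lin.weight.data = np.eye(q_dim, embed_dim)
            self.norm.gain.data = np.ones(embed_dim)

    def attend(self, q_src: Tensor, kv_src: Tensor,
               key_mask: np.ndarray | None = None) -> tuple[Tensor, np.ndarray]:
        """Return (output rows, attention weights (heads, n_q, n_k))."""
        nq = q_src.shape[0]
        nk = kv_src.shape[0]
        h = self.n_heads
        dh = self.embed_dim // h
        q = self.f_q(q_src).reshape(nq, h, dh).transpose(1, 0, 2)   # (h, nq, dh)
        k = self.f_k(kv_src).reshape(nk, h, dh).transpose(1, 0, 2)
        v = self.f_v(kv_src).reshape(nk, h, dh).transpose(1, 0, 2)
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(dh))   # (h, nq, nk)
        if key_mask is not None:
            bias = np.where(np.asarray(key_mask, bool), 0.0, -1e9)
            scores = scores + bias[None, None, :]
        weights = scores.softmax(axis=-1)
        out = (weights @ v).transpose(1, 0, 2).reshape(nq, self.embed_dim)
        return out, weights.data

    def __call__(self, q_src: Tensor, kv_src: Tensor,
                 key_mask: np.ndarray | None = None) -> Tensor:
        attended, _ = self.attend(q_src, kv_src, key_mask)
        return self.norm(attended + self.f_q(q_src))


class SGD:
    def __init__(self, params: list[Parameter], lr: float = 1e-2):
        self.params = list(params)
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            if p.frozen or p.grad is None:
                continue
            p.data = p.data - self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.frozen or p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
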