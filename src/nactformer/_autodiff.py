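"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A small tensor/autograd core sized for the desk-scale transformer in this
package: dense float64 arrays, a dynamically built computation graph, and
exactly the operator set the model needs (broadcast arithmetic, batched
matmul, reshapes/transposes, padding, sliding-window unfold, softmax,
reductions, ReLU, layer norm). Gradients are accumulated by a topological
backward sweep.

Every operation is checked against central finite differences in the test
suite; the engine is deliberately simple rather than fast.
"""

from __future__ import annotations

import contextlib
import math

import numpy as np

_STATE = {"dtype": np.dtype(np.float64)}


def current_dtype() -> np.dtype:
    return _STATE["dtype"]


@contextlib.contextmanager
def precision(dtype):
    """Temporarily switch the working dtype (e.g. "float32" for training).

    Tensors and parameters created inside the context use the given dtype;
    float64 (the default) is kept for oracle-grade numerical checks.
    """
    old = _STATE["dtype"]
    _STATE["dtype"] = np.dtype(dtype)
    try:
        yield
    finally:
        _STATE["dtype"] = old


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=current_dtype())
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- autograd -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=current_dtype())
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if self.requires_grad:
            g = _unbroadcast(np.asarray(g, dtype=current_dtype()), self.data.shape)
            self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(g)
            other._accum(g)

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data ** 2))

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bw(g):
            self._accum(g * e * np.power(self.data, e - 1.0))

        return Tensor._make(np.power(self.data, e), (self,), bw)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(np.matmul(g, np.swapaxes(other.data, -1, -2)))
            other._accum(np.matmul(np.swapaxes(self.data, -1, -2), g))

        return Tensor._make(np.matmul(self.data, other.data), (self, other), bw)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape

        def bw(g):
            self._accum(g.reshape(src))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, key):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        return Tensor._make(self.data[key], (self,), bw)

    def pad2d(self, pad: int):
        """Zero-pad the trailing two axes by `pad` on every side."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]

        def bw(g):
            sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
            self._accum(g[sl])

        return Tensor._make(np.pad(self.data, width), (self,), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        src = self.data.shape

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, src))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, src))

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor._make(out_data, (self,), bw)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accum(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


def unfold(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    """Extract sliding k×k patches from a (..., C, H, W) tensor.

    Returns tokens of shape (..., L, C·k·k) in row-major patch order, matching
    an explicit double loop over patch positions.
    """
    k, s = int(kernel), int(stride)
    xp = x.pad2d(padding)
    *lead, C, H, W = xp.data.shape
    oh = (H - k) // s + 1
    ow = (W - k) // s + 1
    if oh < 1 or ow < 1:
        raise ValueError(f"kernel {k} exceeds padded extent ({H}x{W})")

    view = np.lib.stride_tricks.sliding_window_view(xp.data, (k, k), axis=(-2, -1))
    view = view[..., ::s, ::s, :, :]              # (..., C, oh, ow, k, k)
    nd = view.ndim
    perm = tuple(range(nd - 5)) + (nd - 4, nd - 3, nd - 5, nd - 2, nd - 1)
    out_data = view.transpose(perm).reshape(*lead, oh * ow, C * k * k)

    def bw(g):
        g = g.reshape(*lead, oh, ow, C, k, k)
        full = np.zeros(xp.data.shape, dtype=current_dtype())
        for di in range(k):
            for dj in range(k):
                full[..., di : di + oh * s : s, dj : dj + ow * s : s] += (
                    np.moveaxis(g[..., di, dj], -1, -3)
                )
        xp._accum(full)

    out = Tensor._make(out_data, (xp,), bw)
    return out


def unfold_token_count(h: int, w: int, k: int, s: int, p: int) -> int:
    """Closed-form number of patches produced by `unfold`."""
    return ((h + 2 * p - k) // s + 1) * ((w + 2 * p - k) // s + 1)


# ---------------------------------------------------------------------------
# Neural-network modules
# ---------------------------------------------------------------------------


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class providing recursive parameter discovery and train/eval mode."""

    def parameters(self):
        out = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Parameter):
                        out.append(item)
                    elif isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def set_training(self, flag: bool):
        for value in vars(self).values():
            if isinstance(value, Module):
                value.set_training(flag)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.set_training(flag)
        if hasattr(self, "training"):
            self.training = flag

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            p.data = a.copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / (n_in + n_out))
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.gamma + self.beta


class BatchNorm2d(Module):
    """Per-channel normalization over (batch, H, W) with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones((channels, 1, 1)))
        self.beta = Parameter(np.zeros((channels, 1, 1)))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros((channels, 1, 1))
        self.running_var = np.ones((channels, 1, 1))
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:  # x: (B, C, H, W)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data[0]
            self.running_var = (1 - m) * self.running_var + m * var.data[0]
        else:
            mu = Tensor(self.running_mean[None])
            var = Tensor(self.running_var[None])
            xc = x - mu
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.gamma + self.beta


class Conv2d(Module):
    """Same-padded 2-D convolution built from unfold + matmul."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {kernel}")
        self.kernel = kernel
        scale = math.sqrt(2.0 / (c_in * kernel * kernel + c_out))
        self.weight = Parameter(
            rng.normal(0.0, scale, size=(c_in * kernel * kernel, c_out))
        )
        self.bias = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:  # x: (B, C, H, W)
        B, C, H, W = x.shape
        pad = (self.kernel - 1) // 2
        tokens = unfold(x, self.kernel, 1, pad)      # (B, H*W, C*k*k)
        out = tokens @ self.weight + self.bias        # (B, H*W, c_out)
        return out.reshape(B, H, W, -1).transpose(0, 3, 1, 2)


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """softmax(QKᵀ/√d_k)V over the trailing (tokens, dim) axes."""
    d_k = q.shape[-1]
    scores = (q @ k.transpose(*range(q.ndim - 2), q.ndim - 1, q.ndim - 2)) * (
        1.0 / math.sqrt(d_k)
    )
    return scores.softmax(axis=-1) @ v


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.heads = heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:  # (B, N, C)
        B, N, C = x.shape
        h, dk = self.heads, C // self.heads

        def split(t):
            return t.reshape(B, N, h, dk).transpose(0, 2, 1, 3)

        out = scaled_dot_attention(split(self.q(x)), split(self.k(x)), split(self.v(x)))
        return self.proj(out.transpose(0, 2, 1, 3).reshape(B, N, C))


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class TransformerBlock(Module):
    """Pre-norm multi-head self-attention + feed-forward block."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator, mlp_ratio: int = 2):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.ffn = FeedForward(dim, mlp_ratio * dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.ffn(self.norm2(x))


class AdamW:
    """Decoupled weight-decay Adam."""

    def __init__(
        self,
        params,
        lr: float = 1e-4,
        betas=(0.85, 0.998),
        weight_decay: float = 0.02,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.weight_decay = weight_decay
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - lr * (
                m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data
            )

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_lr(step: int, total_steps: int, lr0: float, lr_min: float = 0.0) -> float:
    """Cosine-annealed learning rate."""
    if total_steps <= 1:
        return lr0
    frac = min(step, total_steps - 1) / (total_steps - 1)
    return lr_min + 0.5 * (lr0 - lr_min) * (1 + math.cos(math.pi * frac))


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of (B, C) logits against integer labels."""
    labels = np.asarray(labels, dtype=int)
    B, C = logits.shape
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))  # constant: safe shift
    z = logits - shift
    log_probs = z - z.exp().sum(axis=-1, keepdims=True).log()
    onehot = np.zeros((B, C))
    onehot[np.arange(B), labels] = 1.0
    return -(log_probs * Tensor(onehot)).sum() * (1.0 / B)
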