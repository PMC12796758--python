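"""Spatio-temporal token embedding.

Two additive components are attached to each arm's token sequence before
the shared encoder:

* a dynamic position embedding (DPE), generated per image by a small
  convolutional network (3×3 → 3×3 → 1×1, each followed by normalization
  and ReLU) and an affine projection E_pos(T) = W_pos·f(T) + b_pos — unlike
  a static table, the embedding depends on the image content;
* a sinusoidal temporal embedding TE_t indexed by the timepoint t ∈ {0, 1}
  (0 = pre-treatment, 1 = post-first-cycle):

      TE_t[2j]   = sin(t / 10000^(2j/d))
      TE_t[2j+1] = cos(t / 10000^(2j/d))

Their sum, broadcast over tokens, is the spatio-temporal embedding ST.
Ablation modes cover every combination used in practice, including a
learned static position table (SPE) in place of the DPE.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import BatchNorm2d, Conv2d, Linear, Module, Parameter, Tensor
from .t2t import flatten_map, reshape_to_map

ST_MODES = ("none", "te", "dpe", "spe", "spe_te", "full")


def temporal_embedding(t: int, d: int) -> np.ndarray:
    """Sinusoidal temporal embedding vector of length d for timepoint t."""
    if t not in (0, 1):
        raise ValueError(f"timepoint must be 0 (pre) or 1 (post), got {t}")
    if d < 2 or d % 2:
        raise ValueError(f"embedding dimension must be even and >= 2, got {d}")
    j = np.arange(d // 2)
    angle = t / np.power(10000.0, 2.0 * j / d)
    te = np.empty(d)
    te[0::2] = np.sin(angle)
    te[1::2] = np.cos(angle)
    return te


class DynamicPositionEmbedder(Module):
    """Image-conditioned position embedding E_pos(T) = W_pos·f(T) + b_pos.

    f is a three-layer conv stack (3×3, 3×3, 1×1) with batch normalization
    and ReLU after each layer, applied to the token sequence reshaped onto
    its spatial grid.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        self.conv1 = Conv2d(dim, dim, 3, rng)
        self.bn1 = BatchNorm2d(dim)
        self.conv2 = Conv2d(dim, dim, 3, rng)
        self.bn2 = BatchNorm2d(dim)
        self.conv3 = Conv2d(dim, dim, 1, rng)
        self.bn3 = BatchNorm2d(dim)
        self.w_pos = Linear(dim, dim, rng)

    def __call__(self, tokens: Tensor, h: int, w: int) -> Tensor:
        B, l, c = tokens.shape
        if h * w != l:
            raise ValueError(f"token count {l} does not fit a {h}x{w} grid")
        x = reshape_to_map(tokens, h, w)
        x = self.bn1(self.conv1(x)).relu()
        x = self.bn2(self.conv2(x)).relu()
        x = self.bn3(self.conv3(x)).relu()
        return self.w_pos(flatten_map(x))


class SpatioTemporalEmbedder(Module):
    """Combined per-token embedding ST = position part + broadcast TE_t.

    mode selects the ablation configuration: "none" (no embedding), "te"
    (temporal only), "dpe" (dynamic position only), "spe" (learned static
    table, shared across images), "spe_te", or "full" (DPE + TE).
    """

    def __init__(self, dim: int, n_tokens: int, mode: str, rng: np.random.Generator):
        if mode not in ST_MODES:
            raise ValueError(f"unknown st mode {mode!r}; choose from {ST_MODES}")
        self.mode = mode
        self.dim = dim
        if mode in ("dpe", "full"):
            self.dpe = DynamicPositionEmbedder(dim, rng)
        if mode in ("spe", "spe_te"):
            self.spe_table = Parameter(0.02 * rng.standard_normal((n_tokens, dim)))

    def spatial_part(self, tokens: Tensor, h: int, w: int) -> Tensor | None:
        if self.mode in ("dpe", "full"):
            return self.dpe(tokens, h, w)
        if self.mode in ("spe", "spe_te"):
            return self.spe_table.reshape(1, *self.spe_table.shape)
        return None

    def __call__(self, tokens: Tensor, t: int, h: int, w: int) -> Tensor:
        """Return tokens + ST for timepoint t (0 = pre, 1 = post)."""
        if self.mode == "none":
            return tokens
        out = tokens
        spatial = self.spatial_part(tokens, h, w)
        if spatial is not None:
            out = out + spatial
        if self.mode in ("te", "spe_te", "full"):
            te = Tensor(temporal_embedding(t, self.dim))
            out = out + te
        return out


def fuse_spatiotemporal(dpe: Tensor, t: int) -> Tensor:
    """ST = DPE + TE_t with the temporal vector broadcast to every token."""
    d = dpe.shape[-1]
    return dpe + Tensor(temporal_embedding(t, d))


def embed_tokens(tokens: Tensor, st: Tensor) -> Tensor:
    """Elementwise sum T + ST (invertible given ST)."""
    if tuple(tokens.shape[-2:]) != tuple(st.shape[-2:]):
        raise ValueError(f"shape mismatch: {tokens.shape} vs {st.shape}")
    return tokens + st
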