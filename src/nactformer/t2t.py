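"""Dual-arm tokens-to-token embedding with multi-scale local/global attention.

Each of the two timepoint arms (pre-treatment, post-first-cycle) owns an
independent stack of tokens-to-token blocks; the arms never share weights.
One block runs, in order:

1. a transformer step (multi-head self-attention + feed-forward),
2. reshape of the token sequence back to a spatial feature map,
3. multi-scale convolution (one same-padded conv per kernel size),
4. per-scale fusion of windowed local attention and global attention with
   learned weights α + β = 1,
5. softmax-weighted fusion across scales (weights ω sum to 1),
6. an overlapping soft split (stride < kernel) that re-tokenizes the map.

Soft splitting with overlap preserves local structure across tokenization
stages, unlike the hard non-overlapping patching of a plain ViT.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._autodiff import (
    Linear,
    Module,
    Parameter,
    Tensor,
    TransformerBlock,
    concat,
    scaled_dot_attention,
    unfold,
    unfold_token_count,
)


@dataclasses.dataclass(frozen=True)
class SoftSplitConfig:
    """Overlapping patch extraction: kernel k, stride s, zero-padding p."""

    kernel: int = 3
    stride: int = 2
    padding: int = 1

    def __post_init__(self):
        if not (self.kernel >= self.stride >= 1):
            raise ValueError(
                f"need kernel >= stride >= 1 for overlap, got k={self.kernel} s={self.stride}"
            )
        if self.padding < 0:
            raise ValueError("padding must be >= 0")

    def token_count(self, h: int, w: int) -> int:
        return unfold_token_count(h, w, self.kernel, self.stride, self.padding)


def reshape_to_map(tokens: Tensor, h: int, w: int) -> Tensor:
    """Row-major (B, l, c) → (B, c, h, w); requires l = h·w."""
    B, l, c = tokens.shape
    if h * w != l:
        raise ValueError(f"h*w = {h * w} does not match token count {l}")
    return tokens.reshape(B, h, w, c).transpose(0, 3, 1, 2)


def flatten_map(fmap: Tensor) -> Tensor:
    """(B, c, h, w) → row-major (B, h·w, c); inverse of reshape_to_map."""
    B, c, h, w = fmap.shape
    return fmap.transpose(0, 2, 3, 1).reshape(B, h * w, c)


def soft_split(fmap: Tensor, cfg: SoftSplitConfig) -> Tensor:
    """Extract overlapping kernel×kernel patches as tokens, row-major.

    Output has cfg.token_count(h, w) tokens of dimension kernel²·c.
    """
    *_, h, w = fmap.shape
    if cfg.kernel > h + 2 * cfg.padding or cfg.kernel > w + 2 * cfg.padding:
        raise ValueError(
            f"kernel {cfg.kernel} exceeds padded extent "
            f"({h + 2 * cfg.padding}x{w + 2 * cfg.padding})"
        )
    return unfold(fmap, cfg.kernel, cfg.stride, cfg.padding)


class MultiScaleConv(Module):
    """One same-padded convolution per (odd) kernel size."""

    def __init__(self, channels: int, kernel_sizes, rng: np.random.Generator):
        from ._autodiff import Conv2d

        for k in kernel_sizes:
            if k % 2 == 0:
                raise ValueError(f"kernel sizes must be odd, got {k}")
        self.kernel_sizes = tuple(kernel_sizes)
        self.convs = [Conv2d(channels, channels, k, rng) for k in kernel_sizes]

    def __call__(self, fmap: Tensor) -> list[Tensor]:
        return [conv(fmap) for conv in self.convs]


class LocalGlobalAttention(Module):
    """Windowed local and full global self-attention with shared Q/K/V.

    Both attention paths use the same single-head projections, so local
    attention with the window covering the whole map coincides exactly
    with global attention.
    """

    def __init__(self, channels: int, window: int, rng: np.random.Generator):
        if window <= 0:
            raise ValueError(f"window must be positive, got {window}")
        self.window = window
        self.q = Linear(channels, channels, rng)
        self.k = Linear(channels, channels, rng)
        self.v = Linear(channels, channels, rng)

    def global_attention(self, fmap: Tensor) -> Tensor:
        """softmax(QKᵀ/√d_k)V over all h·w positions."""
        if np.isnan(fmap.data).any():
            raise ValueError("NaN in attention input")
        B, c, h, w = fmap.shape
        tokens = flatten_map(fmap)
        out = scaled_dot_attention(self.q(tokens), self.k(tokens), self.v(tokens))
        return reshape_to_map(out, h, w)

    def local_attention(self, fmap: Tensor, window: int | None = None) -> Tensor:
        """Self-attention inside non-overlapping ω×ω windows.

        The map is zero-padded up to a multiple of the window, partitioned,
        attended per window (no cross-window attention), and cropped back.
        """
        win = self.window if window is None else window
        if win <= 0:
            raise ValueError(f"window must be positive, got {win}")
        B, c, h, w = fmap.shape
        ph = (-h) % win
        pw = (-w) % win
        x = fmap
        if ph or pw:
            x = _pad_bottom_right(x, ph, pw)
        H, W = h + ph, w + pw
        nh, nw = H // win, W // win
        # (B, c, nh, win, nw, win) → (B, nh, nw, win², c)
        x = x.reshape(B, c, nh, win, nw, win).transpose(0, 2, 4, 3, 5, 1)
        x = x.reshape(B * nh * nw, win * win, c)
        out = scaled_dot_attention(self.q(x), self.k(x), self.v(x))
        out = out.reshape(B, nh, nw, win, win, c).transpose(0, 5, 1, 3, 2, 4)
        out = out.reshape(B, c, H, W)
        if ph or pw:
            out = out[:, :, :h, :w]
        return out


def _pad_bottom_right(x: Tensor, ph: int, pw: int) -> Tensor:
    data = np.pad(x.data, ((0, 0), (0, 0), (0, ph), (0, pw)))

    def bw(g):
        x._accum(g[:, :, : x.shape[2], : x.shape[3]])

    return Tensor._make(data, (x,), bw)


class ScaleBank(Module):
    """Per-scale local/global mixing logits and the scale-fusion head.

    For scale j, (α_j, β_j) = softmax of two learned scalars, so the
    constraint α + β = 1 holds by construction. The scale weights ω are a
    softmax over a fully connected layer applied to the concatenated
    global-average-pooled per-scale descriptors.
    """

    def __init__(self, channels: int, n_scales: int, rng: np.random.Generator):
        self.local_global_logits = [
            Parameter(np.zeros(2)) for _ in range(n_scales)
        ]
        self.scale_fc = Linear(n_scales * channels, n_scales, rng)
        self.n_scales = n_scales

    def local_global_weights(self, scale_index: int) -> Tensor:
        return self.local_global_logits[scale_index].softmax(axis=-1)

    def fuse_local_global(
        self, f_local: Tensor, f_global: Tensor, scale_index: int
    ) -> Tensor:
        """α·F_local + β·F_global with (α, β) = softmax(logits), α + β = 1."""
        if f_local.shape != f_global.shape:
            raise ValueError(
                f"shape mismatch: {f_local.shape} vs {f_global.shape}"
            )
        ab = self.local_global_weights(scale_index)
        return f_local * ab[0] + f_global * ab[1]

    def scale_weights(self, maps: list[Tensor]) -> Tensor:
        """(B, n_scales) softmax weights from pooled per-scale descriptors."""
        pooled = concat([m.mean(axis=(2, 3)) for m in maps], axis=-1)
        return self.scale_fc(pooled).softmax(axis=-1)

    def fuse_scales(self, maps: list[Tensor]) -> Tensor:
        """Σ_j ω_j · map_j with ω = softmax(FC(pooled descriptors))."""
        if not maps:
            raise ValueError("fuse_scales needs at least one map")
        shapes = {m.shape for m in maps}
        if len(shapes) != 1:
            raise ValueError(f"scale maps differ in shape: {sorted(shapes)}")
        omega = self.scale_weights(maps)  # (B, n)
        out = None
        for j, m in enumerate(maps):
            w = omega[:, j].reshape(-1, 1, 1, 1)
            out = m * w if out is None else out + m * w
        return out


class TokensToTokenBlock(Module):
    """One arm-specific tokens-to-token stage."""

    def __init__(
        self,
        in_dim: int,
        channels: int,
        heads: int,
        kernel_sizes,
        window: int,
        split: SoftSplitConfig,
        rng: np.random.Generator,
    ):
        self.proj = Linear(in_dim, channels, rng)
        self.transformer = TransformerBlock(channels, heads, rng)
        self.conv = MultiScaleConv(channels, kernel_sizes, rng)
        self.attn = [
            LocalGlobalAttention(channels, window, rng) for _ in kernel_sizes
        ]
        self.bank = ScaleBank(channels, len(kernel_sizes), rng)
        self.split = split
        self.channels = channels

    def transformer_step(self, tokens: Tensor) -> Tensor:
        """Shape-preserving attention + feed-forward step on (B, l, c)."""
        if np.isnan(tokens.data).any():
            raise ValueError("NaN in token sequence")
        return self.transformer(tokens)

    def __call__(self, tokens: Tensor, h: int, w: int) -> tuple[Tensor, int, int]:
        """(B, l, in_dim) tokens on an h×w grid → next-stage tokens.

        Returns (tokens', h', w') where tokens' has token dimension
        kernel²·channels and length split.token_count(h, w).
        """
        x = self.proj(tokens)
        x = self.transformer_step(x)
        fmap = reshape_to_map(x, h, w)
        scale_maps = [
            self.bank.fuse_local_global(
                attn.local_attention(conv_map),
                attn.global_attention(conv_map),
                j,
            )
            for j, (conv_map, attn) in enumerate(
                zip(self.conv(fmap), self.attn)
            )
        ]
        fused = self.bank.fuse_scales(scale_maps)
        out = soft_split(fused, self.split)
        oh = (h + 2 * self.split.padding - self.split.kernel) // self.split.stride + 1
        ow = (w + 2 * self.split.padding - self.split.kernel) // self.split.stride + 1
        return out, oh, ow


class TokensToTokenArm(Module):
    """The full per-timepoint tokenization arm: an initial soft split of the
    raw six-channel image followed by a stack of tokens-to-token blocks and
    a final projection to the encoder dimension."""

    def __init__(
        self,
        image_side: int,
        in_channels: int,
        block_dims,
        heads: int,
        kernel_sizes,
        window: int,
        split: SoftSplitConfig,
        first_split: SoftSplitConfig,
        out_dim: int,
        rng: np.random.Generator,
    ):
        self.first_split = first_split
        h = (image_side + 2 * first_split.padding - first_split.kernel) // first_split.stride + 1
        self.grid = (h, h)
        in_dim = first_split.kernel**2 * in_channels
        self.blocks = []
        for dim in block_dims:
            self.blocks.append(
                TokensToTokenBlock(in_dim, dim, heads, kernel_sizes, window, split, rng)
            )
            in_dim = split.kernel**2 * dim
        self.out_proj = Linear(in_dim, out_dim, rng)

    def __call__(self, image: Tensor) -> Tensor:
        """(B, 6, H, W) image → (B, N, out_dim) token sequence."""
        tokens = soft_split(image, self.first_split)
        h, w = self.grid
        for block in self.blocks:
            tokens, h, w = block(tokens, h, w)
        self.final_grid = (h, w)
        return self.out_proj(tokens)


class HardSplitArm(Module):
    """Ablation tokenizer: plain non-overlapping patch embedding (ViT-style)."""

    def __init__(
        self,
        image_side: int,
        in_channels: int,
        patch: int,
        out_dim: int,
        rng: np.random.Generator,
    ):
        if image_side % patch:
            raise ValueError("image side must be divisible by the patch size")
        self.split = SoftSplitConfig(kernel=patch, stride=patch, padding=0)
        self.proj = Linear(patch**2 * in_channels, out_dim, rng)
        g = image_side // patch
        self.final_grid = (g, g)

    def __call__(self, image: Tensor) -> Tensor:
        return self.proj(soft_split(image, self.split))
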