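"""Adaptive feature fusion and classification head.

The two embedded token sequences are encoded by a single transformer
encoder with shared parameters, then fused:

    F̄_before = GAP(F_before),  F̄_after = GAP(F_after)
    (α, β)   = softmax(FC([F̄_before ; F̄_after]))
    F_fused  = α·F_before + β·F_after
    ΔF       = F_after − F_before
    F_final  = [F_fused ; ΔF]            (feature-axis concatenation)
    P        = softmax(FC(GAP(F_final))),  ŷ = argmax P

The explicit difference term ΔF hands the classifier the longitudinal
change directly; the convex fusion weights adapt per case. An alternative
"cls" head (prepended class token, as in a plain ViT) is provided for
ablation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._autodiff import (
    LayerNorm,
    Linear,
    Module,
    Parameter,
    Tensor,
    TransformerBlock,
    concat,
)

HEAD_MODES = ("affc", "cls")


@dataclasses.dataclass
class Decision:
    probabilities: np.ndarray  # (B, 2), rows sum to 1
    predicted: np.ndarray      # (B,), argmax with ties → class 0


class SharedEncoder(Module):
    """One transformer encoder applied to both arms with the same weights."""

    def __init__(self, dim: int, depth: int, heads: int, rng: np.random.Generator):
        self.blocks = [TransformerBlock(dim, heads, rng) for _ in range(depth)]
        self.norm = LayerNorm(dim)

    def encode(self, tokens: Tensor) -> Tensor:
        for block in self.blocks:
            tokens = block(tokens)
        return self.norm(tokens)

    def __call__(self, pre_tokens: Tensor, post_tokens: Tensor) -> tuple[Tensor, Tensor]:
        if pre_tokens.shape != post_tokens.shape:
            raise ValueError(
                f"arm shapes differ: {pre_tokens.shape} vs {post_tokens.shape}"
            )
        return self.encode(pre_tokens), self.encode(post_tokens)


def global_average_pool(features: Tensor) -> Tensor:
    """Arithmetic mean over the token axis: (B, N, D) → (B, D)."""
    if features.shape[-2] < 1:
        raise ValueError("cannot pool an empty token sequence")
    return features.mean(axis=-2)


def feature_difference(f_before: Tensor, f_after: Tensor) -> Tensor:
    """ΔF = F_after − F_before."""
    if f_before.shape != f_after.shape:
        raise ValueError(f"shape mismatch: {f_before.shape} vs {f_after.shape}")
    return f_after - f_before


def fuse_features(f_before: Tensor, f_after: Tensor, alpha, beta) -> Tensor:
    """Elementwise convex combination α·F_before + β·F_after (α + β = 1)."""
    if f_before.shape != f_after.shape:
        raise ValueError(f"shape mismatch: {f_before.shape} vs {f_after.shape}")
    a = alpha.data if isinstance(alpha, Tensor) else np.asarray(alpha)
    b = beta.data if isinstance(beta, Tensor) else np.asarray(beta)
    if not np.allclose(a + b, 1.0, atol=1e-6):
        raise ValueError("fusion weights must satisfy alpha + beta = 1")
    return f_before * alpha + f_after * beta


class AdaptiveFusionHead(Module):
    """AFFC: adaptive convex fusion + explicit difference + linear classifier."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.weight_fc = Linear(2 * dim, 2, rng)
        self.classifier = Linear(2 * dim, 2, rng)

    def fusion_weights(self, pooled_before: Tensor, pooled_after: Tensor) -> Tensor:
        """(B, 2) softmax weights (α, β) from the concatenated pooled vectors."""
        if np.isnan(pooled_before.data).any() or np.isnan(pooled_after.data).any():
            raise ValueError("NaN in pooled features")
        logits = self.weight_fc(concat([pooled_before, pooled_after], axis=-1))
        return logits.softmax(axis=-1)

    def __call__(self, f_before: Tensor, f_after: Tensor) -> Tensor:
        """Return (B, 2) class logits; `decide` applies the final softmax."""
        ab = self.fusion_weights(
            global_average_pool(f_before), global_average_pool(f_after)
        )  # (B, 2)
        alpha = ab[:, 0].reshape(-1, 1, 1)
        beta = ab[:, 1].reshape(-1, 1, 1)
        fused = f_before * alpha + f_after * beta
        delta = feature_difference(f_before, f_after)
        final = concat([fused, delta], axis=-1)          # (B, N, 2D)
        return self.classifier(global_average_pool(final))


class ClsTokenHead(Module):
    """Ablation head: a learned class token prepended to each arm's sequence
    is encoded along with the tokens; the two arms' class-token outputs are
    concatenated and classified."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.cls_token = Parameter(0.02 * rng.standard_normal((1, 1, dim)))
        self.classifier = Linear(2 * dim, 2, rng)

    def prepend(self, tokens: Tensor) -> Tensor:
        B = tokens.shape[0]
        cls = self.cls_token + Tensor(np.zeros((B, 1, tokens.shape[-1])))
        return concat([cls, tokens], axis=-2)

    def __call__(self, f_before: Tensor, f_after: Tensor) -> Tensor:
        # caller prepends the token before encoding; here we read position 0
        return self.classifier(concat([f_before[:, 0], f_after[:, 0]], axis=-1))


def decide(logits: Tensor | np.ndarray) -> Decision:
    """Softmax probabilities and argmax labels (tie → class 0)."""
    z = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    z = z - z.max(axis=-1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=-1, keepdims=True)
    # strict argmax with lowest-index tie-break (numpy argmax already
    # returns the first maximal index)
    return Decision(probabilities=p, predicted=p.argmax(axis=-1))
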