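"""Proteome-level transformer encoder.

A proteome is a *set* of proteins, so the encoder uses no positional
encoding: each token is the sum of two linear projections, one of the
protein's embedding channel and one of its functional-encoding channel.
Masked proteins have their embedding channel replaced by their sampled
functional encoding, and the model reconstructs the original embedding from
the rest of the proteome.  The row-stochastic attention matrices of every
head are captured on each forward pass; their symmetrized coefficients are
the unsupervised interaction features used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._autodiff import LayerNorm, Linear, Module, Tensor

__all__ = ["BackboneConfig", "MaskedBatch", "AttentionStack", "Backbone",
           "subsample_context", "apply_masking", "extract_pair_features",
           "feature_names"]


@dataclass
class BackboneConfig:
    n_layers: int = 6
    n_heads_per_layer: int = 8   # 6 x 8 = 48 heads in the default small model
    model_dim: int = 256
    feedforward_dim: int = 512
    input_dim: int = 64
    context_cap: int = 4096
    mask_fraction: float = 0.5
    mask_mode: str = "encoding"  # "encoding" | "zero" embedding channel
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.mask_fraction < 1.0:
            raise ValueError("mask_fraction must lie in (0, 1)")
        if self.context_cap < 1:
            raise ValueError("context_cap must be >= 1")
        if self.model_dim % self.n_heads_per_layer != 0:
            raise ValueError("model_dim must be divisible by n_heads_per_layer")
        if self.mask_mode not in ("encoding", "zero"):
            raise ValueError("mask_mode must be 'encoding' or 'zero'")

    @property
    def total_heads(self) -> int:
        return self.n_layers * self.n_heads_per_layer

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class MaskedBatch:
    """One proteome's token matrices with mask bookkeeping.

    `baselines` holds, for each masked row, the functional-encoding vector
    xbar used for replacement — the same vector the loss's residuals are
    defined against.
    """

    token_embeddings: np.ndarray      # (N, d), masked rows already replaced
    functional_encodings: np.ndarray  # (N, d), never altered by masking
    mask_indicator: np.ndarray        # (N,) bool
    baselines: np.ndarray             # (n_masked, d)
    originals: np.ndarray             # (n_masked, d) true x for masked rows

    @property
    def n_tokens(self) -> int:
        return self.token_embeddings.shape[0]


@dataclass
class AttentionStack:
    """Per layer, per head: the N x N row-stochastic attention matrix."""

    attention: np.ndarray  # (n_layers, n_heads, N, N)

    def validate(self, atol: float = 1e-5) -> None:
        if np.any(self.attention < -atol):
            raise ValueError("negative attention coefficients")
        sums = self.attention.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=atol):
            raise ValueError("attention rows must sum to 1")

    @property
    def n_tokens(self) -> int:
        return self.attention.shape[-1]


def subsample_context(indices: Sequence[int] | int, context_cap: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Uniformly subsample a proteome down to the context cap.

    Accepts either the token count or an explicit index sequence; returns the
    retained indices (identity when already within the cap).
    """
    if context_cap < 1:
        raise ValueError("context_cap must be >= 1")
    idx = np.arange(indices) if isinstance(indices, (int, np.integer)) \
        else np.asarray(indices)
    if idx.size <= context_cap:
        return idx
    keep = rng.choice(idx.size, size=context_cap, replace=False)
    return idx[np.sort(keep)]


def apply_masking(embeddings: np.ndarray, encodings: np.ndarray,
                  mask_fraction: float, rng: np.random.Generator,
                  mask_mode: str = "encoding") -> MaskedBatch:
    """Mask floor(mask_fraction * N) uniformly chosen rows of a proteome."""
    embeddings = np.asarray(embeddings, dtype=np.float32)
    encodings = np.asarray(encodings, dtype=np.float32)
    if embeddings.shape != encodings.shape or embeddings.ndim != 2:
        raise ValueError("embeddings and encodings must be matching (N, d) arrays")
    n = embeddings.shape[0]
    if n == 0:
        raise ValueError("cannot mask an empty proteome")
    n_masked = int(np.floor(mask_fraction * n))
    if n_masked == 0:
        raise ValueError(
            f"mask_fraction {mask_fraction} masks zero of {n} tokens; "
            "the reconstruction loss is only defined over masked tokens")
    chosen = rng.choice(n, size=n_masked, replace=False)
    indicator = np.zeros(n, dtype=bool)
    indicator[chosen] = True
    originals = embeddings[indicator].copy()
    baselines = encodings[indicator].copy()
    tokens = embeddings.copy()
    if mask_mode == "encoding":
        tokens[indicator] = baselines
    elif mask_mode == "zero":
        tokens[indicator] = 0.0
    else:
        raise ValueError("mask_mode must be 'encoding' or 'zero'")
    return MaskedBatch(token_embeddings=tokens, functional_encodings=encodings,
                       mask_indicator=indicator, baselines=baselines,
                       originals=originals)


class _EncoderLayer(Module):
    """Pre-norm transformer encoder layer with GELU feedforward."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        m = cfg.model_dim
        self.n_heads = cfg.n_heads_per_layer
        self.head_dim = m // self.n_heads
        self.ln_attn = LayerNorm(m)
        self.ln_ffn = LayerNorm(m)
        self.w_q = Linear(m, m, rng)
        self.w_k = Linear(m, m, rng)
        self.w_v = Linear(m, m, rng)
        self.w_o = Linear(m, m, rng)
        self.ffn_in = Linear(m, cfg.feedforward_dim, rng)
        self.ffn_out = Linear(cfg.feedforward_dim, m, rng)

    def __call__(self, h: Tensor) -> tuple[Tensor, np.ndarray]:
        n = h.shape[0]
        x = self.ln_attn(h)

        def split(t: Tensor) -> Tensor:  # (N, m) -> (H, N, hd)
            return t.reshape(n, self.n_heads, self.head_dim).transpose(1, 0, 2)

        q, k, v = split(self.w_q(x)), split(self.w_k(x)), split(self.w_v(x))
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(self.head_dim))
        attn = scores.softmax(axis=-1)              # (H, N, N)
        ctx = (attn @ v).transpose(1, 0, 2).reshape(n, -1)
        h = h + self.w_o(ctx)
        y = self.ln_ffn(h)
        h = h + self.ffn_out(self.ffn_in(y).gelu())
        return h, attn.data


class Backbone(Module):
    """Masked-embedding reconstruction transformer over one proteome."""

    def __init__(self, config: BackboneConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, m = config.input_dim, config.model_dim
        self.proj_embedding = Linear(d, m, rng)
        self.proj_functional = Linear(d, m, rng)
        self.layers = [_EncoderLayer(config, rng)
                       for _ in range(config.n_layers)]
        self.ln_final = LayerNorm(m)
        self.head = Linear(m, d, rng)

    # ------------------------------------------------------------------ core
    def forward_tensors(self, token_embeddings: np.ndarray,
                        functional_encodings: np.ndarray
                        ) -> tuple[Tensor, AttentionStack, list[np.ndarray]]:
        """Differentiable forward pass.

        Returns the (N, d) reconstruction tensor, the captured attention
        stack, and the per-layer hidden states (after each encoder layer,
        as plain arrays for downstream feature use).
        """
        e = np.asarray(token_embeddings, dtype=np.float32)
        f = np.asarray(functional_encodings, dtype=np.float32)
        if e.shape != f.shape or e.ndim != 2:
            raise ValueError("token and functional matrices must match (N, d)")
        if e.shape[1] != self.config.input_dim:
            raise ValueError(
                f"input dim {e.shape[1]} != configured {self.config.input_dim}")
        h = self.proj_embedding(Tensor(e)) + self.proj_functional(Tensor(f))
        attn_mats, hidden = [], []
        for layer in self.layers:
            h, attn = layer(h)
            attn_mats.append(attn)
            hidden.append(h.data.copy())
        out = self.head(self.ln_final(h))
        stack = AttentionStack(attention=np.stack(attn_mats))
        return out, stack, hidden

    def forward(self, batch: MaskedBatch) -> tuple[np.ndarray, AttentionStack]:
        """Evaluation forward: reconstructions and attention, no gradients."""
        out, stack, _ = self.forward_tensors(batch.token_embeddings,
                                             batch.functional_encodings)
        return out.data, stack

    def hidden_states(self, embeddings: np.ndarray,
                      encodings: np.ndarray) -> list[np.ndarray]:
        """Per-layer contextual embeddings for an unmasked proteome."""
        _, _, hidden = self.forward_tensors(embeddings, encodings)
        return hidden

    def attention(self, embeddings: np.ndarray,
                  encodings: np.ndarray) -> AttentionStack:
        """Attention stack for an unmasked proteome forward pass."""
        _, stack, _ = self.forward_tensors(embeddings, encodings)
        return stack


def feature_names(n_layers: int, n_heads: int) -> list[str]:
    return [f"attn_l{layer}h{head}" for layer in range(n_layers)
            for head in range(n_heads)]


def extract_pair_features(stack: AttentionStack,
                          pairs: Sequence[tuple[int, int]],
                          ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Symmetrized per-head attention features for unordered protein pairs.

    For pair (i, j) and each head the feature is (A[i,j] + A[j,i]) / 2.
    Self-pairs are excluded with a warning (undefined as interactions).
    """
    attn = stack.attention
    n_layers, n_heads, n, _ = attn.shape
    flat = attn.reshape(n_layers * n_heads, n, n)
    rows, kept = [], []
    for (i, j) in pairs:
        if i == j:
            warnings.warn(f"self-pair ({i}, {j}) excluded from features")
            continue
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"pair ({i}, {j}) out of range for {n} tokens")
        rows.append(0.5 * (flat[:, i, j] + flat[:, j, i]))
        kept.append((i, j))
    cols = feature_names(n_layers, n_heads)
    table = pd.DataFrame(np.array(rows).reshape(len(rows), len(cols)) if rows
                         else np.empty((0, len(cols))), columns=cols)
    if ids is not None:
        table.insert(0, "protein_a", [ids[i] for i, _ in kept])
        table.insert(1, "protein_b", [ids[j] for _, j in kept])
    else:
        table.insert(0, "protein_a", [i for i, _ in kept])
        table.insert(1, "protein_b", [j for _, j in kept])
    return table
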