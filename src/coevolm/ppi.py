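"""Supervised pair classifier combining node and edge features.

Four components, mirroring the screening stage's feature sources:

* per-source *node encoders* (two-layer feedforward nets with layer
  normalization and dropout) reduce each protein's contextual embedding and
  its raw input embedding to 256 dimensions each; the per-protein node
  feature is the elementwise mean of the two source outputs;
* the *interaction processor* compresses the symmetric pair combination
  [a, b, a*b, |a-b|] (4 x 256 = 1024 dims) to 64;
* the *edge processor* compresses the per-head symmetrized attention
  features (48 under the default 6x8-head backbone) to 32;
* the *classifier* maps the concatenated 96-dim vector to a single logit.

An unordered pair's score is the mean of the two concatenation orders'
sigmoid outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autodiff import LayerNorm, Linear, Module, Tensor, concatenate, dropout
from .backbone import Backbone, extract_pair_features, feature_names
from .corpus import ProteomeCorpus
from .encoding import build_hierarchy_vectors
from .training import TrainReport, train_with_early_stopping

__all__ = ["PPINetConfig", "PPINet", "combine_pair", "build_pair_inputs",
           "split_pairs_by_og", "train_ppi"]


@dataclass
class PPINetConfig:
    """Layer widths; defaults are the published head dimensions."""

    context_dim: int = 640        # source A: contextual embeddings
    raw_dim: int = 640            # source B: input (sequence-model) embeddings
    node_hidden: int = 512
    node_out: int = 256
    interaction_dims: tuple[int, int] = (128, 64)
    edge_dim: int = 48            # total attention heads
    edge_dims: tuple[int, int] = (64, 32)
    classifier_dims: tuple[int, int] = (128, 64)
    dropout: float = 0.1
    use_node: bool = True
    use_edge: bool = True
    seed: int = 0

    @property
    def pair_dim(self) -> int:
        return 4 * self.node_out

    @property
    def classifier_in(self) -> int:
        return (self.interaction_dims[1] if self.use_node else 0) + \
            (self.edge_dims[1] if self.use_edge else 0)

    def __post_init__(self):
        if not (self.use_node or self.use_edge):
            raise ValueError("at least one of node/edge features must be used")


class _TwoLayer(Module):
    """Linear -> LayerNorm -> ReLU -> dropout, twice."""

    def __init__(self, dims: tuple[int, int, int], rate: float,
                 rng: np.random.Generator):
        super().__init__()
        self.lin1 = Linear(dims[0], dims[1], rng)
        self.ln1 = LayerNorm(dims[1])
        self.lin2 = Linear(dims[1], dims[2], rng)
        self.ln2 = LayerNorm(dims[2])
        self.rate = rate

    def __call__(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        h = dropout(self.ln1(self.lin1(x)).relu(), self.rate, rng, self.training)
        return dropout(self.ln2(self.lin2(h)).relu(), self.rate, rng,
                       self.training)


def combine_pair(node_a: Tensor, node_b: Tensor) -> Tensor:
    """[a || b || a*b || |a-b|] — the symmetric-blocks pair combination."""
    if node_a.shape != node_b.shape:
        raise ValueError("node features must have equal shapes")
    return concatenate([node_a, node_b, node_a * node_b,
                        (node_a - node_b).abs()], axis=-1)


class PPINet(Module):
    def __init__(self, config: PPINetConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._rng = np.random.default_rng(config.seed + 1)  # dropout stream
        c = config
        if c.use_node:
            self.encoder_context = _TwoLayer(
                (c.context_dim, c.node_hidden, c.node_out), c.dropout, rng)
            self.encoder_raw = _TwoLayer(
                (c.raw_dim, c.node_hidden, c.node_out), c.dropout, rng)
            self.interaction = _TwoLayer(
                (self.pair_dim, *c.interaction_dims), c.dropout, rng)
        if c.use_edge:
            self.edge = _TwoLayer((c.edge_dim, *c.edge_dims), c.dropout, rng)
        self.classifier_hidden = _TwoLayer(
            (c.classifier_in, *c.classifier_dims), c.dropout, rng)
        self.classifier_out = Linear(c.classifier_dims[1], 1, rng)

    @property
    def pair_dim(self) -> int:
        return self.config.pair_dim

    def encode_node(self, ctx: Tensor, raw: Tensor) -> Tensor:
        """Mean-fused 256-dim node feature from the two embedding sources."""
        a = self.encoder_context(ctx, self._rng)
        b = self.encoder_raw(raw, self._rng)
        return (a + b) * 0.5

    def forward_logit(self, ctx_a, raw_a, ctx_b, raw_b, edge) -> Tensor:
        """Single-order logit for pairs given as (B, dim) arrays/tensors."""
        parts = []
        if self.config.use_node:
            na = self.encode_node(Tensor(ctx_a), Tensor(raw_a))
            nb = self.encode_node(Tensor(ctx_b), Tensor(raw_b))
            pair = combine_pair(na, nb)
            if pair.shape[-1] != self.pair_dim:
                raise ValueError("pair combination has unexpected width")
            parts.append(self.interaction(pair, self._rng))
        if self.config.use_edge:
            parts.append(self.edge(Tensor(edge), self._rng))
        h = parts[0] if len(parts) == 1 else concatenate(parts, axis=-1)
        if h.shape[-1] != self.config.classifier_in:
            raise ValueError("classifier input has unexpected width")
        return self.classifier_out(self.classifier_hidden(h, self._rng))

    def score_pairs(self, ctx_a, raw_a, ctx_b, raw_b, edge) -> np.ndarray:
        """Order-invariant score: mean sigmoid over the two input orders."""
        self.eval()
        s1 = self.forward_logit(ctx_a, raw_a, ctx_b, raw_b, edge).sigmoid().data
        s2 = self.forward_logit(ctx_b, raw_b, ctx_a, raw_a, edge).sigmoid().data
        return (0.5 * (s1 + s2)).ravel()


# ----------------------------------------------------------- feature plumbing
@dataclass
class PairInputs:
    """Aligned arrays of supervised inputs for a pair table."""

    ctx_a: np.ndarray
    raw_a: np.ndarray
    ctx_b: np.ndarray
    raw_b: np.ndarray
    edge: np.ndarray
    labels: np.ndarray
    table: pd.DataFrame


def build_pair_inputs(corpus: ProteomeCorpus, model: Backbone,
                      pair_set: pd.DataFrame, layer: int) -> PairInputs:
    """Resolve node and edge features for every pair row.

    Per species, one embedding forward pass supplies the layer-`layer`
    contextual node embeddings and one functional-identity forward pass
    supplies the attention stack for the edge features (matching the
    screening stage's extraction).  Edge features are z-scored over the
    table (attention coefficients live on a ~1/N scale).  Row order is
    aligned with `pair_set` sorted by species.
    """
    if corpus.hierarchy.root not in corpus.hierarchy.vectors:
        build_hierarchy_vectors(corpus)
    ctx_a, raw_a, ctx_b, raw_b, edge = [], [], [], [], []
    cols = feature_names(model.config.n_layers, model.config.n_heads_per_layer)
    for sid, sub in pair_set.groupby("species_id", sort=True):
        records = corpus.species[sid]
        index = {r.protein_id: k for k, r in enumerate(records)}
        emb = np.stack([r.embedding for r in records])
        enc = np.stack([
            corpus.hierarchy.vectors[r.og_leaf_id]
            if r.og_leaf_id is not None else r.embedding for r in records])
        _, _, hidden = model.forward_tensors(emb, enc)
        stack = model.attention(enc, enc)
        h = hidden[layer]
        pairs_idx = [(index[a], index[b])
                     for a, b in zip(sub["protein_a"], sub["protein_b"])]
        feats = extract_pair_features(stack, pairs_idx)
        ia = np.array([p[0] for p in pairs_idx])
        ib = np.array([p[1] for p in pairs_idx])
        ctx_a.append(h[ia]); raw_a.append(emb[ia])
        ctx_b.append(h[ib]); raw_b.append(emb[ib])
        edge.append(feats[cols].to_numpy())
    ordered = pair_set.sort_values("species_id", kind="stable")
    edge_all = np.concatenate(edge)
    edge_all = (edge_all - edge_all.mean(axis=0)) / (edge_all.std(axis=0)
                                                     + 1e-8)
    return PairInputs(
        ctx_a=np.concatenate(ctx_a), raw_a=np.concatenate(raw_a),
        ctx_b=np.concatenate(ctx_b), raw_b=np.concatenate(raw_b),
        edge=edge_all.astype(np.float32),
        labels=ordered["label"].to_numpy(),
        table=ordered.reset_index(drop=True))


def split_pairs_by_og(pair_set: pd.DataFrame, corpus: ProteomeCorpus,
                      fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
                      seed: int = 0) -> pd.DataFrame:
    """Assign train/val/test splits at the unordered leaf-OG-pair level.

    The same interacting group pair recurs across species; splitting at the
    group-pair level keeps those recurrences inside one split.
    """
    og_of = {r.protein_id: (r.og_leaf_id or r.protein_id)
             for r in corpus.records()}
    keys = [frozenset((og_of[a], og_of[b]))
            for a, b in zip(pair_set["protein_a"], pair_set["protein_b"])]
    uniq = sorted({tuple(sorted(k)) for k in keys})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    n_train = int(round(fractions[0] * len(uniq)))
    n_val = int(round(fractions[1] * len(uniq)))
    assign = {}
    for rank, pos in enumerate(order):
        split = ("train" if rank < n_train
                 else "val" if rank < n_train + n_val else "test")
        assign[uniq[pos]] = split
    out = pair_set.copy()
    out["split"] = [assign[tuple(sorted(k))] for k in keys]
    return out


def train_ppi(net: PPINet, inputs: PairInputs, *, learning_rate: float = 1e-3,
              batch_size: int = 64, max_epochs: int = 100, patience: int = 10,
              weight_decay: float = 1e-4, seed: int = 0) -> TrainReport:
    """Early-stopped training of the pair classifier on a split pair table."""
    if "split" not in inputs.table.columns:
        raise ValueError("pair table must carry a split column")
    splits = inputs.table["split"].to_numpy()
    idx = {s: np.flatnonzero(splits == s) for s in ("train", "val", "test")}
    for s, rows in idx.items():
        if len(rows) == 0:
            raise ValueError(f"empty {s} split")

    def logits_fn(model: PPINet, sel: np.ndarray, training: bool) -> Tensor:
        model.train() if training else model.eval()
        return model.forward_logit(inputs.ctx_a[sel], inputs.raw_a[sel],
                                   inputs.ctx_b[sel], inputs.raw_b[sel],
                                   inputs.edge[sel])

    y = inputs.labels
    return train_with_early_stopping(
        net, logits_fn,
        y[idx["train"]], idx["train"], y[idx["val"]], idx["val"],
        y[idx["test"]], idx["test"],
        learning_rate=learning_rate, batch_size=batch_size,
        max_epochs=max_epochs, patience=patience,
        weight_decay=weight_decay, seed=seed)
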