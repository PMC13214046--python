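"""Unsupervised and lightly supervised PPI scoring from attention features.

The unsupervised route profiles each attention head's AUC for separating
interacting from noninteracting pairs, and uses the mean attention
coefficient (per layer or over all heads) as a direct interaction score.
The lightly supervised route fits an L2-regularized logistic regression on
the per-head features of a small labeled set (by default 100 positives and
1,000 random pairs treated as noninteracting) and ranks all remaining pairs
with it; the training pairs are held out from every downstream evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler

from .backbone import Backbone, extract_pair_features
from .corpus import ProteomeCorpus
from .encoding import build_hierarchy_vectors

__all__ = ["auc", "per_head_auc", "mean_attention_score", "train_screener",
           "recall_at_n", "embedding_similarity_baseline", "ScreenerResult",
           "species_feature_table", "planted_attention_auc"]


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties contribute 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: both classes must be present")
    return float(roc_auc_score(labels, scores))


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("attn_")]


def per_head_auc(table: pd.DataFrame, n_layers: int,
                 n_heads: int) -> np.ndarray:
    """AUC of each attention head's feature column, as a (layers, heads) matrix."""
    cols = _feature_columns(table)
    if len(cols) != n_layers * n_heads:
        raise ValueError(
            f"table has {len(cols)} feature columns, expected {n_layers * n_heads}")
    labels = table["label"].to_numpy()
    out = np.array([auc(table[c].to_numpy(), labels) for c in cols])
    return out.reshape(n_layers, n_heads)


def mean_attention_score(table: pd.DataFrame, scope: str = "all",
                         n_heads_per_layer: int | None = None) -> np.ndarray:
    """Per-pair mean attention over all heads, or per layer.

    ``scope='all'`` returns one score per pair; ``scope='per_layer'`` returns
    a (n_pairs, n_layers) matrix (requires `n_heads_per_layer`).
    """
    cols = _feature_columns(table)
    feats = table[cols].to_numpy()
    if scope == "all":
        return feats.mean(axis=1)
    if scope == "per_layer":
        if n_heads_per_layer is None:
            raise ValueError("per_layer scope requires n_heads_per_layer")
        n_layers = feats.shape[1] // n_heads_per_layer
        return feats.reshape(len(table), n_layers,
                             n_heads_per_layer).mean(axis=2)
    raise ValueError("scope must be 'all' or 'per_layer'")


@dataclass
class ScreenerResult:
    coefficients: np.ndarray   # (total_heads,)
    intercept: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    training_index: np.ndarray  # row positions used for training (held out later)

    def score(self, table: pd.DataFrame) -> np.ndarray:
        cols = _feature_columns(table)
        z = (table[cols].to_numpy() - self.scaler_mean) / self.scaler_scale
        return z @ self.coefficients + self.intercept


def train_screener(table: pd.DataFrame, n_pos: int = 100, n_neg: int = 1000,
                   seed: int = 0, C: float = 1.0) -> ScreenerResult:
    """Logistic screener on a small labeled subset of the pair table.

    Positives are sampled from labeled interacting pairs; negatives are
    random pairs treated as noninteracting (no purification).  The sampled
    training rows are recorded so evaluation can exclude them.
    """
    rng = np.random.default_rng(seed)
    labels = table["label"].to_numpy()
    pos_rows = np.flatnonzero(labels == 1)
    if len(pos_rows) < n_pos:
        raise ValueError(
            f"need {n_pos} positives, table only has {len(pos_rows)}")
    pos_pick = rng.choice(pos_rows, size=n_pos, replace=False)
    remaining = np.setdiff1d(np.arange(len(table)), pos_pick)
    if len(remaining) < n_neg:
        raise ValueError(
            f"need {n_neg} random pairs, only {len(remaining)} available")
    neg_pick = rng.choice(remaining, size=n_neg, replace=False)
    train_idx = np.concatenate([pos_pick, neg_pick])
    y = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])

    cols = _feature_columns(table)
    scaler = StandardScaler()
    x = scaler.fit_transform(table.iloc[train_idx][cols].to_numpy())
    clf = LogisticRegression(C=C, max_iter=1000, random_state=int(seed))
    clf.fit(x, y)
    return ScreenerResult(
        coefficients=clf.coef_.ravel(), intercept=float(clf.intercept_[0]),
        scaler_mean=scaler.mean_, scaler_scale=scaler.scale_,
        training_index=np.sort(train_idx))


def recall_at_n(ranked_pairs: pd.DataFrame, truth: set[frozenset],
                n_grid: np.ndarray | list[int]) -> pd.DataFrame:
    """Fraction of truth pairs recovered within the top n predictions.

    `ranked_pairs` must be sorted by nonincreasing score and carry
    protein_a / protein_b columns.
    """
    if not truth:
        raise ValueError("recall undefined for an empty truth set")
    keys = [frozenset((a, b)) for a, b in
            zip(ranked_pairs["protein_a"], ranked_pairs["protein_b"])]
    hits = np.cumsum([k in truth for k in keys])
    rows = []
    for n in n_grid:
        n = int(min(n, len(keys)))
        rows.append((n, hits[n - 1] / len(truth) if n >= 1 else 0.0))
    return pd.DataFrame(rows, columns=["n", "recall"])


def embedding_similarity_baseline(emb_a: np.ndarray,
                                  emb_b: np.ndarray) -> np.ndarray:
    """Cosine similarity of the two proteins' input embeddings, per pair."""
    emb_a = np.atleast_2d(emb_a)
    emb_b = np.atleast_2d(emb_b)
    na = np.linalg.norm(emb_a, axis=1)
    nb = np.linalg.norm(emb_b, axis=1)
    zero = (na == 0) | (nb == 0)
    if np.any(zero):
        warnings.warn("zero-norm embedding in similarity baseline; score 0")
    denom = np.where(zero, 1.0, na * nb)
    sims = (emb_a * emb_b).sum(axis=1) / denom
    return np.where(zero, 0.0, sims)


# --------------------------------------------------------- corpus-level tools
def species_feature_table(corpus: ProteomeCorpus, model: Backbone,
                          species_id: str,
                          pairs: list[tuple[str, str]] | None = None,
                          label_planted: bool = True,
                          tokens: str = "encodings") -> pd.DataFrame:
    """Attention-feature table for protein pairs of one species.

    By default the attention stack is extracted from the functional-identity
    forward pass: every token's embedding channel carries its leaf-level
    functional encoding, matching the distribution of masked queries the
    model was trained on (``tokens='embeddings'`` uses the raw protein
    embeddings instead).  Per-head coefficients are symmetrized.  With
    ``pairs=None`` all unordered non-self pairs are included.  When
    `label_planted` is set, pairs of planted orthologous groups are
    labeled 1, all others 0.
    """
    if tokens not in ("encodings", "embeddings"):
        raise ValueError("tokens must be 'encodings' or 'embeddings'")
    if corpus.hierarchy.root not in corpus.hierarchy.vectors:
        build_hierarchy_vectors(corpus)
    records = corpus.species[species_id]
    ids = [r.protein_id for r in records]
    index = {pid: k for k, pid in enumerate(ids)}
    emb = np.stack([r.embedding for r in records])
    enc = np.stack([corpus.hierarchy.vectors[r.og_leaf_id]
                    if r.og_leaf_id is not None else r.embedding
                    for r in records])
    stack = model.attention(enc if tokens == "encodings" else emb, enc)
    if pairs is None:
        idx_pairs = [(i, j) for i in range(len(ids))
                     for j in range(i + 1, len(ids))]
    else:
        idx_pairs = [(index[a], index[b]) for a, b in pairs]
    table = extract_pair_features(stack, idx_pairs, ids=ids)
    if label_planted:
        og_of = {r.protein_id: r.og_leaf_id for r in records}
        planted = {frozenset((p.og_a, p.og_b)) for p in corpus.planted_pairs}
        table["label"] = [
            int(frozenset((og_of[a], og_of[b])) in planted)
            for a, b in zip(table["protein_a"], table["protein_b"])]
    return table


def planted_attention_auc(corpus: ProteomeCorpus, model: Backbone,
                          seed: int = 0, n_neg_per_pos: int = 20,
                          min_pairs: int = 3) -> tuple[float, pd.DataFrame]:
    """Mean-attention AUC for planted vs. random pairs, per species.

    The AUC is computed within each species (attention rows are stochastic,
    so raw coefficients are only comparable within one proteome) over its
    co-present planted pairs against `n_neg_per_pos` random co-present
    pairs per positive, then averaged over species with at least
    `min_pairs` co-present planted pairs.  Returns the mean AUC and the
    per-species table.
    """
    rng = np.random.default_rng(seed)
    planted = {frozenset((p.og_a, p.og_b)) for p in corpus.planted_pairs}
    rows = []
    for sid in sorted(corpus.species):
        records = corpus.species[sid]
        present = {r.og_leaf_id: r.protein_id for r in records
                   if r.og_leaf_id is not None}
        pos = [(present[p.og_a], present[p.og_b])
               for p in corpus.planted_pairs
               if p.og_a in present and p.og_b in present]
        if len(pos) < min_pairs:
            continue
        ogs = sorted(present)
        neg: list[tuple[str, str]] = []
        while len(neg) < n_neg_per_pos * len(pos):
            i, j = rng.choice(len(ogs), size=2, replace=False)
            if frozenset((ogs[i], ogs[j])) in planted:
                continue
            neg.append((present[ogs[i]], present[ogs[j]]))
        table = species_feature_table(corpus, model, sid, pairs=pos + neg,
                                      label_planted=True)
        scores = mean_attention_score(table, scope="all")
        rows.append((sid, len(pos), auc(scores, table["label"].to_numpy())))
    if not rows:
        raise ValueError("no species with enough co-present planted pairs")
    per_species = pd.DataFrame(rows, columns=["species_id", "n_planted",
                                              "auc"])
    return float(per_species["auc"].mean()), per_species
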