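"""Gene-essentiality classifier on genome-normalized embeddings.

Embeddings are standardized per genome (per-coordinate mean/SD over that
species' proteins) before classification, so the classifier sees each
protein relative to its own proteome.  The classifier is a two-layer fully
connected network: hidden width 2048, ReLU, dropout 0.5, two output logits
softmax-normalized into an essentiality score.  Train/validation/test
splits are assigned at the sequence-cluster level (the simulator supplies
leaf orthologous groups as cluster ids), so similar proteins never straddle
splits; whole held-out species can additionally be excluded from training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autodiff import Linear, Module, Tensor, dropout
from .corpus import ESSENTIAL, NONESSENTIAL, QUASI_ESSENTIAL
from .training import TrainReport, train_with_early_stopping

__all__ = ["EssConfig", "EssNet", "genome_normalize", "cluster_split",
           "train_ess", "call_top_n", "contextual_gene_features"]

_EPS = 1e-8


@dataclass
class EssConfig:
    input_dim: int = 64
    hidden: int = 2048
    dropout: float = 0.5
    layer: int | None = None  # which backbone layer feeds the classifier
    seed: int = 0

    def __post_init__(self):
        if self.hidden < 1:
            raise ValueError("hidden width must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


class EssNet(Module):
    """input -> hidden (ReLU, dropout) -> two logits; score = softmax[ess]."""

    def __init__(self, config: EssConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._rng = np.random.default_rng(config.seed + 1)
        self.hidden = Linear(config.input_dim, config.hidden, rng)
        self.out = Linear(config.hidden, 2, rng)

    def forward_logits(self, x) -> Tensor:
        h = dropout(self.hidden(Tensor(x)).relu(), self.config.dropout,
                    self._rng, self.training)
        return self.out(h)

    def forward_logit(self, x) -> Tensor:
        """Single equivalent logit: difference of the two class logits."""
        logits = self.forward_logits(x)
        return logits[:, 1] - logits[:, 0]

    def score(self, x) -> np.ndarray:
        """Softmax essentiality score in [0, 1]."""
        self.eval()
        logits = self.forward_logits(x).data
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e[:, 1] / e.sum(axis=1)


def contextual_gene_features(corpus, model, layer: int | None = None
                             ) -> tuple[np.ndarray, list[str]]:
    """Genome-normalized contextual embeddings for every protein.

    Runs one unmasked forward pass per species, takes the hidden states of
    `layer` (default: middle layer — intermediate layers carry the most
    essentiality signal) and genome-normalizes them.  With ``layer=-1`` the
    raw input embeddings are used instead (the no-context baseline).
    Returns the feature matrix and the aligned protein-id order.
    """
    from .encoding import build_hierarchy_vectors
    if corpus.hierarchy.root not in corpus.hierarchy.vectors:
        build_hierarchy_vectors(corpus)
    if layer is None:
        layer = model.config.n_layers // 2
    feats, order = [], []
    for sid in sorted(corpus.species):
        records = corpus.species[sid]
        emb = np.stack([r.embedding for r in records])
        if layer == -1:
            h = emb
        else:
            enc = np.stack([corpus.hierarchy.vectors[r.og_leaf_id]
                            if r.og_leaf_id is not None else r.embedding
                            for r in records])
            h = model.hidden_states(emb, enc)[layer]
        feats.append(genome_normalize(h))
        order.extend(r.protein_id for r in records)
    return np.concatenate(feats), order


def genome_normalize(embeddings: np.ndarray) -> np.ndarray:
    """Standardize one genome's embeddings per coordinate (guarded SD)."""
    embeddings = np.asarray(embeddings, dtype=np.float64)
    if embeddings.ndim != 2 or embeddings.shape[0] < 2:
        raise ValueError("genome normalization needs >= 2 proteins per species")
    mean = embeddings.mean(axis=0)
    sd = embeddings.std(axis=0)
    return ((embeddings - mean) / np.maximum(sd, _EPS)).astype(np.float32)


def cluster_split(gene_set: pd.DataFrame,
                  fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
                  seed: int = 0,
                  holdout_species: tuple[str, ...] = ()) -> pd.DataFrame:
    """Assign train/val/test per cluster (never splitting a cluster).

    Clusters are shuffled and assigned by cumulative labeled-protein count
    closest to the requested fractions.  Proteins of held-out species go to
    the test split regardless of cluster, and their clusters are barred from
    train/val.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    known = set(gene_set["species_id"])
    for sp in holdout_species:
        if sp not in known:
            raise KeyError(f"held-out species {sp} absent from gene set")
    out = gene_set.copy()
    held_mask = out["species_id"].isin(holdout_species)
    held_clusters = set(out.loc[held_mask, "cluster_id"]) - {"."}

    assignable = out.loc[~held_mask]
    clusters = sorted(set(assignable["cluster_id"]) - {"."} - held_clusters)
    sizes = assignable.groupby("cluster_id").size()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(clusters))
    total = int(sizes.loc[clusters].sum())
    bounds = (fractions[0] * total, (fractions[0] + fractions[1]) * total)
    assign: dict[str, str] = {}
    seen = 0
    for pos in order:
        c = clusters[pos]
        assign[c] = ("train" if seen < bounds[0]
                     else "val" if seen < bounds[1] else "test")
        seen += int(sizes[c])
    for c in held_clusters:
        assign[c] = "test"

    def split_of(row):
        if row["species_id"] in holdout_species:
            return "test"
        if row["cluster_id"] == ".":
            return "train"  # orphans cannot leak via clusters
        return assign[row["cluster_id"]]

    out["split"] = out.apply(split_of, axis=1)
    return out


def train_ess(config: EssConfig, gene_set: pd.DataFrame,
              features: np.ndarray, *, learning_rate: float = 1e-3,
              batch_size: int = 128, max_epochs: int = 100, patience: int = 10,
              weight_decay: float = 0.0, seed: int = 0
              ) -> tuple[EssNet, TrainReport]:
    """Early-stopped training on labeled rows of a split gene table.

    `features` rows align with `gene_set` rows (already genome-normalized).
    Quasi-essential and unlabeled proteins are excluded from training and
    testing; they are reporting categories only.
    """
    if "split" not in gene_set.columns:
        raise ValueError("gene set must carry a split column")
    labeled = gene_set["label"].isin([ESSENTIAL, NONESSENTIAL]).to_numpy()
    y = (gene_set["label"] == ESSENTIAL).to_numpy().astype(np.float32)
    splits = gene_set["split"].to_numpy()
    idx = {s: np.flatnonzero(labeled & (splits == s))
           for s in ("train", "val", "test")}
    net = EssNet(config)

    def logits_fn(model: EssNet, sel: np.ndarray, training: bool) -> Tensor:
        model.train() if training else model.eval()
        return model.forward_logit(features[sel])

    report = train_with_early_stopping(
        net, logits_fn, y[idx["train"]], idx["train"],
        y[idx["val"]], idx["val"], y[idx["test"]], idx["test"],
        learning_rate=learning_rate, batch_size=batch_size,
        max_epochs=max_epochs, patience=patience,
        weight_decay=weight_decay, seed=seed)
    return net, report


def call_top_n(scores: np.ndarray, protein_ids: list[str],
               labels: list[str], n_essential: int) -> pd.DataFrame:
    """Call the top-N scored genes essential; report per-class agreement.

    Ties at the threshold are broken by stable protein-id order (ascending
    id wins).  Returns one row per true class (E / QE / NE) with the
    percentage of that class called essential, plus the binary call per gene
    attached as a second frame via the `calls` attribute.
    """
    n = len(scores)
    if n_essential > n:
        raise ValueError("n_essential exceeds genome size")
    if n_essential == 0:
        warnings.warn("n_essential is 0; every gene called nonessential")
    order = sorted(range(n), key=lambda i: (-scores[i], protein_ids[i]))
    called = np.zeros(n, dtype=bool)
    called[order[:n_essential]] = True
    rows = []
    for cls in (ESSENTIAL, QUASI_ESSENTIAL, NONESSENTIAL):
        members = [i for i, lab in enumerate(labels) if lab == cls]
        pct = (100.0 * sum(called[i] for i in members) / len(members)
               if members else np.nan)
        rows.append((cls, len(members), pct))
    report = pd.DataFrame(rows, columns=["true_class", "n", "pct_called_essential"])
    report.attrs["calls"] = pd.DataFrame(
        {"protein_id": protein_ids, "score": scores, "called_essential": called})
    return report
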