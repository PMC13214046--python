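"""Masked-reconstruction pretraining over proteome corpora.

Each optimization step processes one proteome: functional encodings are
resampled from the ancestral paths, the context is capped, half the tokens
are masked, and the chosen reconstruction loss is computed over masked
tokens only.  Validation loss is measured each epoch on a held-out set of
whole proteomes (attention never spans species, so proteome-level batching
and proteome-level splitting are the natural granularity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor
from .backbone import Backbone, BackboneConfig, apply_masking, subsample_context
from .corpus import ProteomeCorpus
from .encoding import build_hierarchy_vectors, corpus_encoding_paths
from .losses import LOSSES

__all__ = ["PretrainConfig", "split_corpus", "pretrain"]


@dataclass
class PretrainConfig:
    loss: str = "polar"
    learning_rate: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    epochs: int = 30
    validation_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.loss not in LOSSES:
            raise ValueError(f"unknown loss '{self.loss}'; choose from {list(LOSSES)}")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def split_corpus(corpus: ProteomeCorpus, validation_fraction: float,
                 seed: int) -> tuple[list[str], list[str]]:
    """Whole-proteome train/validation split, seed-reproducible."""
    species = sorted(corpus.species)
    if len(species) < 2:
        raise ValueError("need at least two species to split")
    n_val = max(1, int(round(validation_fraction * len(species))))
    if n_val >= len(species):
        raise ValueError(
            f"validation_fraction {validation_fraction} leaves an empty side")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(species))
    val = sorted(species[i] for i in order[:n_val])
    train = sorted(species[i] for i in order[n_val:])
    return train, val


class _SpeciesCache:
    """Padded per-species arrays for fast per-epoch encoding resampling."""

    def __init__(self, corpus: ProteomeCorpus, paths: dict):
        self.data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for sid, records in corpus.species.items():
            emb = np.stack([r.embedding for r in records])
            plists = [paths[r.protein_id].vectors for r in records]
            lengths = np.array([p.shape[0] for p in plists])
            lmax = lengths.max()
            padded = np.zeros((len(plists), lmax, emb.shape[1]), dtype=np.float32)
            for i, p in enumerate(plists):
                padded[i, :p.shape[0]] = p
            self.data[sid] = (emb, padded, lengths)

    def sample_encodings(self, sid: str, rng: np.random.Generator) -> np.ndarray:
        _, padded, lengths = self.data[sid]
        levels = rng.integers(0, lengths)
        return padded[np.arange(len(lengths)), levels]

    def embeddings(self, sid: str) -> np.ndarray:
        return self.data[sid][0]


def _proteome_loss(model: Backbone, emb: np.ndarray, enc: np.ndarray,
                   cfg: BackboneConfig, loss_fn, rng: np.random.Generator):
    keep = subsample_context(emb.shape[0], cfg.context_cap, rng)
    emb, enc = emb[keep], enc[keep]
    batch = apply_masking(emb, enc, cfg.mask_fraction, rng, cfg.mask_mode)
    pred, _, _ = model.forward_tensors(batch.token_embeddings,
                                       batch.functional_encodings)
    mask_idx = np.flatnonzero(batch.mask_indicator)
    return loss_fn(pred[mask_idx], Tensor(batch.originals),
                   Tensor(batch.baselines))


def pretrain(corpus: ProteomeCorpus, backbone_config: BackboneConfig,
             config: PretrainConfig) -> tuple[Backbone, pd.DataFrame]:
    """Train a backbone on a corpus; returns the model and the loss curves.

    The hierarchy vectors are built (if absent) from the full corpus, and the
    encoding paths are cached once; only the per-epoch level sampling is
    stochastic.  With ``epochs=0`` the returned model is the seeded
    initialization.
    """
    if corpus.hierarchy.root not in corpus.hierarchy.vectors:
        build_hierarchy_vectors(corpus)
    paths = corpus_encoding_paths(corpus)
    cache = _SpeciesCache(corpus, paths)
    train_ids, val_ids = split_corpus(corpus, config.validation_fraction,
                                      config.seed)
    model = Backbone(backbone_config)
    loss_fn = LOSSES[config.loss]
    optimizer = Adam(model.parameters(), lr=config.learning_rate,
                     betas=config.betas)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    curves = []
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(train_ids))
        train_losses = []
        for si in order:
            sid = train_ids[si]
            enc = cache.sample_encodings(sid, rng)
            loss = _proteome_loss(model, cache.embeddings(sid), enc,
                                  backbone_config, loss_fn, rng)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, species {sid}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            train_losses.append(float(loss.data))

        model.eval()
        val_rng = np.random.default_rng(
            np.random.SeedSequence((config.seed, epoch)).generate_state(1)[0])
        val_losses = []
        for sid in val_ids:
            enc = cache.sample_encodings(sid, val_rng)
            loss = _proteome_loss(model, cache.embeddings(sid), enc,
                                  backbone_config, loss_fn, val_rng)
            val_losses.append(float(loss.data))
        curves.append((epoch, float(np.mean(train_losses)),
                       float(np.mean(val_losses))))
    model.eval()
    return model, pd.DataFrame(curves, columns=["epoch", "train_loss",
                                                "val_loss"])
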