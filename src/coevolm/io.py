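"""On-disk formats: corpus container, checkpoints, FASTA, and the embedder
interface.

Tabular interchange is TSV with "." for missing values.  A corpus lives in
one directory:

    species.tsv            species_id per row
    proteins/<sid>.tsv     protein_id, og_leaf_id (or .), essential_label
    embeddings.h5          one float32 matrix per species + stored dimension
    hierarchy.tsv          child_id, parent_id ('' for root), level
    planted_pairs.tsv      og_a, og_b, coupling (latents in embeddings.h5)
    config.yaml            generation config including the seed
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Protocol

import h5py
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .backbone import Backbone, BackboneConfig
from .corpus import OrthologyHierarchy, ProteinRecord, ProteomeCorpus
from .simulate import PlantedPair

__all__ = ["write_corpus", "read_corpus", "write_hierarchy", "read_hierarchy",
           "save_checkpoint", "load_checkpoint", "read_fasta",
           "mean_pool_embedder", "SequenceEmbedder", "read_pairs",
           "write_pairs"]

MISSING = "."


# ------------------------------------------------------------------ hierarchy
def write_hierarchy(hierarchy: OrthologyHierarchy, path: Path) -> None:
    rows = sorted(hierarchy.edges())
    pd.DataFrame(rows, columns=["child_id", "parent_id", "level"]).to_csv(
        path, sep="\t", index=False)


def read_hierarchy(path: Path) -> OrthologyHierarchy:
    df = pd.read_csv(path, sep="\t", dtype={"child_id": str, "parent_id": str},
                     keep_default_na=False)
    h = OrthologyHierarchy()
    # parents must exist before children: add by descending level
    for _, row in df.sort_values("level", ascending=False).iterrows():
        parent = row["parent_id"] if row["parent_id"] != "" else None
        h.add_node(row["child_id"], parent, int(row["level"]))
    h.validate()
    return h


# --------------------------------------------------------------------- corpus
def write_corpus(corpus: ProteomeCorpus, directory: Path) -> None:
    directory = Path(directory)
    (directory / "proteins").mkdir(parents=True, exist_ok=True)
    species_ids = sorted(corpus.species)
    pd.DataFrame({"species_id": species_ids}).to_csv(
        directory / "species.tsv", sep="\t", index=False)
    with h5py.File(directory / "embeddings.h5", "w") as h5:
        h5.attrs["dim"] = corpus.embedding_dim
        grp = h5.create_group("species")
        for sid in species_ids:
            records = corpus.species[sid]
            pd.DataFrame({
                "protein_id": [r.protein_id for r in records],
                "og_leaf_id": [r.og_leaf_id or MISSING for r in records],
                "essential_label": [r.essential_label for r in records],
            }).to_csv(directory / "proteins" / f"{sid}.tsv", sep="\t",
                      index=False)
            grp.create_dataset(sid, data=np.stack(
                [r.embedding for r in records]).astype(np.float32))
        if corpus.planted_pairs:
            h5.create_dataset("pair_latents", data=np.stack(
                [p.shared_latent for p in corpus.planted_pairs]))
        if corpus.hierarchy.vectors:
            vg = h5.create_group("hierarchy_vectors")
            for node, vec in corpus.hierarchy.vectors.items():
                vg.create_dataset(node, data=vec.astype(np.float32))
    write_hierarchy(corpus.hierarchy, directory / "hierarchy.tsv")
    pd.DataFrame(
        [(p.og_a, p.og_b, p.coupling) for p in corpus.planted_pairs],
        columns=["og_a", "og_b", "coupling"]).to_csv(
        directory / "planted_pairs.tsv", sep="\t", index=False)
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump({"config": _plain(corpus.config), "seed": corpus.seed},
                       fh)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def read_corpus(directory: Path) -> ProteomeCorpus:
    directory = Path(directory)
    hierarchy = read_hierarchy(directory / "hierarchy.tsv")
    species_ids = pd.read_csv(directory / "species.tsv", sep="\t",
                              dtype=str)["species_id"].tolist()
    species: dict[str, list[ProteinRecord]] = {}
    with h5py.File(directory / "embeddings.h5", "r") as h5:
        latents = h5["pair_latents"][...] if "pair_latents" in h5 else None
        if "hierarchy_vectors" in h5:
            for node in h5["hierarchy_vectors"]:
                hierarchy.vectors[node] = h5["hierarchy_vectors"][node][...]
        for sid in species_ids:
            table = pd.read_csv(directory / "proteins" / f"{sid}.tsv",
                                sep="\t", dtype=str, keep_default_na=False)
            emb = h5["species"][sid][...]
            records = []
            for k, row in enumerate(table.itertuples(index=False)):
                records.append(ProteinRecord(
                    protein_id=row.protein_id, species_id=sid,
                    og_leaf_id=None if row.og_leaf_id == MISSING
                    else row.og_leaf_id,
                    embedding=emb[k], essential_label=row.essential_label))
            species[sid] = records
    pairs_df = pd.read_csv(directory / "planted_pairs.tsv", sep="\t")
    planted = []
    for k, row in enumerate(pairs_df.itertuples(index=False)):
        latent = (latents[k] if latents is not None
                  else np.zeros(next(iter(species.values()))[0].embedding.shape,
                                dtype=np.float32))
        planted.append(PlantedPair(og_a=row.og_a, og_b=row.og_b,
                                   coupling=float(row.coupling),
                                   shared_latent=latent))
    with open(directory / "config.yaml") as fh:
        meta = yaml.safe_load(fh)
    corpus = ProteomeCorpus(species=species, hierarchy=hierarchy,
                            planted_pairs=planted,
                            config=meta.get("config", {}),
                            seed=meta.get("seed"))
    corpus.validate()
    return corpus


# ---------------------------------------------------------------- pair tables
def write_pairs(pairs: pd.DataFrame, path: Path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_pairs(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"species_id": str, "protein_a": str,
                              "protein_b": str})


# ---------------------------------------------------------------- checkpoints
def save_checkpoint(model: Backbone, path: Path,
                    corpus_fingerprint: str = "") -> None:
    meta = json.dumps({"config": model.config.to_dict(),
                       "corpus_fingerprint": corpus_fingerprint})
    state = model.state_dict()
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **state)


def load_checkpoint(path: Path) -> Backbone:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = BackboneConfig(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in meta["config"].items()})
        model = Backbone(cfg)
        state = {k: data[k] for k in data.files if k != "__meta__"}
        model.load_state_dict(state)
    model.eval()
    return model


# ----------------------------------------------------------------- FASTA path
def read_fasta(path: Path) -> list[tuple[str, str, str]]:
    """(id, description, uppercase sequence) triples; wrapped lines joined."""
    records = [(rec.id, rec.description, str(rec.seq).upper())
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        warnings.warn(f"no FASTA records found in {path}")
    return records


class SequenceEmbedder(Protocol):
    """Pluggable sequence-embedder contract for the real-data path.

    Implementations map a batch of amino-acid sequences to a (n, dim)
    float matrix — one mean-pooled vector per sequence.
    """

    dim: int

    def embed(self, sequences: list[str]) -> np.ndarray:  # pragma: no cover
        ...


def mean_pool_embedder(per_residue: np.ndarray) -> np.ndarray:
    """Mean over residue rows: (L, dim) per-residue matrix -> (dim,) vector."""
    per_residue = np.asarray(per_residue)
    if per_residue.ndim != 2 or per_residue.shape[0] == 0:
        raise ValueError("need a nonempty (residues, dim) matrix")
    return per_residue.mean(axis=0)
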