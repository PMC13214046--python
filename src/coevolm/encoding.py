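"""Hierarchical functional encodings from the orthology tree.

The functional encoding replaces positional encoding in the proteome
transformer: each protein is described by the vector of its orthologous
group at some taxonomic level.  Leaf-group vectors are the arithmetic mean
of member-protein embeddings across the whole corpus; each internal group's
vector is the *equal-weight* mean of its immediate children's vectors
(propagated leaf-to-root), so large groups do not dominate their parents.

During training the encoding of a protein is drawn uniformly from its
ancestral path (leaf group up to the root), exposing the model to functional
descriptions at varying specificity.  At evaluation time the deterministic
leaf-level vector is used.  Orphan proteins (no group) use their own
embedding as their sole encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import OrthologyHierarchy, ProteinRecord, ProteomeCorpus

__all__ = ["EncodingPath", "build_leaf_vectors", "propagate_up",
           "build_hierarchy_vectors", "ancestral_path", "sample_encoding",
           "corpus_encoding_paths"]


@dataclass
class EncodingPath:
    """Ordered candidate encodings for one protein, most specific first."""

    protein_id: str
    vectors: np.ndarray  # (path_length, d)

    def __post_init__(self):
        if self.vectors.ndim != 2 or self.vectors.shape[0] == 0:
            raise ValueError("encoding path must be a nonempty (L, d) array")

    def __len__(self) -> int:
        return self.vectors.shape[0]


def build_leaf_vectors(corpus: ProteomeCorpus,
                       hierarchy: OrthologyHierarchy) -> OrthologyHierarchy:
    """Set each populated leaf group's vector to its members' mean embedding."""
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for rec in corpus.records():
        if rec.og_leaf_id is None:
            continue
        if rec.og_leaf_id not in sums:
            sums[rec.og_leaf_id] = rec.embedding.astype(np.float64).copy()
            counts[rec.og_leaf_id] = 1
        else:
            sums[rec.og_leaf_id] += rec.embedding
            counts[rec.og_leaf_id] += 1
    for leaf in hierarchy.leaves():
        if leaf in sums:
            hierarchy.vectors[leaf] = (sums[leaf] / counts[leaf]).astype(np.float32)
    missing = [og for og in sums if og not in hierarchy.parent]
    if missing:
        raise KeyError(f"corpus references unknown leaf OGs: {missing[:5]}")
    return hierarchy


def propagate_up(hierarchy: OrthologyHierarchy) -> OrthologyHierarchy:
    """Fill internal node vectors as equal-weight means of their children.

    Children without any populated descendant are skipped; a node with no
    populated child and no vector of its own raises.
    """
    order = sorted(hierarchy.nodes, key=lambda n: hierarchy.level[n])
    for node in order:
        kids = hierarchy.children[node]
        if not kids:
            continue  # leaf: either populated by build_leaf_vectors or unused
        vecs = [hierarchy.vectors[c] for c in kids if c in hierarchy.vectors]
        if not vecs:
            if node not in hierarchy.vectors:
                raise ValueError(
                    f"node {node} has no populated child and no vector")
            continue
        hierarchy.vectors[node] = np.mean(np.stack(vecs), axis=0).astype(np.float32)
    return hierarchy


def build_hierarchy_vectors(corpus: ProteomeCorpus) -> OrthologyHierarchy:
    """Convenience: leaf averaging followed by upward propagation."""
    h = build_leaf_vectors(corpus, corpus.hierarchy)
    return propagate_up(h)


def ancestral_path(record: ProteinRecord,
                   hierarchy: OrthologyHierarchy) -> EncodingPath:
    """Vectors along the protein's leaf-to-root chain; orphans get themselves."""
    if record.og_leaf_id is None:
        return EncodingPath(record.protein_id, record.embedding[None, :].copy())
    node_ids = hierarchy.path_to_root(record.og_leaf_id)
    try:
        vectors = np.stack([hierarchy.vectors[n] for n in node_ids])
    except KeyError as exc:
        raise ValueError(
            f"hierarchy vectors not built for node {exc.args[0]}") from exc
    return EncodingPath(record.protein_id, vectors)


def sample_encoding(path: EncodingPath, rng: np.random.Generator) -> np.ndarray:
    """Draw one encoding uniformly from the ancestral path."""
    if len(path) == 0:
        raise ValueError("empty encoding path")
    return path.vectors[int(rng.integers(len(path)))]


def corpus_encoding_paths(corpus: ProteomeCorpus) -> dict[str, EncodingPath]:
    """Cache one EncodingPath per protein (built once per corpus)."""
    return {rec.protein_id: ancestral_path(rec, corpus.hierarchy)
            for rec in corpus.records()}
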