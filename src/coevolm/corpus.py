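"""Core data containers: proteomes, protein records, and the orthology hierarchy.

A :class:`ProteomeCorpus` holds, per species, the set of proteins encoded by
that genome.  Each protein carries a fixed-dimension embedding vector (in the
real-data path these come from a pretrained protein language model; the
bundled simulator generates them) and, unless it is an orphan, a leaf
orthologous-group assignment into an :class:`OrthologyHierarchy` — a rooted
tree of orthologous groups whose levels mirror taxonomic ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

ESSENTIAL = "E"
NONESSENTIAL = "NE"
QUASI_ESSENTIAL = "QE"
UNLABELED = "."


@dataclass
class ProteinRecord:
    protein_id: str
    species_id: str
    og_leaf_id: Optional[str]  # None for orphans
    embedding: np.ndarray
    essential_label: str = UNLABELED

    def __post_init__(self):
        self.embedding = np.asarray(self.embedding, dtype=np.float32)
        if not np.all(np.isfinite(self.embedding)):
            raise ValueError(f"non-finite embedding for {self.protein_id}")


class OrthologyHierarchy:
    """Rooted tree over orthologous-group ids, one optional vector per node.

    Nodes include both leaf orthologous groups (which proteins map to) and
    internal groups at broader taxonomic levels.  Node vectors are filled in
    by the functional-encoding builder.
    """

    def __init__(self):
        self.parent: dict[str, Optional[str]] = {}
        self.children: dict[str, list[str]] = {}
        self.level: dict[str, int] = {}
        self.vectors: dict[str, np.ndarray] = {}

    # --------------------------------------------------------------- building
    def add_node(self, node_id: str, parent_id: Optional[str], level: int) -> None:
        if node_id in self.parent:
            raise ValueError(f"duplicate hierarchy node {node_id}")
        self.parent[node_id] = parent_id
        self.level[node_id] = level
        self.children.setdefault(node_id, [])
        if parent_id is not None:
            if parent_id not in self.parent:
                raise ValueError(f"parent {parent_id} of {node_id} not yet added")
            self.children[parent_id].append(node_id)

    @property
    def root(self) -> str:
        roots = [n for n, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"hierarchy must have exactly one root, found {len(roots)}")
        return roots[0]

    @property
    def nodes(self) -> list[str]:
        return list(self.parent)

    def leaves(self) -> list[str]:
        return [n for n in self.parent if not self.children[n]]

    def path_to_root(self, node_id: str) -> list[str]:
        """Node ids from `node_id` (inclusive) up to the root (inclusive)."""
        if node_id not in self.parent:
            raise KeyError(f"unknown hierarchy node {node_id}")
        path = [node_id]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])
        return path

    def validate(self) -> None:
        _ = self.root
        # acyclicity: every node reaches the root in <= n steps
        n = len(self.parent)
        for node in self.parent:
            if len(self.path_to_root(node)) > n:
                raise ValueError("cycle detected in hierarchy")

    def edges(self) -> list[tuple[str, str, int]]:
        """(child, parent, level-of-child) rows; the root has parent ''. """
        rows = []
        for node, par in self.parent.items():
            rows.append((node, par if par is not None else "", self.level[node]))
        return rows


@dataclass
class ProteomeCorpus:
    """Per-species protein collections plus the hierarchy they reference."""

    species: dict[str, list[ProteinRecord]]
    hierarchy: OrthologyHierarchy
    planted_pairs: list  # list[PlantedPair] from the simulator; may be empty
    config: dict = field(default_factory=dict)
    seed: Optional[int] = None

    @property
    def embedding_dim(self) -> int:
        for records in self.species.values():
            if records:
                return int(records[0].embedding.shape[0])
        raise ValueError("empty corpus")

    def records(self) -> Iterable[ProteinRecord]:
        for sp in self.species.values():
            yield from sp

    def get_record(self, species_id: str, protein_id: str) -> ProteinRecord:
        for rec in self.species[species_id]:
            if rec.protein_id == protein_id:
                return rec
        raise KeyError(f"{protein_id} not in species {species_id}")

    def validate(self) -> None:
        for sid, records in self.species.items():
            ids = [r.protein_id for r in records]
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate protein ids in species {sid}")
            for r in records:
                if r.og_leaf_id is not None and r.og_leaf_id not in self.hierarchy.parent:
                    raise ValueError(
                        f"{r.protein_id}: leaf OG {r.og_leaf_id} missing from hierarchy")
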