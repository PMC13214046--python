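"""Synthetic proteome-corpus simulator with planted coevolution.

The generator emulates, at desk scale, the statistical structure a
proteome-level masked language model exploits:

* a random bifurcating species tree;
* a hierarchy of orthologous groups whose archetype vectors drift as a
  Gaussian random walk from root to leaves (functionally structured
  embeddings);
* presence/absence of each group evolving along the tree as a two-state
  Markov process (loss rate lambda, gain rate mu), with *planted pairs* of
  groups whose loss events co-occur with probability rho — the correlated
  co-occurrence pattern across genomes that phylogenetic profiling exploits;
* per-protein embeddings built from the leaf archetype plus a shared pair
  latent, an essentiality shift, a per-species offset, and protein noise.

Everything is driven by a single integer seed through independent
`SeedSequence` streams per stage, so a corpus is bitwise reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import (ESSENTIAL, NONESSENTIAL, UNLABELED, OrthologyHierarchy,
                     ProteinRecord, ProteomeCorpus)

__all__ = [
    "SpeciesTree", "OGSpec", "PlantedPair", "CorpusConfig",
    "simulate_species_tree", "simulate_og_hierarchy",
    "simulate_presence_absence", "simulate_embeddings", "simulate_corpus",
    "export_labels",
]


# --------------------------------------------------------------------- types
@dataclass
class SpeciesTree:
    """Rooted bifurcating tree; leaves are species.

    `branch_lengths[n]` is the length of the branch above node `n`
    (expected substitutions, arbitrary units).
    """

    parent: dict[str, Optional[str]]
    children: dict[str, list[str]]
    branch_lengths: dict[str, float]
    root: str
    leaves: list[str]

    def validate(self) -> None:
        roots = [n for n, p in self.parent.items() if p is None]
        if roots != [self.root]:
            raise ValueError("tree must have a single root")
        for n, t in self.branch_lengths.items():
            if t < 0:
                raise ValueError(f"negative branch length at {n}")

    def preorder(self) -> list[str]:
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children.get(node, []))
        return order


@dataclass
class OGSpec:
    """One leaf orthologous group and its ancestral chain of archetypes."""

    og_id: str
    level_path: list[str]          # node ids, leaf first, root last
    archetypes: np.ndarray         # (n_levels, d); row k = level-k archetype
    loss_rate: float
    gain_rate: float
    essential: bool

    def __post_init__(self):
        if self.loss_rate < 0 or self.gain_rate < 0:
            raise ValueError("rates must be nonnegative")
        if len(self.level_path) != self.archetypes.shape[0]:
            raise ValueError("one archetype per level required")


@dataclass
class PlantedPair:
    """Two orthologous groups with coupled loss dynamics.

    `coupling` is the probability that a loss drawn for one member on a
    branch co-deletes the partner on the same branch; it also scales the
    embedding-level pair signal (see ``simulate_embeddings``).
    `shared_latent` is the pair's d-dim direction, added to both members'
    embeddings with corpus-level weights.
    """

    og_a: str
    og_b: str
    coupling: float
    shared_latent: np.ndarray

    def __post_init__(self):
        if self.og_a == self.og_b:
            raise ValueError("planted pair members must differ")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")


@dataclass
class CorpusConfig:
    """Default desk-scale study conditions (trains in minutes on one CPU)."""

    n_species: int = 200
    n_ogs: int = 300
    n_levels: int = 4
    embedding_dim: int = 64
    n_planted_pairs: int = 30
    coupling: float = 0.9          # rho
    loss_rate: float = 0.3         # lambda
    gain_rate: float = 0.05        # mu
    branch_length_mean: float = 0.15
    drift_sd: float = 0.5
    species_noise_sd: float = 0.2
    protein_noise_sd: float = 0.1
    outlier_rate: float = 0.1        # fraction of fast-evolving proteins
    outlier_noise_sd: float = 3.0    # their (unpredictable) noise scale
    pair_latent_weight: float = 1.5      # constant shared-direction weight
    pair_covariance_weight: float = 0.6  # co-varying amplitude weight
    essential_fraction: float = 0.3
    essentiality_shift: float = 0.0     # beta, along a fixed unit direction
    essential_loss_multiplier: float = 1.0   # <1: essential OGs rarely lost
    essential_noise_multiplier: float = 1.0  # <1: essential proteins conserved
                                             # (small drift from family mean)
    label_noise: float = 0.05           # epsilon
    orphan_rate: float = 0.02           # orphans per present OG, per species
    seed: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------- operations
def simulate_species_tree(n_species: int, seed: int,
                          branch_length_mean: float = 0.3) -> SpeciesTree:
    """Random bifurcating tree built by repeatedly joining two random lineages."""
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng(seed)
    leaves = [f"S{i:04d}" for i in range(n_species)]
    parent: dict[str, Optional[str]] = {s: None for s in leaves}
    children: dict[str, list[str]] = {s: [] for s in leaves}
    branch: dict[str, float] = {}
    roots = list(leaves)
    k = 0
    while len(roots) > 1:
        i, j = sorted(rng.choice(len(roots), size=2, replace=False))
        a, b = roots[i], roots[j]
        node = f"A{k:04d}"
        k += 1
        parent[node] = None
        children[node] = [a, b]
        parent[a] = parent[b] = node
        branch[a] = float(rng.exponential(branch_length_mean))
        branch[b] = float(rng.exponential(branch_length_mean))
        roots = [r for r in roots if r not in (a, b)] + [node]
    tree = SpeciesTree(parent=parent, children=children, branch_lengths=branch,
                       root=roots[0], leaves=leaves)
    tree.validate()
    return tree


def simulate_og_hierarchy(n_ogs: int, n_levels: int, d: int, drift_sd: float,
                          seed: int) -> tuple[list[OGSpec], OrthologyHierarchy]:
    """Random orthology hierarchy with Gaussian random-walk archetypes.

    Root archetypes are i.i.d. standard normal; each child's archetype is its
    parent's plus N(0, drift_sd^2) per coordinate.  Every leaf group carries
    the full chain of archetypes from its own level up to the root.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if d < 1 or n_ogs < 1:
        raise ValueError("n_ogs and d must be positive")
    rng = np.random.default_rng(seed)

    # node counts per level: n_ogs at the leaf level, geometric decay to 1 root
    counts = [max(1, int(round(n_ogs ** ((n_levels - 1 - k) / (n_levels - 1)))))
              for k in range(n_levels)]
    counts[0] = n_ogs
    counts[-1] = 1

    hierarchy = OrthologyHierarchy()
    names: list[list[str]] = [[] for _ in range(n_levels)]
    vectors: dict[str, np.ndarray] = {}
    parent_of: dict[str, str] = {}

    root = "ROOT"
    names[-1] = [root]
    hierarchy.add_node(root, None, n_levels - 1)
    vectors[root] = rng.normal(0.0, 1.0, size=d).astype(np.float32)

    for level in range(n_levels - 2, -1, -1):
        for i in range(counts[level]):
            node = f"OG{i:05d}" if level == 0 else f"L{level}G{i:04d}"
            par = names[level + 1][int(rng.integers(counts[level + 1]))]
            names[level].append(node)
            hierarchy.add_node(node, par, level)
            parent_of[node] = par
            vectors[node] = (vectors[par]
                             + rng.normal(0.0, drift_sd, size=d)).astype(np.float32)

    # guarantee internal nodes each have at least one child (drop childless ones)
    for level in range(1, n_levels - 1):
        for node in list(names[level]):
            if not hierarchy.children[node]:
                par = hierarchy.parent[node]
                hierarchy.children[par].remove(node)
                del hierarchy.parent[node], hierarchy.children[node]
                del hierarchy.level[node], vectors[node]
                names[level].remove(node)

    specs = []
    for og in names[0]:
        path = hierarchy.path_to_root(og)
        arch = np.stack([vectors[n] for n in path])
        specs.append(OGSpec(og_id=og, level_path=path, archetypes=arch,
                            loss_rate=np.nan, gain_rate=np.nan, essential=False))
    # rates/flags are corpus-level choices; filled by the corpus driver
    for s in specs:
        s.loss_rate = 0.0
        s.gain_rate = 0.0
    hierarchy.validate()
    return specs, hierarchy


def simulate_presence_absence(tree: SpeciesTree, ogs: Sequence[OGSpec],
                              planted_pairs: Sequence[PlantedPair],
                              seed: int) -> pd.DataFrame:
    """Two-state Markov presence/absence along the tree with coupled losses.

    Every group is present at the root.  On a branch of length t a present
    group is lost with probability 1-exp(-lambda*t) and an absent group
    regained with probability 1-exp(-mu*t).  Whenever a loss is *drawn* for
    one member of a planted pair on a branch, the partner (if present and not
    itself already lost) is co-deleted with probability rho.  Returns a
    boolean species x OG DataFrame.
    """
    for og in ogs:
        if not (np.isfinite(og.loss_rate) and np.isfinite(og.gain_rate)):
            raise ValueError(f"non-finite rates for {og.og_id}")
    rng = np.random.default_rng(seed)
    og_ids = [o.og_id for o in ogs]
    idx = {o: i for i, o in enumerate(og_ids)}
    lam = np.array([o.loss_rate for o in ogs])
    mu = np.array([o.gain_rate for o in ogs])

    pair_index = [(idx[p.og_a], idx[p.og_b], p.coupling) for p in planted_pairs]

    state = {tree.root: np.ones(len(ogs), dtype=bool)}
    for node in tree.preorder():
        if node == tree.root:
            continue
        t = tree.branch_lengths[node]
        cur = state[tree.parent[node]].copy()
        p_loss = 1.0 - np.exp(-lam * t)
        p_gain = 1.0 - np.exp(-mu * t)
        u = rng.random(len(ogs))
        lost = cur & (u < p_loss)
        gained = (~cur) & (u < p_gain)
        # coupled co-deletion of planted partners on the same branch
        for ia, ib, rho in pair_index:
            for src, dst in ((ia, ib), (ib, ia)):
                if lost[src] and cur[dst] and not lost[dst]:
                    if rng.random() < rho:
                        lost[dst] = True
        state[node] = (cur & ~lost) | gained
    data = np.stack([state[leaf] for leaf in tree.leaves])
    return pd.DataFrame(data, index=tree.leaves, columns=og_ids)


def simulate_embeddings(tree: SpeciesTree, ogs: Sequence[OGSpec],
                        planted_pairs: Sequence[PlantedPair],
                        presence: pd.DataFrame, config: CorpusConfig,
                        seed: int) -> dict[str, list[ProteinRecord]]:
    """Fill a corpus with embeddings and essentiality labels.

    For each present group in each species:
    embedding = leaf archetype
                + (w0 + w1*c) * shared_latent   (planted-pair members)
                + beta * u                      (essential groups)
                + species offset + protein noise.

    The pair latent has two parts.  The constant part (weight w0 =
    `pair_latent_weight`) is a shared direction both partners carry in every
    genome — interface and complex features that make interacting proteins
    resemble each other.  The co-varying part (weight w1 =
    `pair_covariance_weight`) has an amplitude c drawn per species: a
    *shared* draw when both members are present (their embeddings co-vary
    across genomes — the embedding-level face of coevolution), an
    independent draw when only one member is present, so marginal statistics
    are unchanged and only the correlation carries the pair signal.
    Essentiality labels flip with probability `label_noise`; orphans carry
    unit-scale noise embeddings and no label.
    """
    d = config.embedding_dim
    for og in ogs:
        if og.archetypes.shape[1] != d:
            raise ValueError("archetype dimension mismatch")
    ss = np.random.SeedSequence(seed)
    rng_species, rng_prot, rng_label, rng_dir = (
        np.random.default_rng(s) for s in ss.spawn(4))

    ess_dir = rng_dir.normal(size=d)
    ess_dir = (ess_dir / np.linalg.norm(ess_dir)).astype(np.float32)

    for p in planted_pairs:
        if p.shared_latent.shape != (d,):
            raise ValueError("shared_latent dimension mismatch")

    spec_of = {o.og_id: o for o in ogs}
    species_records: dict[str, list[ProteinRecord]] = {}
    for sp in tree.leaves:
        offset = rng_species.normal(0.0, config.species_noise_sd, size=d)
        # per-species latent amplitudes: shared draw when co-present,
        # independent draws otherwise (same marginals, correlation only
        # between co-present partners)
        latent_term: dict[str, np.ndarray] = {}
        for p in planted_pairs:
            c1, c2 = rng_species.normal(0.0, 1.0, size=2)
            u = rng_species.random()
            here_a = bool(presence.at[sp, p.og_a])
            here_b = bool(presence.at[sp, p.og_b])
            # coupling strength governs every face of coevolution: losses
            # co-occur with probability rho, the shared-direction weight
            # scales with rho (obligate partners share more interface
            # features), and co-present partners share their amplitude draw
            # with probability rho
            shared = here_a and here_b and u < p.coupling
            amp_a, amp_b = (c1, c1) if shared else (c1, c2)
            w0 = config.pair_latent_weight * p.coupling
            w1 = config.pair_covariance_weight
            if here_a:
                latent_term[p.og_a] = (w0 + w1 * amp_a) * p.shared_latent
            if here_b:
                latent_term[p.og_b] = (w0 + w1 * amp_b) * p.shared_latent
        records = []
        present = [og for og in presence.columns if presence.at[sp, og]]
        for og_id in present:
            og = spec_of[og_id]
            emb = og.archetypes[0].astype(np.float64) + offset
            if og_id in latent_term:
                emb = emb + latent_term[og_id]
            if og.essential:
                emb = emb + config.essentiality_shift * ess_dir
            # heavy-tailed noise: a fraction of proteins drift far from their
            # family mean (fast-evolving members), with unpredictable magnitude
            noise_sd = (config.outlier_noise_sd
                        if rng_prot.random() < config.outlier_rate
                        else config.protein_noise_sd)
            if og.essential:
                noise_sd *= config.essential_noise_multiplier
            emb = emb + rng_prot.normal(0.0, noise_sd, size=d)
            true_label = ESSENTIAL if og.essential else NONESSENTIAL
            if rng_label.random() < config.label_noise:
                true_label = NONESSENTIAL if true_label == ESSENTIAL else ESSENTIAL
            records.append(ProteinRecord(
                protein_id=f"{sp}_{og_id}", species_id=sp, og_leaf_id=og_id,
                embedding=emb.astype(np.float32), essential_label=true_label))
        n_orphans = int(round(config.orphan_rate * len(present)))
        for j in range(n_orphans):
            emb = offset + rng_prot.normal(0.0, 1.0, size=d)
            records.append(ProteinRecord(
                protein_id=f"{sp}_ORPH{j:03d}", species_id=sp, og_leaf_id=None,
                embedding=emb.astype(np.float32), essential_label=UNLABELED))
        species_records[sp] = records
    return species_records


def simulate_corpus(config: CorpusConfig) -> ProteomeCorpus:
    """Run the full generative pipeline under one seed."""
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_hier, s_flags, s_pairs, s_presence, s_emb = (
        int(s.generate_state(1)[0]) % (2 ** 31) for s in ss.spawn(6))

    tree = simulate_species_tree(config.n_species, s_tree,
                                 config.branch_length_mean)
    ogs, hierarchy = simulate_og_hierarchy(
        config.n_ogs, config.n_levels, config.embedding_dim,
        config.drift_sd, s_hier)

    rng_flags = np.random.default_rng(s_flags)
    for og in ogs:
        og.essential = bool(rng_flags.random() < config.essential_fraction)
        og.gain_rate = config.gain_rate
        og.loss_rate = config.loss_rate * (
            config.essential_loss_multiplier if og.essential else 1.0)

    rng_pairs = np.random.default_rng(s_pairs)
    if 2 * config.n_planted_pairs > config.n_ogs:
        raise ValueError("not enough OGs for the requested planted pairs")
    chosen = rng_pairs.choice(config.n_ogs, size=2 * config.n_planted_pairs,
                              replace=False)
    planted = []
    for i in range(config.n_planted_pairs):
        latent = rng_pairs.normal(0.0, 1.0,
                                  size=config.embedding_dim).astype(np.float32)
        planted.append(PlantedPair(og_a=ogs[chosen[2 * i]].og_id,
                                   og_b=ogs[chosen[2 * i + 1]].og_id,
                                   coupling=config.coupling,
                                   shared_latent=latent))

    presence = simulate_presence_absence(tree, ogs, planted, s_presence)
    species_records = simulate_embeddings(tree, ogs, planted, presence,
                                          config, s_emb)
    corpus = ProteomeCorpus(species=species_records, hierarchy=hierarchy,
                            planted_pairs=planted, config=config.to_dict(),
                            seed=config.seed)
    corpus.validate()
    return corpus


def export_labels(corpus: ProteomeCorpus, negative_ratio: int = 10,
                  seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Derive the supervised-task label tables from a corpus.

    Returns ``(pair_set, gene_set)``.  Positive pairs are planted pairs in
    every species where both members are present; negatives are sampled
    co-present non-planted pairs at `negative_ratio` negatives per positive.
    The gene table carries essentiality labels with the leaf OG id as the
    cluster id (the stand-in for sequence-similarity clusters).
    """
    rng = np.random.default_rng(seed)
    planted_keys = {frozenset((p.og_a, p.og_b)) for p in corpus.planted_pairs}
    if not corpus.planted_pairs:
        warnings.warn("corpus has no planted pairs; positive set is empty")

    rows = []
    present_by_species: dict[str, dict[str, str]] = {}
    for sid, records in corpus.species.items():
        present_by_species[sid] = {r.og_leaf_id: r.protein_id
                                   for r in records if r.og_leaf_id is not None}
    for p in corpus.planted_pairs:
        for sid, present in present_by_species.items():
            if p.og_a in present and p.og_b in present:
                rows.append((sid, present[p.og_a], present[p.og_b], 1))
    n_pos = len(rows)

    # sample negatives uniformly over species, then over co-present OG pairs
    n_neg = negative_ratio * n_pos
    species_ids = list(corpus.species)
    total_available = sum(
        len(v) * (len(v) - 1) // 2 for v in present_by_species.values())
    if n_neg > total_available:
        raise ValueError(
            f"requested {n_neg} negatives but only {total_available} pairs exist")
    neg_keys: set[tuple[str, str, str]] = set()
    while len(neg_keys) < n_neg:
        sid = species_ids[int(rng.integers(len(species_ids)))]
        ogs_here = list(present_by_species[sid])
        if len(ogs_here) < 2:
            continue
        i, j = rng.choice(len(ogs_here), size=2, replace=False)
        a, b = sorted((ogs_here[i], ogs_here[j]))
        if frozenset((a, b)) in planted_keys:
            continue
        neg_keys.add((sid, a, b))
    for sid, a, b in sorted(neg_keys):
        present = present_by_species[sid]
        rows.append((sid, present[a], present[b], 0))
    pair_set = pd.DataFrame(rows,
                            columns=["species_id", "protein_a", "protein_b",
                                     "label"])

    gene_rows = [(r.protein_id, r.species_id, r.essential_label,
                  r.og_leaf_id if r.og_leaf_id is not None else ".")
                 for r in corpus.records()]
    gene_set = pd.DataFrame(gene_rows, columns=["protein_id", "species_id",
                                                "label", "cluster_id"])
    return pair_set, gene_set
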