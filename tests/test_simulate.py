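"""Simulator: species trees, hierarchies, presence/absence, embeddings, labels."""

import numpy as np
import pytest

from coevolm.corpus import UNLABELED
from coevolm.simulate import (CorpusConfig, PlantedPair, export_labels,
                              simulate_corpus, simulate_og_hierarchy,
                              simulate_presence_absence, simulate_species_tree)


class TestSpeciesTree:
    def test_smallest_tree(self):
        tree = simulate_species_tree(2, seed=0)
        assert len(tree.leaves) == 2
        internal = [n for n in tree.parent if n not in tree.leaves]
        assert internal == [tree.root]

    def test_determinism(self):
        t1 = simulate_species_tree(50, seed=7)
        t2 = simulate_species_tree(50, seed=7)
        assert t1.parent == t2.parent
        assert t1.branch_lengths == t2.branch_lengths

    def test_bifurcating_node_count(self):
        # a rooted bifurcating tree with n leaves has n-1 internal nodes
        tree = simulate_species_tree(50, seed=1)
        internal = [n for n in tree.parent if n not in tree.leaves]
        assert len(tree.leaves) == 50
        assert len(internal) == 49
        for n in internal:
            assert len(tree.children[n]) == 2

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_tree(1, seed=0)


class TestOGHierarchy:
    def test_zero_drift_gives_identical_archetypes(self):
        ogs, _ = simulate_og_hierarchy(20, n_levels=4, d=8, drift_sd=0.0, seed=0)
        for og in ogs:
            assert np.allclose(og.archetypes, og.archetypes[0])

    def test_archetype_shapes(self):
        ogs, h = simulate_og_hierarchy(100, n_levels=4, d=8, drift_sd=0.3,
                                       seed=0)
        assert len(ogs) == 100
        for og in ogs:
            assert og.archetypes.shape == (4, 8)
            assert og.level_path[-1] == h.root

    def test_random_walk_variance(self):
        # E||leaf - root||^2 over a (n_levels-1)-step Gaussian walk is
        # (n_levels-1) * drift_sd^2 * d
        d, drift, levels = 16, 0.5, 4
        ogs, _ = simulate_og_hierarchy(1000, n_levels=levels, d=d,
                                       drift_sd=drift, seed=2)
        sq = np.mean([np.sum((og.archetypes[0] - og.archetypes[-1]) ** 2)
                      for og in ogs])
        expected = (levels - 1) * drift ** 2 * d
        assert sq == pytest.approx(expected, rel=0.15)

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            simulate_og_hierarchy(10, n_levels=1, d=8, drift_sd=0.1, seed=0)
        with pytest.raises(ValueError):
            simulate_og_hierarchy(10, n_levels=3, d=0, drift_sd=0.1, seed=0)


def _ogs_with_rates(n, lam, mu, d=4, seed=0):
    ogs, h = simulate_og_hierarchy(n, n_levels=3, d=d, drift_sd=0.2, seed=seed)
    for og in ogs:
        og.loss_rate, og.gain_rate = lam, mu
    return ogs, h


def _phi(x, y):
    return np.corrcoef(x.astype(float), y.astype(float))[0, 1]


class TestPresenceAbsence:
    def test_no_events_all_present(self):
        tree = simulate_species_tree(20, seed=0)
        ogs, _ = _ogs_with_rates(15, 0.0, 0.0)
        presence = simulate_presence_absence(tree, ogs, [], seed=0)
        assert presence.to_numpy().all()

    def test_full_coupling_identical_columns(self):
        tree = simulate_species_tree(40, seed=1)
        ogs, _ = _ogs_with_rates(10, 0.4, 0.0)
        pair = PlantedPair(og_a=ogs[0].og_id, og_b=ogs[1].og_id, coupling=1.0,
                           shared_latent=np.zeros(4, dtype=np.float32))
        presence = simulate_presence_absence(tree, ogs, [pair], seed=3)
        assert (presence[ogs[0].og_id] == presence[ogs[1].og_id]).all()

    def test_planted_phi_exceeds_random_quantile(self):
        tree = simulate_species_tree(200, seed=2)
        ogs, _ = _ogs_with_rates(60, 0.3, 0.05)
        rng = np.random.default_rng(5)
        pairs = []
        picked = rng.choice(60, size=20, replace=False)
        for k in range(10):
            pairs.append(PlantedPair(
                og_a=ogs[picked[2 * k]].og_id, og_b=ogs[picked[2 * k + 1]].og_id,
                coupling=0.9, shared_latent=np.zeros(4, dtype=np.float32)))
        presence = simulate_presence_absence(tree, ogs, pairs, seed=8)
        planted_phis = [_phi(presence[p.og_a].to_numpy(),
                             presence[p.og_b].to_numpy()) for p in pairs]
        planted_set = {p.og_a for p in pairs} | {p.og_b for p in pairs}
        others = [o.og_id for o in ogs if o.og_id not in planted_set]
        random_phis = [_phi(presence[a].to_numpy(), presence[b].to_numpy())
                       for i, a in enumerate(others) for b in others[i + 1:]]
        assert np.mean(planted_phis) > np.quantile(random_phis, 0.95)

    def test_coupling_monotonicity(self):
        # mean presence phi over planted pairs is nondecreasing in rho
        means = {}
        for rho in (0.0, 0.5, 1.0):
            vals = []
            for seed in range(5):
                tree = simulate_species_tree(200, seed=100 + seed)
                ogs, _ = _ogs_with_rates(30, 0.3, 0.05, seed=seed)
                pairs = [PlantedPair(og_a=ogs[2 * k].og_id,
                                     og_b=ogs[2 * k + 1].og_id, coupling=rho,
                                     shared_latent=np.zeros(4, dtype=np.float32))
                         for k in range(8)]
                presence = simulate_presence_absence(tree, ogs, pairs,
                                                     seed=200 + seed)
                phis = [_phi(presence[p.og_a].to_numpy(),
                             presence[p.og_b].to_numpy()) for p in pairs]
                vals.append(np.nanmean(phis))
            means[rho] = np.mean(vals)
        assert means[0.5] >= means[0.0] - 0.02
        assert means[1.0] >= means[0.5] - 0.02


class TestEmbeddings:
    def test_noise_free_limit(self):
        cfg = CorpusConfig(n_species=10, n_ogs=12, n_levels=3, embedding_dim=8,
                           n_planted_pairs=2, species_noise_sd=0.0,
                           protein_noise_sd=0.0, outlier_rate=0.0,
                           pair_latent_weight=0.0, pair_covariance_weight=0.0,
                           essentiality_shift=0.0, orphan_rate=0.0, seed=4)
        corpus = simulate_corpus(cfg)
        by_og = {}
        for rec in corpus.records():
            by_og.setdefault(rec.og_leaf_id, []).append(rec.embedding)
        for embs in by_og.values():
            for e in embs[1:]:
                np.testing.assert_array_equal(embs[0], e)

    def test_essentiality_probe_separates(self):
        # with a large planted shift and no label noise, a linear probe on raw
        # embeddings separates essential from nonessential nearly perfectly
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import roc_auc_score
        cfg = CorpusConfig(n_species=20, n_ogs=40, embedding_dim=16,
                           n_planted_pairs=4, essentiality_shift=4.0,
                           label_noise=0.0, seed=5)
        corpus = simulate_corpus(cfg)
        recs = [r for r in corpus.records() if r.essential_label != UNLABELED]
        x = np.stack([r.embedding for r in recs])
        y = np.array([r.essential_label == "E" for r in recs])
        clf = LogisticRegression(max_iter=500).fit(x, y)
        assert roc_auc_score(y, clf.decision_function(x)) > 0.98

    def test_corpus_determinism(self):
        cfg = CorpusConfig(n_species=8, n_ogs=10, embedding_dim=8,
                           n_planted_pairs=2, seed=11)
        c1, c2 = simulate_corpus(cfg), simulate_corpus(cfg)
        assert sorted(c1.species) == sorted(c2.species)
        for sid in c1.species:
            for r1, r2 in zip(c1.species[sid], c2.species[sid]):
                assert r1.protein_id == r2.protein_id
                assert r1.essential_label == r2.essential_label
                np.testing.assert_array_equal(r1.embedding, r2.embedding)

    def test_record_conservation(self, tiny_corpus):
        # per species: records = present OGs + configured orphans
        orphan_rate = tiny_corpus.config["orphan_rate"]
        for sid, records in tiny_corpus.species.items():
            n_with_og = sum(r.og_leaf_id is not None for r in records)
            n_orphans = sum(r.og_leaf_id is None for r in records)
            assert n_orphans == int(round(orphan_rate * n_with_og))


class TestExportLabels:
    def test_negative_ratio_arithmetic(self, tiny_corpus):
        pair_set, _ = export_labels(tiny_corpus, negative_ratio=10, seed=0)
        n_pos = int((pair_set["label"] == 1).sum())
        n_neg = int((pair_set["label"] == 0).sum())
        assert n_neg == 10 * n_pos

    def test_no_planted_pairs_warns(self):
        cfg = CorpusConfig(n_species=6, n_ogs=10, embedding_dim=8,
                           n_planted_pairs=0, seed=3)
        corpus = simulate_corpus(cfg)
        with pytest.warns(UserWarning):
            pair_set, _ = export_labels(corpus, seed=0)
        assert (pair_set["label"] == 1).sum() == 0

    def test_exported_pairs_are_co_present(self, tiny_corpus):
        pair_set, _ = export_labels(tiny_corpus, negative_ratio=5, seed=1)
        for row in pair_set.itertuples(index=False):
            ids = {r.protein_id for r in tiny_corpus.species[row.species_id]}
            assert row.protein_a in ids and row.protein_b in ids

    def test_too_many_negatives_rejected(self):
        cfg = CorpusConfig(n_species=4, n_ogs=10, embedding_dim=8,
                           n_planted_pairs=4, seed=3)
        corpus = simulate_corpus(cfg)
        with pytest.raises(ValueError):
            export_labels(corpus, negative_ratio=100000, seed=0)

    def test_gene_set_clusters_are_leaf_ogs(self, tiny_corpus):
        _, gene_set = export_labels(tiny_corpus, seed=0)
        ogs = {r.og_leaf_id for r in tiny_corpus.records() if r.og_leaf_id}
        clustered = gene_set[gene_set["cluster_id"] != "."]
        assert set(clustered["cluster_id"]) <= ogs
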