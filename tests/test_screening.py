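"""Attention-feature PPI screening: metrics, screener, recall curves."""

import numpy as np
import pandas as pd
import pytest

from coevolm.backbone import feature_names
from coevolm.screening import (auc, embedding_similarity_baseline,
                               mean_attention_score, per_head_auc,
                               recall_at_n, train_screener)


def _brute_force_auc(scores, labels):
    """Exhaustive pairwise-comparison oracle with half-credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


def _table(features: np.ndarray, labels, n_layers=2, n_heads=2):
    cols = feature_names(n_layers, n_heads)
    df = pd.DataFrame(features, columns=cols)
    df["label"] = labels
    return df


class TestAUC:
    def test_perfect_separation(self):
        assert auc([5, 4, 1, 0], [1, 1, 0, 0]) == 1.0

    def test_random_scores_near_half(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, size=4000)
        assert auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize("scores,labels", [
        ([3, 2, 1], [1, 0, 1]),
        ([1, 1, 2, 0], [1, 0, 0, 1]),
        ([0.5, 0.2, 0.9, 0.2], [0, 1, 1, 0]),
    ])
    def test_matches_brute_force_oracle(self, scores, labels):
        assert auc(scores, labels) == pytest.approx(
            _brute_force_auc(scores, labels), abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=200)
        labels = (rng.random(200) < 0.3).astype(int)
        a = auc(scores, labels)
        assert auc(np.exp(scores), labels) == pytest.approx(a, abs=1e-9)
        assert auc(3 * scores - 7, labels) == pytest.approx(a, abs=1e-9)


class TestPerHeadAUC:
    def test_label_feature_scores_one(self, rng):
        labels = rng.integers(0, 2, size=50)
        feats = rng.normal(size=(50, 4))
        feats[:, 2] = labels
        m = per_head_auc(_table(feats, labels), 2, 2)
        assert m.shape == (2, 2)
        assert m[1, 0] == 1.0

    def test_constant_feature_is_half(self, rng):
        labels = np.array([0, 1] * 10)
        feats = np.ones((20, 4))
        m = per_head_auc(_table(feats, labels), 2, 2)
        np.testing.assert_allclose(m, 0.5)

    def test_wrong_column_count_rejected(self, rng):
        table = _table(rng.normal(size=(10, 4)), [0, 1] * 5)
        with pytest.raises(ValueError):
            per_head_auc(table, 3, 3)


class TestMeanAttentionScore:
    def test_constant_features_give_constant(self):
        table = _table(np.full((5, 4), 0.25), [0] * 5)
        np.testing.assert_allclose(mean_attention_score(table), 0.25)

    def test_all_scope_equals_mean_of_layer_means(self, rng):
        table = _table(rng.random((20, 4)), [0] * 20)
        all_scores = mean_attention_score(table, "all")
        per_layer = mean_attention_score(table, "per_layer",
                                         n_heads_per_layer=2)
        np.testing.assert_allclose(all_scores, per_layer.mean(axis=1),
                                   rtol=1e-6)

    def test_single_head_identity(self, rng):
        cols = feature_names(1, 1)
        table = pd.DataFrame(rng.random((10, 1)), columns=cols)
        np.testing.assert_allclose(mean_attention_score(table),
                                   table[cols[0]].to_numpy())


class TestScreener:
    @pytest.fixture
    def planted_table(self, rng):
        n = 3000
        labels = (rng.random(n) < 0.1).astype(int)
        feats = rng.normal(size=(n, 4)) * 0.1
        feats[:, 1] += labels * 1.0  # one strongly discriminating head
        return _table(feats, labels)

    def test_training_pairs_held_out(self, planted_table):
        res = train_screener(planted_table, n_pos=50, n_neg=500, seed=0)
        eval_idx = np.setdiff1d(np.arange(len(planted_table)),
                                res.training_index)
        assert len(set(eval_idx) & set(res.training_index.tolist())) == 0
        assert len(res.training_index) == 550

    def test_screener_matches_best_single_head(self, planted_table):
        res = train_screener(planted_table, n_pos=50, n_neg=500, seed=0)
        held = planted_table.drop(index=res.training_index)
        labels = held["label"].to_numpy()
        screen_auc = auc(res.score(held), labels)
        best_head = max(auc(held[c], labels)
                        for c in held.columns if c.startswith("attn_"))
        assert screen_auc >= best_head - 0.02

    def test_coefficient_shape(self, planted_table):
        res = train_screener(planted_table, n_pos=50, n_neg=500, seed=1)
        assert res.coefficients.shape == (4,)

    def test_deterministic_under_seed(self, planted_table):
        r1 = train_screener(planted_table, n_pos=50, n_neg=500, seed=3)
        r2 = train_screener(planted_table, n_pos=50, n_neg=500, seed=3)
        np.testing.assert_array_equal(r1.training_index, r2.training_index)
        np.testing.assert_allclose(r1.coefficients, r2.coefficients)

    def test_insufficient_positives_rejected(self, rng):
        table = _table(rng.normal(size=(30, 4)), [1] * 5 + [0] * 25)
        with pytest.raises(ValueError, match="positives"):
            train_screener(table, n_pos=100, n_neg=10)


class TestRecallAtN:
    def _ranked(self, ids_scores):
        df = pd.DataFrame(ids_scores, columns=["protein_a", "protein_b",
                                               "score"])
        return df.sort_values("score", ascending=False)

    def test_full_list_recall_one(self):
        ranked = self._ranked([("a", "b", 3), ("c", "d", 2), ("e", "f", 1)])
        truth = {frozenset(("a", "b")), frozenset(("e", "f"))}
        curve = recall_at_n(ranked, truth, [3])
        assert curve["recall"].iloc[0] == 1.0

    def test_truth_ranked_first(self):
        ranked = self._ranked([("a", "b", 3), ("c", "d", 2), ("e", "f", 1)])
        truth = {frozenset(("a", "b"))}
        assert recall_at_n(ranked, truth, [1])["recall"].iloc[0] == 1.0

    def test_random_ranking_matches_uniform_expectation(self, rng):
        n = 2000
        pairs = [(f"p{i}", f"q{i}", rng.random()) for i in range(n)]
        truth = {frozenset((f"p{i}", f"q{i}")) for i in range(0, n, 4)}
        ranked = self._ranked(pairs)
        grid = [500, 1000, 1500]
        curve = recall_at_n(ranked, truth, grid)
        for n_at, rec in zip(curve["n"], curve["recall"]):
            expected = n_at / n
            sigma = np.sqrt(expected * (1 - expected) / len(truth))
            assert abs(rec - expected) < 4 * sigma

    def test_empty_truth_rejected(self):
        ranked = self._ranked([("a", "b", 1.0)])
        with pytest.raises(ValueError):
            recall_at_n(ranked, set(), [1])


class TestEmbeddingSimilarityBaseline:
    def test_baseline_tracks_planted_embedding_signal(self):
        """Cosine similarity of raw embeddings separates planted pairs when
        (and only when) the pair latent is present in embedding space;
        presence/absence-only coupling leaves it at chance.  Each corpus
        carries only 12 independent planted pairs, so both estimates are
        averaged over three generator seeds."""
        from coevolm.screening import auc
        from coevolm.simulate import CorpusConfig, simulate_corpus

        def baseline_auc(seed, **kw):
            corpus = simulate_corpus(CorpusConfig(
                n_species=60, n_ogs=120, n_planted_pairs=12, seed=seed, **kw))
            rng = np.random.default_rng(seed)
            planted = {frozenset((p.og_a, p.og_b))
                       for p in corpus.planted_pairs}
            scores, labels = [], []
            for sid, records in corpus.species.items():
                emb = {r.og_leaf_id: r.embedding for r in records
                       if r.og_leaf_id}
                pos = [p for p in corpus.planted_pairs
                       if p.og_a in emb and p.og_b in emb]
                for p in pos:
                    scores.append(embedding_similarity_baseline(
                        emb[p.og_a], emb[p.og_b])[0])
                    labels.append(1)
                ogs = sorted(emb)
                count = 0
                while count < 5 * len(pos):
                    i, j = rng.choice(len(ogs), 2, replace=False)
                    if frozenset((ogs[i], ogs[j])) in planted:
                        continue
                    scores.append(embedding_similarity_baseline(
                        emb[ogs[i]], emb[ogs[j]])[0])
                    labels.append(0)
                    count += 1
            return auc(scores, labels)

        seeds = (17, 18, 19)
        with_latent = np.mean([baseline_auc(s) for s in seeds])
        presence_only = np.mean([
            baseline_auc(s, pair_latent_weight=0.0,
                         pair_covariance_weight=0.0) for s in seeds])
        assert with_latent > 0.7
        assert abs(presence_only - 0.5) < 0.1

    def test_identical_embeddings_score_one(self):
        v = np.array([[1.0, 2.0, 3.0]])
        assert embedding_similarity_baseline(v, v)[0] == pytest.approx(1.0)

    def test_orthogonal_embeddings_score_zero(self):
        a = np.array([[1.0, 0.0]])
        b = np.array([[0.0, 1.0]])
        assert embedding_similarity_baseline(a, b)[0] == pytest.approx(0.0)

    def test_zero_norm_warns_and_scores_zero(self):
        a = np.zeros((1, 3))
        b = np.ones((1, 3))
        with pytest.warns(UserWarning):
            assert embedding_similarity_baseline(a, b)[0] == 0.0
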