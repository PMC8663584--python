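"""SGNS embedding: vocabulary, noise/subsampling, training, queries, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plm import (TrainingConfig, build_vocab, cosine_similarity,
                 load_model, nearest_neighbors, noise_distribution,
                 save_model, subsample_keep_probability, train)
from plm.corpus import Corpus, Post
from plm.sgns import EmbeddingModel, Vocabulary, pair_gradients, pair_loss

from conftest import PLANTED_GROUPS
from oracles import (nearest_bruteforce, ppmi_neighbors, ppmi_svd_embedding,
                     unigram_counts_bruteforce)


def _corpus(token_lists):
    return Corpus([Post(id=f"p{i}", raw_text="", tokens=list(t))
                   for i, t in enumerate(token_lists)])


# -- vocabulary -------------------------------------------------------------

def test_build_vocab_min_count_filter():
    corpus = _corpus([["a"] * 5 + ["b"]])
    vocab = build_vocab(corpus, min_count=2)
    assert vocab.tokens == ["a"]
    assert vocab.counts.tolist() == [5]


def test_build_vocab_min_count_one_keeps_all_distinct():
    corpus = _corpus([["a", "b", "c", "a"]])
    assert len(build_vocab(corpus, min_count=1)) == 3


def test_build_vocab_counts_match_bruteforce(planted_corpus):
    corpus, _ = planted_corpus
    small = Corpus(corpus.posts[:40])
    vocab = build_vocab(small, min_count=1)
    brute = unigram_counts_bruteforce(small)
    assert dict(zip(vocab.tokens, vocab.counts.tolist())) == brute


# -- noise distribution & subsampling ---------------------------------------

def _vocab(counts: dict[str, int]):
    tokens = list(counts)
    return Vocabulary(tokens=tokens,
                      counts=np.array([counts[t] for t in tokens]),
                      min_count=1)


def test_noise_distribution_exact_powers():
    p = noise_distribution(_vocab({"a": 16, "b": 1}), exponent=0.75)
    assert p.tolist() == pytest.approx([8 / 9, 1 / 9])


def test_noise_distribution_exponent_one_is_relative_frequency():
    p = noise_distribution(_vocab({"a": 3, "b": 1}), exponent=1.0)
    assert p.tolist() == pytest.approx([0.75, 0.25])


@given(st.lists(st.integers(1, 10_000), min_size=1, max_size=30),
       st.floats(0.05, 1.0))
@settings(max_examples=100, deadline=None)
def test_noise_distribution_is_probability_vector(counts, exponent):
    vocab = _vocab({f"t{i}": c for i, c in enumerate(counts)})
    p = noise_distribution(vocab, exponent)
    assert (p >= 0).all()
    assert abs(p.sum() - 1.0) < 1e-12
    if len(set(counts)) == 1:
        assert p.tolist() == pytest.approx([1 / len(counts)] * len(counts))


def test_noise_distribution_empty_vocab_errors():
    with pytest.raises(ValueError):
        noise_distribution(Vocabulary([], np.array([], dtype=np.int64), 1))


@pytest.mark.parametrize("f,t,expected", [
    (1e-4, 1e-4, 1.0),
    (4e-4, 1e-4, 0.5),
    (1e-2, 1e-4, 0.1),
    (1e-6, 1e-4, 1.0),  # rare tokens always kept
])
def test_subsample_keep_probability(f, t, expected):
    assert subsample_keep_probability(f, t) == pytest.approx(expected)


@given(st.floats(1e-8, 1.0), st.floats(1e-8, 1.0), st.floats(1e-6, 1e-2))
@settings(max_examples=100, deadline=None)
def test_subsample_monotone_nonincreasing(f1, f2, t):
    lo, hi = sorted([f1, f2])
    assert subsample_keep_probability(lo, t) >= subsample_keep_probability(hi, t)


def test_subsample_invalid_frequency_errors():
    with pytest.raises(ValueError):
        subsample_keep_probability(0.0, 1e-4)


# -- pair objective ---------------------------------------------------------

def test_pair_gradients_match_central_differences():
    rng = np.random.default_rng(0)
    for _ in range(10):
        d, k = 8, 4
        w_in = rng.normal(size=d)
        w_out = rng.normal(size=d)
        w_neg = rng.normal(size=(k, d))
        g_in, g_out, g_neg = pair_gradients(w_in, w_out, w_neg)
        eps = 1e-6

        def num_grad(arr, set_arr):
            g = np.zeros_like(arr)
            flat = arr.reshape(-1)
            for i in range(flat.size):
                for sign in (+1, -1):
                    pert = arr.copy().reshape(-1)
                    pert[i] += sign * eps
                    g.reshape(-1)[i] += sign * set_arr(pert.reshape(arr.shape))
            return g / (2 * eps)

        gn_in = num_grad(w_in, lambda a: pair_loss(a, w_out, w_neg))
        gn_out = num_grad(w_out, lambda a: pair_loss(w_in, a, w_neg))
        gn_neg = num_grad(w_neg, lambda a: pair_loss(w_in, w_out, a))
        for ana, num in [(g_in, gn_in), (g_out, gn_out), (g_neg, gn_neg)]:
            denom = np.maximum(np.abs(num), 1e-8)
            assert np.max(np.abs(ana - num) / denom) < 1e-4


# -- training ---------------------------------------------------------------

def test_train_is_deterministic(planted_corpus):
    corpus, _ = planted_corpus
    small = Corpus(corpus.posts[:60])
    cfg = TrainingConfig(dimension=16, epochs=2, min_count=2, rng_seed=5)
    m1 = train(small, cfg)
    m2 = train(small, cfg)
    assert np.array_equal(m1.w_in, m2.w_in)
    assert np.array_equal(m1.w_out, m2.w_out)
    assert m1.epoch_mean_loss == m2.epoch_mean_loss


def test_train_loss_decreases(planted_model):
    losses = planted_model.epoch_mean_loss
    assert losses[-1] < losses[0]
    assert all(np.isfinite(losses))


def test_train_empty_vocab_errors():
    corpus = _corpus([["a", "b"]])
    with pytest.raises(ValueError, match="vocabulary"):
        train(corpus, TrainingConfig(min_count=10))


def test_planted_group_tighter_than_background(planted_model):
    model = planted_model
    members = [m for m in PLANTED_GROUPS["breathlessness"] if m in model.vocab]
    within = np.mean([cosine_similarity(model.vector(a), model.vector(b))
                      for a in members for b in members if a < b])
    rng = np.random.default_rng(3)
    bg = [t for t in model.vocab.tokens if t.startswith("word")]
    cross = np.mean([cosine_similarity(model.vector(members[0]),
                                       model.vector(w))
                     for w in rng.choice(bg, size=30, replace=False)])
    assert within > cross


# -- similarity queries -----------------------------------------------------

def test_cosine_similarity_identities():
    v = np.array([1.0, 2.0, -3.0])
    assert cosine_similarity(v, v) == pytest.approx(1.0)
    assert cosine_similarity(v, -v) == pytest.approx(-1.0)
    assert cosine_similarity(np.array([1.0, 0.0]),
                             np.array([0.0, 1.0])) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        cosine_similarity(v, np.zeros(3))


def _toy_model(vectors: dict[str, list[float]]):
    tokens = list(vectors)
    vocab = Vocabulary(tokens=tokens,
                       counts=np.full(len(tokens), 5, dtype=np.int64),
                       min_count=1)
    w = np.array([vectors[t] for t in tokens], dtype=np.float32)
    return EmbeddingModel(w_in=w, w_out=np.zeros_like(w), vocab=vocab,
                          config=TrainingConfig(dimension=w.shape[1]))


def test_nearest_neighbors_matches_bruteforce(planted_model):
    for query in ["breathlessness", "cough", "sputum"]:
        fast = nearest_neighbors(planted_model, query, 15)
        slow = nearest_bruteforce(planted_model, query, 15)
        assert [t for t, _ in fast] == [t for t, _ in slow]
        np.testing.assert_allclose([s for _, s in fast], [s for _, s in slow],
                                   atol=1e-12)


def test_nearest_neighbors_full_rank_is_permutation(planted_model):
    v = len(planted_model.vocab)
    out = nearest_neighbors(planted_model, "cough", v - 1)
    assert sorted(t for t, _ in out) == sorted(
        t for t in planted_model.vocab.tokens if t != "cough")


def test_nearest_neighbors_tie_break_by_vocab_index():
    model = _toy_model({"q": [1.0, 0.0], "a": [2.0, 0.0], "b": [3.0, 0.0],
                        "c": [0.0, 1.0]})
    out = nearest_neighbors(model, "q", 3)
    assert [t for t, _ in out] == ["a", "b", "c"]  # a before b: equal sims


def test_nearest_neighbors_oov_errors(planted_model):
    with pytest.raises(KeyError, match="definitely-not-a-token"):
        nearest_neighbors(planted_model, "definitely-not-a-token", 5)


def test_planted_synonyms_are_close_neighbors(planted_model):
    for name, members in PLANTED_GROUPS.items():
        got = [t for t, _ in nearest_neighbors(planted_model, members[0], 10)]
        assert set(got) & set(members[1:]), name


def test_neighbor_overlap_with_count_based_embedding():
    """Soft cross-check: an independent PPMI+SVD embedding largely agrees
    with SGNS on planted-synonym neighborhoods (Jaccard of top-10, averaged
    over groups).  Six-member groups so the planted signal, not the noise
    tail, dominates the neighbor lists of both routes."""
    from plm import SynonymGroup, SyntheticSpec, generate_corpus, train

    members = {
        "breath": ["breathlessness", "gasping", "wheezy", "puffed",
                   "winded", "huffing"],
        "mucus": ["sputum", "phlegm", "muck", "gunk", "slime", "gloop"],
        "tired": ["fatigue", "exhausted", "drained", "weary", "sleepy",
                  "sluggish"],
        "anx": ["anxiety", "panicky", "worried", "jittery", "uneasy",
                "nervy"],
    }
    spec = SyntheticSpec(
        n_posts=1200, post_length_mean=100, background_vocab_size=200,
        synonym_groups=[SynonymGroup(n, m, 0.4) for n, m in members.items()],
        rng_seed=21)
    corpus, _ = generate_corpus(spec)
    model = train(corpus, TrainingConfig(dimension=50, epochs=5, min_count=3,
                                         rng_seed=13))
    tokens, index, emb = ppmi_svd_embedding(corpus, window=5, dim=50,
                                            min_count=3)
    jaccards = []
    for group in members.values():
        q = group[0]
        a = {t for t, _ in nearest_neighbors(model, q, 10)}
        b = set(ppmi_neighbors(tokens, index, emb, q, 10))
        jaccards.append(len(a & b) / len(a | b))
    assert np.mean(jaccards) >= 0.3


# -- persistence ------------------------------------------------------------

def test_save_load_roundtrip_bit_exact(planted_model, tmp_path):
    path = tmp_path / "model.vec"
    save_model(planted_model, path)
    back = load_model(path)
    assert np.array_equal(back.w_in, planted_model.w_in)
    assert np.array_equal(back.w_out, planted_model.w_out)
    assert back.vocab.tokens == planted_model.vocab.tokens
    assert back.vocab.counts.tolist() == planted_model.vocab.counts.tolist()
    assert back.config == planted_model.config
    assert back.epoch_mean_loss == planted_model.epoch_mean_loss
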