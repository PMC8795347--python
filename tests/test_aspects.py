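"""Aspect-feature extractors against brute-force recounts and hand examples."""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pandas as pd
import pytest

import oracles
from mdhan.aspects import (
    FeatureNormalizer,
    antidepressant_count,
    assemble_features,
    emoji_vad_features,
    expand_symptom_lexicon,
    feature_matrix,
    fit_topic_model,
    social_features,
    symptom_counts,
    topic_features,
)
from mdhan.timeline_io import EmbeddingTable, Lexicons, Tweet, UserTimeline


def _tw(text="", hour=12, tokens=(), emojis=(), rt=False, minute=0):
    return Tweet(
        text=text,
        timestamp=datetime(2020, 3, 1, hour, minute),
        is_retweet=rt,
        tokens=tuple(tokens),
        emoji_list=tuple(emojis),
    )


def _lex(**over):
    base = dict(
        emoji_polarity={"😀": "positive", "☹": "negative", "😐": "neutral"},
        vad={"w": (0.5, 0.3, 0.2), "calm": (0.8, 0.1, 0.6)},
        fp_singular=frozenset({"i", "me"}),
        fp_plural=frozenset({"we"}),
        symptom_seeds={f"g{k}": [f"s{k}"] for k in range(9)},
        antidepressants=frozenset({"prozac", "st johns wort"}),
    )
    base.update(over)
    return Lexicons(**base)


# ---------------------------------------------------------------------------
# social
# ---------------------------------------------------------------------------


def test_social_histogram_example():
    u = UserTimeline("u", 1, [_tw(hour=13, minute=5), _tw(hour=13, minute=59), _tw(hour=2)])
    vec = social_features(u)
    hist = vec[6:]
    assert hist[13] == 2 and hist[2] == 1 and hist.sum() == 3
    assert vec[2] == 0  # no retweets


def test_social_matches_bruteforce():
    rng = np.random.default_rng(0)
    tweets = [
        _tw(text="x" * int(rng.integers(0, 50)), hour=int(rng.integers(0, 24)),
            rt=bool(rng.random() < 0.3))
        for _ in range(50)
    ]
    u = UserTimeline("u", 0, tweets, followers=12, friends=34, favourites=56)
    assert np.array_equal(social_features(u), oracles.recount_social(u))


# ---------------------------------------------------------------------------
# emoji / VAD / first person
# ---------------------------------------------------------------------------


def test_emoji_polarity_counts():
    u = UserTimeline("u", 1, [_tw(emojis=["😀", "😀", "☹"])])
    vec = emoji_vad_features(u, _lex())
    assert tuple(vec[:3]) == (2, 0, 1)


def test_vad_single_word():
    u = UserTimeline("u", 1, [_tw(tokens=["w"])])
    assert emoji_vad_features(u, _lex())[3:6] == pytest.approx([0.5, 0.3, 0.2])


def test_first_person_counts():
    u = UserTimeline("u", 1, [_tw(tokens=["i", "we", "me"])])
    vec = emoji_vad_features(u, _lex())
    assert tuple(vec[6:]) == (2, 1)


def test_unknown_emoji_counted_neutral():
    u = UserTimeline("u", 1, [_tw(emojis=["🛸"])])
    assert tuple(emoji_vad_features(u, _lex())[:3]) == (0, 1, 0)


# ---------------------------------------------------------------------------
# topics
# ---------------------------------------------------------------------------


def test_topic_model_normalized_and_deterministic():
    rng = np.random.default_rng(1)
    corpus = [[f"w{int(rng.integers(0, 20))}" for _ in range(8)] for _ in range(30)]
    m1 = fit_topic_model(corpus, K=4, seed=3)
    m2 = fit_topic_model(corpus, K=4, seed=3)
    assert np.allclose(m1.word_topic_weights.sum(axis=0), 1.0, atol=1e-8)
    assert np.array_equal(m1.word_topic_weights, m2.word_topic_weights)


def test_topic_separation_two_disjoint_documents():
    docs = [["apple", "pear", "plum"] * 10, ["iron", "zinc", "lead"] * 10]
    model = fit_topic_model(docs, K=2, seed=0, max_iter=30)
    u1 = UserTimeline("a", 1, [_tw(tokens=["apple", "pear", "plum"] * 5)])
    u2 = UserTimeline("b", 1, [_tw(tokens=["iron", "zinc", "lead"] * 5)])
    t1, t2 = topic_features(u1, model), topic_features(u2, model)
    assert t1.max() > 0.5 and t2.max() > 0.5
    assert np.argmax(t1) != np.argmax(t2)


def test_topic_fallback_uniform_and_simplex():
    docs = [["apple", "pear"] * 5]
    model = fit_topic_model(docs, K=5, seed=0)
    u = UserTimeline("u", 0, [_tw(tokens=["unseen"])])
    assert np.allclose(topic_features(u, model), 0.2)
    u2 = UserTimeline("u2", 0, [_tw(tokens=["apple", "pear", "apple"])])
    assert topic_features(u2, model).sum() == pytest.approx(1.0, abs=1e-8)


def test_empty_corpus_fatal():
    with pytest.raises(ValueError):
        fit_topic_model([], K=2, seed=0)


# ---------------------------------------------------------------------------
# symptom lexicon expansion
# ---------------------------------------------------------------------------


def _toy_embeddings():
    vecs = {
        "sad": np.array([1.0, 0.0, 0.0]),
        "gloomy": np.array([0.9, 0.1, 0.0]),  # cos(sad, gloomy) ≈ 0.994
        "happy": np.array([0.0, 1.0, 0.0]),  # orthogonal to sad
        "tired": np.array([0.0, 0.0, 1.0]),
        "weary": np.array([0.1, 0.0, 0.9]),  # close to tired
        "blue": np.array([0.8, 0.0, 0.6]),  # cos with sad 0.8, with tired 0.6
    }
    return EmbeddingTable(dim=3, vectors=vecs)


def test_expansion_matches_bruteforce_ranking():
    seeds = {"mood": ["sad"], "energy": ["tired"]}
    emb = _toy_embeddings()
    out = expand_symptom_lexicon(seeds, emb, top_k=10, min_cosine=0.6)
    # brute force: cosines to sad: gloomy .994, blue .8, weary .110, happy 0
    #              cosines to tired: weary .994, blue .6, gloomy 0, happy 0
    assert out["mood"] == ["blue", "gloomy", "sad"]
    assert out["energy"] == ["tired", "weary"]


def test_expansion_identical_vector_included_orthogonal_excluded():
    emb = EmbeddingTable(dim=2, vectors={
        "seed": np.array([1.0, 0.0]),
        "clone": np.array([2.0, 0.0]),  # cosine exactly 1
        "ortho": np.array([0.0, 1.0]),  # cosine 0
    })
    out = expand_symptom_lexicon({"g": ["seed"]}, emb, min_cosine=0.6)
    assert "clone" in out["g"] and "ortho" not in out["g"]


def test_expansion_missing_seed_kept_literal():
    emb = EmbeddingTable(dim=2, vectors={"other": np.ones(2)})
    out = expand_symptom_lexicon({"g": ["notinvocab"]}, emb)
    assert out["g"] == ["notinvocab"]


# ---------------------------------------------------------------------------
# symptom / antidepressant counts
# ---------------------------------------------------------------------------


def test_symptom_count_multiplicity_and_zero():
    expanded = {f"g{k}": [f"s{k}"] for k in range(9)}
    expanded["g3"] = ["sleep"]
    u = UserTimeline("u", 1, [_tw(tokens=["sleep", "sleep"])])
    counts = symptom_counts(u, expanded)
    assert counts[3] == 2 and counts.sum() == 2
    u2 = UserTimeline("u", 1, [_tw(tokens=["nothing", "here"])])
    assert symptom_counts(u2, expanded).sum() == 0


def test_antidepressant_count_with_ngram():
    lex = _lex()
    u = UserTimeline("u", 1, [
        _tw(tokens=["prozac", "st", "johns", "wort", "prozac"]),
        _tw(tokens=["st", "johns"]),  # incomplete n-gram: no match
    ])
    assert antidepressant_count(u, lex) == 3


def test_counts_match_bruteforce_on_random_timelines():
    rng = np.random.default_rng(7)
    vocab = ["a", "b", "s0", "s1", "prozac", "st", "johns", "wort"]
    expanded = {f"g{k}": [f"s{k}"] for k in range(9)}
    lex = _lex()
    for _ in range(30):
        tweets = [
            _tw(tokens=[vocab[int(j)] for j in rng.integers(0, len(vocab), rng.integers(0, 8))])
            for _ in range(int(rng.integers(1, 10)))
        ]
        u = UserTimeline("u", 1, tweets)
        assert np.array_equal(symptom_counts(u, expanded), oracles.recount_symptoms(u, expanded))
        assert antidepressant_count(u, lex) == oracles.recount_antidepressants(u, lex)


# ---------------------------------------------------------------------------
# assembly / masking / normalization
# ---------------------------------------------------------------------------


def test_assembled_lengths(sim_small):
    data = sim_small
    expanded = expand_symptom_lexicon(data.lexicons.symptom_seeds, data.embeddings)
    corpus = [list(t.tokens) for u in data.users[:20] for t in u.tweets if t.tokens]
    tm = fit_topic_model(corpus, K=25, seed=0, max_iter=5)
    full = assemble_features(data.users[0], data.lexicons, tm, expanded)
    assert full.shape == (73,)  # 30 + 8 + 25 + 10
    no_topic = assemble_features(
        data.users[0], data.lexicons, tm, expanded, mask=("social", "emo", "domain")
    )
    assert no_topic.shape == (48,)
    # masked assembly is the exact subvector of the full assembly
    assert np.array_equal(no_topic, np.concatenate([full[:38], full[63:]]))
    with pytest.raises(ValueError):
        assemble_features(data.users[0], data.lexicons, tm, expanded, mask=())


def test_normalizer_zscores_non_simplex_columns(sim_small):
    data = sim_small
    expanded = expand_symptom_lexicon(data.lexicons.symptom_seeds, data.embeddings)
    corpus = [list(t.tokens) for u in data.users[:20] for t in u.tweets if t.tokens]
    tm = fit_topic_model(corpus, K=5, seed=0, max_iter=5)
    feats = feature_matrix(data.users, data.lexicons, tm, expanded)
    z = FeatureNormalizer().fit_transform(feats)
    non_topic = [c for c in z.columns if not c.startswith("topic:")]
    means = z[non_topic].mean().to_numpy()
    sds = z[non_topic].std(ddof=0).to_numpy()
    assert np.allclose(means, 0.0, atol=1e-6)
    # constant columns keep sd 0; all others must be 1
    assert np.all((np.abs(sds - 1) < 1e-6) | (sds < 1e-12))
    # topic columns untouched
    topics = [c for c in z.columns if c.startswith("topic:")]
    assert np.array_equal(z[topics].to_numpy(), feats[topics].to_numpy())


def test_extraction_deterministic(sim_small):
    data = sim_small
    expanded = expand_symptom_lexicon(data.lexicons.symptom_seeds, data.embeddings)
    u = data.users[3]
    a = emoji_vad_features(u, data.lexicons)
    b = emoji_vad_features(u, data.lexicons)
    assert np.array_equal(a, b)
    assert np.array_equal(symptom_counts(u, expanded), symptom_counts(u, expanded))


def test_hour_histogram_sums_to_timeline_length(sim_small):
    for u in sim_small.users[:20]:
        assert social_features(u)[6:].sum() == len(u.tweets)
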