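"""Network forward/backward correctness: finite-difference gradients, an
independent scalar forward-pass oracle, attention simplexes, masking and
training behaviour."""

from __future__ import annotations

import numpy as np
import pytest

import oracles
from mdhan import _nn
from mdhan.model import MDHAN, ModelConfig, loss, pad_batch, user_token_matrices
from mdhan.train_eval import Dataset, train


def _random_batch(rng, n_users=3, embed_dim=5):
    mats = [
        [rng.normal(size=(int(rng.integers(0, 5)), embed_dim))
         for _ in range(int(rng.integers(1, 4)))]
        for _ in range(n_users)
    ]
    return pad_batch(mats, dim=embed_dim)


# ---------------------------------------------------------------------------
# Gradients
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "variant,maxpool",
    [("MDHAN", None), ("HAN", None), ("MM", None), ("HAN", 2)],
)
def test_gradients_match_finite_differences(variant, maxpool):
    rng = np.random.default_rng(0)
    cfg = ModelConfig(
        embed_dim=5, hidden_dim=3, mlp_hidden=4, attn_dim=4, dropout=0.0,
        variant=variant, tweet_maxpool=maxpool, seed=3,
    )
    model = MDHAN(cfg, aspect_dim=6 if cfg.uses_aspects else None)
    X, wm, tm = _random_batch(rng)
    if not cfg.uses_text:
        X = wm = tm = None
    m = rng.normal(size=(3, 6)) if cfg.uses_aspects else None
    y = np.array([1.0, 0.0, 1.0])

    def loss_fn():
        y_hat, cache = model.forward(X, wm, tm, m, train=False)
        l, dlogit = _nn.bce_loss(y_hat, y)
        return l, dlogit, cache

    _, dlogit, cache = loss_fn()
    grads = model.backward(dlogit, cache)
    eps = 1e-6
    for name, arr in model.params.items():
        for _ in range(min(4, arr.size)):
            ix = tuple(rng.integers(0, s) for s in arr.shape)
            orig = arr[ix]
            arr[ix] = orig + eps
            lp, _, _ = loss_fn()
            arr[ix] = orig - eps
            lm, _, _ = loss_fn()
            arr[ix] = orig
            numeric = (lp - lm) / (2 * eps)
            assert grads[name][ix] == pytest.approx(numeric, abs=1e-7, rel=1e-4), name


# ---------------------------------------------------------------------------
# Forward-pass oracle
# ---------------------------------------------------------------------------


def test_forward_matches_naive_oracle():
    """2 users × 3 tweets × ≤4 words, d=2: vectorized forward equals a
    step-by-step scalar re-implementation."""
    rng = np.random.default_rng(42)
    cfg = ModelConfig(
        embed_dim=3, hidden_dim=2, mlp_hidden=3, attn_dim=3, dropout=0.0,
        variant="MDHAN", seed=9,
    )
    model = MDHAN(cfg, aspect_dim=4)
    users = [
        [rng.normal(size=(n, 3)) for n in (4, 2, 3)],
        [rng.normal(size=(n, 3)) for n in (1, 4, 2)],
    ]
    m = rng.normal(size=(2, 4))
    X, wm, tm = pad_batch(users)
    y_hat, cache = model.forward(X, wm, tm, m, train=False)
    for b in range(2):
        expected, alpha_t = oracles.naive_forward(model.params, cfg, users[b], m[b])
        assert y_hat[b] == pytest.approx(expected, abs=1e-5)
        assert cache["alpha_t"][b, : len(alpha_t)] == pytest.approx(alpha_t, abs=1e-5)


def test_word_attention_uniform_when_scores_equal():
    # zero context vector -> all scores equal -> uniform over real words
    rng = np.random.default_rng(0)
    params = _nn.attention_init(rng, 4, 3)
    params["u"] = np.zeros(3)
    h = rng.normal(size=(1, 5, 4))
    mask = np.array([[1.0, 1.0, 1.0, 1.0, 0.0]])
    _, alpha, _ = _nn.attention_forward(params, h, mask)
    assert alpha[0, :4] == pytest.approx([0.25] * 4)
    assert alpha[0, 4] == 0.0


def test_attention_onehot_endpoint():
    # one dominating score -> pooled vector equals that position's state
    rng = np.random.default_rng(1)
    params = _nn.attention_init(rng, 3, 3)
    h = rng.normal(size=(1, 4, 3))
    mask = np.ones((1, 4))
    pooled, alpha, cache = _nn.attention_forward(params, h, mask)
    # force one-hot by replaying with an extreme context vector
    u = np.tanh(h @ params["W"] + params["b"])
    scores = u @ params["u"]
    j = int(np.argmax(scores[0]))
    params["u"] = params["u"] * 1e4
    pooled2, alpha2, _ = _nn.attention_forward(params, h, mask)
    assert alpha2[0, j] == pytest.approx(1.0, abs=1e-6)
    assert pooled2[0] == pytest.approx(h[0, j], abs=1e-5)


def test_singleton_tweet_attention():
    rng = np.random.default_rng(2)
    cfg = ModelConfig(embed_dim=4, hidden_dim=3, dropout=0.0, variant="HAN", seed=0)
    model = MDHAN(cfg)
    mats = [[rng.normal(size=(3, 4))]]  # L = 1
    X, wm, tm = pad_batch(mats)
    _, cache = model.forward(X, wm, tm, None)
    assert cache["alpha_t"][0, 0] == pytest.approx(1.0)
    # s equals the single tweet's hidden state
    assert cache["s"][0] == pytest.approx(
        model.forward(X, wm, tm, None)[1]["c_tattn"]["h"][0, 0], abs=1e-12
    )


# ---------------------------------------------------------------------------
# Fusion / loss arithmetic
# ---------------------------------------------------------------------------


def test_fusion_zero_weights_give_half():
    cfg = ModelConfig(embed_dim=4, hidden_dim=2, mlp_hidden=2, dropout=0.0,
                      variant="MM", seed=0)
    model = MDHAN(cfg, aspect_dim=3)
    model.params["out.W"][:] = 0.0
    model.params["out.b"][:] = 0.0
    y_hat, _ = model.forward(None, None, None, np.ones((2, 3)))
    assert y_hat == pytest.approx([0.5, 0.5])
    model.params["out.b"][:] = 50.0  # saturation
    y_hat, _ = model.forward(None, None, None, np.ones((2, 3)))
    assert y_hat == pytest.approx([1.0, 1.0], abs=1e-9)


def test_aspect_encoder_arithmetic():
    cfg = ModelConfig(embed_dim=4, hidden_dim=2, mlp_hidden=2, dropout=0.0,
                      variant="MM", seed=0)
    model = MDHAN(cfg, aspect_dim=2)
    model.params["mlp.W"][:] = 0.0
    model.params["mlp.b"][:] = 0.0
    _, cache = model.forward(None, None, None, np.array([[3.0, -1.0]]))
    assert np.all(cache["p"] == 0.0)  # W=0, b=0, ReLU -> 0
    model.params["mlp.W"][:] = np.eye(2)
    _, cache = model.forward(None, None, None, np.array([[3.0, 2.0]]))
    assert cache["p"][0] == pytest.approx([3.0, 2.0])  # ReLU transparent
    rng = np.random.default_rng(5)
    W = rng.normal(size=(2, 2))
    b = rng.normal(size=2)
    model.params["mlp.W"][:] = W
    model.params["mlp.b"][:] = b
    m = rng.normal(size=(1, 2))
    _, cache = model.forward(None, None, None, m)
    assert cache["p"][0] == pytest.approx(np.maximum(m[0] @ W + b, 0.0))


def test_loss_closed_forms():
    assert loss(np.array([1.0]), np.array([1.0])) == pytest.approx(0.0, abs=1e-6)
    assert loss(np.array([0.5]), np.array([0.0])) == pytest.approx(np.log(2))
    assert loss(np.array([0.5]), np.array([1.0])) == pytest.approx(np.log(2))
    y_hat = np.array([0.9, 0.2, 0.6, 0.4])
    y = np.array([1.0, 0.0, 0.0, 1.0])
    by_hand = -np.mean([np.log(0.9), np.log(0.8), np.log(0.4), np.log(0.4)])
    assert loss(y_hat, y) == pytest.approx(by_hand)


def test_dimension_mismatch_reports_both_dims():
    cfg = ModelConfig(embed_dim=4, hidden_dim=2, dropout=0.0, variant="MM", seed=0)
    model = MDHAN(cfg, aspect_dim=5)
    with pytest.raises(ValueError, match="3.*5|5.*3"):
        model.forward(None, None, None, np.ones((1, 3)))


# ---------------------------------------------------------------------------
# Attention simplexes and padding invariance on random inputs
# ---------------------------------------------------------------------------


def test_attention_rows_are_simplexes_and_padding_is_inert():
    rng = np.random.default_rng(3)
    cfg = ModelConfig(embed_dim=4, hidden_dim=3, dropout=0.0, variant="HAN", seed=1)
    model = MDHAN(cfg)
    for _ in range(20):
        X, wm, tm = _random_batch(rng, n_users=2, embed_dim=4)
        y_hat, cache = model.forward(X, wm, tm, None)
        aw, at = cache["alpha_w"], cache["alpha_t"]
        assert np.all(aw >= 0) and np.all(at >= 0)
        word_sums = aw.sum(axis=2)
        has_words = wm.sum(axis=2) > 0
        assert np.allclose(word_sums[has_words], 1.0, atol=1e-6)
        assert np.allclose(word_sums[~has_words], 0.0)
        assert np.allclose(at.sum(axis=1), 1.0, atol=1e-6)
        # append padding tweets and words: prediction must not move
        B, L, N, d = X.shape
        X2 = np.zeros((B, L + 2, N + 3, d))
        X2[:, :L, :N] = X
        wm2 = np.zeros((B, L + 2, N + 3))
        wm2[:, :L, :N] = wm
        tm2 = np.zeros((B, L + 2))
        tm2[:, :L] = tm
        y_hat2, _ = model.forward(X2, wm2, tm2, None)
        assert np.max(np.abs(y_hat - y_hat2)) < 1e-5


# ---------------------------------------------------------------------------
# Training behaviour
# ---------------------------------------------------------------------------


def _separated_dataset(rng, n=32, embed_dim=8):
    """Labels determined by which half of the embedding space tweets use."""
    mats, ys = [], []
    for i in range(n):
        y = i % 2
        centre = np.zeros(embed_dim)
        centre[: embed_dim // 2] = 2.0 * (1 if y else -1)
        user = [
            centre + 0.3 * rng.normal(size=(int(rng.integers(2, 6)), embed_dim))
            for _ in range(int(rng.integers(2, 5)))
        ]
        mats.append(user)
        ys.append(float(y))
    return Dataset(ids=[f"u{i}" for i in range(n)], y=np.array(ys),
                   tweet_mats=mats, m=None)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_one_epoch_decreases_loss_on_separated_batch(seed):
    rng = np.random.default_rng(100 + seed)
    data = _separated_dataset(rng)
    cfg = ModelConfig(embed_dim=8, hidden_dim=6, dropout=0.0, variant="HAN", seed=seed)
    model = MDHAN(cfg)
    before = loss(model.predict_proba(data.tweet_mats, None), data.y)
    train(model, data, epochs=1, batch_size=16, lr=0.01, seed=seed)
    after = loss(model.predict_proba(data.tweet_mats, None), data.y)
    assert after < before


def test_training_deterministic_given_seed():
    rng = np.random.default_rng(10)
    data = _separated_dataset(rng, n=16)
    histories = []
    for _ in range(2):
        cfg = ModelConfig(embed_dim=8, hidden_dim=4, dropout=0.3, variant="HAN", seed=7)
        model = MDHAN(cfg)
        histories.append(train(model, data, epochs=2, batch_size=8, lr=0.01, seed=7))
    assert histories[0][-1] == pytest.approx(histories[1][-1], abs=1e-6)


def test_zero_epochs_returns_empty_history():
    rng = np.random.default_rng(11)
    data = _separated_dataset(rng, n=8)
    cfg = ModelConfig(embed_dim=8, hidden_dim=4, variant="HAN", seed=0)
    model = MDHAN(cfg)
    assert train(model, data, epochs=0) == []


def test_embeddings_frozen_during_training(sim_small):
    data = sim_small
    emb = data.embeddings
    before = {w: v.copy() for w, v in emb.vectors.items()}
    cfg = ModelConfig(embed_dim=emb.dim, hidden_dim=4, max_tweets=10, max_words=10,
                      variant="HAN", seed=0)
    model = MDHAN(cfg)
    users = data.users[:12]
    ds = Dataset(
        ids=[u.user_id for u in users],
        y=np.array([float(u.label) for u in users]),
        tweet_mats=[user_token_matrices(u, emb, cfg) for u in users],
        m=None,
    )
    train(model, ds, epochs=1, batch_size=4)
    for w, v in emb.vectors.items():
        assert np.array_equal(before[w], v)


def test_checkpoint_roundtrip(tmp_path):
    rng = np.random.default_rng(12)
    cfg = ModelConfig(embed_dim=6, hidden_dim=4, mlp_hidden=5, dropout=0.2,
                      variant="MDHAN", seed=3)
    model = MDHAN(cfg, aspect_dim=7)
    X, wm, tm = _random_batch(rng, n_users=2, embed_dim=6)
    m = rng.normal(size=(2, 7))
    y1, _ = model.forward(X, wm, tm, m)
    path = tmp_path / "model.ckpt.npz"
    model.save(path)
    loaded = MDHAN.load(path)
    assert loaded.config == cfg
    y2, _ = loaded.forward(X, wm, tm, m)
    assert np.array_equal(y1, y2)
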