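"""The depression classifier: hierarchical attention over tweets fused
with an MLP over multi-aspect behavioural features.

Architecture, per user:

* every tweet's word embeddings run through a bidirectional GRU; a tanh
  attention layer pools the per-word states into a tweet vector
  ``v_i = sum_j alpha_ij h^w_ij``;
* the sequence of tweet vectors runs through a second bidirectional GRU;
  tweet-level attention pools the states into one user vector
  ``s = sum_i alpha_i h^t_i``;
* the assembled aspect vector ``m`` passes through a one-layer MLP,
  ``p = relu(W m + b)``;
* the fused vector ``[p, s]`` feeds a sigmoid unit,
  ``y_hat = sigmoid(b_f + [p, s] W_f)``, trained with binary cross-entropy.

Variants gate the two branches: ``HAN`` uses the text branch alone, ``MM``
the aspect branch alone.  The attention weights are retained — they are
the model's explanation signal.

Everything is plain NumPy with hand-derived backward passes (see
``_nn.py``); word embeddings are frozen inputs, never trained.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import _nn
from .aspects import BLOCK_ORDER
from .timeline_io import EmbeddingTable, UserTimeline

VARIANTS = ("MDHAN", "HAN", "MM")
_VARIANT_ALIASES = {"HAN-ONLY": "HAN", "MM-ONLY": "MM"}


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier.

    ``hidden_dim`` is the size of one GRU direction (states are 2× that
    after concatenation); ``max_tweets``/``max_words`` truncate timelines
    (keeping the most recent tweets and the first words of each tweet).
    ``tweet_maxpool`` optionally max-pools runs of that many consecutive
    tweet hidden states before tweet attention (off by default).
    """

    embed_dim: int = 100
    hidden_dim: int = 100
    mlp_hidden: int = 100
    attn_dim: int | None = None  # default: 2 * hidden_dim
    dropout: float = 0.5
    max_tweets: int = 200
    max_words: int = 50
    variant: str = "MDHAN"
    aspect_mask: tuple[str, ...] = BLOCK_ORDER
    tweet_maxpool: int | None = None
    embeddings_frozen: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.variant = _VARIANT_ALIASES.get(self.variant.upper(), self.variant.upper())
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        for name in ("embed_dim", "hidden_dim", "mlp_hidden", "max_tweets", "max_words"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.attn_dim is None:
            self.attn_dim = 2 * self.hidden_dim

    @property
    def uses_text(self) -> bool:
        return self.variant in ("MDHAN", "HAN")

    @property
    def uses_aspects(self) -> bool:
        return self.variant in ("MDHAN", "MM")


@dataclass
class EncodedUser:
    """All intermediate quantities of one user's forward pass."""

    user_id: str
    tweet_vectors: np.ndarray | None  # (L, 2d)
    word_attn: list[np.ndarray] | None  # per real tweet, weights over its words
    tweet_attn: np.ndarray | None  # (L,)
    user_vector: np.ndarray | None  # (2d,)
    aspect_vector: np.ndarray | None  # (mlp_hidden,)
    score: float  # predicted probability of depression


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------


def user_token_matrices(
    user: UserTimeline, emb: EmbeddingTable, config: ModelConfig
) -> list[np.ndarray]:
    """Per-tweet embedding matrices after truncation.

    Keeps the ``max_tweets`` most recent tweets and the first ``max_words``
    tokens of each; a tweet emptied by cleaning yields a (0, d) matrix.
    """
    tweets = user.tweets[-config.max_tweets :]
    out = []
    for t in tweets:
        toks = t.tokens[: config.max_words]
        out.append(emb.matrix(list(toks)).astype(float))
    return out


def pad_batch(
    tweet_mats: Sequence[list[np.ndarray]], dim: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad a batch of per-user tweet matrices into dense tensors.

    Returns ``X`` (B, L, N, d), word mask (B, L, N) and tweet mask (B, L).
    Real-but-empty tweets have a tweet-mask of 1 and an all-zero word mask.
    ``dim`` overrides the embedding dimension (needed when every tweet in
    the batch is empty).
    """
    B = len(tweet_mats)
    L = max(1, max(len(u) for u in tweet_mats))
    N = max(1, max((m.shape[0] for u in tweet_mats for m in u), default=1))
    d = dim if dim is not None else next(
        (m.shape[1] for u in tweet_mats for m in u if m.size), 1
    )
    X = np.zeros((B, L, N, d))
    wmask = np.zeros((B, L, N))
    tmask = np.zeros((B, L))
    for b, mats in enumerate(tweet_mats):
        for i, m in enumerate(mats):
            tmask[b, i] = 1.0
            n = m.shape[0]
            if n:
                X[b, i, :n] = m
                wmask[b, i, :n] = 1.0
    return X, wmask, tmask


# ---------------------------------------------------------------------------
# Max-pool over tweet states (optional)
# ---------------------------------------------------------------------------


def _maxpool_forward(h: np.ndarray, mask: np.ndarray, k: int):
    B, L, D = h.shape
    Lp = -(-L // k)
    pad = Lp * k - L
    hp = np.concatenate([h, np.full((B, pad, D), -np.inf)], axis=1) if pad else h
    mp = np.concatenate([mask, np.zeros((B, pad))], axis=1) if pad else mask
    hp = np.where(mp[:, :, None] > 0, hp, -np.inf)
    hg = hp.reshape(B, Lp, k, D)
    arg = np.argmax(hg, axis=2)  # (B, Lp, D)
    out = np.take_along_axis(hg, arg[:, :, None, :], axis=2)[:, :, 0, :]
    gmask = (mp.reshape(B, Lp, k).sum(axis=2) > 0).astype(float)
    out = np.where(gmask[:, :, None] > 0, out, 0.0)
    return out, gmask, {"arg": arg, "shape": (B, L, D), "k": k, "gmask": gmask}


def _maxpool_backward(dout: np.ndarray, cache: dict) -> np.ndarray:
    B, L, D = cache["shape"]
    k, arg = cache["k"], cache["arg"]
    Lp = arg.shape[1]
    dh = np.zeros((B, Lp, k, D))
    dout = dout * cache["gmask"][:, :, None]
    np.put_along_axis(dh, arg[:, :, None, :], dout[:, :, None, :], axis=2)
    return dh.reshape(B, Lp * k, D)[:, :L]


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


def _sub(params: Mapping[str, np.ndarray], prefix: str) -> dict[str, np.ndarray]:
    pre = prefix + "."
    return {k[len(pre) :]: v for k, v in params.items() if k.startswith(pre)}


class MDHAN:
    """Multi-aspect depression detection with hierarchical attention.

    Parameters live in one flat dict of named arrays (``wf.Wxr`` etc.) so
    the optimizer and checkpointing stay trivial.  ``aspect_dim`` is the
    length M of the assembled aspect vector (``None`` for the text-only
    variant).
    """

    def __init__(self, config: ModelConfig, aspect_dim: int | None = None):
        self.config = config
        self.aspect_dim = aspect_dim
        if config.uses_aspects and not aspect_dim:
            raise ValueError("variant needs aspect features but aspect_dim is unset")
        rng = np.random.default_rng(config.seed)
        d, a = config.hidden_dim, config.attn_dim
        p: dict[str, np.ndarray] = {}
        if config.uses_text:
            for pre, d_in in (("wf", config.embed_dim), ("wb", config.embed_dim),
                              ("tf", 2 * d), ("tb", 2 * d)):
                for k, v in _nn.gru_init(rng, d_in, d).items():
                    p[f"{pre}.{k}"] = v
            for pre in ("wa", "ta"):
                for k, v in _nn.attention_init(rng, 2 * d, a).items():
                    p[f"{pre}.{k}"] = v
        if config.uses_aspects:
            for k, v in _nn.dense_init(rng, aspect_dim, config.mlp_hidden).items():
                p[f"mlp.{k}"] = v
        fused = (config.mlp_hidden if config.uses_aspects else 0) + (
            2 * d if config.uses_text else 0
        )
        for k, v in _nn.dense_init(rng, fused, 1).items():
            p[f"out.{k}"] = v
        self.params = p
        self._dropout_rng = np.random.default_rng(config.seed + 1)

    # -- forward ----------------------------------------------------------

    def forward(
        self,
        X: np.ndarray | None,
        wmask: np.ndarray | None,
        tmask: np.ndarray | None,
        m_feats: np.ndarray | None,
        train: bool = False,
    ) -> tuple[np.ndarray, dict]:
        """Batch forward pass; returns probabilities (B,) and a cache."""
        cfg = self.config
        cache: dict = {}
        parts = []
        rng = self._dropout_rng if train else None

        if cfg.uses_aspects:
            if m_feats is None:
                raise ValueError("aspect features required for this variant")
            if m_feats.shape[1] != self.aspect_dim:
                raise ValueError(
                    f"aspect dimension mismatch: got {m_feats.shape[1]}, "
                    f"model expects {self.aspect_dim}"
                )
            z, c_mlp = _nn.dense_forward(_sub(self.params, "mlp"), m_feats)
            ph, c_relu = _nn.relu_forward(z)
            pdrop, m_do = _nn.dropout_forward(ph, cfg.dropout, rng, train)
            cache.update(c_mlp=c_mlp, c_relu=c_relu, m_do=m_do)
            cache["p"] = ph
            parts.append(pdrop)

        if cfg.uses_text:
            if X is None:
                raise ValueError("tweet tensors required for this variant")
            B, L, N, de = X.shape
            Xw = X.reshape(B * L, N, de)
            wm = wmask.reshape(B * L, N)
            Hw, c_wgru = _nn.bigru_forward(
                _sub(self.params, "wf"), _sub(self.params, "wb"), Xw, wm
            )
            v, alpha_w, c_wattn = _nn.attention_forward(_sub(self.params, "wa"), Hw, wm)
            vdrop, v_do = _nn.dropout_forward(v, cfg.dropout, rng, train)
            V = vdrop.reshape(B, L, -1)
            Ht, c_tgru = _nn.bigru_forward(
                _sub(self.params, "tf"), _sub(self.params, "tb"), V, tmask
            )
            amask = tmask
            if cfg.tweet_maxpool:
                Ht, amask, c_pool = _maxpool_forward(Ht, tmask, cfg.tweet_maxpool)
                cache["c_pool"] = c_pool
            s, alpha_t, c_tattn = _nn.attention_forward(_sub(self.params, "ta"), Ht, amask)
            sdrop, s_do = _nn.dropout_forward(s, cfg.dropout, rng, train)
            cache.update(
                c_wgru=c_wgru, c_wattn=c_wattn, v_do=v_do, c_tgru=c_tgru,
                c_tattn=c_tattn, s_do=s_do, batch_shape=(B, L, N),
                alpha_w=alpha_w.reshape(B, L, N), alpha_t=alpha_t,
                v=v.reshape(B, L, -1), s=s,
            )
            parts.append(sdrop)

        fused = np.concatenate(parts, axis=1)
        logit, c_out = _nn.dense_forward(_sub(self.params, "out"), fused)
        cache["c_out"] = c_out
        y_hat = _nn.sigmoid(logit[:, 0])
        return y_hat, cache

    # -- backward ---------------------------------------------------------

    def backward(self, dlogit: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Gradients for every parameter given dLoss/dlogit (B,)."""
        cfg = self.config
        grads: dict[str, np.ndarray] = {}
        g_out, dfused = _nn.dense_backward(dlogit[:, None], cache["c_out"])
        for k, v in g_out.items():
            grads[f"out.{k}"] = v

        offset = 0
        if cfg.uses_aspects:
            P = cfg.mlp_hidden
            dp = dfused[:, :P]
            offset = P
            dp = _nn.dropout_backward(dp, cache["m_do"])
            dz = _nn.relu_backward(dp, cache["c_relu"])
            g_mlp, _ = _nn.dense_backward(dz, cache["c_mlp"])
            for k, v in g_mlp.items():
                grads[f"mlp.{k}"] = v

        if cfg.uses_text:
            ds = dfused[:, offset:]
            ds = _nn.dropout_backward(ds, cache["s_do"])
            g_ta, dHt = _nn.attention_backward(ds, cache["c_tattn"])
            for k, v in g_ta.items():
                grads[f"ta.{k}"] = v
            if cfg.tweet_maxpool:
                dHt = _maxpool_backward(dHt, cache["c_pool"])
            g_tf, g_tb, dV = _nn.bigru_backward(dHt, cache["c_tgru"], need_dx=True)
            for pre, g in (("tf", g_tf), ("tb", g_tb)):
                for k, v in g.items():
                    grads[f"{pre}.{k}"] = v
            B, L, N = cache["batch_shape"]
            dv = dV.reshape(B * L, -1)
            dv = _nn.dropout_backward(dv, cache["v_do"])
            g_wa, dHw = _nn.attention_backward(dv, cache["c_wattn"])
            for k, v in g_wa.items():
                grads[f"wa.{k}"] = v
            g_wf, g_wb, _ = _nn.bigru_backward(dHw, cache["c_wgru"], need_dx=False)
            for pre, g in (("wf", g_wf), ("wb", g_wb)):
                for k, v in g.items():
                    grads[f"{pre}.{k}"] = v
        return grads

    # -- convenience ------------------------------------------------------

    def predict_proba(
        self,
        tweet_mats: Sequence[list[np.ndarray]] | None,
        m_feats: np.ndarray | None,
        batch_size: int = 64,
    ) -> np.ndarray:
        """Probabilities for a list of users (inference mode, no dropout)."""
        n = len(tweet_mats) if tweet_mats is not None else m_feats.shape[0]
        out = np.zeros(n)
        for lo in range(0, n, batch_size):
            hi = min(n, lo + batch_size)
            X = wm = tm = None
            if self.config.uses_text:
                X, wm, tm = pad_batch(tweet_mats[lo:hi], dim=self.config.embed_dim)
            mf = m_feats[lo:hi] if self.config.uses_aspects else None
            out[lo:hi], _ = self.forward(X, wm, tm, mf, train=False)
        return out

    def encode_user(
        self,
        user: UserTimeline,
        emb: EmbeddingTable | None,
        m_feat: np.ndarray | None,
    ) -> EncodedUser:
        """Forward one user and keep every attention weight (for explanation)."""
        cfg = self.config
        X = wm = tm = None
        if cfg.uses_text:
            mats = user_token_matrices(user, emb, cfg)
            if not mats:
                raise ValueError(f"user {user.user_id!r} has no tweets to encode")
            X, wm, tm = pad_batch([mats], dim=cfg.embed_dim)
        mf = m_feat[None, :] if cfg.uses_aspects else None
        y_hat, cache = self.forward(X, wm, tm, mf, train=False)
        if not cfg.uses_text:
            return EncodedUser(user.user_id, None, None, None, None,
                               cache["p"][0] if cfg.uses_aspects else None, float(y_hat[0]))
        L = len(user.tweets[-cfg.max_tweets :])
        word_attn = []
        for i in range(L):
            n_real = int(wm[0, i].sum())
            word_attn.append(cache["alpha_w"][0, i, :n_real].copy())
        return EncodedUser(
            user_id=user.user_id,
            tweet_vectors=cache["v"][0, :L].copy(),
            word_attn=word_attn,
            tweet_attn=cache["alpha_t"][0, :L].copy() if not cfg.tweet_maxpool else None,
            user_vector=cache["s"][0].copy(),
            aspect_vector=cache["p"][0].copy() if cfg.uses_aspects else None,
            score=float(y_hat[0]),
        )

    # -- checkpointing ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: config JSON plus named parameter arrays."""
        cfg = asdict(self.config)
        cfg["aspect_mask"] = list(cfg["aspect_mask"])
        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps({"config": cfg, "aspect_dim": self.aspect_dim}).encode(),
                dtype=np.uint8,
            ),
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "MDHAN":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__config__"]).decode())
            cfg = meta["config"]
            cfg["aspect_mask"] = tuple(cfg["aspect_mask"])
            model = cls(ModelConfig(**cfg), aspect_dim=meta["aspect_dim"])
            for k in model.params:
                model.params[k] = data[k].copy()
        return model


def loss(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy (probabilities clipped at 1e-7)."""
    return _nn.bce_loss(np.asarray(y_hat, dtype=float), np.asarray(y, dtype=float))[0]
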