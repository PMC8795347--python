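"""Training loop, data splitting, confusion-matrix metrics, cross-validation
and ablation runs.

The headline evaluation protocol is stratified five-fold cross-validation;
a single stratified 80/20 split is also provided.  All randomness (splits,
batch shuffling, parameter init, dropout) is derived from explicit seeds.

Per-split fitting discipline: the LDA topic model is fitted on the pooled
tweets of the *depressed training* users only, and the feature z-scoring
statistics come from the training rows only; both are then applied to all
users.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _nn
from .aspects import (
    BLOCK_ORDER,
    FeatureNormalizer,
    expand_symptom_lexicon,
    feature_matrix,
    fit_topic_model,
)
from .model import MDHAN, ModelConfig, pad_batch, user_token_matrices
from .timeline_io import EmbeddingTable, Lexicons, UserTimeline

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metrics:
    """Confusion matrix (positive class = depressed) and derived scores.

    Precision, recall and F1 are macro-averaged over the two classes; a
    class with no predicted (or true) members contributes zero to the
    average rather than NaN.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else 0.0

    @staticmethod
    def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        return prec, rec, f1

    def per_class(self) -> dict[int, tuple[float, float, float]]:
        return {
            1: self._prf(self.tp, self.fp, self.fn),
            0: self._prf(self.tn, self.fn, self.fp),
        }

    @property
    def precision(self) -> float:
        pc = self.per_class()
        return (pc[0][0] + pc[1][0]) / 2

    @property
    def recall(self) -> float:
        pc = self.per_class()
        return (pc[0][1] + pc[1][1]) / 2

    @property
    def f1(self) -> float:
        pc = self.per_class()
        return (pc[0][2] + pc[1][2]) / 2

    @classmethod
    def from_predictions(cls, y_true: Sequence[int], y_pred: Sequence[int]) -> "Metrics":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        if yt.size == 0:
            raise ValueError("cannot compute metrics on an empty evaluation set")
        return cls(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            fp=int(np.sum((yt == 0) & (yp == 1))),
            fn=int(np.sum((yt == 1) & (yp == 0))),
            tn=int(np.sum((yt == 0) & (yp == 0))),
        )

    def as_dict(self) -> dict:
        return {
            "confusion": {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn},
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def mean_metrics(items: Sequence[Metrics]) -> dict[str, float]:
    """Arithmetic mean of the four derived scores over folds/seeds."""
    return {
        k: float(np.mean([getattr(m, k) for m in items]))
        for k in ("accuracy", "precision", "recall", "f1")
    }


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def split(
    users: Sequence[UserTimeline], train_frac: float = 0.8, seed: int = 0
) -> tuple[list[UserTimeline], list[UserTimeline]]:
    """Stratified random train/test split, reproducible by seed.

    Per class, ``floor(n_class * train_frac)`` users go to training.  The
    assignment depends only on user ids and the seed, not on input order.
    """
    by_class: dict[int, list[UserTimeline]] = {0: [], 1: []}
    for u in users:
        if u.label not in (0, 1):
            raise ValueError(f"user {u.user_id!r} has no binary label")
        by_class[u.label].append(u)
    for c, members in by_class.items():
        if len(members) < 2:
            raise ValueError(f"class {c} has fewer than 2 members; cannot split")
    rng = np.random.default_rng(seed)
    train: list[UserTimeline] = []
    test: list[UserTimeline] = []
    for c in (0, 1):
        members = sorted(by_class[c], key=lambda u: u.user_id)
        order = rng.permutation(len(members))
        n_train = int(len(members) * train_frac)
        train.extend(members[i] for i in order[:n_train])
        test.extend(members[i] for i in order[n_train:])
    return train, test


def stratified_folds(
    users: Sequence[UserTimeline], folds: int = 5, seed: int = 0
) -> list[list[UserTimeline]]:
    """Partition users into stratified folds (every user in exactly one)."""
    by_class: dict[int, list[UserTimeline]] = {0: [], 1: []}
    for u in users:
        by_class[u.label].append(u)
    for c, members in by_class.items():
        if len(members) < folds:
            raise ValueError(f"class {c} has fewer members than folds")
    rng = np.random.default_rng(seed)
    out: list[list[UserTimeline]] = [[] for _ in range(folds)]
    for c in (0, 1):
        members = sorted(by_class[c], key=lambda u: u.user_id)
        order = rng.permutation(len(members))
        for k, i in enumerate(order):
            out[k % folds].append(members[i])
    return out


# ---------------------------------------------------------------------------
# Feature building (per split)
# ---------------------------------------------------------------------------


@dataclass
class FeatureBundle:
    features: pd.DataFrame  # all users × full-mask columns, z-scored
    topic_model: object
    expanded: dict[str, list[str]]
    normalizer: FeatureNormalizer


def build_features(
    train_users: Sequence[UserTimeline],
    all_users: Sequence[UserTimeline],
    lex: Lexicons,
    emb: EmbeddingTable,
    K: int = 25,
    seed: int = 0,
    top_k: int = 10,
    min_cosine: float = 0.6,
    lda_max_iter: int = 10,
) -> FeatureBundle:
    """Fit topic model + lexicon expansion + normalizer, featurize everyone."""
    corpus = [
        list(t.tokens)
        for u in train_users
        if u.label == 1
        for t in u.tweets
        if t.tokens
    ]
    topic_model = fit_topic_model(corpus, K=K, seed=seed, max_iter=lda_max_iter)
    expanded = expand_symptom_lexicon(lex.symptom_seeds, emb, top_k=top_k, min_cosine=min_cosine)
    feats = feature_matrix(all_users, lex, topic_model, expanded, mask=BLOCK_ORDER)
    normalizer = FeatureNormalizer().fit(feats.loc[[u.user_id for u in train_users]])
    return FeatureBundle(
        features=normalizer.transform(feats),
        topic_model=topic_model,
        expanded=expanded,
        normalizer=normalizer,
    )


def mask_columns(features: pd.DataFrame, mask: Sequence[str]) -> pd.DataFrame:
    """Column subset of the full feature matrix for an aspect mask."""
    keep = [c for c in features.columns if c.split(":", 1)[0] in set(mask)]
    return features[keep]


# ---------------------------------------------------------------------------
# Tensor preparation / training
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """Model-ready arrays for a list of users, aligned by position."""

    ids: list[str]
    y: np.ndarray
    tweet_mats: list[list[np.ndarray]] | None
    m: np.ndarray | None


def prepare_dataset(
    users: Sequence[UserTimeline],
    emb: EmbeddingTable | None,
    features: pd.DataFrame | None,
    config: ModelConfig,
) -> Dataset:
    ids = [u.user_id for u in users]
    y = np.array([u.label for u in users], dtype=float)
    mats = None
    if config.uses_text:
        mats = [user_token_matrices(u, emb, config) for u in users]
    m = None
    if config.uses_aspects:
        m = features.loc[ids].to_numpy(dtype=float)
    return Dataset(ids=ids, y=y, tweet_mats=mats, m=m)


def train(
    model: MDHAN,
    data: Dataset,
    epochs: int = 10,
    batch_size: int = 16,
    lr: float = 0.001,
    seed: int = 0,
) -> list[float]:
    """Adam training; returns the per-epoch mean loss history.

    A NaN loss aborts with the epoch and batch index in the message.
    """
    opt = _nn.Adam(model.params, lr=lr)
    rng = np.random.default_rng(seed)
    n = len(data.ids)
    history: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for bi, lo in enumerate(range(0, n, batch_size)):
            idx = order[lo : lo + batch_size]
            X = wm = tm = mf = None
            if model.config.uses_text:
                X, wm, tm = pad_batch([data.tweet_mats[i] for i in idx],
                                      dim=model.config.embed_dim)
            if model.config.uses_aspects:
                mf = data.m[idx]
            y = data.y[idx]
            y_hat, cache = model.forward(X, wm, tm, mf, train=True)
            batch_loss, dlogit = _nn.bce_loss(y_hat, y)
            if not np.isfinite(batch_loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}, batch {bi}")
            grads = model.backward(dlogit, cache)
            opt.step(grads)
            losses.append(batch_loss)
        history.append(float(np.mean(losses)))
        logger.info("epoch %d/%d mean loss %.4f", epoch + 1, epochs, history[-1])
    return history


def evaluate(model: MDHAN, data: Dataset, threshold: float = 0.5) -> Metrics:
    """Confusion-matrix metrics on a dataset (score >= 0.5 -> depressed)."""
    if not data.ids:
        raise ValueError("empty evaluation set")
    proba = model.predict_proba(data.tweet_mats, data.m)
    return Metrics.from_predictions(data.y.astype(int), (proba >= threshold).astype(int))


# ---------------------------------------------------------------------------
# End-to-end pipeline, cross-validation, ablations
# ---------------------------------------------------------------------------


@dataclass
class TrainSettings:
    epochs: int = 10
    batch_size: int = 16
    lr: float = 0.001
    k_topics: int = 25
    lda_max_iter: int = 10


def run_pipeline(
    train_users: Sequence[UserTimeline],
    test_users: Sequence[UserTimeline],
    lex: Lexicons,
    emb: EmbeddingTable,
    config: ModelConfig,
    settings: TrainSettings | None = None,
    seed: int = 0,
    bundle: FeatureBundle | None = None,
) -> tuple[MDHAN, Metrics, list[float]]:
    """Featurize, train and evaluate one split with one variant.

    A precomputed ``bundle`` (from :func:`build_features` on the same
    training split) can be passed to share featurization across variants.
    """
    settings = settings or TrainSettings()
    all_users = list(train_users) + list(test_users)
    feats = None
    if config.uses_aspects:
        if bundle is None:
            bundle = build_features(
                train_users, all_users, lex, emb, K=settings.k_topics, seed=seed,
                lda_max_iter=settings.lda_max_iter,
            )
        feats = mask_columns(bundle.features, config.aspect_mask)
    model = MDHAN(config, aspect_dim=feats.shape[1] if feats is not None else None)
    train_data = prepare_dataset(train_users, emb, feats, config)
    test_data = prepare_dataset(test_users, emb, feats, config)
    history = train(
        model, train_data, epochs=settings.epochs, batch_size=settings.batch_size,
        lr=settings.lr, seed=seed,
    )
    return model, evaluate(model, test_data), history


def cross_validate(
    users: Sequence[UserTimeline],
    lex: Lexicons,
    emb: EmbeddingTable,
    config: ModelConfig,
    folds: int = 5,
    settings: TrainSettings | None = None,
    seed: int = 0,
) -> tuple[list[Metrics], dict[str, float]]:
    """Stratified k-fold cross-validation of the full pipeline."""
    parts = stratified_folds(users, folds=folds, seed=seed)
    fold_metrics: list[Metrics] = []
    for k in range(folds):
        test_users = parts[k]
        train_users = [u for j, p in enumerate(parts) if j != k for u in p]
        cfg = ModelConfig(**{**config.__dict__, "seed": config.seed + k})
        _, metrics, _ = run_pipeline(
            train_users, test_users, lex, emb, cfg, settings, seed=seed + k
        )
        fold_metrics.append(metrics)
        logger.info("fold %d/%d: %s", k + 1, folds, metrics.as_dict())
    return fold_metrics, mean_metrics(fold_metrics)


#: The ablation grid: the three headline variants, each aspect removed
#: from the full model, and each aspect alone alongside the text branch.
ABLATION_VARIANTS: dict[str, tuple[str, tuple[str, ...]]] = {
    "MDHAN": ("MDHAN", BLOCK_ORDER),
    "HAN": ("HAN", ()),
    "MM": ("MM", BLOCK_ORDER),
    "MDHAN-D": ("MDHAN", ("social", "emo", "topic")),
    "MDHAN-E": ("MDHAN", ("social", "topic", "domain")),
    "MDHAN-S": ("MDHAN", ("emo", "topic", "domain")),
    "MDHAN-T": ("MDHAN", ("social", "emo", "domain")),
    "D+HAN": ("MDHAN", ("domain",)),
    "E+HAN": ("MDHAN", ("emo",)),
    "S+HAN": ("MDHAN", ("social",)),
    "T+HAN": ("MDHAN", ("topic",)),
}


def run_ablations(
    users: Sequence[UserTimeline],
    lex: Lexicons,
    emb: EmbeddingTable,
    base_config: ModelConfig,
    settings: TrainSettings | None = None,
    seeds: Sequence[int] = (0, 1, 2),
    variants: Sequence[str] | None = None,
    train_frac: float = 0.8,
) -> pd.DataFrame:
    """Metrics per (variant, seed) on shared splits and shared features.

    For each seed, one stratified split and one feature bundle are reused
    by every variant, so variants differ only in branch gating and aspect
    mask.  Returns a tidy DataFrame with one row per variant × seed.
    """
    settings = settings or TrainSettings()
    names = list(variants) if variants is not None else list(ABLATION_VARIANTS)
    rows = []
    for seed in seeds:
        train_users, test_users = split(users, train_frac=train_frac, seed=seed)
        bundle = build_features(
            train_users, list(train_users) + list(test_users), lex, emb,
            K=settings.k_topics, seed=seed, lda_max_iter=settings.lda_max_iter,
        )
        for name in names:
            variant, mask = ABLATION_VARIANTS[name]
            cfg = ModelConfig(
                **{**base_config.__dict__, "variant": variant,
                   "aspect_mask": mask, "seed": base_config.seed + seed}
            )
            _, metrics, _ = run_pipeline(
                train_users, test_users, lex, emb, cfg, settings,
                seed=seed, bundle=bundle,
            )
            rows.append({"variant": name, "seed": seed, **metrics.as_dict()})
            logger.info("ablation %s seed %d: f1=%.3f", name, seed, metrics.f1)
    return pd.DataFrame(rows)
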