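"""The four behavioural aspect-feature blocks computed per user.

Each user is summarized by four named feature groups ("aspects"):

``social``  (30)  profile & activity statistics plus a 24-hour posting
                  histogram;
``emo``     (8)   emoji polarity counts, summed valence/arousal/dominance,
                  and first-person singular/plural token counts;
``topic``   (K)   LDA topic mixture of the user's concatenated tokens
                  (K = 25 by default), on the probability simplex;
``domain``  (10)  counts of mentions of the nine depression-symptom groups
                  (lexicon-expanded via embedding similarity) plus a count
                  of antidepressant-name mentions.

The concatenation of the masked blocks is the multi-aspect vector fed to
the MLP branch of the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import LatentDirichletAllocation

from .timeline_io import EmbeddingTable, Lexicons, UserTimeline

logger = logging.getLogger(__name__)

#: Fixed order of the aspect blocks in the assembled vector.
BLOCK_ORDER = ("social", "emo", "topic", "domain")

SOCIAL_DIM = 30  # 6 scalars + 24-hour histogram
EMO_DIM = 8
DOMAIN_DIM = 10  # 9 symptom groups + antidepressants

SOCIAL_NAMES = [
    "n_tweets",
    "total_char_length",
    "n_retweets",
    "followers",
    "friends",
    "favourites",
] + [f"hour_{h:02d}" for h in range(24)]

EMO_NAMES = [
    "emoji_pos",
    "emoji_neu",
    "emoji_neg",
    "valence_sum",
    "arousal_sum",
    "dominance_sum",
    "fp_singular",
    "fp_plural",
]


def social_features(user: UserTimeline) -> np.ndarray:
    """Profile/activity scalars plus the 24-hour posting histogram.

    The histogram entry ``h`` counts tweets whose stored clock hour equals
    ``h`` (no timezone correction is applied).
    """
    hist = np.zeros(24)
    total_len = 0
    n_rt = 0
    for t in user.tweets:
        hist[t.timestamp.hour] += 1
        total_len += len(t.text)
        n_rt += int(t.is_retweet)
    head = [user.n_tweets, total_len, n_rt, user.followers, user.friends, user.favourites]
    return np.concatenate([np.asarray(head, dtype=float), hist])


def emoji_vad_features(user: UserTimeline, lex: Lexicons) -> np.ndarray:
    """Emoji polarity counts, summed VAD scores and first-person counts.

    Per-tweet quantities are summed over the whole timeline ("add up", no
    length normalization).  An emoji absent from the polarity map counts as
    neutral.  Words missing from the VAD norm list contribute nothing.
    """
    pos = neu = neg = 0
    vad_sum = np.zeros(3)
    fp_s = fp_p = 0
    for t in user.tweets:
        for e in t.emoji_list:
            polarity = lex.emoji_polarity.get(e)
            if polarity is None:
                logger.debug("emoji %r not in polarity map; counted neutral", e)
                polarity = "neutral"
            if polarity == "positive":
                pos += 1
            elif polarity == "negative":
                neg += 1
            else:
                neu += 1
        for w in t.tokens:
            triple = lex.vad.get(w)
            if triple is not None:
                vad_sum += triple
            if w in lex.fp_singular:
                fp_s += 1
            elif w in lex.fp_plural:
                fp_p += 1
    return np.concatenate([[pos, neu, neg], vad_sum, [fp_s, fp_p]])


# ---------------------------------------------------------------------------
# Topic features (LDA)
# ---------------------------------------------------------------------------


@dataclass
class TopicModel:
    """Thin adapter over a fitted LDA model.

    ``word_topic_weights`` holds P(word | topic) as a vocabulary × K matrix
    (columns sum to one).  Inference for a user treats the concatenation of
    all their tokens as one document.
    """

    K: int
    vocabulary: list[str]
    word_topic_weights: np.ndarray  # (V, K), columns on the simplex
    seed: int
    _lda: LatentDirichletAllocation = field(repr=False)
    _vocab_index: dict[str, int] = field(repr=False)

    def infer(self, tokens: Iterable[str]) -> np.ndarray:
        counts = np.zeros(len(self.vocabulary))
        for w in tokens:
            j = self._vocab_index.get(w)
            if j is not None:
                counts[j] += 1
        if counts.sum() == 0:
            logger.debug("no in-vocabulary tokens; uniform topic mixture returned")
            return np.full(self.K, 1.0 / self.K)
        theta = self._lda.transform(counts[None, :])[0]
        return theta / theta.sum()


def fit_topic_model(
    corpus: Sequence[Sequence[str]], K: int = 25, seed: int = 0, max_iter: int = 10
) -> TopicModel:
    """Fit LDA on a corpus of token lists (one list per tweet).

    The training corpus is conventionally the pooled tweets of the
    depressed users in the training split; the fitted model is then applied
    to every user.  Deterministic given ``seed``.
    """
    vocab = sorted({w for doc in corpus for w in doc})
    if not vocab:
        raise ValueError("empty corpus: no in-vocabulary tokens to fit topics on")
    vocab_index = {w: j for j, w in enumerate(vocab)}
    dtm = np.zeros((len(corpus), len(vocab)))
    for i, doc in enumerate(corpus):
        for w in doc:
            dtm[i, vocab_index[w]] += 1
    dtm = dtm[dtm.sum(axis=1) > 0]
    if dtm.shape[0] == 0:
        raise ValueError("empty corpus: all documents empty after cleaning")
    lda = LatentDirichletAllocation(
        n_components=K, random_state=seed, max_iter=max_iter, learning_method="batch"
    )
    lda.fit(dtm)
    weights = (lda.components_ / lda.components_.sum(axis=1)[:, None]).T  # (V, K)
    return TopicModel(
        K=K,
        vocabulary=vocab,
        word_topic_weights=weights,
        seed=seed,
        _lda=lda,
        _vocab_index=vocab_index,
    )


def topic_features(user: UserTimeline, model: TopicModel) -> np.ndarray:
    """Posterior topic mixture of the user's pooled tokens (simplex-valued)."""
    tokens = [w for t in user.tweets for w in t.tokens]
    return model.infer(tokens)


# ---------------------------------------------------------------------------
# Domain-specific features
# ---------------------------------------------------------------------------


def expand_symptom_lexicon(
    seeds: Mapping[str, Sequence[str]],
    emb: EmbeddingTable,
    top_k: int = 10,
    min_cosine: float = 0.6,
) -> dict[str, list[str]]:
    """Extend each symptom seed list with embedding nearest neighbours.

    For every seed word present in the embedding vocabulary, the ``top_k``
    most cosine-similar vocabulary words with similarity >= ``min_cosine``
    are added to that seed's group.  Seed words are always retained.  A
    candidate drawn into several groups is assigned to the group of its
    most similar seed (ties break toward the earlier-listed group).
    """
    vocab = list(emb.vectors)
    mat = np.stack([emb.vectors[w] for w in vocab]) if vocab else np.zeros((0, emb.dim))
    norms = np.linalg.norm(mat, axis=1)
    norms[norms == 0] = 1.0
    unit = mat / norms[:, None]
    index = {w: i for i, w in enumerate(vocab)}

    group_names = list(seeds)
    seed_sets = {g: set(map(str.lower, ws)) for g, ws in seeds.items()}
    # candidate word -> (best cosine, group index) over all seeds
    best: dict[str, tuple[float, int]] = {}
    for gi, g in enumerate(group_names):
        for seed in seeds[g]:
            i = index.get(seed)
            if i is None:
                logger.warning("seed word %r absent from embeddings; kept literal", seed)
                continue
            sims = unit @ unit[i]
            order = np.argsort(-sims)
            taken = 0
            for j in order:
                w = vocab[j]
                if w == seed:
                    continue
                if sims[j] < min_cosine:
                    break
                if taken >= top_k:
                    break
                key = (float(sims[j]), -gi)  # tie -> lower group index wins
                if w not in best or key > (best[w][0], -best[w][1]):
                    best[w] = (float(sims[j]), gi)
                taken += 1

    expanded = {g: sorted(seed_sets[g]) for g in group_names}
    all_seeds = {w for ws in seed_sets.values() for w in ws}
    for w, (_, gi) in best.items():
        if w not in all_seeds:
            expanded[group_names[gi]].append(w)
    return {g: sorted(set(ws)) for g, ws in expanded.items()}


def symptom_counts(
    user: UserTimeline, expanded: Mapping[str, Sequence[str]]
) -> np.ndarray:
    """Occurrences (with multiplicity) of each symptom group's words."""
    sets = [frozenset(ws) for ws in expanded.values()]
    counts = np.zeros(len(sets))
    for t in user.tweets:
        for w in t.tokens:
            for g, ws in enumerate(sets):
                if w in ws:
                    counts[g] += 1
    return counts


def antidepressant_count(user: UserTimeline, lex: Lexicons) -> int:
    """Mentions of antidepressant names, with multiplicity.

    Multi-word names are matched as token n-grams.
    """
    singles = {w for w in lex.antidepressants if " " not in w}
    multis = [tuple(w.split()) for w in lex.antidepressants if " " in w]
    n = 0
    for t in user.tweets:
        toks = t.tokens
        n += sum(1 for w in toks if w in singles)
        for gram in multis:
            k = len(gram)
            n += sum(1 for i in range(len(toks) - k + 1) if toks[i : i + k] == gram)
    return n


def domain_features(
    user: UserTimeline, expanded: Mapping[str, Sequence[str]], lex: Lexicons
) -> np.ndarray:
    return np.concatenate(
        [symptom_counts(user, expanded), [antidepressant_count(user, lex)]]
    )


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def block_sizes(K: int = 25) -> dict[str, int]:
    return {"social": SOCIAL_DIM, "emo": EMO_DIM, "topic": K, "domain": DOMAIN_DIM}


def feature_names(
    mask: Sequence[str] = BLOCK_ORDER, K: int = 25, symptom_names: Sequence[str] | None = None
) -> list[str]:
    """Column names ``block:name`` for the assembled matrix."""
    sym = list(symptom_names) if symptom_names else [f"symptom_{g+1}" for g in range(9)]
    names = {
        "social": [f"social:{n}" for n in SOCIAL_NAMES],
        "emo": [f"emo:{n}" for n in EMO_NAMES],
        "topic": [f"topic:topic_{k}" for k in range(K)],
        "domain": [f"domain:{n}" for n in sym] + ["domain:antidepressants"],
    }
    return [c for b in BLOCK_ORDER if b in mask for c in names[b]]


def assemble_features(
    user: UserTimeline,
    lex: Lexicons,
    topic_model: TopicModel | None,
    expanded: Mapping[str, Sequence[str]],
    mask: Sequence[str] = BLOCK_ORDER,
) -> np.ndarray:
    """Concatenate the masked aspect blocks in fixed order."""
    mask = set(mask)
    if not mask:
        raise ValueError("empty aspect mask: no feature blocks requested")
    parts = []
    if "social" in mask:
        parts.append(social_features(user))
    if "emo" in mask:
        parts.append(emoji_vad_features(user, lex))
    if "topic" in mask:
        if topic_model is None:
            raise ValueError("topic block requested but no topic model supplied")
        parts.append(topic_features(user, topic_model))
    if "domain" in mask:
        parts.append(domain_features(user, expanded, lex))
    return np.concatenate(parts)


def feature_matrix(
    users: Sequence[UserTimeline],
    lex: Lexicons,
    topic_model: TopicModel | None,
    expanded: Mapping[str, Sequence[str]],
    mask: Sequence[str] = BLOCK_ORDER,
) -> pd.DataFrame:
    """Assembled features for many users as a DataFrame (index = user_id)."""
    K = topic_model.K if topic_model is not None else 25
    cols = feature_names(mask, K=K, symptom_names=list(expanded))
    rows = [assemble_features(u, lex, topic_model, expanded, mask) for u in users]
    return pd.DataFrame(rows, index=[u.user_id for u in users], columns=cols)


class FeatureNormalizer:
    """Z-scores non-simplex columns using statistics of the training split.

    Topic columns are already on the probability simplex and are passed
    through unchanged.  Constant columns get unit scale to avoid division
    by zero.
    """

    def __init__(self) -> None:
        self.mean_: pd.Series | None = None
        self.scale_: pd.Series | None = None

    @staticmethod
    def _zcols(df: pd.DataFrame) -> list[str]:
        return [c for c in df.columns if not str(c).startswith("topic:")]

    def fit(self, train: pd.DataFrame) -> "FeatureNormalizer":
        cols = self._zcols(train)
        self.mean_ = train[cols].mean()
        sd = train[cols].std(ddof=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None:
            raise RuntimeError("normalizer not fitted")
        out = df.copy()
        cols = self._zcols(df)
        out[cols] = (df[cols] - self.mean_) / self.scale_
        return out

    def fit_transform(self, train: pd.DataFrame) -> pd.DataFrame:
        return self.fit(train).transform(train)
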