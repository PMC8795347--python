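"""Synthetic labelled timelines with planted class-conditional signals.

The generator emulates the behavioural contrasts the classifier is built
to exploit: depressed users mention symptom words more often, use more
negative emojis and more first-person singular language, post more at
night, and draw their filler text from a shifted topic mixture.  It also
emits a matching toy embedding table (symptom seed words sit close to
their planted synonyms, so lexicon expansion has something to find) and a
full lexicon bundle, so every pipeline stage runs without any external
download.

Text is not linguistically realistic — tweets are bags of pseudo-words
with Zipf-like frequencies plus planted tokens — but it carries exactly
the statistical structure the model assumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .timeline_io import (
    EmbeddingTable,
    Lexicons,
    Tweet,
    UserTimeline,
    clean_timeline,
    load_stopwords,
    write_embeddings,
    write_lexicons,
    write_timelines,
)

# Nine symptom families: (name, seed words, planted synonyms).  Seeds go
# into the shipped lexicon; synonyms are only discoverable through
# embedding-similarity expansion.
SYMPTOM_FAMILIES: list[tuple[str, list[str], list[str]]] = [
    ("depressed_mood", ["sad", "hopeless", "depressed"], ["miserable", "gloomy", "despair"]),
    ("anhedonia", ["empty", "numb", "joyless"], ["apathy", "unmotivated", "disinterest"]),
    ("sleep_problems", ["insomnia", "sleepless", "awake"], ["nightmares", "restless", "tossing"]),
    ("fatigue", ["tired", "drained", "fatigue"], ["weary", "sluggish", "lethargic"]),
    ("appetite_changes", ["appetite", "overeating", "starving"], ["bingeing", "nausea", "craving"]),
    ("worthlessness_guilt", ["worthless", "guilty", "failure"], ["ashamed", "useless", "blameworthy"]),
    ("concentration", ["unfocused", "distracted", "foggy"], ["indecisive", "scattered", "muddled"]),
    ("psychomotor", ["agitated", "slowed", "restlessness"], ["jittery", "fidgety", "lagging"]),
    ("suicidal_ideation", ["suicidal", "die", "selfharm"], ["overdose", "cutting", "ending"]),
]

ANTIDEPRESSANTS = [
    "prozac", "zoloft", "sertraline", "fluoxetine", "citalopram",
    "lexapro", "effexor", "wellbutrin", "st johns wort",
]

FP_SINGULAR = ["i", "me", "my", "mine", "myself"]
FP_PLURAL = ["we", "us", "our", "ours", "ourselves"]

EMOJI_POLARITY = {
    "\U0001F600": "positive",  # 😀
    "\U0001F60A": "positive",  # 😊
    "\U0001F610": "neutral",   # 😐
    "☹": "negative",      # ☹
    "\U0001F622": "negative",  # 😢
}
_POS_EMOJIS = [e for e, p in EMOJI_POLARITY.items() if p == "positive"]
_NEU_EMOJIS = [e for e, p in EMOJI_POLARITY.items() if p == "neutral"]
_NEG_EMOJIS = [e for e, p in EMOJI_POLARITY.items() if p == "negative"]

N_THEMES = 5  # latent filler-text themes (what LDA is meant to recover)


@dataclass
class SimConfig:
    """Study conditions of the simulator.

    Rates are per-tweet event probabilities; the ``_dep``/``_ctl`` pairs
    set the planted class contrast.  ``night_shift_*`` is the fraction of
    a class's tweets drawn from the 00:00–05:00 posting-hour distribution;
    ``topic_shift`` in [0, 1] is how strongly depressed users' filler text
    leans toward the first themes (0 = identical mixtures).
    """

    n_users: int = 200
    prevalence: float = 0.5
    tweets_per_user: tuple[int, int] = (10, 200)
    symptom_rate_dep: float = 0.30
    symptom_rate_ctl: float = 0.02
    neg_emoji_rate_dep: float = 0.25
    neg_emoji_rate_ctl: float = 0.05
    fp_singular_rate_dep: float = 0.20
    fp_singular_rate_ctl: float = 0.08
    night_shift_dep: float = 0.4
    night_shift_ctl: float = 0.1
    antidep_rate_dep: float = 0.02
    antidep_rate_ctl: float = 0.002
    topic_shift: float = 0.6
    vocab_size: int = 300
    embed_dim: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 4:
            raise ValueError("n_users must be at least 4")
        n_symptom_words = sum(len(s) + len(y) for _, s, y in SYMPTOM_FAMILIES)
        if self.vocab_size < n_symptom_words + N_THEMES * 5:
            raise ValueError(
                f"vocab_size={self.vocab_size} too small to host the "
                f"{n_symptom_words} symptom words plus themed filler"
            )
        for f in dataclasses.fields(self):
            if f.name.endswith(("_dep", "_ctl")) or f.name in ("prevalence", "topic_shift"):
                v = getattr(self, f.name)
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{f.name}={v} outside [0, 1]")

    def null(self) -> "SimConfig":
        """A copy with every class contrast removed (negative control)."""
        return dataclasses.replace(
            self,
            symptom_rate_dep=self.symptom_rate_ctl,
            neg_emoji_rate_dep=self.neg_emoji_rate_ctl,
            fp_singular_rate_dep=self.fp_singular_rate_ctl,
            night_shift_dep=self.night_shift_ctl,
            antidep_rate_dep=self.antidep_rate_ctl,
            topic_shift=0.0,
        )


@dataclass
class SyntheticData:
    """Everything one :func:`generate` call produced, in memory."""

    users: list[UserTimeline]  # cleaned & tokenized, time-sorted
    raw_users: list[UserTimeline]  # as written to JSONL (uncleaned)
    lexicons: Lexicons
    embeddings: EmbeddingTable
    labels: pd.DataFrame  # index user_id, column "label"
    symptom_words: dict[str, list[str]]  # seeds + planted synonyms
    config: SimConfig


def _build_vocab(cfg: SimConfig) -> tuple[list[str], list[list[str]]]:
    """Filler vocabulary split into themed word pools."""
    reserved = {w for _, s, y in SYMPTOM_FAMILIES for w in s + y}
    n_filler = cfg.vocab_size - len(reserved)
    filler = [f"w{idx:04d}" for idx in range(n_filler)]
    themes = [filler[t::N_THEMES] for t in range(N_THEMES)]
    return filler, themes


def _build_embeddings(cfg: SimConfig, filler: list[str], themes: list[list[str]],
                      rng: np.random.Generator) -> EmbeddingTable:
    """Toy embedding table: family members cluster (cosine > 0.8)."""
    d = cfg.embed_dim
    vectors: dict[str, np.ndarray] = {}

    def unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    # noise scales with 1/sqrt(d) so pairwise cosines are dimension-free:
    # family members stay above ~0.9, themed filler around ~0.5
    for _, seeds, syns in SYMPTOM_FAMILIES:
        centre = unit(rng.normal(size=d))
        for w in seeds + syns:
            vectors[w] = unit(centre + (0.25 / np.sqrt(d)) * rng.normal(size=d))
    for t, words in enumerate(themes):
        centre = unit(rng.normal(size=d))
        for w in words:
            vectors[w] = unit(centre + (1.0 / np.sqrt(d)) * rng.normal(size=d))
    for w in FP_SINGULAR + FP_PLURAL:
        vectors[w] = unit(rng.normal(size=d))
    for name in ANTIDEPRESSANTS:
        for tok in name.split():
            vectors.setdefault(tok, unit(rng.normal(size=d)))
    return EmbeddingTable(dim=d, vectors=vectors)


def _build_lexicons(filler: list[str], rng: np.random.Generator) -> Lexicons:
    vad: dict[str, tuple[float, float, float]] = {}
    for _, seeds, syns in SYMPTOM_FAMILIES:
        for w in seeds + syns:  # symptom words: low valence, mid arousal
            vad[w] = (round(rng.uniform(0.05, 0.3), 3),
                      round(rng.uniform(0.3, 0.7), 3),
                      round(rng.uniform(0.2, 0.5), 3))
    for w in filler[:: max(1, len(filler) // 120)]:  # a spread of filler words
        vad[w] = tuple(round(x, 3) for x in rng.uniform(0.2, 0.8, size=3))
    return Lexicons(
        emoji_polarity=dict(EMOJI_POLARITY),
        vad=vad,
        fp_singular=frozenset(FP_SINGULAR),
        fp_plural=frozenset(FP_PLURAL),
        symptom_seeds={name: list(seeds) for name, seeds, _ in SYMPTOM_FAMILIES},
        antidepressants=frozenset(ANTIDEPRESSANTS),
    )


_STOP_SPRINKLE = ["the", "and", "to", "a", "of", "is", "was", "in", "on", "it"]
_DAY_HOURS = np.arange(6, 24)
_DAY_W = np.concatenate([np.full(6, 0.5), np.full(6, 1.0), np.full(6, 1.5)])
_DAY_W = _DAY_W / _DAY_W.sum()


def _make_tweet(cls: int, cfg: SimConfig, themes: list[list[str]],
                theme_probs: np.ndarray, base: datetime,
                rng: np.random.Generator) -> Tweet:
    dep = cls == 1
    sym_rate = cfg.symptom_rate_dep if dep else cfg.symptom_rate_ctl
    neg_rate = cfg.neg_emoji_rate_dep if dep else cfg.neg_emoji_rate_ctl
    fp_rate = cfg.fp_singular_rate_dep if dep else cfg.fp_singular_rate_ctl
    night = cfg.night_shift_dep if dep else cfg.night_shift_ctl
    anti_rate = cfg.antidep_rate_dep if dep else cfg.antidep_rate_ctl

    theme = rng.choice(N_THEMES, p=theme_probs)
    pool = themes[theme]
    n_fill = 4 + rng.poisson(4)
    # Zipf-like draw within the theme pool
    ranks = np.arange(1, len(pool) + 1, dtype=float)
    pz = (1.0 / ranks) / (1.0 / ranks).sum()
    words = [pool[j] for j in rng.choice(len(pool), size=n_fill, p=pz)]

    if rng.random() < sym_rate:
        fam = SYMPTOM_FAMILIES[rng.integers(9)]
        k = int(1 + (rng.random() < 0.4))
        words += list(rng.choice(fam[1] + fam[2], size=k))
    if rng.random() < fp_rate:
        words += list(rng.choice(FP_SINGULAR, size=int(1 + (rng.random() < 0.5))))
    if rng.random() < 0.05:
        words.append(str(rng.choice(FP_PLURAL)))
    if rng.random() < anti_rate:
        words.append(str(rng.choice(ANTIDEPRESSANTS)))
    rng.shuffle(words)
    # sprinkle stopwords so that cleaning actually has work to do
    out: list[str] = []
    for w in words:
        if rng.random() < 0.3:
            out.append(str(rng.choice(_STOP_SPRINKLE)))
        out.append(w)
    text = " ".join(out)
    if rng.random() < neg_rate:
        text += " " + str(rng.choice(_NEG_EMOJIS))
    elif rng.random() < 0.15:
        text += " " + str(rng.choice(_POS_EMOJIS))
    elif rng.random() < 0.05:
        text += " " + str(rng.choice(_NEU_EMOJIS))

    if rng.random() < night:
        hour = int(rng.integers(0, 6))
    else:
        hour = int(rng.choice(_DAY_HOURS, p=_DAY_W))
    ts = base + timedelta(days=int(rng.integers(0, 365)), hours=hour,
                          minutes=int(rng.integers(0, 60)),
                          seconds=int(rng.integers(0, 60)))
    return Tweet(text=text, timestamp=ts, is_retweet=bool(rng.random() < 0.1))


def generate(cfg: SimConfig) -> SyntheticData:
    """Generate a labelled synthetic cohort; fully reproducible by seed."""
    rng = np.random.default_rng(cfg.seed)
    filler, themes = _build_vocab(cfg)
    emb = _build_embeddings(cfg, filler, themes, rng)
    lex = _build_lexicons(filler, rng)

    # class-conditional theme mixtures
    base_mix = np.full(N_THEMES, 1.0 / N_THEMES)
    lean = np.array([2.0, 1.5, 1.0, 0.5, 0.3])
    lean = lean / lean.sum()
    dep_mix = (1 - cfg.topic_shift) * base_mix + cfg.topic_shift * lean
    ctl_mix = (1 - cfg.topic_shift) * base_mix + cfg.topic_shift * lean[::-1]

    labels = (rng.random(cfg.n_users) < cfg.prevalence).astype(int)
    base_time = datetime(2020, 1, 1)
    raw_users: list[UserTimeline] = []
    lo, hi = cfg.tweets_per_user
    for idx in range(cfg.n_users):
        cls = int(labels[idx])
        L = int(rng.integers(lo, hi + 1))
        mix = dep_mix if cls == 1 else ctl_mix
        tweets = sorted(
            (_make_tweet(cls, cfg, themes, mix, base_time, rng) for _ in range(L)),
            key=lambda t: t.timestamp,
        )
        raw_users.append(
            UserTimeline(
                user_id=f"u{idx:05d}",
                label=cls,
                tweets=tweets,
                followers=int(rng.integers(10, 5001)),
                friends=int(rng.integers(10, 2000)),
                favourites=int(rng.integers(0, 5000)),
            )
        )

    stop = load_stopwords()
    users = [clean_timeline(u, stop) for u in raw_users]
    labels_df = pd.DataFrame(
        {"label": labels}, index=[u.user_id for u in raw_users]
    )
    labels_df.index.name = "user_id"
    symptom_words = {
        name: sorted(seeds + syns) for name, seeds, syns in SYMPTOM_FAMILIES
    }
    return SyntheticData(
        users=users,
        raw_users=raw_users,
        lexicons=lex,
        embeddings=emb,
        labels=labels_df,
        symptom_words=symptom_words,
        config=cfg,
    )


def write_outputs(data: SyntheticData, out_dir: str | Path) -> dict[str, Path]:
    """Write timelines.jsonl, lexicons/, embeddings.txt and labels.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "timelines": out_dir / "timelines.jsonl",
        "lexicons": out_dir / "lexicons",
        "embeddings": out_dir / "embeddings.txt",
        "labels": out_dir / "labels.tsv",
    }
    write_timelines(data.raw_users, paths["timelines"])
    write_lexicons(data.lexicons, paths["lexicons"])
    write_embeddings(data.embeddings, paths["embeddings"])
    data.labels.to_csv(paths["labels"], sep="\t")
    return paths


def make_probe_users(
    n: int, cfg: SimConfig, seed: int = 0
) -> tuple[list[UserTimeline], list[int]]:
    """Depressed probe users with exactly one symptom-laden tweet.

    Each probe has ten tweets: nine neutral fillers (control-style, no
    symptom words) and one tweet carrying several symptom words, at a
    random position in the timeline.  Returns the cleaned users and, per
    user, the index of the planted tweet among the time-sorted tweets —
    the expected argmax of tweet attention for a model that has learned
    the symptom signal.
    """
    rng = np.random.default_rng(seed)
    _, themes = _build_vocab(cfg)
    base_mix = np.full(N_THEMES, 1.0 / N_THEMES)
    # filler tweets must carry no symptom words at all
    null_cfg = dataclasses.replace(
        cfg.null(), symptom_rate_dep=0.0, symptom_rate_ctl=0.0
    )
    base_time = datetime(2020, 1, 1)
    users: list[UserTimeline] = []
    planted: list[int] = []
    for idx in range(n):
        tweets = [
            _make_tweet(0, null_cfg, themes, base_mix, base_time, rng)
            for _ in range(9)
        ]
        fam = SYMPTOM_FAMILIES[rng.integers(9)]
        words = list(rng.choice(fam[1] + fam[2], size=3)) + [
            str(rng.choice(themes[int(rng.integers(N_THEMES))]))
        ]
        rng.shuffle(words)
        loaded = _make_tweet(0, null_cfg, themes, base_mix, base_time, rng)
        loaded = Tweet(text=" ".join(words), timestamp=loaded.timestamp,
                       is_retweet=False)
        tweets.append(loaded)
        tweets.sort(key=lambda t: t.timestamp)
        users.append(
            UserTimeline(user_id=f"probe{idx:04d}", label=1, tweets=tweets,
                         followers=100, friends=100, favourites=10)
        )
        planted.append(tweets.index(loaded))
    stop = load_stopwords()
    return [clean_timeline(u, stop) for u in users], planted


def planted_signal_check(data: SyntheticData) -> pd.DataFrame:
    """Empirical per-class rates of every planted signal.

    Rates are fractions of tweets exhibiting the signal (at least one
    symptom word / negative emoji / first-person singular token, or a
    night-time posting hour), computed on the cleaned timelines.
    """
    all_symptoms = {w for ws in data.symptom_words.values() for w in ws}
    neg = set(_NEG_EMOJIS)
    fp_s = set(FP_SINGULAR)
    rows = {}
    for cls, name in ((1, "depressed"), (0, "control")):
        n_tweets = 0
        hits = {"symptom_tweet_rate": 0, "neg_emoji_rate": 0,
                "fp_singular_rate": 0, "night_rate": 0}
        for u in data.users:
            if u.label != cls:
                continue
            for t in u.tweets:
                n_tweets += 1
                toks = set(t.tokens)
                hits["symptom_tweet_rate"] += bool(toks & all_symptoms)
                hits["neg_emoji_rate"] += bool(set(t.emoji_list) & neg)
                hits["fp_singular_rate"] += bool(toks & fp_s)
                hits["night_rate"] += t.timestamp.hour < 6
        rows[name] = {k: v / max(1, n_tweets) for k, v in hits.items()}
        rows[name]["n_tweets"] = n_tweets
    return pd.DataFrame(rows).T
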