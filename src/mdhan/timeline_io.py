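"""Reading, writing, filtering and cleaning of user timelines.

A *timeline* is one social-media user's ordered sequence of posts ("tweets")
together with a few profile statistics (followers, friends, favourites) and,
for labelled data, a binary depression label (1 = depressed, 0 = control).

On disk a timeline collection is JSON-lines: one user object per line,

    {"user_id": str, "label": 0|1|null, "followers": int, "friends": int,
     "favourites": int,
     "tweets": [{"text": str, "created_at": ISO-8601, "is_retweet": bool}]}

This module also loads GloVe-format text embeddings and the lexicon bundle
(emoji polarity, valence/arousal/dominance norms, first-person word lists,
the nine depression-symptom seed lists, antidepressant names), and
round-trips feature matrices through TSV.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from dataclasses import dataclass, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Number of symptom groups in the diagnostic criteria used for counting.
N_SYMPTOM_GROUPS = 9

_STOPWORD_FILE = Path(__file__).parent / "data" / "stopwords.txt"

# Tokens are split on anything that is not a word character or an apostrophe;
# apostrophes are kept so contractions ("don't") survive as single tokens.
_TOKEN_SPLIT = re.compile(r"[^\w']+")


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Load the stopword list (bundled default, or a user-supplied file)."""
    p = Path(path) if path is not None else _STOPWORD_FILE
    words = set()
    for line in p.read_text(encoding="utf-8").splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


def _is_emoji_char(ch: str) -> bool:
    """True for characters in the common emoji / pictograph code ranges."""
    cp = ord(ch)
    return (
        0x1F000 <= cp <= 0x1FAFF  # pictographs, emoticons, symbols
        or 0x2600 <= cp <= 0x27BF  # misc symbols + dingbats (incl. ☹ ☀ ✊)
        or cp in (0x2B50, 0x2B55)
        or 0x1F1E6 <= cp <= 0x1F1FF  # regional indicators
        or unicodedata.category(ch) == "So"
    )


@dataclass
class Tweet:
    """One post: raw text plus derived tokens and extracted emojis."""

    text: str
    timestamp: datetime
    is_retweet: bool = False
    tokens: tuple[str, ...] = ()
    emoji_list: tuple[str, ...] = ()


@dataclass
class UserTimeline:
    """One user's profile statistics, label and time-ordered tweets."""

    user_id: str
    label: int | None
    tweets: list[Tweet]
    followers: int = 0
    friends: int = 0
    favourites: int = 0

    @property
    def n_tweets(self) -> int:
        return len(self.tweets)


def clean_tokenize(tweet: Tweet, stopwords: frozenset[str]) -> Tweet:
    """Tokenize a tweet: extract emojis, lowercase, split, drop stopwords
    and any token containing a non-ASCII character.

    Emojis are pulled out *before* the ASCII filter so they survive into
    ``emoji_list``; the raw text is preserved unchanged.
    """
    emojis = tuple(ch for ch in tweet.text if _is_emoji_char(ch))
    toks = []
    for raw in _TOKEN_SPLIT.split(tweet.text.lower()):
        tok = raw.strip("'_")
        if not tok or tok in stopwords:
            continue
        if any(ord(c) > 127 for c in tok):
            continue
        toks.append(tok)
    return replace(tweet, tokens=tuple(toks), emoji_list=emojis)


def clean_timeline(user: UserTimeline, stopwords: frozenset[str]) -> UserTimeline:
    """Apply :func:`clean_tokenize` to every tweet of a user."""
    return replace(user, tweets=[clean_tokenize(t, stopwords) for t in user.tweets])


def filter_users(
    users: Sequence[UserTimeline],
    min_posts: int = 10,
    max_followers: int = 5000,
) -> list[UserTimeline]:
    """Retain users with at least ``min_posts`` tweets and at most
    ``max_followers`` followers (drops celebrity/bot-like accounts).

    Order is preserved; the operation is idempotent.
    """
    return [
        u
        for u in users
        if u.n_tweets >= min_posts and u.followers <= max_followers
    ]


# ---------------------------------------------------------------------------
# JSONL timelines
# ---------------------------------------------------------------------------


def _parse_record(obj: Mapping) -> UserTimeline:
    tweets = [
        Tweet(
            text=str(t["text"]),
            timestamp=datetime.fromisoformat(str(t["created_at"])),
            is_retweet=bool(t.get("is_retweet", False)),
        )
        for t in obj["tweets"]
    ]
    tweets.sort(key=lambda t: t.timestamp)
    label = obj.get("label")
    return UserTimeline(
        user_id=str(obj["user_id"]),
        label=None if label is None else int(label),
        tweets=tweets,
        followers=int(obj.get("followers", 0)),
        friends=int(obj.get("friends", 0)),
        favourites=int(obj.get("favourites", 0)),
    )


def load_timelines(path: str | Path) -> tuple[list[UserTimeline], int]:
    """Parse a JSONL timeline file.

    Returns ``(users, n_malformed)``.  Malformed lines are skipped with a
    logged warning; duplicate user ids keep the first occurrence.  An
    unreadable file raises ``OSError``.
    """
    path = Path(path)
    users: list[UserTimeline] = []
    seen: set[str] = set()
    n_malformed = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = _parse_record(json.loads(line))
            except Exception as exc:  # malformed line: count, warn, continue
                n_malformed += 1
                logger.warning("%s:%d malformed line skipped (%s)", path, lineno, exc)
                continue
            if rec.user_id in seen:
                logger.warning("%s:%d duplicate user %r dropped", path, lineno, rec.user_id)
                continue
            seen.add(rec.user_id)
            users.append(rec)
    if not users:
        logger.warning("%s contained no valid timeline records", path)
    return users, n_malformed


def read_timelines(path: str | Path) -> list[UserTimeline]:
    """Like :func:`load_timelines` but returns only the parsed users."""
    return load_timelines(path)[0]


def write_timelines(users: Iterable[UserTimeline], path: str | Path) -> None:
    """Write timelines as JSONL (inverse of :func:`read_timelines`)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for u in users:
            obj = {
                "user_id": u.user_id,
                "label": u.label,
                "followers": u.followers,
                "friends": u.friends,
                "favourites": u.favourites,
                "tweets": [
                    {
                        "text": t.text,
                        "created_at": t.timestamp.isoformat(),
                        "is_retweet": t.is_retweet,
                    }
                    for t in u.tweets
                ],
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# Embeddings
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingTable:
    """Word → vector map in GloVe text-file format.

    ``oov_policy`` controls lookups of absent words: ``"zero"`` returns the
    zero vector, ``"seeded-random"`` returns a reproducible random vector
    derived from the word and ``oov_seed``.
    """

    dim: int
    vectors: dict[str, np.ndarray]
    oov_policy: str = "zero"
    oov_seed: int = 0

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def lookup(self, word: str) -> np.ndarray:
        vec = self.vectors.get(word)
        if vec is not None:
            return vec
        if self.oov_policy == "zero":
            return np.zeros(self.dim)
        # Stable per-word randomness: hash the word together with the seed.
        h = abs(hash((self.oov_seed, word))) % (2**32)
        rng = np.random.default_rng(h)
        return rng.normal(scale=0.1, size=self.dim)

    def matrix(self, words: Sequence[str]) -> np.ndarray:
        return np.stack([self.lookup(w) for w in words]) if words else np.zeros((0, self.dim))


def read_embeddings(
    path: str | Path, oov_policy: str = "zero", oov_seed: int = 0
) -> EmbeddingTable:
    """Read a GloVe-format text file (word then floats, space-separated).

    Duplicate words keep the first occurrence; an inconsistent vector length
    is fatal and reports the offending line number.
    """
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            word, vals = parts[0], parts[1:]
            vec = np.asarray([float(v) for v in vals])
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise ValueError(
                    f"{path}:{lineno}: vector for {word!r} has length "
                    f"{vec.size}, expected {dim}"
                )
            vectors.setdefault(word, vec)
    if dim is None:
        raise ValueError(f"{path}: no embedding vectors found")
    return EmbeddingTable(dim=dim, vectors=vectors, oov_policy=oov_policy, oov_seed=oov_seed)


def write_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for word, vec in table.vectors.items():
            fh.write(word + " " + " ".join(repr(float(v)) for v in vec) + "\n")


# ---------------------------------------------------------------------------
# Lexicons
# ---------------------------------------------------------------------------


@dataclass
class Lexicons:
    """Lexical resources used by the aspect-feature extractors."""

    emoji_polarity: dict[str, str]  # emoji -> positive|neutral|negative
    vad: dict[str, tuple[float, float, float]]  # word -> (valence, arousal, dominance)
    fp_singular: frozenset[str]
    fp_plural: frozenset[str]
    symptom_seeds: dict[str, list[str]]  # 9 named symptom groups
    antidepressants: frozenset[str]

    @property
    def symptom_names(self) -> list[str]:
        return list(self.symptom_seeds)


_LEXICON_FILES = ("emoji.json", "vad.json", "fp.json", "symptoms.json", "antidepressants.json")


def read_lexicons(
    dir_path: str | Path, stopwords: frozenset[str] | None = None
) -> Lexicons:
    """Load the five lexicon JSON files from a directory.

    A missing file is fatal and the error names it.  ``symptoms.json`` must
    contain exactly nine named lists, disjoint from the stopword list.
    """
    dir_path = Path(dir_path)
    raw: dict[str, object] = {}
    for fname in _LEXICON_FILES:
        fpath = dir_path / fname
        if not fpath.exists():
            raise FileNotFoundError(f"required lexicon file missing: {fname}")
        raw[fname] = json.loads(fpath.read_text(encoding="utf-8"))

    symptoms = {str(k): [str(w).lower() for w in v] for k, v in raw["symptoms.json"].items()}
    if len(symptoms) != N_SYMPTOM_GROUPS:
        raise ValueError(
            f"symptoms.json must define exactly {N_SYMPTOM_GROUPS} symptom "
            f"groups, found {len(symptoms)}"
        )
    if stopwords:
        clash = {w for ws in symptoms.values() for w in ws} & set(stopwords)
        if clash:
            raise ValueError(f"symptom seed words collide with stopwords: {sorted(clash)}")

    vad = {str(w).lower(): tuple(float(x) for x in v) for w, v in raw["vad.json"].items()}
    if not vad:
        raise ValueError("vad.json must contain at least one entry")
    fp = raw["fp.json"]
    return Lexicons(
        emoji_polarity={str(k): str(v) for k, v in raw["emoji.json"].items()},
        vad=vad,  # type: ignore[arg-type]
        fp_singular=frozenset(str(w).lower() for w in fp["singular"]),
        fp_plural=frozenset(str(w).lower() for w in fp["plural"]),
        symptom_seeds=symptoms,
        antidepressants=frozenset(str(w).lower() for w in raw["antidepressants.json"]),
    )


def write_lexicons(lex: Lexicons, dir_path: str | Path) -> None:
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    (dir_path / "emoji.json").write_text(
        json.dumps(lex.emoji_polarity, ensure_ascii=False, indent=1), encoding="utf-8"
    )
    (dir_path / "vad.json").write_text(
        json.dumps({w: list(v) for w, v in lex.vad.items()}, indent=1), encoding="utf-8"
    )
    (dir_path / "fp.json").write_text(
        json.dumps({"singular": sorted(lex.fp_singular), "plural": sorted(lex.fp_plural)}),
        encoding="utf-8",
    )
    (dir_path / "symptoms.json").write_text(
        json.dumps(lex.symptom_seeds, indent=1), encoding="utf-8"
    )
    (dir_path / "antidepressants.json").write_text(
        json.dumps(sorted(lex.antidepressants)), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    """Write a user × feature matrix as TSV.

    The index holds user ids; column names are ``block:name`` so the aspect
    block of every column is recoverable.  Floats are written with ``repr``
    precision so the round-trip is bit-exact.
    """
    df = features.copy()
    df.index.name = "user_id"
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("user_id\t" + "\t".join(map(str, df.columns)) + "\n")
        for uid, row in df.iterrows():
            fh.write(str(uid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="user_id", float_precision="round_trip")
    df.index = df.index.astype(str)
    return df


# ---------------------------------------------------------------------------
# Dataset summary
# ---------------------------------------------------------------------------


def _truncate_pct(x: float, digits: int = 2) -> float:
    scale = 10**digits
    return int(x * 100 * scale) / scale


def summarize_labels(n_depressed: int, n_control: int) -> dict[str, float]:
    """Summary statistics of a labelled cohort.

    Percentage shares are reported truncated (not rounded) to two decimal
    places, matching the convention of published dataset tables.
    """
    total = n_depressed + n_control
    return {
        "n_depressed": n_depressed,
        "n_control": n_control,
        "total_users": total,
        "depressed_share_pct": _truncate_pct(n_depressed / total),
        "control_share_pct": _truncate_pct(n_control / total),
    }


def summarize_users(users: Sequence[UserTimeline]) -> dict[str, float]:
    """:func:`summarize_labels` computed from a list of labelled users."""
    n_dep = sum(1 for u in users if u.label == 1)
    n_ctl = sum(1 for u in users if u.label == 0)
    return summarize_labels(n_dep, n_ctl)
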