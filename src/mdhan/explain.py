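"""Attention-based explanations and symptom term-frequency tables.

The attention weights the classifier used for pooling are reported as-is:
an explanation is the very ``alpha`` vector of the prediction's forward
pass, never a re-computation, so explanations are faithful by
construction.  Tweets emptied by cleaning are excluded from reports (any
weight they carry is a padding artifact).
"""

from __future__ import annotations

import html
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .aspects import symptom_counts
from .model import MDHAN, EncodedUser
from .timeline_io import EmbeddingTable, UserTimeline

logger = logging.getLogger(__name__)


@dataclass
class AttentionRecord:
    """One user's prediction with its attention-weight explanation.

    ``tweet_attn[i]`` and ``word_attn[i]`` refer to the i-th retained
    tweet (most recent ``max_tweets``, skipping tweets with no tokens);
    ``top_tweets`` ranks those indices by attention, ties broken toward
    the earlier tweet.
    """

    user_id: str
    score: float
    tweet_texts: list[str]
    tweet_tokens: list[list[str]]
    tweet_attn: np.ndarray
    word_attn: list[np.ndarray]
    top_tweets: list[int]


def _stable_ranking(weights: np.ndarray) -> list[int]:
    # descending by weight, ascending by index on ties
    return sorted(range(len(weights)), key=lambda i: (-weights[i], i))


def explain_user(
    model: MDHAN,
    user: UserTimeline,
    emb: EmbeddingTable,
    m_feat: np.ndarray | None = None,
) -> AttentionRecord:
    """Extract the attention explanation for one user from a forward pass."""
    if not user.tweets:
        raise ValueError(f"user {user.user_id!r} has an empty timeline")
    if not model.config.uses_text:
        raise ValueError("the aspect-only variant has no attention to explain")
    enc: EncodedUser = model.encode_user(user, emb, m_feat)
    if enc.tweet_attn is None:
        raise ValueError("tweet attention unavailable (max-pooled tweet states)")
    kept = user.tweets[-model.config.max_tweets :]
    keep_idx = [i for i, t in enumerate(kept) if t.tokens]
    if not keep_idx:
        raise ValueError(f"user {user.user_id!r} has no tokens after cleaning")
    tweet_attn = enc.tweet_attn[keep_idx]
    word_attn = [enc.word_attn[i] for i in keep_idx]
    return AttentionRecord(
        user_id=user.user_id,
        score=enc.score,
        tweet_texts=[kept[i].text for i in keep_idx],
        tweet_tokens=[list(kept[i].tokens[: model.config.max_words]) for i in keep_idx],
        tweet_attn=tweet_attn,
        word_attn=word_attn,
        top_tweets=_stable_ranking(tweet_attn),
    )


# ---------------------------------------------------------------------------
# HTML report
# ---------------------------------------------------------------------------

_CSS = """
body { font-family: sans-serif; max-width: 60em; margin: 2em auto; }
.tweet { margin: 0.4em 0; padding: 0.4em; border-radius: 4px; }
.word { padding: 0 2px; border-radius: 2px; }
.meta { color: #555; font-size: 0.9em; }
"""


def _red(intensity: float) -> str:
    """White→red scale, monotone in intensity ∈ [0, 1]."""
    v = int(round(255 * (1.0 - 0.85 * min(max(intensity, 0.0), 1.0))))
    return f"rgb(255,{v},{v})"


def render_report(
    records: Sequence[AttentionRecord], out_path: str | Path
) -> tuple[Path, Path]:
    """Write a self-contained HTML attention map plus a JSON sidecar.

    Colour intensity is monotone in attention weight (each weight scaled
    by the maximum of its own softmax row).  The sidecar carries the exact
    numeric weights.
    """
    if not records:
        raise ValueError("no attention records to render")
    out_path = Path(out_path)
    parts = [f"<!DOCTYPE html><html><head><meta charset='utf-8'>"
             f"<title>Attention report</title><style>{_CSS}</style></head><body>"]
    sidecar = []
    for rec in records:
        parts.append(f"<h2>User {html.escape(rec.user_id)}</h2>")
        parts.append(f"<p class='meta'>predicted probability of depression: "
                     f"{rec.score:.4f}</p>")
        t_max = float(rec.tweet_attn.max()) or 1.0
        for i in rec.top_tweets:
            t_w = float(rec.tweet_attn[i])
            w_max = float(rec.word_attn[i].max()) if len(rec.word_attn[i]) else 1.0
            words = "".join(
                f"<span class='word' style='background:{_red(float(w) / w_max if w_max else 0.0)}'>"
                f"{html.escape(tok)}</span> "
                for tok, w in zip(rec.tweet_tokens[i], rec.word_attn[i])
            )
            parts.append(
                f"<div class='tweet' style='border-left: 12px solid {_red(t_w / t_max)}'>"
                f"<span class='meta'>α={t_w:.4f}</span> {words}</div>"
            )
        sidecar.append(
            {
                "user_id": rec.user_id,
                "score": rec.score,
                "tweet_attn": [float(w) for w in rec.tweet_attn],
                "word_attn": [[float(w) for w in ws] for ws in rec.word_attn],
                "top_tweets": rec.top_tweets,
            }
        )
    parts.append("</body></html>")
    out_path.write_text("\n".join(parts), encoding="utf-8")
    json_path = out_path.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar, indent=1), encoding="utf-8")
    return out_path, json_path


# ---------------------------------------------------------------------------
# Symptom term tables
# ---------------------------------------------------------------------------


def symptom_term_table(
    users: Sequence[UserTimeline],
    expanded: Mapping[str, Sequence[str]],
    top_n: int = 5,
) -> dict[str, list[tuple[str, int]]]:
    """Frequency tables of words co-occurring with the top symptoms.

    Selects the ``top_n`` symptom groups by aggregate mention count over
    the given (typically predicted-depressed) users; for each, returns the
    frequency-sorted co-occurring tweet words (the data behind a word
    cloud).  ``top_n`` is clamped to the number of symptom groups.
    """
    names = list(expanded)
    if top_n > len(names):
        logger.warning("top_n=%d clamped to %d symptom groups", top_n, len(names))
        top_n = len(names)
    totals = np.zeros(len(names))
    for u in users:
        totals += symptom_counts(u, expanded)
    top = [names[i] for i in np.argsort(-totals, kind="stable")[:top_n]]

    sets = {g: frozenset(expanded[g]) for g in top}
    freq: dict[str, dict[str, int]] = {g: {} for g in top}
    for u in users:
        for t in u.tweets:
            toks = list(t.tokens)
            for g, ws in sets.items():
                if any(w in ws for w in toks):
                    for w in toks:
                        if w not in ws:
                            freq[g][w] = freq[g].get(w, 0) + 1
    return {
        g: sorted(freq[g].items(), key=lambda kv: (-kv[1], kv[0])) for g in top
    }
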