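"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive — plain Python loops over tweets and
tokens, a step-by-step scalar GRU — and shares no code with the package's
vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# Aspect-feature recounts
# ---------------------------------------------------------------------------


def recount_social(user):
    vec = [0.0] * 30
    vec[0] = len(user.tweets)
    for t in user.tweets:
        vec[1] += len(t.text)
        if t.is_retweet:
            vec[2] += 1
        vec[6 + t.timestamp.hour] += 1
    vec[3], vec[4], vec[5] = user.followers, user.friends, user.favourites
    return np.array(vec)


def recount_emoji_vad(user, lex):
    pos = neu = neg = 0
    v = a = d = 0.0
    fps = fpp = 0
    for t in user.tweets:
        for e in t.emoji_list:
            p = lex.emoji_polarity.get(e, "neutral")
            if p == "positive":
                pos += 1
            elif p == "negative":
                neg += 1
            else:
                neu += 1
        for w in t.tokens:
            if w in lex.vad:
                v += lex.vad[w][0]
                a += lex.vad[w][1]
                d += lex.vad[w][2]
            if w in lex.fp_singular:
                fps += 1
            elif w in lex.fp_plural:
                fpp += 1
    return np.array([pos, neu, neg, v, a, d, fps, fpp])


def recount_symptoms(user, expanded):
    out = []
    for name in expanded:
        ws = set(expanded[name])
        c = 0
        for t in user.tweets:
            for w in t.tokens:
                if w in ws:
                    c += 1
        out.append(c)
    return np.array(out, dtype=float)


def recount_antidepressants(user, lex):
    c = 0
    for t in user.tweets:
        toks = list(t.tokens)
        for name in lex.antidepressants:
            gram = name.split()
            for i in range(len(toks) - len(gram) + 1):
                if toks[i : i + len(gram)] == gram:
                    c += 1
    return c


# ---------------------------------------------------------------------------
# Naive forward pass of the hierarchical attention network
# ---------------------------------------------------------------------------


def _sig(x):
    return 1.0 / (1.0 + math.exp(-x)) if x >= 0 else math.exp(x) / (1.0 + math.exp(x))


def naive_gru_sequence(p, xs):
    """Scalar-loop GRU over a list of input vectors; returns all states."""
    d = p["Uhr"].shape[0]
    h = np.zeros(d)
    states = []
    for x in xs:
        r = np.array([_sig(v) for v in x @ p["Wxr"] + h @ p["Uhr"] + p["br"]])
        z = np.array([_sig(v) for v in x @ p["Wxz"] + h @ p["Uhz"] + p["bz"]])
        n = np.tanh(x @ p["Wxn"] + r * (h @ p["Uhn"] + p["bn"]))
        h = (1 - z) * n + z * h
        states.append(h.copy())
    return states


def naive_bigru(pf, pb, xs):
    fwd = naive_gru_sequence(pf, xs)
    bwd = naive_gru_sequence(pb, xs[::-1])[::-1]
    return [np.concatenate([f, b]) for f, b in zip(fwd, bwd)]


def naive_attention(p, hs):
    scores = [float(np.tanh(h @ p["W"] + p["b"]) @ p["u"]) for h in hs]
    mx = max(scores)
    ex = [math.exp(s - mx) for s in scores]
    total = sum(ex)
    alpha = [e / total for e in ex]
    pooled = sum(a * h for a, h in zip(alpha, hs))
    return pooled, alpha


def naive_forward(params, config, user_tweets, m_feat):
    """Full scalar re-implementation of the fused classifier forward pass.

    ``user_tweets`` is a list of (n_words, embed_dim) arrays for one user;
    ``params`` is the model's flat parameter dict.
    """

    def sub(prefix):
        return {k.split(".", 1)[1]: v for k, v in params.items() if k.startswith(prefix + ".")}

    vs = []
    for mat in user_tweets:
        if mat.shape[0] == 0:
            vs.append(np.zeros(2 * config.hidden_dim))
            continue
        hs = naive_bigru(sub("wf"), sub("wb"), list(mat))
        v, _ = naive_attention(sub("wa"), hs)
        vs.append(v)
    hts = naive_bigru(sub("tf"), sub("tb"), vs)
    s, alpha_t = naive_attention(sub("ta"), hts)

    parts = []
    if m_feat is not None:
        p_vec = np.maximum(m_feat @ params["mlp.W"] + params["mlp.b"], 0.0)
        parts.append(p_vec)
    parts.append(s)
    fused = np.concatenate(parts)
    logit = float(fused @ params["out.W"][:, 0] + params["out.b"][0])
    return _sig(logit), alpha_t
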