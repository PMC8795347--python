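"""Minimal NumPy neural-network primitives with hand-derived gradients.

Implements exactly the pieces the classifier needs — GRU steps over masked
padded sequences, tanh attention pooling, dense layers, inverted dropout
and Adam — with explicit forward caches and backward passes.  Gradients are
validated against finite differences in the test suite.

Conventions: sequences are padded at the end; a mask entry of 1 marks a
real position.  At masked steps the recurrent state is carried through
unchanged, so trailing padding can never influence the output.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy.special import expit as sigmoid


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


# ---------------------------------------------------------------------------
# GRU
# ---------------------------------------------------------------------------


def gru_init(rng: np.random.Generator, d_in: int, d_hid: int) -> dict[str, np.ndarray]:
    """Parameters of a single-direction GRU (reset r, update z, candidate n)."""
    p = {}
    for gate in ("r", "z", "n"):
        p[f"Wx{gate}"] = glorot(rng, d_in, d_hid)
        p[f"Uh{gate}"] = glorot(rng, d_hid, d_hid)
        p[f"b{gate}"] = np.zeros(d_hid)
    return p


def gru_forward(
    params: Mapping[str, np.ndarray],
    x: np.ndarray,  # (B, T, d_in)
    mask: np.ndarray,  # (B, T) in {0,1}
    reverse: bool = False,
) -> tuple[np.ndarray, dict]:
    """Run a GRU over time; returns hidden states (B, T, d_hid) and a cache.

    ``reverse=True`` processes the sequence back-to-front (the returned
    array is still indexed in natural time order).  Masked steps carry the
    previous state through unchanged.

    The three gates are computed fused: the input projection for all
    timesteps is one matmul hoisted out of the loop, and the recurrent
    projection is one matmul per step.
    """
    B, T, _ = x.shape
    d = params["Uhr"].shape[0]
    Wx = np.concatenate([params["Wxr"], params["Wxz"], params["Wxn"]], axis=1)
    Uh = np.concatenate([params["Uhr"], params["Uhz"], params["Uhn"]], axis=1)
    bx = np.concatenate([params["br"], params["bz"], np.zeros(d)])
    bn = params["bn"]
    Xp = x @ Wx + bx  # (B, T, 3d)

    h = np.zeros((B, d))
    hs = np.zeros((B, T, d))
    R = np.zeros((T, B, d))
    Z = np.zeros((T, B, d))
    Nc = np.zeros((T, B, d))
    G = np.zeros((T, B, d))
    Hp = np.zeros((T, B, d))  # h_{t-1} in processing order
    order = list(range(T - 1, -1, -1) if reverse else range(T))
    for t in order:
        hp = h @ Uh  # (B, 3d)
        r = sigmoid(Xp[:, t, :d] + hp[:, :d])
        z = sigmoid(Xp[:, t, d : 2 * d] + hp[:, d : 2 * d])
        g = hp[:, 2 * d :] + bn
        n = np.tanh(Xp[:, t, 2 * d :] + r * g)
        m = mask[:, t][:, None]
        Hp[t], R[t], Z[t], Nc[t], G[t] = h, r, z, n, g
        h = m * ((1.0 - z) * n + z * h) + (1.0 - m) * h
        hs[:, t] = h
    cache = {
        "R": R, "Z": Z, "N": Nc, "G": G, "Hp": Hp, "x": x, "mask": mask,
        "order": order, "Wx": Wx, "Uh": Uh, "d": d,
    }
    return hs, cache


def gru_backward(
    dhs: np.ndarray,  # (B, T, d) gradient w.r.t. every output state
    cache: dict,
    need_dx: bool = True,
) -> tuple[dict[str, np.ndarray], np.ndarray | None]:
    """Backpropagate through :func:`gru_forward`.

    Returns parameter gradients and (optionally) the gradient w.r.t. the
    input sequence.
    """
    x, mask, order = cache["x"], cache["mask"], cache["order"]
    Wx, Uh, d = cache["Wx"], cache["Uh"], cache["d"]
    R, Z, Nc, G, Hp = cache["R"], cache["Z"], cache["N"], cache["G"], cache["Hp"]
    B, T, d_in = x.shape
    dXp = np.zeros((B, T, 3 * d))  # grads w.r.t. the input projection
    Dpre3 = np.zeros((T, B, 3 * d))  # grads w.r.t. the recurrent projection
    dh = np.zeros((B, d))
    for t in reversed(order):
        m = mask[:, t][:, None]
        dh_t = dh + dhs[:, t]
        dh_new = m * dh_t
        r, z, n, g, h_prev = R[t], Z[t], Nc[t], G[t], Hp[t]
        dn = dh_new * (1.0 - z)
        dz = dh_new * (h_prev - n)
        dh_prev = dh_new * z
        dn_pre = dn * (1.0 - n * n)
        dg = dn_pre * r
        dr = dn_pre * g
        dz_pre = dz * z * (1.0 - z)
        dr_pre = dr * r * (1.0 - r)
        dpre3 = np.concatenate([dr_pre, dz_pre, dg], axis=1)
        Dpre3[t] = dpre3
        dXp[:, t, :d] = dr_pre
        dXp[:, t, d : 2 * d] = dz_pre
        dXp[:, t, 2 * d :] = dn_pre
        dh = dh_prev + dpre3 @ Uh.T + (1.0 - m) * dh_t

    gWx = x.reshape(-1, d_in).T @ dXp.reshape(-1, 3 * d)
    gUh = Hp.reshape(-1, d).T @ Dpre3.reshape(-1, 3 * d)
    grads = {
        "Wxr": gWx[:, :d], "Wxz": gWx[:, d : 2 * d], "Wxn": gWx[:, 2 * d :],
        "Uhr": gUh[:, :d], "Uhz": gUh[:, d : 2 * d], "Uhn": gUh[:, 2 * d :],
        "br": dXp[:, :, :d].sum(axis=(0, 1)),
        "bz": dXp[:, :, d : 2 * d].sum(axis=(0, 1)),
        "bn": Dpre3[:, :, 2 * d :].sum(axis=(0, 1)),
    }
    dx = (dXp.reshape(-1, 3 * d) @ Wx.T).reshape(B, T, d_in) if need_dx else None
    return grads, dx


def bigru_forward(
    params_f: Mapping[str, np.ndarray],
    params_b: Mapping[str, np.ndarray],
    x: np.ndarray,
    mask: np.ndarray,
) -> tuple[np.ndarray, dict]:
    """Forward and backward GRU states concatenated per position (B,T,2d)."""
    hf, cf = gru_forward(params_f, x, mask, reverse=False)
    hb, cb = gru_forward(params_b, x, mask, reverse=True)
    return np.concatenate([hf, hb], axis=2), {"cf": cf, "cb": cb, "d": hf.shape[2]}


def bigru_backward(
    dh: np.ndarray, cache: dict, need_dx: bool = True
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], np.ndarray | None]:
    d = cache["d"]
    gf, dxf = gru_backward(dh[:, :, :d], cache["cf"], need_dx)
    gb, dxb = gru_backward(dh[:, :, d:], cache["cb"], need_dx)
    dx = dxf + dxb if need_dx else None
    return gf, gb, dx


# ---------------------------------------------------------------------------
# Attention pooling
# ---------------------------------------------------------------------------


def attention_init(rng: np.random.Generator, d_in: int, d_attn: int) -> dict[str, np.ndarray]:
    return {
        "W": glorot(rng, d_in, d_attn),
        "b": np.zeros(d_attn),
        "u": glorot(rng, d_attn, 1)[:, 0],
    }


def attention_forward(
    params: Mapping[str, np.ndarray],
    h: np.ndarray,  # (B, T, d_in)
    mask: np.ndarray,  # (B, T)
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Tanh-projection attention: scores u·tanh(Wh+b), masked softmax, pool.

    Returns the pooled vectors (B, d_in), the attention weights (B, T) —
    rows with no real positions get all-zero weights — and a cache.
    """
    u = np.tanh(h @ params["W"] + params["b"])  # (B, T, a)
    scores = u @ params["u"]  # (B, T)
    neg = np.where(mask > 0, 0.0, -np.inf)
    shifted = scores + neg
    mx = np.max(shifted, axis=1, keepdims=True)
    mx = np.where(np.isfinite(mx), mx, 0.0)  # rows with no real positions
    ex = np.exp(shifted - mx)
    ex = np.where(mask > 0, ex, 0.0)
    denom = ex.sum(axis=1, keepdims=True)
    alpha = np.divide(ex, denom, out=np.zeros_like(ex), where=denom > 0)
    pooled = (alpha[:, None, :] @ h)[:, 0, :]
    return pooled, alpha, {"u_proj": u, "alpha": alpha, "h": h, "params": params}


def attention_backward(
    dpooled: np.ndarray, cache: dict
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Gradients of attention pooling w.r.t. parameters and input states."""
    params, alpha, h, u = cache["params"], cache["alpha"], cache["h"], cache["u_proj"]
    dalpha = (h @ dpooled[:, :, None])[:, :, 0]
    dh = alpha[:, :, None] * dpooled[:, None, :]
    # softmax backward (rows of zeros stay zero)
    ds = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
    du_proj = ds[:, :, None] * params["u"][None, None, :]
    dpre = du_proj * (1.0 - u * u)
    a = u.shape[2]
    grads = {
        "u": (ds[:, None, :] @ u)[:, 0, :].sum(axis=0),
        "W": h.reshape(-1, h.shape[2]).T @ dpre.reshape(-1, a),
        "b": dpre.sum(axis=(0, 1)),
    }
    dh = dh + dpre @ params["W"].T
    return grads, dh


# ---------------------------------------------------------------------------
# Dense / dropout / loss
# ---------------------------------------------------------------------------


def dense_init(rng: np.random.Generator, d_in: int, d_out: int) -> dict[str, np.ndarray]:
    return {"W": glorot(rng, d_in, d_out), "b": np.zeros(d_out)}


def dense_forward(params, x):
    return x @ params["W"] + params["b"], {"x": x, "params": params}


def dense_backward(dy, cache):
    x, params = cache["x"], cache["params"]
    grads = {"W": x.T @ dy, "b": dy.sum(axis=0)}
    return grads, dy @ params["W"].T


def relu_forward(x):
    out = np.maximum(x, 0.0)
    return out, {"mask": x > 0}


def relu_backward(dy, cache):
    return dy * cache["mask"]


def dropout_forward(x, rate: float, rng: np.random.Generator | None, train: bool):
    """Inverted dropout; identity when not training or rate == 0."""
    if not train or rate <= 0.0 or rng is None:
        return x, None
    keep = rng.random(x.shape) >= rate
    scale = 1.0 / (1.0 - rate)
    return x * keep * scale, keep * scale


def dropout_backward(dy, mask):
    return dy if mask is None else dy * mask


def bce_loss(y_hat: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logit.

    ``y_hat`` are sigmoid probabilities; the returned gradient is with
    respect to the pre-sigmoid score (the usual (p - y)/B form).
    """
    p = np.clip(y_hat, eps, 1.0 - eps)
    loss = float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    dlogit = (p - y) / y.shape[0]
    return loss, dlogit


class Adam:
    """Adam optimizer over a flat dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
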