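"""Minimal numpy neural layers with hand-written gradients.

Provides exactly what the decision scorers need: a one-hidden-layer tanh
feedforward network, a GRU (and a simple Elman cell as the non-gated
alternative), softmax cross-entropy with support masks, and Adam.
Parameters live in a flat ``dict[str, np.ndarray]``; gradients accumulate
in a mirror dict.  Everything is float64 and single-example (the models
here are small; determinism matters more than throughput).
"""

from __future__ import annotations

import numpy as np

NEG_INF = -np.inf


def init_params(rng: np.random.Generator) -> dict:
    return {}


def _glorot(rng, fan_in, fan_out):
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


def zeros_like_params(P: dict) -> dict:
    return {k: np.zeros_like(v) for k, v in P.items()}


# ---------------------------------------------------------------------------
# embeddings


def init_embedding(P: dict, rng, name: str, n_rows: int, dim: int, scale=0.1):
    P[name] = rng.normal(0.0, scale, size=(n_rows, dim))


# ---------------------------------------------------------------------------
# MLP: out = W2 @ tanh(W1 x + b1) + b2


def init_mlp(P: dict, rng, name: str, d_in: int, d_hid: int, d_out: int):
    P[f"{name}.W1"] = _glorot(rng, d_in, d_hid)
    P[f"{name}.b1"] = np.zeros(d_hid)
    P[f"{name}.W2"] = _glorot(rng, d_hid, d_out)
    P[f"{name}.b2"] = np.zeros(d_out)


def mlp_forward(P: dict, name: str, x: np.ndarray):
    a = np.tanh(x @ P[f"{name}.W1"] + P[f"{name}.b1"])
    out = a @ P[f"{name}.W2"] + P[f"{name}.b2"]
    return out, (x, a)


def mlp_backward(P: dict, G: dict, name: str, dout: np.ndarray, cache):
    x, a = cache
    G[f"{name}.W2"] += np.outer(a, dout)
    G[f"{name}.b2"] += dout
    da = P[f"{name}.W2"] @ dout
    dz = (1.0 - a * a) * da
    G[f"{name}.W1"] += np.outer(x, dz)
    G[f"{name}.b1"] += dz
    return P[f"{name}.W1"] @ dz


# ---------------------------------------------------------------------------
# recurrent cells


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def init_gru(P: dict, rng, name: str, d_in: int, d_hid: int):
    for gate in ("z", "r", "c"):
        P[f"{name}.W{gate}"] = _glorot(rng, d_in, d_hid)
        P[f"{name}.U{gate}"] = _glorot(rng, d_hid, d_hid)
        P[f"{name}.b{gate}"] = np.zeros(d_hid)


def gru_step(P: dict, name: str, x: np.ndarray, h: np.ndarray):
    z = _sigmoid(x @ P[f"{name}.Wz"] + h @ P[f"{name}.Uz"] + P[f"{name}.bz"])
    r = _sigmoid(x @ P[f"{name}.Wr"] + h @ P[f"{name}.Ur"] + P[f"{name}.br"])
    rh = r * h
    c = np.tanh(x @ P[f"{name}.Wc"] + rh @ P[f"{name}.Uc"] + P[f"{name}.bc"])
    h_new = (1.0 - z) * h + z * c
    return h_new, (x, h, z, r, rh, c)


def gru_step_backward(P: dict, G: dict, name: str, dh_new: np.ndarray, cache):
    x, h, z, r, rh, c = cache
    dz = dh_new * (c - h)
    dc = dh_new * z
    dh = dh_new * (1.0 - z)
    dc_pre = (1.0 - c * c) * dc
    G[f"{name}.Wc"] += np.outer(x, dc_pre)
    G[f"{name}.Uc"] += np.outer(rh, dc_pre)
    G[f"{name}.bc"] += dc_pre
    dx = P[f"{name}.Wc"] @ dc_pre
    drh = P[f"{name}.Uc"] @ dc_pre
    dr = drh * h
    dh += drh * r
    dz_pre = z * (1.0 - z) * dz
    G[f"{name}.Wz"] += np.outer(x, dz_pre)
    G[f"{name}.Uz"] += np.outer(h, dz_pre)
    G[f"{name}.bz"] += dz_pre
    dx += P[f"{name}.Wz"] @ dz_pre
    dh += P[f"{name}.Uz"] @ dz_pre
    dr_pre = r * (1.0 - r) * dr
    G[f"{name}.Wr"] += np.outer(x, dr_pre)
    G[f"{name}.Ur"] += np.outer(h, dr_pre)
    G[f"{name}.br"] += dr_pre
    dx += P[f"{name}.Wr"] @ dr_pre
    dh += P[f"{name}.Ur"] @ dr_pre
    return dx, dh


def init_rnn(P: dict, rng, name: str, d_in: int, d_hid: int):
    """Simple (Elman) recurrent cell; the non-gated configuration option."""
    P[f"{name}.Wx"] = _glorot(rng, d_in, d_hid)
    P[f"{name}.Uh"] = _glorot(rng, d_hid, d_hid)
    P[f"{name}.bh"] = np.zeros(d_hid)


def rnn_step(P: dict, name: str, x: np.ndarray, h: np.ndarray):
    h_new = np.tanh(x @ P[f"{name}.Wx"] + h @ P[f"{name}.Uh"] + P[f"{name}.bh"])
    return h_new, (x, h, h_new)


def rnn_step_backward(P: dict, G: dict, name: str, dh_new: np.ndarray, cache):
    x, h, h_new = cache
    dpre = (1.0 - h_new * h_new) * dh_new
    G[f"{name}.Wx"] += np.outer(x, dpre)
    G[f"{name}.Uh"] += np.outer(h, dpre)
    G[f"{name}.bh"] += dpre
    return P[f"{name}.Wx"] @ dpre, P[f"{name}.Uh"] @ dpre


CELLS = {
    "gru": (init_gru, gru_step, gru_step_backward),
    "rnn": (init_rnn, rnn_step, rnn_step_backward),
}


# ---------------------------------------------------------------------------
# softmax utilities


def log_softmax(logits: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Log-softmax over the unmasked entries; masked entries get -inf."""
    x = np.asarray(logits, dtype=float)
    if mask is not None:
        x = np.where(mask, x, NEG_INF)
    m = np.max(x)
    if not np.isfinite(m):
        raise ValueError("log_softmax over an empty support")
    e = np.exp(x - m)
    return x - (m + np.log(e.sum()))


def softmax_xent_grad(
    logits: np.ndarray, target: int, mask: np.ndarray | None = None
):
    """(loss, dlogits) for -log softmax(logits)[target]."""
    lp = log_softmax(logits, mask)
    p = np.exp(lp)
    d = p.copy()
    d[target] -= 1.0
    if mask is not None:
        d[~mask] = 0.0
    return -lp[target], d


# ---------------------------------------------------------------------------
# Adam


class Adam:
    def __init__(self, P: dict, lr=1e-2, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = zeros_like_params(P)
        self.v = zeros_like_params(P)
        self.t = 0

    def step(self, P: dict, G: dict):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in G.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            P[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
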