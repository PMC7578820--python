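"""Minimal numpy neural-network layers with manual backpropagation.

Implements exactly what the sequence models need: embeddings, LSTM/GRU
recurrences (uni- and bidirectional), dot attention, linear projections,
softmax cross-entropy, inverted dropout, and Adam.  Every layer exposes
``forward(...) -> (out, cache)`` and ``backward(dout, cache)`` returning
input gradients plus parameter gradients keyed like the parameter dict;
all are covered by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "init_matrix",
    "sigmoid",
    "softmax",
    "LSTMLayer",
    "GRULayer",
    "BiRecurrent",
    "Attention",
    "Linear",
    "softmax_cross_entropy",
    "dropout_mask",
    "Adam",
    "clip_gradients",
]


def init_matrix(rng: np.random.Generator, *shape: int, scale: float | None = None) -> np.ndarray:
    if scale is None:
        scale = 1.0 / np.sqrt(shape[0])
    return rng.uniform(-scale, scale, size=shape)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = x - x.max(axis=axis, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=axis, keepdims=True)


class LSTMLayer:
    """Single-direction LSTM over a (T, D) sequence; gate order i, f, o, g."""

    def __init__(self, rng: np.random.Generator, input_dim: int, hidden_dim: int):
        self.D, self.H = input_dim, hidden_dim
        self.params = {
            "W": init_matrix(rng, input_dim + hidden_dim, 4 * hidden_dim),
            "b": np.zeros(4 * hidden_dim),
        }
        # positive forget-gate bias helps optimisation
        self.params["b"][hidden_dim : 2 * hidden_dim] = 1.0

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list]:
        H = self.H
        W, b = self.params["W"], self.params["b"]
        h = np.zeros(H)
        c = np.zeros(H)
        out = np.zeros((len(X), H))
        cache = []
        for t, x in enumerate(X):
            xh = np.concatenate([x, h])
            z = xh @ W + b
            i = sigmoid(z[:H])
            f = sigmoid(z[H : 2 * H])
            o = sigmoid(z[2 * H : 3 * H])
            g = np.tanh(z[3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((xh, c, i, f, o, g, tanh_c))
            h, c = h_new, c_new
            out[t] = h
        return out, cache

    def backward(self, dout: np.ndarray, cache: list) -> tuple[np.ndarray, dict]:
        H, D = self.H, self.D
        W = self.params["W"]
        dW = np.zeros_like(W)
        db = np.zeros_like(self.params["b"])
        dX = np.zeros((len(cache), D))
        dh_next = np.zeros(H)
        dc_next = np.zeros(H)
        for t in range(len(cache) - 1, -1, -1):
            xh, c_prev, i, f, o, g, tanh_c = cache[t]
            dh = dout[t] + dh_next
            dc = dc_next + dh * o * (1.0 - tanh_c**2)
            do = dh * tanh_c
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    do * o * (1 - o),
                    dg * (1 - g**2),
                ]
            )
            dW += np.outer(xh, dz)
            db += dz
            dxh = W @ dz
            dX[t] = dxh[:D]
            dh_next = dxh[D:]
            dc_next = dc * f
        return dX, {"W": dW, "b": db}


class GRULayer:
    """Single-direction GRU over a (T, D) sequence; gate order z, r, n."""

    def __init__(self, rng: np.random.Generator, input_dim: int, hidden_dim: int):
        self.D, self.H = input_dim, hidden_dim
        self.params = {
            "Wx": init_matrix(rng, input_dim, 3 * hidden_dim),
            "Wh": init_matrix(rng, hidden_dim, 3 * hidden_dim),
            "b": np.zeros(3 * hidden_dim),
        }

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list]:
        H = self.H
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros(H)
        out = np.zeros((len(X), H))
        cache = []
        for t, x in enumerate(X):
            px = x @ Wx + b
            ph = h @ Wh
            z = sigmoid(px[:H] + ph[:H])
            r = sigmoid(px[H : 2 * H] + ph[H : 2 * H])
            n = np.tanh(px[2 * H :] + r * ph[2 * H :])
            h_new = (1.0 - z) * n + z * h
            cache.append((x, h, ph, z, r, n))
            h = h_new
            out[t] = h
        return out, cache

    def backward(self, dout: np.ndarray, cache: list) -> tuple[np.ndarray, dict]:
        H, D = self.H, self.D
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dX = np.zeros((len(cache), D))
        dh_next = np.zeros(H)
        for t in range(len(cache) - 1, -1, -1):
            x, h_prev, ph, z, r, n = cache[t]
            dh = dout[t] + dh_next
            dn = dh * (1.0 - z)
            dz = dh * (h_prev - n)
            dh_prev = dh * z
            dn_pre = dn * (1.0 - n**2)
            dr = dn_pre * ph[2 * H :]
            dphn = dn_pre * r
            dz_pre = dz * z * (1 - z)
            dr_pre = dr * r * (1 - r)
            dpx = np.concatenate([dz_pre, dr_pre, dn_pre])
            dph = np.concatenate([dz_pre, dr_pre, dphn])
            dWx += np.outer(x, dpx)
            db += dpx
            dWh += np.outer(h_prev, dph)
            dX[t] = Wx @ dpx
            dh_next = dh_prev + Wh @ dph
        return dX, {"Wx": dWx, "Wh": dWh, "b": db}


class BiRecurrent:
    """Bidirectional wrapper: concatenates forward and backward passes."""

    def __init__(self, forward_layer, backward_layer):
        self.fwd = forward_layer
        self.bwd = backward_layer

    @property
    def out_dim(self) -> int:
        return self.fwd.H + self.bwd.H

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, tuple]:
        hf, cf = self.fwd.forward(X)
        hb_rev, cb = self.bwd.forward(X[::-1])
        return np.concatenate([hf, hb_rev[::-1]], axis=1), (cf, cb)

    def backward(self, dout: np.ndarray, cache: tuple) -> tuple[np.ndarray, dict, dict]:
        cf, cb = cache
        H = self.fwd.H
        dXf, gf = self.fwd.backward(dout[:, :H], cf)
        dXb_rev, gb = self.bwd.backward(dout[::-1, H:], cb)
        return dXf + dXb_rev[::-1], gf, gb


class Attention:
    """Dot attention pooling a (T, H) sequence to a single (H,) vector."""

    def __init__(self, rng: np.random.Generator, hidden_dim: int):
        self.H = hidden_dim
        self.params = {"v": init_matrix(rng, hidden_dim)}

    def forward(self, H_seq: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple]:
        if len(H_seq) == 0:
            raise ValueError("attention over an empty sequence")
        scores = H_seq @ self.params["v"]
        a = softmax(scores)
        return a @ H_seq, a, (H_seq, a)

    def backward(self, dout: np.ndarray, cache: tuple) -> tuple[np.ndarray, dict]:
        H_seq, a = cache
        v = self.params["v"]
        dH = np.outer(a, dout)
        da = H_seq @ dout
        ds = a * (da - a @ da)
        dv = H_seq.T @ ds
        dH += np.outer(ds, v)
        return dH, {"v": dv}


class Linear:
    def __init__(self, rng: np.random.Generator, input_dim: int, output_dim: int):
        self.params = {
            "W": init_matrix(rng, input_dim, output_dim),
            "b": np.zeros(output_dim),
        }

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return X @ self.params["W"] + self.params["b"], X

    def backward(self, dout: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, dict]:
        if X.ndim == 1:
            dW = np.outer(X, dout)
            db = dout
        else:
            dW = X.T @ dout
            db = dout.sum(axis=0)
        return dout @ self.params["W"].T, {"W": dW, "b": db}


def softmax_cross_entropy(
    logits: np.ndarray, target: int
) -> tuple[float, np.ndarray, np.ndarray]:
    """Returns (loss, probabilities, dlogits)."""
    p = softmax(logits)
    loss = -float(np.log(max(p[target], 1e-300)))
    dlogits = p.copy()
    dlogits[target] -= 1.0
    return loss, p, dlogits


def dropout_mask(rng: np.random.Generator, shape, rate: float) -> np.ndarray:
    """Inverted dropout mask; identity when rate == 0."""
    if rate <= 0:
        return np.ones(shape)
    keep = rng.random(shape) >= rate
    return keep / (1.0 - rate)


def clip_gradients(grads: dict, max_norm: float) -> dict:
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        return {k: g * scale for k, g in grads.items()}
    return grads


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        """In-place update; `params` and `grads` share flat string keys."""
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
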