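"""NumPy bidirectional LSTM sequence labeller with full BPTT and Adam.

The network is a stack of bidirectional LSTM layers followed by a
per-frame linear map and a sigmoid, producing one event-probability
score per frame.  Forward, backward (backpropagation through time) and
the Adam optimiser are implemented directly on NumPy arrays; gradients
are verified against numerical differentiation in the test suite.

Conventions: sequences are (T, B, C) time-major; gate order i, f, g, o;
weights follow the standard uniform(-1/sqrt(H), 1/sqrt(H)) init.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def weighted_bce_from_logits(logits: np.ndarray, targets: np.ndarray,
                             pos_weight: float) -> tuple[float, np.ndarray]:
    """Numerically stable weighted BCE; returns (loss, dloss/dlogits)."""
    y = targets
    w = pos_weight
    # -[w y log p + (1-y) log(1-p)] with log p = -softplus(-z)
    loss_el = w * y * _softplus(-logits) + (1.0 - y) * _softplus(logits)
    n = logits.size
    p = sigmoid(logits)
    grad = (-w * y * (1.0 - p) + (1.0 - y) * p) / n
    return float(loss_el.mean()), grad


class BiLSTM:
    """Stacked bidirectional LSTM -> per-frame linear -> sigmoid."""

    def __init__(self, n_inputs: int, hidden_size: int, n_layers: int,
                 dropout: float = 0.0,
                 rng: np.random.Generator | None = None) -> None:
        if not (0.0 <= dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        self.n_inputs = n_inputs
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.dropout = dropout
        rng = rng or np.random.default_rng()
        H = hidden_size
        k = 1.0 / np.sqrt(H)
        self.params: dict[str, np.ndarray] = {}
        for layer in range(n_layers):
            d_in = n_inputs if layer == 0 else 2 * H
            for direction in ("f", "b"):
                self.params[f"W{layer}{direction}"] = rng.uniform(
                    -k, k, size=(d_in + H, 4 * H))
                b = rng.uniform(-k, k, size=4 * H)
                b[H:2 * H] += 1.0  # forget-gate bias init
                self.params[f"b{layer}{direction}"] = b
        self.params["Wout"] = rng.uniform(-k, k, size=(2 * H, 1))
        self.params["bout"] = rng.uniform(-k, k, size=1)

    # -- single-direction LSTM pass -------------------------------------

    def _lstm_forward(self, x: np.ndarray, W: np.ndarray, b: np.ndarray):
        T, B, _ = x.shape
        H = self.hidden_size
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        gates = np.empty((T, B, 4 * H))
        cs = np.empty((T, B, H))
        hs = np.empty((T, B, H))
        c_prevs = np.empty((T, B, H))
        for t in range(T):
            z = np.concatenate([x[t], h], axis=1) @ W + b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = sigmoid(z[:, 3 * H:])
            c_prevs[t] = c
            c = f * c + i * g
            h = o * np.tanh(c)
            gates[t, :, :H] = i
            gates[t, :, H:2 * H] = f
            gates[t, :, 2 * H:3 * H] = g
            gates[t, :, 3 * H:] = o
            cs[t] = c
            hs[t] = h
        return hs, (x, gates, cs, c_prevs, hs)

    def _lstm_backward(self, cache, dh_out: np.ndarray, W: np.ndarray):
        x, gates, cs, c_prevs, hs = cache
        T, B, D = x.shape
        H = self.hidden_size
        dW = np.zeros_like(W)
        db = np.zeros(4 * H)
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i = gates[t, :, :H]
            f = gates[t, :, H:2 * H]
            g = gates[t, :, 2 * H:3 * H]
            o = gates[t, :, 3 * H:]
            tc = np.tanh(cs[t])
            dh = dh_out[t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc ** 2) + dc_next
            di = dc * g
            df = dc * c_prevs[t]
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            h_prev = hs[t - 1] if t > 0 else np.zeros((B, H))
            xin = np.concatenate([x[t], h_prev], axis=1)
            dW += xin.T @ dz
            db += dz.sum(axis=0)
            dxin = dz @ W.T
            dx[t] = dxin[:, :D]
            dh_next = dxin[:, D:]
        return dx, dW, db

    # -- full network ----------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """Return per-frame logits (T, B) and a backward cache."""
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[:, None, :]
        if x.shape[2] != self.n_inputs:
            raise ValueError(
                f"expected {self.n_inputs} input channels, got {x.shape[2]}")
        caches = []
        out = x
        for layer in range(self.n_layers):
            hs_f, cache_f = self._lstm_forward(
                out, self.params[f"W{layer}f"], self.params[f"b{layer}f"])
            hs_b_rev, cache_b = self._lstm_forward(
                out[::-1], self.params[f"W{layer}b"],
                self.params[f"b{layer}b"])
            out = np.concatenate([hs_f, hs_b_rev[::-1]], axis=2)
            mask = None
            if training and self.dropout > 0 and layer < self.n_layers - 1:
                if rng is None:
                    raise ValueError("training forward pass needs an rng")
                keep = 1.0 - self.dropout
                mask = (rng.random(out.shape) < keep) / keep
                out = out * mask
            caches.append((cache_f, cache_b, mask))
        T, B, _ = out.shape
        logits = (out.reshape(T * B, -1) @ self.params["Wout"]
                  + self.params["bout"]).reshape(T, B)
        cache = (caches, out, x.shape)
        if squeeze:
            logits = logits[:, 0]
        return logits, cache

    def backward(self, cache, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        caches, last_out, x_shape = cache
        if dlogits.ndim == 1:
            dlogits = dlogits[:, None]
        T, B, _ = last_out.shape
        grads: dict[str, np.ndarray] = {}
        flat_out = last_out.reshape(T * B, -1)
        dflat = dlogits.reshape(T * B, 1)
        grads["Wout"] = flat_out.T @ dflat
        grads["bout"] = dflat.sum(axis=0)
        dout = (dflat @ self.params["Wout"].T).reshape(T, B, -1)
        H = self.hidden_size
        for layer in range(self.n_layers - 1, -1, -1):
            cache_f, cache_b, mask = caches[layer]
            if mask is not None:
                dout = dout * mask
            dx_f, dWf, dbf = self._lstm_backward(
                cache_f, dout[:, :, :H], self.params[f"W{layer}f"])
            dx_b, dWb, dbb = self._lstm_backward(
                cache_b, dout[:, :, H:][::-1], self.params[f"W{layer}b"])
            grads[f"W{layer}f"] = dWf
            grads[f"b{layer}f"] = dbf
            grads[f"W{layer}b"] = dWb
            grads[f"b{layer}b"] = dbb
            dout = dx_f + dx_b[::-1]
        return grads

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-frame event probability; deterministic (no dropout)."""
        logits, _ = self.forward(x, training=False)
        return sigmoid(logits)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=float).reshape(
                self.params[k].shape)


class Adam:
    """Adaptive Moment Estimation on a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k].reshape(p.shape)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[k] / bc1) / (
                np.sqrt(self.v[k] / bc2) + self.eps)


def clip_grad_norm(grads: dict[str, np.ndarray], max_norm: float) -> float:
    total = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale
    return total
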