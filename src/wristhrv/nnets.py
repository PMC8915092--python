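"""Minimal numpy recurrent regressors for the wrist-to-reference mapping.

Two small sequence models predict the reference heart rate from a sliding
window of the wrist series: a single-layer vanilla RNN, and an LSTM
followed by two sigmoid dense layers with dropout between layers.  Both
train with mini-batch Adam on mean-squared error against targets min-max
normalised to [0, 1] (matching their sigmoid output heads); predictions
are inverse-transformed back to bpm by the caller.

The implementation is deliberately small — dense matmuls and explicit
backpropagation through time — sized for one-dimensional physiological
series of a few thousand samples on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AdamState", "RNNRegressor", "LSTMRegressor"]

_CLIP_NORM = 1.0  # global gradient-norm clip, for stability at high learning rates


@dataclass
class AdamState:
    """Adam optimiser state over a dict of parameter arrays."""

    lr: float = 0.1
    beta1: float = 0.5
    beta2: float = 0.9  # fast second-moment adaptation keeps the large lr stable
    eps: float = 1e-8
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
        scale = _CLIP_NORM / norm if norm > _CLIP_NORM else 1.0
        self.t += 1
        for name, g in grads.items():
            g = g * scale
            m = self.m.setdefault(name, np.zeros_like(g))
            v = self.v.setdefault(name, np.zeros_like(g))
            m[:] = self.beta1 * m + (1 - self.beta1) * g
            v[:] = self.beta2 * v + (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -40.0, 40.0)))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class _SequenceRegressor:
    """Shared training loop: shuffled mini-batches, fixed epoch count."""

    def __init__(self, hidden_units: int, *, epochs: int = 15, batch_size: int = 64,
                 learning_rate: float = 0.1, beta1: float = 0.5, dropout: float = 0.2,
                 seed: int = 0):
        self.hidden_units = int(hidden_units)
        self.epochs = int(epochs)
        self.batch_size = int(batch_size)
        self.dropout = float(dropout)
        self.rng = np.random.default_rng(seed)
        self.adam = AdamState(lr=learning_rate, beta1=beta1)
        self.params: dict[str, np.ndarray] = {}
        self.history: list[float] = []  # mean MSE per epoch, on normalised targets

    def fit(self, windows: np.ndarray, targets: np.ndarray) -> "_SequenceRegressor":
        """Train on windows (n, T) against scalar targets (n,) in [0, 1]."""
        n = windows.shape[0]
        self._init_params(windows.shape[1])
        self.history = []
        for _ in range(self.epochs):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                loss, grads = self._loss_and_grads(windows[idx], targets[idx], train=True)
                losses.append(loss)
                self.adam.step(self.params, grads)
            self.history.append(float(np.mean(losses)))
        return self

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return self._forward(windows, train=False)[0]

    # subclasses implement
    def _init_params(self, seq_len: int) -> None:  # pragma: no cover
        raise NotImplementedError

    def _forward(self, x, train):  # pragma: no cover
        raise NotImplementedError

    def _loss_and_grads(self, x, y, train):  # pragma: no cover
        raise NotImplementedError


class RNNRegressor(_SequenceRegressor):
    """Single-layer vanilla RNN (tanh) with a sigmoid scalar head."""

    def _init_params(self, seq_len: int) -> None:
        H = self.hidden_units
        rng = self.rng
        self.params = {
            "Wx": _glorot(rng, 1, H),
            "Wh": _glorot(rng, H, H),
            "bh": np.zeros((1, H)),
            "wo": np.zeros((H, 1)),  # zero head: training starts at mid-range output
            "bo": np.zeros((1, 1)),
        }

    def _forward(self, x: np.ndarray, train: bool):
        p = self.params
        B, T = x.shape
        H = self.hidden_units
        h = np.zeros((B, H))
        hs = [h]
        for t in range(T):
            h = np.tanh(x[:, t:t + 1] @ p["Wx"] + h @ p["Wh"] + p["bh"])
            hs.append(h)
        mask = None
        h_out = hs[-1]
        if train and self.dropout > 0:
            mask = (self.rng.random(h_out.shape) >= self.dropout) / (1 - self.dropout)
            h_out = h_out * mask
        yhat = _sigmoid(h_out @ p["wo"] + p["bo"])[:, 0]
        return yhat, (hs, mask, h_out)

    def _loss_and_grads(self, x: np.ndarray, y: np.ndarray, train: bool):
        p = self.params
        B, T = x.shape
        yhat, (hs, mask, h_out) = self._forward(x, train)
        err = yhat - y
        loss = float(np.mean(err**2))
        dz = (2.0 * err / B * yhat * (1 - yhat))[:, None]
        grads = {
            "wo": h_out.T @ dz,
            "bo": dz.sum(axis=0, keepdims=True),
        }
        dh = dz @ p["wo"].T
        if mask is not None:
            dh = dh * mask
        gWx = np.zeros_like(p["Wx"])
        gWh = np.zeros_like(p["Wh"])
        gbh = np.zeros_like(p["bh"])
        for t in range(T - 1, -1, -1):
            da = dh * (1 - hs[t + 1] ** 2)
            gWx += x[:, t:t + 1].T @ da
            gWh += hs[t].T @ da
            gbh += da.sum(axis=0, keepdims=True)
            dh = da @ p["Wh"].T
        grads.update({"Wx": gWx, "Wh": gWh, "bh": gbh})
        return loss, grads


class LSTMRegressor(_SequenceRegressor):
    """LSTM layer + two sigmoid dense layers, dropout after LSTM and dense1."""

    def _init_params(self, seq_len: int) -> None:
        H = self.hidden_units
        rng = self.rng
        self.params = {
            "Wx": _glorot(rng, 1, 4 * H),
            "Wh": _glorot(rng, H, 4 * H),
            "b": np.zeros((1, 4 * H)),
            "W1": _glorot(rng, H, H),
            "b1": np.zeros((1, H)),
            "w2": np.zeros((H, 1)),  # zero head: training starts at mid-range output
            "b2": np.zeros((1, 1)),
        }
        # forget-gate bias starts at 1 so memory persists early in training
        self.params["b"][0, H:2 * H] = 1.0

    def _forward(self, x: np.ndarray, train: bool):
        p = self.params
        B, T = x.shape
        H = self.hidden_units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in range(T):
            z = x[:, t:t + 1] @ p["Wx"] + h @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tanh_c = np.tanh(c)
            cache.append((h, i, f, g, o, c_prev, c, tanh_c))  # h here is h_{t-1}
            h = o * tanh_c
        m1 = m2 = None
        h_drop = h
        if train and self.dropout > 0:
            m1 = (self.rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
            h_drop = h * m1
        a1_pre = h_drop @ p["W1"] + p["b1"]
        a1 = _sigmoid(a1_pre)
        a1_drop = a1
        if train and self.dropout > 0:
            m2 = (self.rng.random(a1.shape) >= self.dropout) / (1 - self.dropout)
            a1_drop = a1 * m2
        yhat = _sigmoid(a1_drop @ p["w2"] + p["b2"])[:, 0]
        return yhat, (cache, h, h_drop, a1, a1_drop, m1, m2)

    def _loss_and_grads(self, x: np.ndarray, y: np.ndarray, train: bool):
        p = self.params
        B, T = x.shape
        H = self.hidden_units
        yhat, (cache, h_last, h_drop, a1, a1_drop, m1, m2) = self._forward(x, train)
        err = yhat - y
        loss = float(np.mean(err**2))
        dz2 = (2.0 * err / B * yhat * (1 - yhat))[:, None]
        grads = {"w2": a1_drop.T @ dz2, "b2": dz2.sum(axis=0, keepdims=True)}
        da1 = dz2 @ p["w2"].T
        if m2 is not None:
            da1 = da1 * m2
        da1_pre = da1 * a1 * (1 - a1)
        grads["W1"] = h_drop.T @ da1_pre
        grads["b1"] = da1_pre.sum(axis=0, keepdims=True)
        dh = da1_pre @ p["W1"].T
        if m1 is not None:
            dh = dh * m1
        dc = np.zeros((B, H))
        gWx = np.zeros_like(p["Wx"])
        gWh = np.zeros_like(p["Wh"])
        gb = np.zeros_like(p["b"])
        for t in range(T - 1, -1, -1):
            h_prev, i, f, g, o, c_prev, c, tanh_c = cache[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            gWx += x[:, t:t + 1].T @ dz
            gWh += h_prev.T @ dz
            gb += dz.sum(axis=0, keepdims=True)
            dh = dz @ p["Wh"].T
            dc = dc * f
        grads.update({"Wx": gWx, "Wh": gWh, "b": gb})
        return loss, grads
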