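"""A compact LSTM sequence regressor implemented in numpy.

Architecture: one LSTM layer (default 50 units) over a univariate sequence,
followed by two dense layers (ReLU hidden layer, linear scalar output).
Training is full backpropagation-through-time with mean-squared-error loss,
Adam updates, mini-batches, and early stopping on a validation set with
best-weight restoration.  Everything is seeded through a numpy Generator, so
training is bit-reproducible.

The implementation is deliberately small: fixed topology, scalar inputs and
outputs, no dropout or recurrent regularisation — sized for short windows of
wearable vitals (sequence length six), not general deep learning.
"""

from __future__ import annotations

import json

import numpy as np

__all__ = ["LSTMRegressor"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class LSTMRegressor:
    """One-layer LSTM + two dense layers mapping a (B, T) batch to (B,) outputs."""

    def __init__(self, n_units: int = 50, dense_units: int = 25,
                 learning_rate: float = 1e-3, rng=None):
        self.n_units = int(n_units)
        self.dense_units = int(dense_units)
        self.learning_rate = float(learning_rate)
        self.rng = np.random.default_rng(rng)
        H, D = self.n_units, self.dense_units
        self.params = {
            "Wx": self._glorot((4 * H, 1)),
            "Wh": self._glorot((4 * H, H)),
            "b": np.zeros(4 * H),
            "W1": self._glorot((H, D)),
            "b1": np.zeros(D),
            "W2": self._glorot((D, 1)),
            "b2": np.zeros(1),
        }
        self.params["b"][H:2 * H] = 1.0  # forget-gate bias init
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self.history: dict = {}

    def _glorot(self, shape):
        fan_in, fan_out = shape[1], shape[0]
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return self.rng.uniform(-limit, limit, size=shape)

    # ---- forward / backward -------------------------------------------------

    def _forward(self, X):
        """X: (B, T) scaled inputs. Returns predictions (B,) and caches."""
        B, T = X.shape
        H = self.n_units
        p = self.params
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in range(T):
            x_t = X[:, t:t + 1]
            a = x_t @ p["Wx"].T + h @ p["Wh"].T + p["b"]
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = _sigmoid(a[:, 3 * H:])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            cache.append((x_t, h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
        d_pre = h @ p["W1"] + p["b1"]
        d = np.maximum(d_pre, 0.0)
        y_hat = (d @ p["W2"] + p["b2"]).ravel()
        return y_hat, (cache, h, d_pre, d)

    def _backward(self, X, y, y_hat, caches):
        B, T = X.shape
        H = self.n_units
        p = self.params
        cache, hT, d_pre, d = caches
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        dy = (2.0 / B) * (y_hat - y)[:, None]          # dL/dy_hat, (B, 1)
        grads["W2"] = d.T @ dy
        grads["b2"] = dy.sum(axis=0)
        dd = dy @ p["W2"].T
        dd[d_pre <= 0.0] = 0.0
        grads["W1"] = hT.T @ dd
        grads["b1"] = dd.sum(axis=0)
        dh = dd @ p["W1"].T
        dc = np.zeros((B, H))
        for t in reversed(range(T)):
            x_t, h_prev, c_prev, i, f, g, o, c_new = cache[t]
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g ** 2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            grads["Wx"] += da.T @ x_t
            grads["Wh"] += da.T @ h_prev
            grads["b"] += da.sum(axis=0)
            dh = da @ p["Wh"]
            dc = dc * f
        return grads

    def _adam_step(self, grads, clip_norm: float = 5.0):
        norm = np.sqrt(sum(float(np.sum(g ** 2)) for g in grads.values()))
        if norm > clip_norm:
            scale = clip_norm / norm
            grads = {k: g * scale for k, g in grads.items()}
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g ** 2
            m_hat = self._adam_m[k] / (1 - b1 ** self._adam_t)
            v_hat = self._adam_v[k] / (1 - b2 ** self._adam_t)
            self.params[k] -= self.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

    # ---- public API ---------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        y_hat, _ = self._forward(X)
        return y_hat

    def loss(self, X, y) -> float:
        y_hat = self.predict(X)
        return float(np.mean((y_hat - np.asarray(y, dtype=float)) ** 2))

    def fit(
        self,
        X,
        y,
        X_val=None,
        y_val=None,
        epochs: int = 100,
        batch_size: int = 5,
        patience: int = 10,
    ) -> "LSTMRegressor":
        """Train with MSE/Adam; early-stop on validation loss (or training
        loss when no validation set is given), restoring the best weights."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size or X.shape[0] == 0:
            raise ValueError("X must be (n, seq_len) with matching targets")
        has_val = X_val is not None and len(X_val) > 0
        best_loss = np.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        best_epoch = 0
        wait = 0
        n = X.shape[0]
        train_losses, val_losses = [], []
        for epoch in range(1, epochs + 1):
            order = self.rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                y_hat, caches = self._forward(X[idx])
                if not np.all(np.isfinite(y_hat)):
                    raise FloatingPointError("training diverged (non-finite loss)")
                grads = self._backward(X[idx], y[idx], y_hat, caches)
                self._adam_step(grads)
            train_loss = self.loss(X, y)
            monitor = self.loss(X_val, y_val) if has_val else train_loss
            if not np.isfinite(monitor):
                raise FloatingPointError("training diverged (non-finite loss)")
            train_losses.append(train_loss)
            val_losses.append(monitor if has_val else np.nan)
            if monitor < best_loss - 1e-12:
                best_loss = monitor
                best_params = {k: v.copy() for k, v in self.params.items()}
                best_epoch = epoch
                wait = 0
            else:
                wait += 1
                if wait >= patience:
                    break
        self.params = best_params
        self.history = {
            "epochs_run": len(train_losses),
            "best_epoch": best_epoch,
            "train_loss": train_losses,
            "val_loss": val_losses,
        }
        return self

    # ---- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_units": self.n_units,
            "dense_units": self.dense_units,
            "learning_rate": self.learning_rate,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }

    @classmethod
    def from_dict(cls, blob: dict) -> "LSTMRegressor":
        net = cls(blob["n_units"], blob["dense_units"], blob["learning_rate"])
        net.params = {k: np.asarray(v, dtype=float) for k, v in blob["params"].items()}
        return net

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "LSTMRegressor":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
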