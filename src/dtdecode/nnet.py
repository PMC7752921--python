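"""Neural-network regression decoder (lightweight numpy implementation).

Two architectures are provided:

``"lstm"``
    The feature vector of each subject is fed to the network as a univariate
    sequence of length p (one feature per time step), followed by an LSTM
    layer (default 125 hidden units, last hidden state kept), a fully
    connected layer (50 units), dropout (p = 0.5), and a fully connected
    scalar output. Because the features enter as a sequence, predictions
    depend on the design-matrix column order, which is therefore fixed to the
    canonical [GM | WM | site | gender] layout.
``"mlp"``
    An order-free multilayer perceptron p -> 125 -> 50 -> 1 with ReLU
    activations on the hidden layers and dropout (0.5) before the output.

Training minimises mean squared error with Adam (defaults: 100 epochs,
mini-batch 20, learning rate 0.01, beta1 = 0.9, beta2 = 0.999) and gradient
clipping by global L2 norm at threshold 1. All randomness (initialisation,
shuffling, dropout) derives from a single seed, so training is deterministic
under single-threaded execution. Inputs are expected to be z-scored
(non-indicator columns) before fitting.

Gradients are computed by explicit backpropagation (backpropagation through
time for the LSTM) and are validated against finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_X_y

__all__ = ["NeuralNetRegressor", "fit_dnn", "predict_dnn"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _Dense:
    def __init__(self, rng, n_in: int, n_out: int, relu: bool = False) -> None:
        self.W = _glorot(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.relu = relu

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        out = x @ self.W + self.b
        if self.relu:
            self._pre = out
            out = np.maximum(out, 0.0)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = dout * (self._pre > 0)
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [(self.W, "dW"), (self.b, "db")]


class _Dropout:
    def __init__(self, rate: float) -> None:
        self.rate = rate

    def forward(self, x: np.ndarray, training: bool, rng=None) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class _LSTM:
    """Univariate-input LSTM, sequence-to-last-hidden-state.

    Gate order in the stacked weight matrices is [input, forget, cell, output].
    """

    def __init__(self, rng, n_in: int, hidden: int) -> None:
        H = hidden
        self.H = H
        self.Wx = _glorot(rng, n_in, 4 * H, (n_in, 4 * H))
        self.Wh = _glorot(rng, H, 4 * H, (H, 4 * H))
        self.b = np.zeros(4 * H)
        # positive forget-gate bias: standard stabilisation for LSTM training
        self.b[H:2 * H] = 1.0

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, T, _ = x.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        for t in range(T):
            xt = x[:, t, :]
            z = xt @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            self._cache.append((xt, h, c, i, f, g, o, tanh_c))
            h = o * tanh_c
            c = c_new
        self._T = T
        self._B = B
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        H = self.H
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        dx = np.zeros((self._B, self._T, self.Wx.shape[0]))
        dc = np.zeros((self._B, H))
        for t in range(self._T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1.0 - i), df * f * (1.0 - f),
                 dg * (1.0 - g ** 2), do * o * (1.0 - o)], axis=1)
            self.dWx += xt.T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dh = dz @ self.Wh.T
            dc = dc * f
        return dx  # input gradient unused (input layer)

    def params(self):
        return [(self.Wx, "dWx"), (self.Wh, "dWh"), (self.b, "db")]


class NeuralNetRegressor(RegressorMixin, BaseEstimator):
    """Deep regression network trained with Adam and MSE loss.

    Parameters mirror the defaults described in the module docstring; see
    there for the two architectures. ``fit`` records ``loss_history_`` (mean
    per-epoch training MSE) and raises ``RuntimeError`` on a NaN loss.
    """

    def __init__(self, architecture: str = "lstm", hidden_units: int = 125,
                 fc_units: int = 50, dropout: float = 0.5, epochs: int = 100,
                 batch_size: int = 20, learning_rate: float = 0.01,
                 grad_clip: float = 1.0, seed: int = 0) -> None:
        self.architecture = architecture
        self.hidden_units = hidden_units
        self.fc_units = fc_units
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.grad_clip = grad_clip
        self.seed = seed

    # ------------------------------------------------------------- internals
    def _build(self, p: int, rng: np.random.Generator) -> None:
        if self.architecture == "lstm":
            self._lstm = _LSTM(rng, 1, self.hidden_units)
            self._fc1 = _Dense(rng, self.hidden_units, self.fc_units)
            self._drop = _Dropout(self.dropout)
            self._fc2 = _Dense(rng, self.fc_units, 1)
            self._layers = [self._lstm, self._fc1, self._drop, self._fc2]
        elif self.architecture == "mlp":
            self._fc0 = _Dense(rng, p, self.hidden_units, relu=True)
            self._fc1 = _Dense(rng, self.hidden_units, self.fc_units, relu=True)
            self._drop = _Dropout(self.dropout)
            self._fc2 = _Dense(rng, self.fc_units, 1)
            self._layers = [self._fc0, self._fc1, self._drop, self._fc2]
        else:
            raise ValueError(f"unknown architecture {self.architecture!r}")

    def _forward(self, X: np.ndarray, training: bool,
                 rng: np.random.Generator | None = None) -> np.ndarray:
        out = X[:, :, None] if self.architecture == "lstm" else X
        for layer in self._layers:
            if isinstance(layer, _Dropout):
                out = layer.forward(out, training, rng)
            else:
                out = layer.forward(out, training)
        return out[:, 0]

    def _backward(self, dpred: np.ndarray) -> None:
        dout = dpred[:, None]
        for layer in reversed(self._layers):
            dout = layer.backward(dout)

    def _loss_and_grads(self, X: np.ndarray, y: np.ndarray, training: bool,
                        rng: np.random.Generator | None = None):
        pred = self._forward(X, training, rng)
        err = pred - y
        loss = float(np.mean(err ** 2))
        self._backward(2.0 * err / err.size)
        grads = []
        for layer in self._layers:
            if isinstance(layer, _Dropout):
                continue
            for param, gname in layer.params():
                grads.append((param, getattr(layer, gname)))
        return loss, grads

    # ------------------------------------------------------------------ API
    def fit(self, X, y) -> "NeuralNetRegressor":
        X, y = check_X_y(X, y, y_numeric=True)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.seed)
        self._build(X.shape[1], rng)
        # Adam state per parameter array
        state = {}
        step = 0
        lr, b1, b2, eps = self.learning_rate, 0.9, 0.999, 1e-8
        n = X.shape[0]
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                batch = order[start:start + self.batch_size]
                loss, grads = self._loss_and_grads(X[batch], y[batch],
                                                   training=True, rng=rng)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: non-finite loss {loss} at Adam "
                        f"step {step}; reduce the learning rate or rescale "
                        "inputs")
                epoch_losses.append(loss)
                # global-norm gradient clipping
                total = np.sqrt(sum(float(np.sum(g ** 2)) for _, g in grads))
                if total > self.grad_clip:
                    scale = self.grad_clip / total
                    grads = [(p_, g * scale) for p_, g in grads]
                step += 1
                for idx, (param, grad) in enumerate(grads):
                    m, v = state.get(idx, (np.zeros_like(param),
                                           np.zeros_like(param)))
                    m = b1 * m + (1 - b1) * grad
                    v = b2 * v + (1 - b2) * grad ** 2
                    state[idx] = (m, v)
                    m_hat = m / (1 - b1 ** step)
                    v_hat = v / (1 - b2 ** step)
                    param -= lr * m_hat / (np.sqrt(v_hat) + eps)
            self.loss_history_.append(float(np.mean(epoch_losses)))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "_layers"):
            raise AttributeError("NeuralNetRegressor is not fitted")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects {self.n_features_in_}"
            )
        return self._forward(np.asarray(X, dtype=float), training=False)


def fit_dnn(X, y, **config) -> NeuralNetRegressor:
    """Train the deep regression network on (z-scored) training data."""
    return NeuralNetRegressor(**config).fit(X, y)


def predict_dnn(model: NeuralNetRegressor, X) -> np.ndarray:
    return model.predict(X)
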