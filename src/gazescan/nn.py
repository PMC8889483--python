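"""A self-contained numpy LSTM for binary sequence classification.

Architecture: a single LSTM layer unrolled over the window length (one cell
per frame; each cell takes a one-hot 16-vector and emits a cell state c_i
and hidden state h_i), with the final hidden state feeding a fully connected
layer with a single output followed by a sigmoid.  Training uses Adam and a
class-weighted binary cross-entropy loss; gradients come from explicit
backpropagation through time.

Everything is plain numpy with an explicit ``numpy.random.Generator``, so a
fixed seed gives bit-reproducible initialization, shuffling and training.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMClassifierNet", "AdamOptimizer", "weighted_bce"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def weighted_bce(p: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Mean per-sample-weighted binary cross-entropy."""
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    return float(np.mean(w * -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


class LSTMClassifierNet:
    """LSTM -> dense(1) -> sigmoid, with forward, BPTT and parameter access.

    Gate layout in the fused weight matrices is (input, forget, candidate,
    output).  Weights use Glorot-uniform init; the forget-gate bias starts
    at +1 (standard remedy against early vanishing of the cell state).
    """

    def __init__(self, input_size: int = 16, hidden_size: int = 64,
                 rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng()
        self.input_size = input_size
        self.hidden_size = hidden_size
        H = hidden_size

        def glorot(n_in, n_out):
            lim = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-lim, lim, size=(n_in, n_out))

        self.Wx = glorot(input_size, 4 * H)
        self.Wh = glorot(H, 4 * H)
        self.b = np.zeros(4 * H)
        self.b[H:2 * H] = 1.0  # forget gate bias
        self.Wo = glorot(H, 1)
        self.bo = np.zeros(1)

    # -- parameter plumbing -------------------------------------------------
    _PARAM_NAMES = ("Wx", "Wh", "b", "Wo", "bo")

    def get_params(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k).copy() for k in self._PARAM_NAMES}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self._PARAM_NAMES:
            setattr(self, k, params[k].copy())

    # -- forward ------------------------------------------------------------
    def forward(self, X: np.ndarray, cache: bool = False):
        """Forward pass.  X has shape (batch, window, input_size).

        Returns probabilities of shape (batch,); with ``cache=True`` also
        returns the intermediates needed by :meth:`backward`.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != self.input_size:
            raise ValueError(
                f"expected input of shape (batch, window, {self.input_size}), "
                f"got {X.shape}")
        B, T, _ = X.shape
        H = self.hidden_size
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(T):
            x_t = X[:, t, :]
            z = x_t @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev, h_prev = c, h
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            if cache:
                steps.append((x_t, h_prev, c_prev, i, f, g, o, tc))
        logit = (h @ self.Wo + self.bo).ravel()
        p = _sigmoid(logit)
        if cache:
            return p, (steps, h)
        return p

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    # -- backward -----------------------------------------------------------
    def backward(self, X, y, sample_weight, cache) -> dict[str, np.ndarray]:
        """Gradients of the weighted BCE loss w.r.t. all parameters."""
        steps, h_last = cache
        p = _sigmoid((h_last @ self.Wo + self.bo).ravel())
        B = len(y)
        H = self.hidden_size
        dlogit = (sample_weight * (p - y) / B)[:, None]  # (B, 1)

        grads = {k: np.zeros_like(getattr(self, k)) for k in self._PARAM_NAMES}
        grads["Wo"] = h_last.T @ dlogit
        grads["bo"] = dlogit.sum(axis=0)

        dh = dlogit @ self.Wo.T
        dc = np.zeros((B, H))
        for x_t, h_prev, c_prev, i, f, g, o, tc in reversed(steps):
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc**2)
            di, dg, df = dc * g, dc * i, dc * c_prev
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ], axis=1)
            # gate layout in the fused matrices is i, f, g, o
            grads["Wx"] += x_t.T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dh = dz @ self.Wh.T
            dc = dc * f
        return grads


class AdamOptimizer:
    """Adam with optional global-norm gradient clipping."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float | None = 5.0):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, net: LSTMClassifierNet, grads: dict[str, np.ndarray]) -> None:
        if self.clip_norm is not None:
            norm = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
            if norm > self.clip_norm:
                scale = self.clip_norm / (norm + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        bc1 = 1.0 - self.beta1**self.t
        bc2 = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g**2
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            setattr(net, k, getattr(net, k) - self.lr * update)
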