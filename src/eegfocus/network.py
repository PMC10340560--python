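"""A small LSTM classifier implemented on numpy.

This is a standard LSTM cell (input, forget, output gates and a tanh cell
candidate) followed by a fully connected layer and a softmax output,
trained with mini-batch Adam, cross-entropy loss, and global-norm gradient
clipping. The feature vectors fed to the classifier are short sequences
(length 1 by default: one band-energy vector per epoch), so the network is
deliberately compact and runs comfortably on a single CPU core.

All randomness flows through a caller-supplied ``numpy.random.Generator``,
making initialization and batch shuffling exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Params = dict[str, np.ndarray]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def init_params(
    input_size: int, hidden: int, n_classes: int, rng: np.random.Generator
) -> Params:
    """Glorot-uniform weights; forget-gate bias initialized to 1."""

    def glorot(n_out: int, n_in: int) -> np.ndarray:
        bound = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-bound, bound, size=(n_out, n_in))

    H = hidden
    params = {
        "Wx": glorot(4 * H, input_size),
        "Wh": glorot(4 * H, H),
        "b": np.zeros(4 * H),
        "Wfc": glorot(n_classes, H),
        "bfc": np.zeros(n_classes),
    }
    params["b"][H : 2 * H] = 1.0  # forget gate
    return params


def forward(params: Params, X: np.ndarray) -> tuple[np.ndarray, dict]:
    """Run the network on a batch.

    ``X`` is (batch, time, features). Returns class probabilities
    (batch, n_classes) and a cache for backpropagation.
    """
    B, T, _ = X.shape
    H = params["Wh"].shape[1]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    steps = []
    for t in range(T):
        x_t = X[:, t, :]
        z = x_t @ params["Wx"].T + h @ params["Wh"].T + params["b"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_next = f * c + i * g
        tanh_c = np.tanh(c_next)
        h_next = o * tanh_c
        steps.append((x_t, h, c, i, f, g, o, tanh_c))
        h, c = h_next, c_next
    logits = h @ params["Wfc"].T + params["bfc"]
    probs = softmax(logits)
    return probs, {"steps": steps, "h_last": h, "probs": probs, "X": X}


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-likelihood of integer labels ``y``."""
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(-np.log(p).mean())


def backward(params: Params, cache: dict, y: np.ndarray) -> Params:
    """Gradients of the mean cross-entropy w.r.t. every parameter."""
    probs = cache["probs"]
    B = probs.shape[0]
    H = params["Wh"].shape[1]
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B

    grads = {k: np.zeros_like(v) for k, v in params.items()}
    grads["Wfc"] = dlogits.T @ cache["h_last"]
    grads["bfc"] = dlogits.sum(axis=0)

    dh = dlogits @ params["Wfc"]
    dc = np.zeros((B, H))
    for x_t, h_prev, c_prev, i, f, g, o, tanh_c in reversed(cache["steps"]):
        do = dh * tanh_c
        dc = dc + dh * o * (1.0 - tanh_c**2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        grads["Wx"] += dz.T @ x_t
        grads["Wh"] += dz.T @ h_prev
        grads["b"] += dz.sum(axis=0)
        dh = dz @ params["Wh"]
        dc = dc * f
    return grads


def clip_gradients(grads: Params, threshold: float) -> Params:
    """Scale all gradients so their global L2 norm is at most ``threshold``."""
    norm = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
    if norm > threshold > 0:
        scale = threshold / norm
        return {k: g * scale for k, g in grads.items()}
    return grads


@dataclass
class Adam:
    """Adam optimizer with bias correction."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    m: Params = field(default_factory=dict)
    v: Params = field(default_factory=dict)
    t: int = 0

    def step(self, params: Params, grads: Params) -> None:
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            m_hat = self.m[k] / (1 - self.beta1**self.t)
            v_hat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def predict_proba(params: Params, X: np.ndarray) -> np.ndarray:
    probs, _ = forward(params, X)
    return probs


def accuracy(params: Params, X: np.ndarray, y: np.ndarray) -> float:
    if len(y) == 0:
        return float("nan")
    return float((predict_proba(params, X).argmax(axis=1) == y).mean())
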