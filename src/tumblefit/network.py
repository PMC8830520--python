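"""Small fully connected surrogate network, in plain NumPy.

Four hidden layers of 20 tanh units by default, one linear output unit
(the predicted angular speed), Xavier/Glorot initialisation, and an Adam
optimiser.  The network is small enough that batched NumPy matmuls are
fast on one CPU, and keeping it dependency-free makes checkpoints trivial
plain-text documents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SurrogateNet", "Adam"]


@dataclass
class SurrogateNet:
    """Feed-forward tanh network mapping an angle encoding to a speed.

    Parameters
    ----------
    n_inputs : int
        Input features (default 2: cos 2phi, sin 2phi).
    hidden_layers, width : int
        Depth and width of the hidden stack.
    seed : int
        Xavier initialisation seed; the same seed gives bitwise-identical
        initial weights.
    """

    n_inputs: int = 2
    hidden_layers: int = 4
    width: int = 20
    seed: int = 0
    weights: list = field(default_factory=list)
    biases: list = field(default_factory=list)

    def __post_init__(self):
        if not self.weights:
            rng = np.random.default_rng(self.seed)
            sizes = [self.n_inputs] + [self.width] * self.hidden_layers + [1]
            for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
                bound = np.sqrt(6.0 / (fan_in + fan_out))
                self.weights.append(rng.uniform(-bound, bound, (fan_in, fan_out)))
                self.biases.append(np.zeros(fan_out))

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Predicted speeds for inputs of shape (n, n_inputs); returns (n,)."""
        return self._forward_cached(x)[0]

    def _forward_cached(self, x: np.ndarray):
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.n_inputs:
            raise ValueError(
                f"expected inputs of shape (n, {self.n_inputs}), got {x.shape}"
            )
        activations = [x]
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.tanh(h @ w + b)
            activations.append(h)
        out = h @ self.weights[-1] + self.biases[-1]
        return out[:, 0], activations

    def backward(self, x: np.ndarray, d_out: np.ndarray):
        """Gradients of sum(d_out * output) w.r.t. every weight and bias.

        ``d_out`` is the upstream gradient per sample, shape (n,).
        Returns (weight_grads, bias_grads) matching the parameter lists.
        """
        out, acts = self._forward_cached(x)
        delta = np.asarray(d_out, dtype=float)[:, None]  # (n, 1)
        w_grads = [None] * len(self.weights)
        b_grads = [None] * len(self.biases)
        for layer in range(len(self.weights) - 1, -1, -1):
            w_grads[layer] = acts[layer].T @ delta
            b_grads[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (1.0 - acts[layer] ** 2)
        return w_grads, b_grads

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_inputs": self.n_inputs,
            "hidden_layers": self.hidden_layers,
            "width": self.width,
            "seed": self.seed,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurrogateNet":
        net = cls(
            n_inputs=d["n_inputs"],
            hidden_layers=d["hidden_layers"],
            width=d["width"],
            seed=d["seed"],
            weights=[np.asarray(w) for w in d["weights"]],
            biases=[np.asarray(b) for b in d["biases"]],
        )
        return net


class Adam:
    """Adaptive-moment gradient descent over a flat list of arrays."""

    def __init__(self, shapes, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params: list, grads: list, lr: float) -> list:
        """One update; returns the updated parameter list (in place)."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p -= lr * m_hat / (np.sqrt(v_hat) + self.eps)
        return params

    def to_dict(self) -> dict:
        return {
            "beta1": self.beta1,
            "beta2": self.beta2,
            "eps": self.eps,
            "t": self.t,
            "m": [m.tolist() for m in self.m],
            "v": [v.tolist() for v in self.v],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Adam":
        opt = cls([np.asarray(m).shape for m in d["m"]],
                  beta1=d["beta1"], beta2=d["beta2"], eps=d["eps"])
        opt.m = [np.asarray(m) for m in d["m"]]
        opt.v = [np.asarray(v) for v in d["v"]]
        opt.t = d["t"]
        return opt
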