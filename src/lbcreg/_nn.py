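"""Minimal fully-connected network engine used by the emulator modules.

Implements exactly what the training loops need: ReLU multilayer
perceptrons with He initialisation, reverse-mode gradients for a loss
gradient supplied at the output layer, an optional softplus output
transform (for nonnegative interval widths), inverted dropout, and the
Adam optimiser. Everything is plain float64 numpy; networks here are
small (tens of thousands of parameters) and CPU-bound by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit


@dataclass
class NetworkSpec:
    """Shape description of a fully connected network.

    ``output_transform`` is ``"identity"`` for point predictors and
    ``"softplus"`` for interval-width heads, whose outputs must be
    nonnegative.
    """

    input_dim: int
    hidden_widths: list[int] = field(default_factory=list)
    output_dim: int = 1
    activation: str = "relu"
    output_transform: str = "identity"

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.output_dim < 1:
            raise ValueError("input_dim and output_dim must be positive")
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")
        if self.activation != "relu":
            raise ValueError(f"unsupported activation: {self.activation!r}")
        if self.output_transform not in ("identity", "softplus"):
            raise ValueError(f"unsupported output transform: {self.output_transform!r}")

    @property
    def layer_dims(self) -> list[tuple[int, int]]:
        dims = [self.input_dim, *self.hidden_widths, self.output_dim]
        return list(zip(dims[:-1], dims[1:]))

    def n_parameters(self) -> int:
        return sum(fi * fo + fo for fi, fo in self.layer_dims)


def _softplus(z: np.ndarray) -> np.ndarray:
    # log(1 + e^z), overflow-safe
    return np.logaddexp(0.0, z)


class MLP:
    """Fully connected ReLU network with manual reverse-mode gradients."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        self.spec = spec
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in spec.layer_dims:
            scale = np.sqrt(2.0 / fan_in)  # He init for ReLU
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # -- forward ---------------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        dropout_rate: float = 0.0,
        dropout_rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Return (output, cache). Dropout applies to hidden activations
        (inverted scaling) when ``dropout_rate > 0`` and a generator is given."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"expected {self.spec.input_dim} input features, got {x.shape[1]}"
            )
        acts = [x]
        pre: list[np.ndarray] = []
        masks: list[np.ndarray | None] = []
        h = x
        n_layers = len(self.weights)
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            pre.append(z)
            if k < n_layers - 1:
                h = np.maximum(z, 0.0)
                if dropout_rate > 0.0 and dropout_rng is not None:
                    keep = 1.0 - dropout_rate
                    mask = (dropout_rng.random(h.shape) < keep) / keep
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                acts.append(h)
            else:
                h = z
        if self.spec.output_transform == "softplus":
            out = _softplus(h)
        else:
            out = h
        cache = {"acts": acts, "pre": pre, "masks": masks}
        return out, cache

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    # -- backward --------------------------------------------------------

    def backward(self, cache: dict, grad_out: np.ndarray) -> list[np.ndarray]:
        """Backpropagate d(loss)/d(output); returns gradients ordered as
        ``[dW0, db0, dW1, db1, ...]`` matching :meth:`parameters`."""
        pre = cache["pre"]
        acts = cache["acts"]
        masks = cache["masks"]
        if self.spec.output_transform == "softplus":
            delta = grad_out * expit(pre[-1])  # d softplus/dz = sigmoid(z)
        else:
            delta = np.asarray(grad_out, dtype=np.float64)
        grads: list[np.ndarray] = []
        for k in range(len(self.weights) - 1, -1, -1):
            grads.append(delta.sum(axis=0))  # db
            grads.append(acts[k].T @ delta)  # dW
            if k > 0:
                delta = delta @ self.weights[k].T
                if masks[k - 1] is not None:
                    delta = delta * masks[k - 1]
                delta = delta * (pre[k - 1] > 0.0)
        grads.reverse()
        return grads

    # -- parameter access ------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        out = []
        for w, b in zip(self.weights, self.biases):
            out.extend((w, b))
        return out

    def n_parameters(self) -> int:
        return self.spec.n_parameters()

    def get_state(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            state[f"w{k}"] = w.copy()
            state[f"b{k}"] = b.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k in range(len(self.weights)):
            w = np.asarray(state[f"w{k}"], dtype=np.float64)
            b = np.asarray(state[f"b{k}"], dtype=np.float64)
            if w.shape != self.weights[k].shape or b.shape != self.biases[k].shape:
                raise ValueError("parameter state does not match network shape")
            self.weights[k] = w
            self.biases[k] = b


class Adam:
    """Adam optimiser (beta1=0.9, beta2=0.999, eps=1e-8) updating in place."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
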