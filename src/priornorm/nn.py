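"""Minimal dense-network primitives: parameter init, Adam, ReLU MLP heads.

The conditional VAE used here is small (one hidden layer, two linear heads
per network), so forward and backward passes are written directly as NumPy
matrix algebra. Gradients are exact and are checked against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["init_two_head_mlp", "two_head_forward", "two_head_backward", "Adam"]


def init_two_head_mlp(
    d_in: int,
    hidden: int,
    d_out: int,
    n_hidden_layers: int = 1,
    rng: np.random.Generator | None = None,
) -> dict:
    """He-initialised MLP with ReLU hidden layers and two linear output heads.

    Heads share the hidden trunk: ``head_a`` and ``head_b`` each map the last
    hidden layer to ``d_out`` units (used for a mean and a log-variance).
    """
    if rng is None:
        rng = np.random.default_rng()
    params = {"n_hidden_layers": n_hidden_layers}
    d = d_in
    for layer in range(n_hidden_layers):
        params[f"W{layer}"] = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, hidden))
        params[f"b{layer}"] = np.zeros(hidden)
        d = hidden
    for head in ("a", "b"):
        params[f"W_{head}"] = rng.normal(0.0, np.sqrt(1.0 / d), size=(d, d_out))
        params[f"b_{head}"] = np.zeros(d_out)
    return params


def two_head_forward(params: dict, x: np.ndarray, cache: bool = False):
    """Forward pass; returns ``(a, b)`` and optionally the activation cache."""
    h = x
    acts = [x]
    for layer in range(params["n_hidden_layers"]):
        h = np.maximum(h @ params[f"W{layer}"] + params[f"b{layer}"], 0.0)
        acts.append(h)
    a = h @ params["W_a"] + params["b_a"]
    b = h @ params["W_b"] + params["b_b"]
    if cache:
        return (a, b), acts
    return a, b


def two_head_backward(
    params: dict, acts: list[np.ndarray], d_a: np.ndarray, d_b: np.ndarray
) -> tuple[dict, np.ndarray]:
    """Backward pass given upstream gradients on the two heads.

    Returns ``(grads, d_input)`` where ``grads`` mirrors the parameter dict.
    """
    h = acts[-1]
    grads = {
        "W_a": h.T @ d_a,
        "b_a": d_a.sum(axis=0),
        "W_b": h.T @ d_b,
        "b_b": d_b.sum(axis=0),
    }
    d_h = d_a @ params["W_a"].T + d_b @ params["W_b"].T
    for layer in range(params["n_hidden_layers"] - 1, -1, -1):
        d_h = d_h * (acts[layer + 1] > 0)
        grads[f"W{layer}"] = acts[layer].T @ d_h
        grads[f"b{layer}"] = d_h.sum(axis=0)
        d_h = d_h @ params[f"W{layer}"].T
    return grads, d_h


class Adam:
    """Adaptive-moment gradient descent over a dict-of-arrays parameter set."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()
                  if isinstance(v, np.ndarray)}
        self.v = {k: np.zeros_like(v) for k, v in self.m.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k in self.m:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] = params[k] - self.lr * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + self.eps
            )
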