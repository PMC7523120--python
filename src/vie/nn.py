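"""Small neural-network building blocks on top of autograd.

All learnable state lives in plain nested dicts/lists of numpy arrays so that
``autograd.grad`` can differentiate through any sub-tree and checkpoints can be
serialized to JSON. Layers are deliberately minimal: dense affine maps, tanh
nonlinearities, and a hand-rolled Adam optimizer over flattened parameter
vectors.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.misc import flatten


def asarr(x):
    """Coerce to a float array unless ``x`` is an autograd box (leave traced)."""
    return x if hasattr(x, "_value") else anp.asarray(x, dtype=float)


def softplus(x):
    """Numerically stable log(1+exp(x)); the positivity transform used for scales."""
    return anp.logaddexp(0.0, x)


def inv_softplus(y: float) -> float:
    """Inverse of :func:`softplus` for initializing unconstrained scale parameters."""
    return float(np.log(np.expm1(y)))


def sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def init_mlp(sizes, rng, w_scale=0.1):
    """Initialize a fully connected net as ``[{'W':..., 'b':...}, ...]``.

    Weights are small Gaussian, biases zero. ``sizes`` is the list of layer
    widths including input and output.
    """
    layers = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        layers.append({
            "W": rng.normal(0.0, w_scale / np.sqrt(max(n_in, 1)), size=(n_in, n_out)),
            "b": np.zeros(n_out),
        })
    return layers


def mlp_forward(layers, x, hidden_activation=anp.tanh):
    """Forward pass; tanh on all but the final (linear) layer."""
    h = x
    for layer in layers[:-1]:
        h = hidden_activation(h @ layer["W"] + layer["b"])
    last = layers[-1]
    return h @ last["W"] + last["b"]


class Adam:
    """Adam over an arbitrary autograd-flattenable parameter tree."""

    def __init__(self, params, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        flat, self._unflatten = flatten(params)
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = np.zeros_like(flat)
        self.v = np.zeros_like(flat)
        self.t = 0

    def step(self, params, grads, ascend=False):
        """One update; ``ascend=True`` maximizes instead of minimizing."""
        flat_p, unflatten = flatten(params)
        flat_g, _ = flatten(grads)
        if ascend:
            flat_g = -flat_g
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * flat_g
        self.v = self.b2 * self.v + (1 - self.b2) * flat_g**2
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return unflatten(flat_p - self.lr * mhat / (np.sqrt(vhat) + self.eps))


def tree_to_jsonable(tree):
    """Recursively convert a parameter tree into JSON-serializable lists."""
    if isinstance(tree, dict):
        return {k: tree_to_jsonable(v) for k, v in tree.items()}
    if isinstance(tree, (list, tuple)):
        return [tree_to_jsonable(v) for v in tree]
    if isinstance(tree, np.ndarray):
        return {"__ndarray__": tree.tolist(), "shape": list(tree.shape)}
    return tree


def tree_from_jsonable(tree):
    if isinstance(tree, dict):
        if "__ndarray__" in tree:
            return np.asarray(tree["__ndarray__"], dtype=float).reshape(tree["shape"])
        return {k: tree_from_jsonable(v) for k, v in tree.items()}
    if isinstance(tree, list):
        return [tree_from_jsonable(v) for v in tree]
    return tree
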