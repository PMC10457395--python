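"""Small feed-forward building blocks on top of HIPS autograd.

Models are parameter pytrees (nested dicts/lists of ndarrays); losses are pure
functions of the pytree, differentiated with ``autograd.grad``.  The Adam
optimizer operates on the flattened pytree.  Everything is float64 and
single-threaded, so fixed seeds give bit-identical runs.
"""

from __future__ import annotations

from typing import Callable, Sequence

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.misc.flatten import flatten

Array = np.ndarray


def softplus(x):
    return anp.logaddexp(0.0, x)


def relu(x):
    return anp.maximum(0.0, x)


def init_mlp(sizes: Sequence[int], rng: np.random.Generator) -> list[dict]:
    """Glorot-uniform initialized dense layers [{'W', 'b'}, ...]."""
    layers = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        layers.append(
            {
                "W": rng.uniform(-limit, limit, size=(fan_in, fan_out)),
                "b": np.zeros(fan_out),
            }
        )
    return layers


def mlp_forward(layers, x, activation=relu, dropout_masks=None):
    """Apply dense layers with an activation after every layer.

    ``dropout_masks`` (one per layer, pre-scaled by 1/keep) are supplied by the
    training loop; inference passes ``None`` and is deterministic.
    """
    h = x
    for i, layer in enumerate(layers):
        h = activation(h @ layer["W"] + layer["b"])
        if dropout_masks is not None:
            h = h * dropout_masks[i]
    return h


def linear_forward(layer, x):
    return x @ layer["W"] + layer["b"]


def make_dropout_masks(layers, batch: int, rate: float, rng: np.random.Generator):
    if rate <= 0:
        return None
    keep = 1.0 - rate
    return [
        rng.binomial(1, keep, size=(batch, layer["W"].shape[1])) / keep
        for layer in layers
    ]


def l2_penalty(params) -> float:
    flat, _ = flatten(params)
    return anp.sum(flat * flat)


def gaussian_logpdf_sum(x, mean, var):
    """Sum over all entries of log N(x; mean, var) with diagonal variance."""
    return anp.sum(
        -0.5 * (anp.log(2.0 * anp.pi) + anp.log(var) + (x - mean) ** 2 / var)
    )


def kl_standard_normal(mu, var):
    """Sum over entries of KL( N(mu, var) || N(0, I) ) — nonnegative."""
    return 0.5 * anp.sum(var + mu**2 - 1.0 - anp.log(var))


class Adam:
    """Adam over a flattened parameter pytree."""

    def __init__(self, params, lr: float = 1e-3, b1: float = 0.9, b2: float = 0.999,
                 eps: float = 1e-8):
        self.x, self.unflatten = flatten(params)
        self.lr = lr
        self.b1, self.b2, self.eps = b1, b2, eps
        self.m = np.zeros_like(self.x)
        self.v = np.zeros_like(self.x)
        self.t = 0

    @property
    def params(self):
        return self.unflatten(self.x)

    def step(self, grad_pytree, lr: float | None = None):
        g, _ = flatten(grad_pytree)
        self.t += 1
        lr = self.lr if lr is None else lr
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g * g
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        self.x = self.x - lr * mhat / (np.sqrt(vhat) + self.eps)


def minimize_adam(
    loss_fn: Callable,
    params,
    lr: float = 1e-3,
    max_steps: int = 5000,
    rel_tol: float = 1e-5,
    patience: int = 25,
    callback: Callable | None = None,
):
    """Minimize ``loss_fn(params)`` with Adam until the relative objective
    change stays below ``rel_tol`` over ``patience`` steps (or ``max_steps``).

    Returns (best_params, history, converged).
    """
    vag = value_and_grad(loss_fn)
    opt = Adam(params, lr=lr)
    history: list[float] = []
    best_val, best_x = np.inf, opt.x.copy()
    window_ref = np.inf
    converged = False
    for step in range(max_steps):
        val, grads = vag(opt.params)
        val = float(val)
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite objective at step {step}: {val}")
        history.append(val)
        if val < best_val:
            best_val, best_x = val, opt.x.copy()
        # convergence: relative improvement over the last `patience` steps
        if step % patience == 0:
            if window_ref - best_val < rel_tol * max(1.0, abs(window_ref)):
                converged = True
                break
            window_ref = best_val
        opt.step(grads)
        if callback is not None:
            callback(step, val, opt.params)
    return opt.unflatten(best_x), history, converged
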