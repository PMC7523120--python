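"""Approximate posterior q(z|x): Gaussian encoder + inverse autoregressive flow.

The encoder is conditioned on the covariates only (labels are unavailable at
inference time) and produces a diagonal-Gaussian base (mu0, sigma0) plus a
context vector. T affine IAF steps

    z_t = mu_t + sigma_t * z_{t-1}

refine the base draw; the (mu_t, sigma_t) come from masked autoregressive
conditioners over (z_{t-1}, context) so the Jacobian of each step is
triangular and the exact log-density stays closed-form:

    log q(z_T | x) = -sum_j ( e_j^2/2 + log(2 pi)/2 + sum_{t=0..T} log sigma_{t,j} )

with e the standardized base residual (z_0 - mu0)/sigma0. An *implicit*
encoder variant (a feed-forward sampler with injected noise, no tractable
density) is provided for the ablation in which the prior is matched only
through the adversarial penalty.

Conventions: natural dimension ordering for the autoregressive masks (no
permutations between steps); sigma_t = sigmoid(s + 1.5) for stability;
sigma_0 through softplus; context feeds every flow step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

from .nn import init_mlp, mlp_forward, sigmoid, softplus

LOG_2PI = float(np.log(2.0 * np.pi))


class UnsupportedOperationError(RuntimeError):
    """Raised when a log-density is requested from a density-free sampler."""


@dataclass
class EncoderOutput:
    """Base-distribution parameters and conditioning vector for one batch."""

    mu0: np.ndarray      # (n, p)
    sigma0: np.ndarray   # (n, p), > 0
    context: np.ndarray  # (n, c)


@dataclass
class FlowPath:
    """A flow trajectory with its exact log-density.

    ``z_steps`` holds z_0 ... z_T (length T+1); ``log_sigma_sums`` accumulates
    sum_{t=0..T} log sigma_{t,j} per dimension; ``log_q`` is the exact
    log-posterior density of z_T, one scalar per row.
    """

    z_steps: list = field(default_factory=list)
    log_sigma_sums: np.ndarray | None = None
    log_q: np.ndarray | None = None
    eps: np.ndarray | None = None

    @property
    def z(self):
        return self.z_steps[-1]


def _made_degrees(p: int, hidden: int, rng: np.random.Generator):
    d_in = np.arange(1, p + 1)
    max_deg = max(p - 1, 1)
    d_hidden = (np.arange(hidden) % max_deg) + 1
    return d_in, d_hidden


def make_made_masks(p: int, hidden_sizes, context_dim: int, seed: int = 0):
    """Binary masks for a MADE-style conditioner over (z, context).

    Context units get degree 0 so every output may use them; output j may
    depend only on z-inputs with degree strictly below j, which makes
    d mu_t / d z_{t-1} and d sigma_t / d z_{t-1} strictly upper triangular.
    """
    rng = np.random.default_rng(seed)
    d_in, _ = _made_degrees(p, hidden_sizes[0], rng)
    in_degrees = np.concatenate([d_in, np.zeros(context_dim, dtype=int)])
    masks = []
    prev = in_degrees
    for h in hidden_sizes:
        _, d_h = _made_degrees(p, h, rng)
        masks.append((d_h[None, :] >= prev[:, None]).astype(float))
        prev = d_h
    out_degrees = np.arange(1, p + 1)
    masks.append((out_degrees[None, :] > prev[:, None]).astype(float))
    return masks


def init_encoder(d_in: int, p: int, hidden: int = 32, context_dim: int = 8,
                 rng: np.random.Generator | None = None):
    """Feed-forward initial encoder: x -> (mu0, sigma0_raw, context)."""
    rng = rng or np.random.default_rng(0)
    return {
        "trunk": init_mlp([d_in, hidden, hidden], rng),
        "mu": init_mlp([hidden, p], rng),
        "sigma_raw": init_mlp([hidden, p], rng),
        "context": init_mlp([hidden, context_dim], rng),
    }


def init_flow(p: int, T: int, hidden: int = 32, context_dim: int = 8,
              rng: np.random.Generator | None = None, mask_seed: int = 0):
    """T masked autoregressive conditioners, one per flow step."""
    rng = rng or np.random.default_rng(0)
    steps = []
    for _ in range(T):
        steps.append({
            "W1": rng.normal(0, 0.1 / np.sqrt(p + context_dim), (p + context_dim, hidden)),
            "b1": np.zeros(hidden),
            "W2": rng.normal(0, 0.1 / np.sqrt(hidden), (hidden, hidden)),
            "b2": np.zeros(hidden),
            "W_mu": rng.normal(0, 0.1 / np.sqrt(hidden), (hidden, p)),
            "b_mu": np.zeros(p),
            "W_s": rng.normal(0, 0.1 / np.sqrt(hidden), (hidden, p)),
            "b_s": np.zeros(p),
        })
    masks = make_made_masks(p, [hidden, hidden], context_dim, seed=mask_seed)
    return {"steps": steps, "masks": masks, "T": T, "p": p, "context_dim": context_dim}


def encode(enc_params, x):
    """Deterministic map x -> EncoderOutput; rejects non-finite inputs."""
    x = anp.atleast_2d(x)
    if not hasattr(x, "_value") and not np.all(np.isfinite(np.asarray(x, dtype=float))):
        raise ValueError("encoder input contains NaN or infinite values")
    d_expected = enc_params["trunk"][0]["W"].shape[0]
    if x.shape[-1] != d_expected:
        raise ValueError(f"feature dimension {x.shape[-1]} != model dimension {d_expected}")
    h = x
    for layer in enc_params["trunk"]:
        h = anp.tanh(h @ layer["W"] + layer["b"])
    mu0 = mlp_forward(enc_params["mu"], h)
    sigma0 = softplus(mlp_forward(enc_params["sigma_raw"], h))
    context = mlp_forward(enc_params["context"], h)
    return EncoderOutput(mu0=mu0, sigma0=sigma0, context=context)


def _conditioner(step, masks, z_prev, context):
    """One masked autoregressive conditioner: (z, context) -> (mu_t, sigma_t)."""
    inp = anp.concatenate([z_prev, context], axis=-1)
    m1, m2, m_out = masks
    h = anp.tanh(inp @ (step["W1"] * m1) + step["b1"])
    h = anp.tanh(h @ (step["W2"] * m2) + step["b2"])
    mu_t = h @ (step["W_mu"] * m_out) + step["b_mu"]
    s_pre = h @ (step["W_s"] * m_out) + step["b_s"]
    sigma_t = sigmoid(s_pre + 1.5)
    return mu_t, sigma_t


def flow_forward(eps, enc: EncoderOutput, flow_params) -> FlowPath:
    """Push a standard-normal draw through the base and T IAF steps.

    Returns the full trajectory with the exact log-density of the endpoint.
    With T=0 the log-density reduces to the diagonal-Gaussian density of z_0.
    """
    eps = anp.atleast_2d(eps)
    z = enc.mu0 + enc.sigma0 * eps
    z_steps = [z]
    log_sigma_sum = anp.log(enc.sigma0)
    for step in flow_params["steps"]:
        mu_t, sigma_t = _conditioner(step, flow_params["masks"], z, enc.context)
        z = mu_t + sigma_t * z
        z_steps.append(z)
        log_sigma_sum = log_sigma_sum + anp.log(sigma_t)
    log_q_val = -anp.sum(0.5 * eps**2 + 0.5 * LOG_2PI + log_sigma_sum, axis=-1)
    return FlowPath(z_steps=z_steps, log_sigma_sums=log_sigma_sum, log_q=log_q_val, eps=eps)


def log_q(path: FlowPath, enc: EncoderOutput | None = None):
    """Exact log-density of the flow endpoint (closed form, already accumulated)."""
    if path.log_q is None:
        raise UnsupportedOperationError(
            "log q(z|x) is not available for this sample (implicit encoder?)")
    return path.log_q


def flow_inverse(z_T, enc: EncoderOutput, flow_params, n_sweeps: int | None = None):
    """Recover z_0 from z_T by sequential per-dimension inversion of each step.

    Because (mu_t, sigma_t) for dimension j depend only on dimensions < j of
    z_{t-1}, filling dimensions in ascending order inverts each affine step
    exactly in p passes.
    """
    p = flow_params["p"]
    z = np.atleast_2d(np.asarray(z_T, dtype=float))
    for step in reversed(flow_params["steps"]):
        z_prev = np.zeros_like(z)
        for _ in range(p):
            mu_t, sigma_t = _conditioner(step, flow_params["masks"], z_prev, enc.context)
            z_prev = (z - mu_t) / sigma_t
        z = z_prev
    return z


# -- implicit (density-free) encoder ----------------------------------------

def init_implicit(d_in: int, p: int, hidden: int = 32,
                  rng: np.random.Generator | None = None):
    """Feed-forward sampler z = f(x, eps); used when no tractable density is needed."""
    rng = rng or np.random.default_rng(0)
    return {"net": init_mlp([d_in + p, hidden, hidden, p], rng)}


def implicit_sample(imp_params, x, rng=None, seed: int | None = None, eps=None):
    """Draw posterior samples from the implicit encoder.

    Returns a :class:`FlowPath` whose ``log_q`` is None; requesting the
    density raises :class:`UnsupportedOperationError`.
    """
    x = anp.atleast_2d(x)
    p = imp_params["net"][-1]["W"].shape[1]
    if eps is None:
        rng = rng if rng is not None else np.random.default_rng(seed)
        eps = rng.standard_normal((np.shape(x)[0], p))
    z = mlp_forward(imp_params["net"], anp.concatenate([x, eps], axis=-1))
    return FlowPath(z_steps=[z], log_sigma_sums=None, log_q=None, eps=eps)
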