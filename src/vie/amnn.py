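"""Additive monotonic neural network decoder with complementary log-log link.

The risk score of a latent vector z is

    H(z; theta) = sum_j alpha_j * int_l^{z_j} h_j(s) ds + gamma,

where each h_j is a one-input network made strictly positive by an
exponential output activation, alpha_j is a signed direction weight (an
"event stimulator" when positive, a "blocker" when negative) and gamma is a
bias. Each additive term is monotone in z_j with the sign of alpha_j, which
disentangles the per-dimension effect of the latent representation on risk.

The integral is evaluated by trapezoidal quadrature on a uniform grid whose
upper endpoint is z_j, so gradients flow through both the integrand and the
integration limit. The binary likelihood uses the complementary log-log link
P(y=1) = 1 - exp(-exp(H)), which is more tail-sensitive than the logistic.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

from .nn import asarr, init_mlp, mlp_forward

#: Lower integration limit; below the effective support of the latent prior.
DEFAULT_LOWER_END = -10.0
#: Default number of trapezoid panels.
DEFAULT_N_GRID = 64
#: exp-argument clamp in the CLL link.
CLL_CLAMP = 30.0


def init_amnn(p: int, hidden: int = 16, rng: np.random.Generator | None = None,
              lower_end: float = DEFAULT_LOWER_END, n_grid: int = DEFAULT_N_GRID):
    """Parameters: p stacked one-input integrand nets, direction weights, bias.

    Integrand weights are stacked along a leading latent-dimension axis:
    W1 (p, 1, hidden), W2 (p, hidden, 1). alpha and gamma start small and are
    learned freely (sign unconstrained).
    """
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    rng = rng or np.random.default_rng(0)
    return {
        "W1": rng.normal(0, 0.1, (p, 1, hidden)),
        "b1": np.zeros((p, hidden)),
        "W2": rng.normal(0, 0.1 / np.sqrt(hidden), (p, hidden, 1)),
        "b2": np.zeros((p, 1)),
        "alpha": rng.normal(0, 0.1, p),
        "gamma": np.array(0.0),
        "lower_end": float(lower_end),
        "n_grid": int(n_grid),
    }


def integrand(params, s):
    """h_j(s) = exp(net_j(s)) > 0 for every latent dimension at once.

    ``s`` has shape (..., p, k); returns the same shape. The exponential
    output activation guarantees strict positivity, hence monotonicity of the
    integral.
    """
    s = asarr(s)
    # (..., p, k, 1) @ (p, 1, hidden) -> (..., p, k, hidden)
    h = anp.tanh(s[..., None] * params["W1"][..., 0, :][..., None, :]
                 + params["b1"][..., None, :])
    out = anp.sum(h * anp.swapaxes(params["W2"], -1, -2), axis=-1) + params["b2"]
    return anp.exp(out)


def integrate_dim(params, z, n_grid: int | None = None):
    """Signed trapezoidal integral of each h_j from the lower end to z_j.

    ``z`` has shape (..., p). The grid is uniform on [l, z_j] per element, so
    the result is negative when z_j < l and exactly 0 when z_j = l.
    """
    z = asarr(z)
    n = int(n_grid if n_grid is not None else params.get("n_grid", DEFAULT_N_GRID))
    l = params.get("lower_end", DEFAULT_LOWER_END)
    frac = np.linspace(0.0, 1.0, n + 1)  # (k,)
    s = l + (z[..., None] - l) * frac    # (..., p, k)
    h = integrand(params, s)
    weights = np.full(n + 1, 1.0)
    weights[0] = weights[-1] = 0.5
    dz = (z - l) / n
    return dz * anp.sum(h * weights, axis=-1)


def amnn_forward(params, z):
    """H(z) = sum_j alpha_j * integral_j + gamma; shape (...,) -> scalar per row."""
    z = asarr(z)
    p = params["alpha"].shape[0]
    if z.shape[-1] != p:
        raise ValueError(f"latent dimension {z.shape[-1]} != decoder dimension {p}")
    terms = params["alpha"] * integrate_dim(params, z)
    return anp.sum(terms, axis=-1) + params["gamma"]


def init_mlp_decoder(p: int, hidden: int = 32, rng: np.random.Generator | None = None):
    """Plain feed-forward score network (the non-monotone ablation decoder)."""
    rng = rng or np.random.default_rng(0)
    return {"net": init_mlp([p, hidden, 1], rng)}


def mlp_decoder_forward(params, z):
    z = asarr(z)
    return mlp_forward(params["net"], z)[..., 0]


def cll_log_lik(y, a):
    """Complementary log-log log-likelihood of binary labels given scores.

    y=1 -> log(1 - exp(-exp(a))); y=0 -> -exp(a). The exponent is clamped at
    +-CLL_CLAMP to avoid overflow; computed with expm1 for stability.
    """
    y_arr = np.asarray(y)
    if not np.all(np.isin(y_arr, (0, 1))):
        raise ValueError("labels must be binary 0/1")
    a = anp.clip(a, -CLL_CLAMP, CLL_CLAMP)
    b = anp.exp(a)
    log_p1 = anp.log(-anp.expm1(-b))
    return anp.where(y_arr == 1, log_p1, -b)


def predicted_risk(a):
    """Inverse CLL link: P(y=1) = 1 - exp(-exp(a)), in (0, 1)."""
    a = anp.clip(a, -CLL_CLAMP, CLL_CLAMP)
    return -anp.expm1(-anp.exp(a))


def risk_curves(params, z_grid):
    """Per-dimension partial risk contributions alpha_j * integral_j on a grid.

    Returns an (len(z_grid), p) array for exporting one-dimensional
    latent-vs-risk profiles as delimited text.
    """
    z_grid = np.asarray(z_grid, dtype=float)
    p = params["alpha"].shape[0]
    z = np.tile(z_grid[:, None], (1, p))
    return np.asarray(params["alpha"] * integrate_dim(params, z))
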