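"""Generalized Pareto distribution and the truncated-Gaussian/GPD mixture prior.

The latent prior is, per dimension, a standard Gaussian for values below a high
threshold ``u`` and a generalized Pareto tail above it:

    F(z) = Phi(z)                                   for z <= u
    F(z) = Phi(u) + (1 - Phi(u)) * G_{xi,sigma}(z-u) for z >  u

Above the threshold this is itself a GPD with *translated* parameters
(xi~, sigma~, u~); building the upper branch through the translation makes the
mixture CDF continuous at ``u`` by construction. Only the right tail is
modeled: rare events are mapped to large latent values, and the direction of
the effect on the outcome is carried by the decoder's per-dimension sign
weights, not by a left tail.

All functions are autograd-differentiable in (xi, sigma) so the tail
parameters can be learned by gradient ascent on the variational objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np
from autograd.scipy.stats import norm as _norm
from scipy.stats import norm as _snorm

from .nn import asarr, inv_softplus, softplus

#: |xi| below this is treated as the exponential (xi = 0) branch.
XI_TOL = 1e-6

#: Default threshold: the 99th percentile of the standard normal body.
DEFAULT_U = float(_snorm.ppf(0.99))


@dataclass(frozen=True)
class GPDParams:
    """Shape ``xi``, scale ``sigma`` (> 0) and threshold ``u`` of a GPD.

    For ``xi < 0`` the support is the bounded interval
    ``[u, u - sigma/xi]``; for ``xi >= 0`` it is ``[u, inf)``.
    """

    xi: float
    sigma: float
    u: float = 0.0

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"GPD scale must be positive, got sigma={self.sigma}")


@dataclass(frozen=True)
class TranslatedTail:
    """GPD parameters of the mixture's upper branch expressed on the z scale."""

    xi_t: float
    sigma_t: float
    u_t: float


def _as_params(params, xi, sigma, u):
    if params is not None:
        return params.xi, params.sigma, params.u
    return xi, sigma, u


def gpd_cdf(x, params: GPDParams | None = None, *, xi=None, sigma=None, u=None):
    """CDF of the generalized Pareto distribution.

    Uses the exponential branch when ``|xi| < XI_TOL``. Below ``u`` the CDF is
    0; for ``xi < 0``, points above the finite upper endpoint clamp to 1.
    """
    xi, sigma, u = _as_params(params, xi, sigma, u)
    x = asarr(x)
    _validate_sigma(sigma)
    t = anp.maximum((x - u) / sigma, 0.0)
    xi_arr = asarr(xi)
    near_zero = anp.abs(xi_arr) < XI_TOL
    xi_safe = anp.where(near_zero, 1.0, xi_arr)
    arg = anp.maximum(1.0 + xi_safe * t, 1e-300)
    general = 1.0 - arg ** (-1.0 / xi_safe)
    exponential = 1.0 - anp.exp(-t)
    return anp.where(near_zero, exponential, general)


def gpd_log_pdf(x, params: GPDParams | None = None, *, xi=None, sigma=None, u=None):
    """Log-density of the GPD; ``-inf`` outside the support."""
    xi, sigma, u = _as_params(params, xi, sigma, u)
    x = asarr(x)
    _validate_sigma(sigma)
    t = (x - u) / sigma
    xi_arr = asarr(xi)
    near_zero = anp.abs(xi_arr) < XI_TOL
    xi_safe = anp.where(near_zero, 1.0, xi_arr)
    neg = xi_arr < -XI_TOL  # only a genuinely negative shape bounds the support
    upper_bound = -1.0 / anp.where(neg, xi_arr, -1.0)
    in_support = (t >= 0) & (~neg | (t <= upper_bound))
    t_safe = anp.where(in_support, t, 0.0)
    arg = anp.maximum(1.0 + xi_safe * t_safe, 1e-300)
    general = -anp.log(sigma) - (1.0 + 1.0 / xi_safe) * anp.log(arg)
    exponential = -anp.log(sigma) - t_safe
    out = anp.where(near_zero, exponential, general)
    return anp.where(in_support, out, -anp.inf)


def gpd_quantile(q, params: GPDParams | None = None, *, xi=None, sigma=None, u=None):
    """Inverse CDF (closed form for both branches)."""
    xi, sigma, u = _as_params(params, xi, sigma, u)
    q = asarr(q)
    _validate_sigma(sigma)
    xi_arr = asarr(xi)
    near_zero = anp.abs(xi_arr) < XI_TOL
    xi_safe = anp.where(near_zero, 1.0, xi_arr)
    one_m_q = anp.maximum(1.0 - q, 1e-300)
    general = u + sigma * (one_m_q ** (-xi_safe) - 1.0) / xi_safe
    exponential = u - sigma * anp.log(one_m_q)
    return anp.where(near_zero, exponential, general)


def _validate_sigma(sigma):
    s = np.asarray(sigma, dtype=float) if not hasattr(sigma, "_value") else None
    if s is not None and np.any(s <= 0):
        raise ValueError("GPD scale sigma must be strictly positive")


def translate_tail_params(xi, sigma, u):
    """Re-express the upper mixture branch as a GPD on the original z scale.

    For xi != 0:  sigma~ = sigma * (1 - Phi(u))**xi,
                  u~ = u - sigma~ * ((1 - Phi(u))**(-xi) - 1) / xi.
    For xi  = 0:  sigma~ = sigma,  u~ = u + sigma * log(1 - Phi(u)).
    The shape is unchanged. The branch switch uses the same tolerance as
    :func:`gpd_cdf`.
    """
    _validate_sigma(sigma)
    xi_arr = asarr(xi)
    tail_mass = _norm.cdf(-asarr(u))  # 1 - Phi(u), accurately
    near_zero = anp.abs(xi_arr) < XI_TOL
    xi_safe = anp.where(near_zero, 1.0, xi_arr)
    sigma_t_gen = sigma * tail_mass**xi_safe
    u_t_gen = u - sigma_t_gen * (tail_mass ** (-xi_safe) - 1.0) / xi_safe
    sigma_t_exp = sigma * anp.ones_like(xi_arr)
    u_t_exp = u + sigma * anp.log(tail_mass) * anp.ones_like(xi_arr)
    sigma_t = anp.where(near_zero, sigma_t_exp, sigma_t_gen)
    u_t = anp.where(near_zero, u_t_exp, u_t_gen)
    if anp.ndim(xi) == 0 and not hasattr(xi_arr, "_value"):
        return TranslatedTail(float(xi_arr), float(sigma_t), float(u_t))
    return TranslatedTail(xi_arr, sigma_t, u_t)


# -- mixture: functional forms, differentiable in (xi, sigma) ----------------

def mixture_cdf_fn(z, xi, sigma, u):
    """Mixture CDF: Gaussian body below ``u``, translated GPD above."""
    z = asarr(z)
    tail = translate_tail_params(xi, sigma, u)
    upper = gpd_cdf(anp.maximum(z, u), xi=tail.xi_t, sigma=tail.sigma_t, u=tail.u_t)
    lower = _norm.cdf(anp.minimum(z, u))
    return anp.where(z <= u, lower, upper)


def mixture_log_pdf_fn(z, xi, sigma, u):
    """Mixture log-density: standard normal below ``u``, translated GPD above."""
    z = asarr(z)
    body = _norm.logpdf(anp.minimum(z, u))
    tail = translate_tail_params(xi, sigma, u)
    upper = gpd_log_pdf(anp.maximum(z, u), xi=tail.xi_t, sigma=tail.sigma_t, u=tail.u_t)
    return anp.where(z <= u, body, upper)


def mixture_quantile_fn(q, xi, sigma, u):
    """Inverse mixture CDF; differentiable in (xi, sigma) for reparameterized sampling."""
    q = asarr(q)
    phi_u = _snorm.cdf(np.asarray(u, dtype=float))
    tail = translate_tail_params(xi, sigma, u)
    body = _snorm.ppf(np.clip(np.where(np.asarray(q) <= phi_u, np.asarray(q), 0.5), 1e-300, 1 - 1e-16))
    upper = gpd_quantile(anp.maximum(q, phi_u), xi=tail.xi_t, sigma=tail.sigma_t, u=tail.u_t)
    return anp.where(q <= phi_u, body, upper)


class MixedGPDPrior:
    """Factorized latent prior with per-dimension learnable tail parameters.

    Each of the ``p`` latent dimensions carries its own (xi_j, sigma_j); the
    threshold ``u`` is a single user-set constant shared across dimensions,
    defaulting to the standard-normal 99% quantile. The scale is stored
    unconstrained (``sigma_raw``) and mapped through softplus.
    """

    def __init__(self, p: int, u: float = DEFAULT_U, xi_init: float = 0.1,
                 sigma_init: float = 1.0):
        if p < 1:
            raise ValueError("latent dimension p must be >= 1")
        self.p = p
        self.u = float(u)
        self.params = {
            "xi": np.full(p, float(xi_init)),
            "sigma_raw": np.full(p, inv_softplus(sigma_init)),
        }

    # params may be an external (traced) tree during training
    def sigma(self, params=None):
        params = self.params if params is None else params
        return softplus(params["sigma_raw"])

    def _dim(self, params, dim):
        params = self.params if params is None else params
        xi = params["xi"]
        sigma = softplus(params["sigma_raw"])
        if dim is not None:
            if not 0 <= dim < self.p:
                raise IndexError(f"dim {dim} out of range for p={self.p}")
            return xi[dim], sigma[dim]
        return xi, sigma

    def cdf(self, z, dim: int | None = None, params=None):
        xi, sigma = self._dim(params, dim)
        return mixture_cdf_fn(z, xi, sigma, self.u)

    def log_pdf(self, z, dim: int | None = None, params=None):
        xi, sigma = self._dim(params, dim)
        return mixture_log_pdf_fn(z, xi, sigma, self.u)

    def quantile(self, q, dim: int | None = None, params=None):
        xi, sigma = self._dim(params, dim)
        return mixture_quantile_fn(q, xi, sigma, self.u)

    def log_pdf_sum(self, z, params=None, floor: float | None = None):
        """Row-wise log-density of an (n, p) latent array (sum over dimensions).

        ``floor`` clips each per-dimension log-density from below; training
        uses a finite floor so a sample outside a bounded (xi < 0) tail
        support yields a large penalty instead of -inf.
        """
        xi, sigma = self._dim(params, None)
        per_dim = mixture_log_pdf_fn(z, xi, sigma, self.u)
        if floor is not None:
            per_dim = anp.maximum(per_dim, floor)
        return anp.sum(per_dim, axis=-1)

    def sample(self, n: int, rng=None, seed: int | None = None, params=None):
        """Draw ``(n, p)`` latents by inverse-CDF sampling; differentiable in params."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        v = rng.uniform(size=(n, self.p))
        xi, sigma = self._dim(params, None)
        return mixture_quantile_fn(v, xi, sigma, self.u)
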