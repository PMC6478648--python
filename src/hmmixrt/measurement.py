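"""State-conditional measurement models for a single item.

Responses follow a 2PL (optionally 3PL for probability/information
utilities): P(x=1 | theta, state c) = gamma + (1-gamma) * omega(alpha_c *
theta + beta_c) with gamma fixed at 0 in the estimable models.  Categorized
response times follow a partial-credit model subject to heteroscedasticity:
the adjacent-category log-odds are (nu_it - delta_c - lambda_i * tau) /
sigma_c, with delta0 = 0 and sigma0 = 1 as identification anchors.  Larger
latent speed tau shifts mass toward category 0 (the fastest bin) when
lambda_i > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, softmax
from scipy.stats import norm

from .core import ModelSpec, ParameterSet


@dataclass(frozen=True)
class LatentPoint:
    """A point (theta, tau) on the bivariate latent scale."""

    theta: float
    tau: float


def _link(x, link: str):
    if link == "logistic":
        return expit(x)
    if link == "probit":
        return norm.cdf(x)
    raise ValueError(f"unknown link {link!r}")


def prob_correct(point: LatentPoint, alpha: float, beta: float, gamma: float = 0.0,
                 link: str = "logistic") -> float:
    """3PL probability of a correct response, gamma + (1-gamma)*omega(alpha*theta + beta)."""
    if not 0.0 <= gamma < 1.0:
        raise ValueError("gamma must lie in [0, 1)")
    return float(gamma + (1.0 - gamma) * _link(alpha * point.theta + beta, link))


def _state_item_params(params: ParameterSet, spec: ModelSpec, item: int, state: int):
    if state not in (0, 1):
        raise ValueError("state must be 0 or 1")
    if state == 1 and not spec.has_states:
        raise ValueError("baseline variant has a single state (state 0)")
    if state == 0:
        return float(params.alpha0[item]), float(params.beta0[item])
    return float(params.alpha1[item]), float(params.beta1[item])


def response_pmf(x: int, point: LatentPoint, state: int, params: ParameterSet,
                 spec: ModelSpec, item: int = 0) -> float:
    """State-conditional Bernoulli pmf of a response (2PL, gamma = 0)."""
    if x not in (0, 1):
        raise ValueError("x must be 0 or 1")
    alpha, beta = _state_item_params(params, spec, item, state)
    p = prob_correct(point, alpha, beta, 0.0)
    return p if x == 1 else 1.0 - p


def pcm_category_probs(tau, nu_i: np.ndarray, lam_i: float, delta_c: float,
                       sigma_c: float) -> np.ndarray:
    """Heteroscedastic partial-credit category probabilities.

    ``tau`` may be scalar or a vector; returns probabilities with the
    category axis last.  ``nu_i`` holds the T-1 free thresholds (nu_i0 = 0).
    """
    if sigma_c <= 0:
        raise ValueError("sigma_c must be > 0")
    scalar = np.ndim(tau) == 0
    tau_arr = np.atleast_1d(np.asarray(tau, dtype=float))
    nu_full = np.concatenate([[0.0], np.asarray(nu_i, dtype=float)])  # (T,)
    s = (nu_full[None, :] - delta_c - lam_i * tau_arr[:, None]) / sigma_c
    logits = np.cumsum(s, axis=1)
    out = softmax(logits, axis=1)
    return out[0] if scalar else out


def pcm_pmf(t: int, point: LatentPoint, state: int, params: ParameterSet,
            spec: ModelSpec, item: int = 0) -> float:
    """State-conditional pmf of one RT category under the heteroscedastic PCM."""
    T = spec.n_categories
    if not 0 <= t <= T - 1:
        raise ValueError(f"category {t} outside 0..{T - 1}")
    if state == 1 and not spec.has_states:
        raise ValueError("baseline variant has a single state (state 0)")
    delta_c = 0.0 if state == 0 else float(params.delta1)
    sigma_c = 1.0 if state == 0 else params.effective_sigma1(spec)
    probs = pcm_category_probs(point.tau, params.nu[item], float(params.lam[item]), delta_c, sigma_c)
    return float(probs[t])


# ---------------------------------------------------------------------------
# Information functions
# ---------------------------------------------------------------------------


def item_information_response(theta_grid, alpha: float, beta: float,
                              gamma: float = 0.0) -> np.ndarray:
    """3PL item information P'(theta)^2 / (P (1-P)); alpha^2 P(1-P) when gamma=0."""
    theta = np.asarray(theta_grid, dtype=float)
    L = expit(alpha * theta + beta)
    P = gamma + (1.0 - gamma) * L
    dP = (1.0 - gamma) * alpha * L * (1.0 - L)
    return dP**2 / (P * (1.0 - P))


def rt_category_information(tau_grid, nu_i: np.ndarray, lam_i: float,
                            delta_c: float = 0.0, sigma_c: float = 1.0) -> np.ndarray:
    """Fisher information about tau in one item's categorized response time.

    The PCM is an exponential family in tau with category score
    a_t = -lambda*(t+1)/sigma, so -E[d^2/dtau^2 log pmf] equals the category
    variance of a_t, i.e. (lambda/sigma)^2 * Var(t) under the category
    distribution at tau.
    """
    tau = np.atleast_1d(np.asarray(tau_grid, dtype=float))
    probs = pcm_category_probs(tau, nu_i, lam_i, delta_c, sigma_c)
    cats = np.arange(probs.shape[-1], dtype=float)
    mean = probs @ cats
    var = probs @ cats**2 - mean**2
    info = (lam_i / sigma_c) ** 2 * var
    return info if np.ndim(tau_grid) else float(info[0])


__all__ = [
    "LatentPoint", "prob_correct", "response_pmf", "pcm_category_probs", "pcm_pmf",
    "item_information_response", "rt_category_information",
]
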