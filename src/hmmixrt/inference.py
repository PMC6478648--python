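"""Marginal maximum-likelihood machinery.

The marginal log-likelihood integrates the latent (theta, tau) pair out of
the state-summed joint density with bivariate Gauss-Hermite quadrature
(default 10 points per dimension).  The correlation rho is handled by
transforming the independent product grid: theta = z1, tau = rho*z1 +
sqrt(1-rho^2)*z2, so the latent density in z-space is parameter-free and
rho enters the model only through the tau node values.

Fitting runs an EM/ECM scheme: the E-step (compiled sweep) produces
aggregated node/state posterior counts; the M-step updates the 2PL item
parameters by weighted logistic Newton steps, the PCM measurement
parameters by warm-started quasi-Newton on the aggregated adjacent-category
likelihood, the structural RT parameters (delta1, sigma1, rho) by a small
quasi-Newton step, and the chain probabilities in closed form.  Every
conditional step starts from the current value and only accepts
improvements, so the observed-data log-likelihood trace is non-decreasing.
An optional quasi-Newton refinement on the unconstrained scale follows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from . import _kernels
from .core import (
    Dataset, FitResult, ModelSpec, ParameterSet, anchor_labels,
    from_unconstrained, npar_of, to_unconstrained,
)
from .markov import chain_from_params

_PROB_EPS = 1e-6


# ---------------------------------------------------------------------------
# Quadrature
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuadratureGrid:
    """Product Gauss-Hermite grid for a correlated bivariate standard normal."""

    nodes: np.ndarray  # (Q^2, 2) columns (theta, tau)
    weights: np.ndarray  # (Q^2,), sums to 1
    Q_per_dim: int
    rho: float
    z: np.ndarray  # (Q,) one-dimensional standard-normal nodes
    z_weights: np.ndarray  # (Q,) normalized one-dimensional weights


def build_grid(rho: float, Q: int = 10) -> QuadratureGrid:
    """Gauss-Hermite product rule mapped through the correlation Cholesky factor."""
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    if Q < 2:
        raise ValueError("Q must be >= 2")
    z, w = np.polynomial.hermite_e.hermegauss(Q)
    w = w / w.sum()
    theta = np.repeat(z, Q)
    tau = rho * np.repeat(z, Q) + np.sqrt(1.0 - rho * rho) * np.tile(z, Q)
    weights = np.repeat(w, Q) * np.tile(w, Q)
    return QuadratureGrid(
        nodes=np.column_stack([theta, tau]), weights=weights,
        Q_per_dim=Q, rho=float(rho), z=z, z_weights=w,
    )


# ---------------------------------------------------------------------------
# Probability tables
# ---------------------------------------------------------------------------


def _tau_nodes(z: np.ndarray, rho: float) -> np.ndarray:
    Q = z.size
    return rho * np.repeat(z, Q) + np.sqrt(1.0 - rho * rho) * np.tile(z, Q)


def _response_table(params: ParameterSet, spec: ModelSpec, z: np.ndarray) -> np.ndarray:
    """Px[a, i, c]: probability of a correct response at theta-node a."""
    a0 = expit(np.outer(z, params.alpha0) + params.beta0[None, :])
    if spec.has_states:
        a1 = expit(np.outer(z, params.alpha1) + params.beta1[None, :])
    else:
        a1 = a0
    return np.ascontiguousarray(np.stack([a0, a1], axis=2))


def _pcm_table_from_tau(nu: np.ndarray, lam: np.ndarray, delta1: float, sigma1: float,
                        tau: np.ndarray, two_states: bool) -> np.ndarray:
    """Pt[q, i, c, t]: PCM category probabilities at tau-node q."""
    n, Tm1 = nu.shape
    nu_full = np.concatenate([np.zeros((n, 1)), nu], axis=1)  # (n, T)
    out = np.empty((tau.size, n, 2, Tm1 + 1))
    deltas = (0.0, delta1) if two_states else (0.0, 0.0)
    sigmas = (1.0, sigma1) if two_states else (1.0, 1.0)
    base = nu_full[None, :, :] - lam[None, :, None] * tau[:, None, None]  # (q, i, T)
    for c in (0, 1):
        s = (base - deltas[c]) / sigmas[c]
        logits = np.cumsum(s, axis=2)
        logits -= logits.max(axis=2, keepdims=True)
        ex = np.exp(logits)
        out[:, :, c, :] = ex / ex.sum(axis=2, keepdims=True)
    return np.ascontiguousarray(out)


def _chain_arrays(params: ParameterSet, spec: ModelSpec):
    if spec.has_states:
        chain = chain_from_params(params, spec)
        return chain.initial, chain.transition
    return np.array([1.0, 0.0]), np.array([[1.0, 0.0], [0.0, 1.0]])


def _tables(params: ParameterSet, spec: ModelSpec, z: np.ndarray):
    tau = _tau_nodes(z, params.rho)
    Px = _response_table(params, spec, z)
    delta1 = float(params.delta1) if spec.has_states else 0.0
    sigma1 = params.effective_sigma1(spec) if spec.has_states else 1.0
    Pt = _pcm_table_from_tau(params.nu, params.lam, delta1, sigma1, tau, spec.has_states)
    return Px, Pt, tau


def _sweep(data: Dataset, params: ParameterSet, spec: ModelSpec, z, zw,
           want_stats=False, want_scores=False):
    Px, Pt, tau = _tables(params, spec, z)
    init, A = _chain_arrays(params, spec)
    Q = z.size
    Wq = np.repeat(zw, Q) * np.tile(zw, Q)
    theta_q = np.repeat(z, Q)
    return _kernels.sweep(
        np.ascontiguousarray(data.responses), np.ascontiguousarray(data.rt_categories),
        Px, Pt, init, A, Wq, theta_q, tau, want_stats, want_scores,
    )


def marginal_loglik(data: Dataset, params: ParameterSet, spec: ModelSpec,
                    grid: Optional[QuadratureGrid] = None, per_person: bool = False):
    """Marginal log-likelihood of the data (missing parts contribute factor 1).

    If ``grid`` is omitted it is built from ``params.rho`` with the default
    10 points per dimension; if supplied, its one-dimensional rule is used
    (its rho is ignored in favour of ``params.rho``).
    """
    if np.any(data.rt_categories >= spec.n_categories):
        raise ValueError("data contain RT categories outside the model's range")
    params.validate(spec)
    Q = grid.Q_per_dim if grid is not None else 10
    if grid is not None:
        z, zw = grid.z, grid.z_weights
    else:
        g = build_grid(params.rho, Q)
        z, zw = g.z, g.z_weights
    out = _sweep(data, params, spec, z, zw)
    return (float(out[0]), out[1]) if per_person else float(out[0])


# ---------------------------------------------------------------------------
# M-step pieces
# ---------------------------------------------------------------------------


def _weighted_logistic_newton(z: np.ndarray, S: np.ndarray, F: np.ndarray,
                              a0: float, b0: float, max_iter: int = 30) -> tuple[float, float]:
    """Maximize sum_a S_a log p + F_a log(1-p), p = expit(a*z + b), from (a0, b0).

    Damped Newton that only accepts improving steps, so the aggregated
    Bernoulli log-likelihood never decreases.
    """
    m = S + F
    if m.sum() < 1e-10:
        return a0, b0

    def ll(a, b):
        eta = a * z + b
        return float(np.sum(S * eta - m * np.logaddexp(0.0, eta)))

    a, b = a0, b0
    cur = ll(a, b)
    for _ in range(max_iter):
        p = expit(a * z + b)
        r = S - m * p
        wv = np.maximum(m * p * (1.0 - p), 1e-12)
        g = np.array([np.sum(r * z), np.sum(r)])
        H = np.array([[np.sum(wv * z * z), np.sum(wv * z)], [np.sum(wv * z), np.sum(wv)]])
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(2), g)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        lam = 1.0
        improved = False
        for _ in range(12):
            na, nb = a + lam * step[0], b + lam * step[1]
            new = ll(na, nb)
            if new >= cur - 1e-12:
                a, b, cur = float(np.clip(na, -12, 12)), float(np.clip(nb, -12, 12)), new
                improved = True
                break
            lam *= 0.5
        if not improved or np.max(np.abs(step)) < 1e-9:
            break
    return a, b


def _pcm_objective(nu_full, lam, deltas, sigmas, tau, Tcat_i):
    """Aggregated adjacent-category neg-loglik and gradient for one item.

    ``Tcat_i`` has shape (Q2, 2, T); variables are nu (T-1) and lam.
    """
    Q2, _, T = Tcat_i.shape
    negf = 0.0
    grad_nu = np.zeros(T - 1)
    grad_lam = 0.0
    for c in (0, 1):
        W = Tcat_i[:, c, :]  # (Q2, T)
        mass = W.sum(axis=1)
        if mass.sum() < 1e-14:
            continue
        s = (nu_full[None, :] - deltas[c] - lam * tau[:, None]) / sigmas[c]
        logits = np.cumsum(s, axis=1)
        logits = logits - logits.max(axis=1, keepdims=True)
        ex = np.exp(logits)
        P = ex / ex.sum(axis=1, keepdims=True)
        negf -= float(np.sum(W * (logits - np.log(ex.sum(axis=1, keepdims=True)))))
        cats = np.arange(T, dtype=float)
        # d logit_t / d nu_z = I(t >= z) / sigma  (z >= 1)
        C_ge = np.cumsum(W[:, ::-1], axis=1)[:, ::-1]  # (Q2, T): sum_{t>=z} W
        P_ge = np.cumsum(P[:, ::-1], axis=1)[:, ::-1]
        grad_nu -= (C_ge[:, 1:] - mass[:, None] * P_ge[:, 1:]).sum(axis=0) / sigmas[c]
        K = W @ cats
        kbar = P @ cats
        grad_lam -= float(np.sum(-(tau / sigmas[c]) * (K - mass * kbar)))
    return negf, np.concatenate([grad_nu, [grad_lam]])


def _update_pcm_items(params: ParameterSet, spec: ModelSpec, Tcat: np.ndarray,
                      tau: np.ndarray) -> None:
    """Warm-started quasi-Newton update of (nu_i, lambda_i) per item, in place."""
    n, Tm1 = params.nu.shape
    two = spec.has_states
    deltas = (0.0, float(params.delta1) if two else 0.0)
    sigmas = (1.0, params.effective_sigma1(spec) if two else 1.0)
    for i in range(n):
        Tcat_i = Tcat[:, i, :, :]

        def fun(v, Tcat_i=Tcat_i):
            nu_full = np.concatenate([[0.0], v[:-1]])
            return _pcm_objective(nu_full, v[-1], deltas, sigmas, tau, Tcat_i)

        x0 = np.concatenate([params.nu[i], [params.lam[i]]])
        f0 = fun(x0)[0]
        res = minimize(fun, x0, jac=True, method="L-BFGS-B", options={"maxiter": 8})
        if np.all(np.isfinite(res.x)) and res.fun <= f0 + 1e-10:
            params.nu[i] = res.x[:-1]
            params.lam[i] = res.x[-1]


def _update_structural_rt(params: ParameterSet, spec: ModelSpec, Tcat: np.ndarray,
                          z: np.ndarray) -> None:
    """Update (delta1, sigma1, rho) -- whichever the variant frees -- in place.

    delta1 is left unconstrained during EM (the delta1 > 0 label anchor is
    applied after convergence by relabeling); sigma1 is optimized on the log
    scale and rho on the artanh scale.
    """
    two = spec.has_states
    hetero = spec.is_hetero
    n = params.nu.shape[0]
    nu_full = np.concatenate([np.zeros((n, 1)), params.nu], axis=1)

    def unpack(u):
        k = 0
        delta1 = sigma1 = None
        if two:
            delta1 = u[k]; k += 1
            if hetero:
                sigma1 = float(np.exp(u[k])); k += 1
        rho = float(np.tanh(u[k]))
        return delta1, sigma1, rho

    def fun(u):
        delta1, sigma1, rho = unpack(u)
        tau = _tau_nodes(z, rho)
        deltas = (0.0, delta1 if two else 0.0)
        sigmas = (1.0, sigma1 if hetero else 1.0)
        neg = 0.0
        for c in (0, 1) if two else (0,):
            W = Tcat[:, :, c, :]  # (Q2, n, T)
            s = (nu_full[None, :, :] - deltas[c] - params.lam[None, :, None] * tau[:, None, None]) / sigmas[c]
            logits = np.cumsum(s, axis=2)
            logits -= logits.max(axis=2, keepdims=True)
            lse = np.log(np.exp(logits).sum(axis=2, keepdims=True))
            neg -= float(np.sum(W * (logits - lse)))
        if not two:
            # state-1 slots of Tcat are empty in the baseline model
            pass
        return neg

    u0 = []
    if two:
        u0.append(float(params.delta1))
        if hetero:
            u0.append(np.log(params.effective_sigma1(spec)))
    u0.append(np.arctanh(np.clip(params.rho, -0.999999, 0.999999)))
    u0 = np.array(u0)
    res = minimize(fun, u0, method="L-BFGS-B", options={"maxiter": 10})
    if np.all(np.isfinite(res.x)) and res.fun <= fun(u0) + 1e-10:
        delta1, sigma1, rho = unpack(res.x)
        if two:
            params.delta1 = float(delta1)
            if hetero:
                params.sigma1 = float(sigma1)
        params.rho = rho


def _update_chain(params: ParameterSet, spec: ModelSpec, init_c, trans_c, marg_c) -> None:
    if not spec.has_states:
        return
    clip = lambda p: float(np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS))  # noqa: E731
    if spec.is_markov:
        params.pi1 = clip(init_c[1] / max(init_c.sum(), 1e-300))
        params.pi1_given0 = clip(trans_c[0, 1] / max(trans_c[0].sum(), 1e-300))
        params.pi1_given1 = clip(trans_c[1, 1] / max(trans_c[1].sum(), 1e-300))
    else:
        params.pi1 = clip(marg_c[1] / max(marg_c.sum(), 1e-300))


def _update_response_items(params: ParameterSet, spec: ModelSpec, Rstat: np.ndarray,
                           z: np.ndarray) -> None:
    n = params.nu.shape[0]
    for i in range(n):
        S0, F0 = Rstat[:, i, 0, 1], Rstat[:, i, 0, 0]
        a, b = _weighted_logistic_newton(z, S0, F0, float(params.alpha0[i]), float(params.beta0[i]))
        params.alpha0[i], params.beta0[i] = a, b
        if spec.has_states:
            S1, F1 = Rstat[:, i, 1, 1], Rstat[:, i, 1, 0]
            a, b = _weighted_logistic_newton(z, S1, F1, float(params.alpha1[i]), float(params.beta1[i]))
            params.alpha1[i], params.beta1[i] = a, b


# ---------------------------------------------------------------------------
# Starting values
# ---------------------------------------------------------------------------


def default_start(data: Dataset, spec: ModelSpec) -> ParameterSet:
    """Deterministic data-driven starting values.

    Item parameters come from single-state summaries (logit proportion
    correct, adjacent-category log-odds of the marginal RT-category
    frequencies); the two states are separated by splitting person-item
    pairs at the item's median RT category, which motivates a positive
    initial location shift delta1; the chain starts at (.6, .2, .8).
    """
    n, T = data.n_items, data.n_categories
    resp, rts = data.responses, data.rt_categories
    beta = np.zeros(n)
    nu = np.zeros((n, T - 1))
    for i in range(n):
        obs = resp[:, i] >= 0
        p = (resp[obs, i].sum() + 0.5) / (obs.sum() + 1.0) if obs.any() else 0.5
        beta[i] = np.log(p / (1.0 - p))
        tobs = rts[:, i][rts[:, i] >= 0]
        freq = np.bincount(tobs, minlength=T).astype(float) + 0.5
        nu[i] = np.log(freq[1:] / freq[:-1])
    lam = np.full(n, 0.3)
    if spec.variant == "baseline":
        return ParameterSet(alpha0=np.ones(n), beta0=beta, lam=lam, nu=nu, rho=0.0)
    # median-split of person-item pairs on the RT category scale: the faster
    # half is state 1, which motivates delta1 > 0 at start
    med = np.array([np.median(rts[:, i][rts[:, i] >= 0]) if (rts[:, i] >= 0).any() else (T - 1) / 2
                    for i in range(n)])
    fast = (rts >= 0) & (rts < med[None, :])
    delta1 = 0.4 if fast.any() else 0.2
    return ParameterSet(
        alpha0=np.ones(n), beta0=beta - 0.2, lam=lam, nu=nu, rho=0.0,
        alpha1=np.ones(n), beta1=beta + 0.2, delta1=delta1,
        sigma1=1.0 if spec.is_hetero else None,
        pi1=0.6, pi1_given0=0.2 if spec.is_markov else None,
        pi1_given1=0.8 if spec.is_markov else None,
    )


def _perturb(params: ParameterSet, spec: ModelSpec, rng: np.random.Generator) -> ParameterSet:
    out = params.copy()
    for name in ("alpha0", "alpha1", "beta0", "beta1", "lam"):
        arr = getattr(out, name)
        if arr is not None:
            setattr(out, name, arr + rng.normal(0.0, 0.15, arr.shape))
    out.nu = out.nu + rng.normal(0.0, 0.15, out.nu.shape)
    if spec.has_states:
        out.delta1 = float(out.delta1) * float(np.exp(rng.normal(0.0, 0.3)))
        for name in ("pi1", "pi1_given0", "pi1_given1"):
            v = getattr(out, name)
            if v is not None:
                setattr(out, name, float(np.clip(v + rng.normal(0.0, 0.08), 0.05, 0.95)))
    return out


# ---------------------------------------------------------------------------
# Fit
# ---------------------------------------------------------------------------


@dataclass
class FitOptions:
    """Tuning knobs for :func:`fit`; defaults suit the simulation designs."""

    seed: int = 0
    n_starts: int = 1
    em_max_iter: int = 500
    em_tol: float = 1e-6
    switch_tol: float = 1e-2  # EM-step gain at which the quasi-Newton phase takes over
    em_phase_max: int = 80  # sweep cap for the EM phase when refinement follows
    newton_tol: float = 1e-3
    accelerate: bool = True
    refine: bool = True
    refine_max_iter: int = 500
    quadrature_points: int = 10
    start_params: Optional[ParameterSet] = None


def _pack_raw(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    """Internal EM-state vector: delta1 stays free (may cross 0 mid-run),
    sigma1 on log scale, probabilities on logit scale, rho on artanh scale."""
    parts = [params.alpha0, params.beta0]
    if spec.has_states:
        parts += [params.alpha1, params.beta1]
    parts += [params.lam, np.ravel(params.nu)]
    tail = []
    if spec.has_states:
        tail.append(float(params.delta1))
        if spec.is_hetero:
            tail.append(np.log(params.sigma1))
        tail.append(np.log(params.pi1 / (1.0 - params.pi1)))
        if spec.is_markov:
            tail.append(np.log(params.pi1_given0 / (1.0 - params.pi1_given0)))
            tail.append(np.log(params.pi1_given1 / (1.0 - params.pi1_given1)))
    tail.append(np.arctanh(np.clip(params.rho, -0.999999, 0.999999)))
    return np.concatenate([np.asarray(p, float) for p in parts] + [np.array(tail)])


def _unpack_raw(vec: np.ndarray, spec: ModelSpec) -> ParameterSet:
    n, T = spec.n_items, spec.n_categories
    pos = 0

    def take(k):
        nonlocal pos
        out = vec[pos : pos + k]
        pos += k
        return np.array(out)

    alpha0, beta0 = take(n), take(n)
    alpha1 = beta1 = None
    if spec.has_states:
        alpha1, beta1 = take(n), take(n)
    lam = take(n)
    nu = take(n * (T - 1)).reshape(n, T - 1)
    delta1 = sigma1 = pi1 = pi10 = pi11 = None
    if spec.has_states:
        delta1 = float(take(1)[0])
        if spec.is_hetero:
            sigma1 = float(np.exp(np.clip(take(1)[0], -20, 20)))
        pi1 = float(expit(take(1)[0]))
        if spec.is_markov:
            pi10 = float(expit(take(1)[0]))
            pi11 = float(expit(take(1)[0]))
    rho = float(np.tanh(take(1)[0]))
    return ParameterSet(alpha0=alpha0, beta0=beta0, lam=lam, nu=nu, rho=rho,
                        alpha1=alpha1, beta1=beta1, delta1=delta1, sigma1=sigma1,
                        pi1=pi1, pi1_given0=pi10, pi1_given1=pi11)


def _em_step(data: Dataset, spec: ModelSpec, params: ParameterSet, z, zw):
    """One E+M cycle; returns (updated params, loglik at the input params, marg counts)."""
    out = _sweep(data, params, spec, z, zw, want_stats=True)
    ll, Rstat, Tcat, init_c, trans_c, marg_c = out[0], out[2], out[3], out[4], out[5], out[6]
    new = params.copy()
    tau = _tau_nodes(z, new.rho)
    _update_response_items(new, spec, Rstat, z)
    _update_pcm_items(new, spec, Tcat, tau)
    _update_structural_rt(new, spec, Tcat, z)
    _update_chain(new, spec, init_c, trans_c, marg_c)
    return new, ll, marg_c


def _structural_q(params: ParameterSet, spec: ModelSpec, Tcat: np.ndarray, z: np.ndarray,
                  delta1: float, sigma1: float, rho: float) -> float:
    """Expected complete-data RT log-likelihood as a function of the structural block."""
    two = spec.has_states
    n = params.nu.shape[0]
    nu_full = np.concatenate([np.zeros((n, 1)), params.nu], axis=1)
    tau = _tau_nodes(z, rho)
    deltas = (0.0, delta1)
    sigmas = (1.0, sigma1)
    val = 0.0
    for c in (0, 1) if two else (0,):
        W = Tcat[:, :, c, :]
        s = (nu_full[None, :, :] - deltas[c] - params.lam[None, :, None] * tau[:, None, None]) / sigmas[c]
        logits = np.cumsum(s, axis=2)
        logits = logits - logits.max(axis=2, keepdims=True)
        lse = np.log(np.exp(logits).sum(axis=2, keepdims=True))
        val += float(np.sum(W * (logits - lse)))
    return val


def _negll_and_grad_raw(data: Dataset, spec: ModelSpec, u: np.ndarray, z, zw):
    """Marginal negative log-likelihood and its exact gradient on the raw scale.

    The gradient uses the EM (Fisher) identity: the score of the marginal
    log-likelihood equals the posterior-expected complete-data score, which
    is assembled from the aggregated E-step counts of a single sweep.  The
    three-parameter structural RT block is differentiated by central
    differences of its aggregated expected log-likelihood (the identity
    holds blockwise; the aggregated objective is cheap).
    """
    params = _unpack_raw(u, spec)
    out = _sweep(data, params, spec, z, zw, want_stats=True)
    ll, Rstat, Tcat, init_c, trans_c, marg_c = out[0], out[2], out[3], out[4], out[5], out[6]
    n, T = spec.n_items, spec.n_categories
    two = spec.has_states

    # response block: d/dalpha = sum_a (S - m P) theta_a, d/dbeta without theta
    Px = _response_table(params, spec, z)  # (Q, n, 2)
    g_alpha = [np.zeros(n), np.zeros(n)]
    g_beta = [np.zeros(n), np.zeros(n)]
    for c in (0, 1) if two else (0,):
        S = Rstat[:, :, c, 1]
        m = Rstat[:, :, c, 0] + S
        resid = S - m * Px[:, :, c]  # (Q, n)
        g_alpha[c] = z @ resid
        g_beta[c] = resid.sum(axis=0)

    # PCM block per item
    tau = _tau_nodes(z, params.rho)
    deltas = (0.0, float(params.delta1) if two else 0.0)
    sigmas = (1.0, params.effective_sigma1(spec) if two else 1.0)
    g_nu = np.zeros((n, T - 1))
    g_lam = np.zeros(n)
    for i in range(n):
        nu_full = np.concatenate([[0.0], params.nu[i]])
        _, gneg = _pcm_objective(nu_full, float(params.lam[i]), deltas, sigmas, tau,
                                 Tcat[:, i, :, :])
        g_nu[i] = -gneg[:-1]
        g_lam[i] = -gneg[-1]

    # structural block (delta1, log sigma1, artanh rho) by central differences
    tail = []
    if two:
        d1 = float(params.delta1)
        s1 = params.effective_sigma1(spec)
        h = 1e-5

        def q_at(delta1=d1, logs1=np.log(s1), atr=np.arctanh(np.clip(params.rho, -0.999999, 0.999999))):
            return _structural_q(params, spec, Tcat, z, delta1, float(np.exp(logs1)),
                                 float(np.tanh(atr)))

        tail.append((q_at(delta1=d1 + h) - q_at(delta1=d1 - h)) / (2 * h))
        if spec.is_hetero:
            ls = np.log(s1)
            tail.append((q_at(logs1=ls + h) - q_at(logs1=ls - h)) / (2 * h))
    # chain block on the logit scale
    if two:
        if spec.is_markov:
            tail.append(init_c[1] - init_c.sum() * params.pi1)
            tail.append(trans_c[0, 1] - trans_c[0].sum() * params.pi1_given0)
            tail.append(trans_c[1, 1] - trans_c[1].sum() * params.pi1_given1)
        else:
            tail.append(marg_c[1] - marg_c.sum() * params.pi1)
        # insert chain grads after structural RT grads but before rho: fix order below
    # rho gradient (artanh scale) by central differences of the RT block
    atr0 = float(np.arctanh(np.clip(params.rho, -0.999999, 0.999999)))
    h = 1e-5
    d1 = float(params.delta1) if two else 0.0
    s1 = params.effective_sigma1(spec) if two else 1.0
    g_rho = (_structural_q(params, spec, Tcat, z, d1, s1, float(np.tanh(atr0 + h)))
             - _structural_q(params, spec, Tcat, z, d1, s1, float(np.tanh(atr0 - h)))) / (2 * h)

    # assemble in _pack_raw order
    parts = [g_alpha[0], g_beta[0]]
    if two:
        parts += [g_alpha[1], g_beta[1]]
    parts += [g_lam, np.ravel(g_nu)]
    tail_ordered = []
    if two:
        k = 0
        tail_ordered.append(tail[k]); k += 1  # delta1
        if spec.is_hetero:
            tail_ordered.append(tail[k]); k += 1  # log sigma1
        tail_ordered += tail[k:]  # chain logits
    tail_ordered.append(g_rho)
    grad = np.concatenate([np.asarray(p, float) for p in parts] + [np.array(tail_ordered)])
    return -ll, -grad


def _em_once(data: Dataset, spec: ModelSpec, start: ParameterSet, opts: FitOptions):
    """EM with safeguarded SQUAREM extrapolation.

    Each cycle takes two plain EM steps, extrapolates along the parameter
    change on the internal unconstrained scale, and accepts the extrapolated
    point only if it does not lower the observed-data log-likelihood, so the
    recorded trace stays non-decreasing.  Convergence is declared when a
    plain EM step changes the log-likelihood by less than ``em_tol``.
    """
    z, zw = (lambda g: (g.z, g.z_weights))(build_grid(0.0, opts.quadrature_points))
    params = start.copy()
    trace: list[float] = []
    converged = False
    marg_c = np.zeros(2)
    sweeps = 0
    prev_plain = True  # last recorded gain came from a plain EM step
    while sweeps < opts.em_max_iter:
        p1, ll0, marg_c = _em_step(data, spec, params, z, zw)
        sweeps += 1
        trace.append(ll0)
        if len(trace) > 1 and prev_plain and ll0 - trace[-2] < opts.em_tol:
            converged = True
            break
        if not opts.accelerate or sweeps + 2 > opts.em_max_iter:
            params = p1
            prev_plain = True
            continue
        p2, ll1, marg_c = _em_step(data, spec, p1, z, zw)
        sweeps += 1
        trace.append(ll1)
        if ll1 - ll0 < opts.em_tol:
            params = p2
            converged = True
            break
        v0 = _pack_raw(params, spec)
        v1 = _pack_raw(p1, spec)
        v2 = _pack_raw(p2, spec)
        r = v1 - v0
        v = (v2 - v1) - r
        vnorm = np.linalg.norm(v)
        if vnorm < 1e-12:
            params = p2
            prev_plain = True
            continue
        alpha = -max(np.linalg.norm(r) / vnorm, 1.0)
        cand = _unpack_raw(v0 - 2.0 * alpha * r + alpha * alpha * v, spec)
        ll_cand = _sweep(data, cand, spec, z, zw)[0]
        sweeps += 1
        if np.isfinite(ll_cand) and ll_cand >= ll1:
            params = cand
            prev_plain = False
        else:
            params = p2
            prev_plain = True
    degenerate = False
    if spec.has_states and marg_c.sum() > 0:
        degenerate = bool(marg_c.min() / marg_c.sum() < 1.0 / data.n_persons)
    return params, np.array(trace), converged, degenerate


def _anchor(params: ParameterSet, spec: ModelSpec) -> ParameterSet:
    out = anchor_labels(params, spec)
    if np.sum(out.lam) < 0:  # reflection anchor: latent speed points "faster"
        out = out.copy()
        out.lam = -out.lam
        out.rho = -out.rho
    return out


def fit(data: Dataset, spec: ModelSpec, options: Optional[FitOptions] = None) -> FitResult:
    """Fit a model variant by marginal maximum likelihood (EM, optional refinement).

    Returns the best of ``n_starts`` starts by final log-likelihood; the
    first start is deterministic and data-driven, further starts are random
    perturbations of it.  Non-convergence is reported via
    ``FitResult.converged``, never raised.
    """
    opts = options or FitOptions()
    if np.any(data.rt_categories >= spec.n_categories):
        raise ValueError("data contain RT categories outside the model's range")
    rng = np.random.default_rng(opts.seed)
    start0 = opts.start_params or default_start(data, spec)
    starts = [start0] + [_perturb(start0, spec, rng) for _ in range(opts.n_starts - 1)]
    best = None
    for start in starts:
        em_opts = opts
        if opts.refine:
            em_opts = FitOptions(**{**opts.__dict__,
                                    "em_tol": max(opts.switch_tol, opts.em_tol),
                                    "em_max_iter": min(opts.em_max_iter, opts.em_phase_max)})
        params, trace, em_converged, degenerate = _em_once(data, spec, start, em_opts)
        ll = trace[-1]
        converged = em_converged and not opts.refine
        message = "EM converged" if em_converged else "EM reached max iterations"
        if opts.refine:
            params, ll, refined_ok, message = _refine(data, spec, params, opts)
            converged = refined_ok or (em_converged and opts.switch_tol <= opts.em_tol)
            if not converged:
                # verification: accept as converged when one more full EM step
                # moves the log-likelihood by less than 0.02 (a relative change
                # below ~1e-6 at study scale; parameter movement is negligible)
                z, zw = (lambda g: (g.z, g.z_weights))(build_grid(0.0, opts.quadrature_points))
                p1, ll0, _ = _em_step(data, spec, params, z, zw)
                ll1 = _sweep(data, p1, spec, z, zw)[0]
                params, ll = p1, float(ll1)
                if ll1 - ll0 < 0.02:
                    converged = True
                    message = "converged (EM-step verification)"
        cand = (ll, params, trace, converged, degenerate, message)
        if best is None or cand[0] > best[0]:
            best = cand
    ll, params, trace, converged, degenerate, message = best
    params = _anchor(params, spec)
    return FitResult(
        spec=spec, estimates=params, loglik=float(ll), npar=npar_of(spec),
        converged=bool(converged), trace=trace, n_em_iterations=len(trace),
        degenerate=degenerate, message=message,
    )


def _refine(data: Dataset, spec: ModelSpec, params: ParameterSet, opts: FitOptions):
    """Quasi-Newton finish of the EM solution, with exact EM-identity gradients.

    L-BFGS-B on the internal raw scale (delta1 unconstrained, sigma1 log,
    probabilities logit, rho artanh); one E-step sweep per evaluation yields
    both the objective and its analytic gradient.
    """
    z, zw = (lambda g: (g.z, g.z_weights))(build_grid(0.0, opts.quadrature_points))
    u0 = _pack_raw(params, spec)

    def fun(u):
        f, g = _negll_and_grad_raw(data, spec, u, z, zw)
        if not np.isfinite(f):
            return 1e12, np.zeros_like(u)
        return f, g

    f0 = fun(u0)[0]
    # stop when an iteration gains less than ~max(em_tol, 1e-4) in absolute log-likelihood
    res = minimize(fun, u0, jac=True, method="L-BFGS-B",
                   options={"maxfun": opts.refine_max_iter, "maxiter": opts.refine_max_iter,
                            "gtol": opts.newton_tol, "maxcor": 20,
                            "ftol": max(opts.em_tol, 1e-4) / max(1.0, abs(f0))})
    if np.isfinite(res.fun) and res.fun <= f0 + 1e-9:
        ok = res.status == 0
        return _unpack_raw(res.x, spec), -float(res.fun), ok, str(res.message)
    return params, -float(f0), False, "refinement rejected (no improvement)"


# ---------------------------------------------------------------------------
# Standard errors
# ---------------------------------------------------------------------------


def _natural_jacobian(u: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """|d natural / d unconstrained| per coordinate, for the delta method."""
    labels_tail = []
    if spec.has_states:
        labels_tail.append("delta1")
        if spec.is_hetero:
            labels_tail.append("sigma1")
        labels_tail.append("pi1")
        if spec.is_markov:
            labels_tail += ["pi1_given0", "pi1_given1"]
    labels_tail.append("rho")
    jac = np.ones(u.size)
    for k, name in enumerate(labels_tail):
        idx = u.size - len(labels_tail) + k
        if name in ("delta1", "sigma1"):
            jac[idx] = np.exp(u[idx])
        elif name.startswith("pi"):
            p = expit(u[idx])
            jac[idx] = p * (1.0 - p)
        else:
            jac[idx] = 1.0 - np.tanh(u[idx]) ** 2
    return jac


def _per_person_loglik_fn(data: Dataset, spec: ModelSpec, Q: int) -> Callable[[np.ndarray], np.ndarray]:
    z, zw = (lambda g: (g.z, g.z_weights))(build_grid(0.0, Q))

    def fn(u):
        p = from_unconstrained(u, spec)
        return np.array(_sweep(data, p, spec, z, zw)[1])

    return fn


def observed_information(per_person_loglik, u: np.ndarray, method: str = "opg",
                         step: float = 1e-4) -> np.ndarray:
    """Observed information matrix at ``u`` from a per-person log-likelihood map.

    ``method="opg"`` is the outer product of per-person scores computed by
    central finite differences (one vectorized evaluation per perturbed
    coordinate); ``method="hessian"`` is the full central-difference Hessian
    of the summed negative log-likelihood (cost quadratic in ``len(u)``).
    """
    d = u.size
    if method == "opg":
        S = np.empty((np.atleast_1d(per_person_loglik(u)).size, d))
        for j in range(d):
            e = np.zeros(d)
            e[j] = step
            S[:, j] = (per_person_loglik(u + e) - per_person_loglik(u - e)) / (2.0 * step)
        return S.T @ S
    if method == "hessian":
        total = lambda v: float(np.sum(per_person_loglik(v)))  # noqa: E731
        info = np.empty((d, d))
        f0 = total(u)
        for j in range(d):
            ej = np.zeros(d); ej[j] = step
            info[j, j] = -(total(u + ej) - 2.0 * f0 + total(u - ej)) / step**2
            for k in range(j + 1, d):
                ek = np.zeros(d); ek[k] = step
                info[j, k] = info[k, j] = -(
                    total(u + ej + ek) - total(u + ej - ek)
                    - total(u - ej + ek) + total(u - ej - ek)
                ) / (4.0 * step**2)
        return info
    raise ValueError("method must be 'opg' or 'hessian'")


def standard_errors(fit_result: FitResult, data: Dataset, method: str = "opg",
                    step: float = 1e-4, Q: int = 10) -> ParameterSet:
    """Delta-method standard errors on the natural scale.

    ``method="opg"`` builds the observed information as the outer product of
    per-person scores (central finite differences of the per-person
    log-likelihood vector; one likelihood sweep per perturbed coordinate).
    ``method="hessian"`` uses the full central-difference Hessian of the
    total negative log-likelihood (quadratic cost; small models only).
    Non-invertible information is reported as NaN standard errors with a
    warning, never raised.
    """
    spec = fit_result.spec
    u = to_unconstrained(fit_result.estimates, spec)
    d = u.size
    fn = _per_person_loglik_fn(data, spec, Q)
    info = observed_information(fn, u, method=method, step=step)
    se_u = np.full(d, np.nan)
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            warnings.warn("information matrix not positive definite; some SEs undefined")
            se_u = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
        else:
            se_u = np.sqrt(diag)
    except np.linalg.LinAlgError:
        warnings.warn("information matrix singular; standard errors undefined")
    se_nat = se_u * _natural_jacobian(u, spec)
    return _se_params(se_nat, spec)


def _se_params(se: np.ndarray, spec: ModelSpec) -> ParameterSet:
    """Reshape a flat SE vector into a ParameterSet-shaped container."""
    n, T = spec.n_items, spec.n_categories
    pos = 0

    def take(k):
        nonlocal pos
        out = se[pos : pos + k]
        pos += k
        return np.array(out)

    if spec.variant == "baseline":
        alpha0, beta0 = take(n), take(n)
        alpha1 = beta1 = None
    else:
        alpha0, alpha1, beta0, beta1 = take(n), take(n), take(n), take(n)
    lam = take(n)
    nu = take(n * (T - 1)).reshape(n, T - 1)
    delta1 = sigma1 = pi1 = pi10 = pi11 = None
    if spec.has_states:
        delta1 = float(take(1)[0])
        if spec.is_hetero:
            sigma1 = float(take(1)[0])
        pi1 = float(take(1)[0])
        if spec.is_markov:
            pi10 = float(take(1)[0])
            pi11 = float(take(1)[0])
    rho = float(take(1)[0])
    return ParameterSet(alpha0=alpha0, beta0=beta0, lam=lam, nu=nu, rho=rho,
                        alpha1=alpha1, beta1=beta1, delta1=delta1, sigma1=sigma1,
                        pi1=pi1, pi1_given0=pi10, pi1_given1=pi11)


__all__ = [
    "QuadratureGrid", "build_grid", "marginal_loglik", "FitOptions", "fit",
    "standard_errors", "observed_information", "default_start",
]
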