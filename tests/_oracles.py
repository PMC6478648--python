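"""Independent brute-force oracles used by the markov/inference tests.

Everything here is written from the model definition directly (explicit
enumeration of state paths, dense-grid numerical integration, plain formula
evaluation) and deliberately shares no code with the package's forward
recursion, quadrature or probability tables.
"""

import itertools

import numpy as np


def enum_loglik(emissions: np.ndarray, initial: np.ndarray, transition: np.ndarray) -> float:
    """Log-likelihood by explicit summation over all 2^n state paths."""
    n = emissions.shape[0]
    total = 0.0
    for path in itertools.product((0, 1), repeat=n):
        p = initial[path[0]] * emissions[0, path[0]]
        for i in range(1, n):
            p *= transition[path[i - 1], path[i]] * emissions[i, path[i]]
        total += p
    return float(np.log(total))


def enum_posteriors(emissions: np.ndarray, initial: np.ndarray, transition: np.ndarray):
    """Per-item state posteriors by path enumeration."""
    n = emissions.shape[0]
    joint = np.zeros((n, 2))
    total = 0.0
    for path in itertools.product((0, 1), repeat=n):
        p = initial[path[0]] * emissions[0, path[0]]
        for i in range(1, n):
            p *= transition[path[i - 1], path[i]] * emissions[i, path[i]]
        total += p
        for i in range(n):
            joint[i, path[i]] += p
    return joint / total


def logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def pcm_probs_plain(tau, nu_free, lam, delta, sigma):
    """PCM category probabilities from the adjacent-category definition."""
    nu_full = np.concatenate([[0.0], np.asarray(nu_free, float)])
    expo = np.array([np.sum((nu_full[: t + 1] - delta - lam * tau) / sigma)
                     for t in range(nu_full.size)])
    expo -= expo.max()
    w = np.exp(expo)
    return w / w.sum()


def _pcm_probs_grid(tau_vec, nu_free, lam, delta, sigma):
    """PCM category probabilities on a vector of tau values, shape (G, T)."""
    nu_full = np.concatenate([[0.0], np.asarray(nu_free, float)])
    expo = np.cumsum((nu_full[None, :] - delta - lam * tau_vec[:, None]) / sigma, axis=1)
    expo -= expo.max(axis=1, keepdims=True)
    w = np.exp(expo)
    return w / w.sum(axis=1, keepdims=True)


def dense_marginal_loglik(responses, rt_cats, params, spec, grid_points=201, bound=8.0):
    """Marginal log-likelihood by dense-grid integration over (theta, tau)
    and explicit state-path enumeration; no quadrature, no forward recursion."""
    g = np.linspace(-bound, bound, grid_points)
    TH, TA = np.meshgrid(g, g, indexing="ij")
    rho = params.rho
    dens = np.exp(-(TH**2 - 2 * rho * TH * TA + TA**2) / (2 * (1 - rho**2)))
    dens /= dens.sum()  # normalized cell weights over the truncated grid
    two = spec.has_states
    if two:
        initial = np.array([1 - params.pi1, params.pi1])
        if spec.is_markov:
            transition = np.array([
                [1 - params.pi1_given0, params.pi1_given0],
                [1 - params.pi1_given1, params.pi1_given1],
            ])
        else:
            transition = np.vstack([initial, initial])
        paths = list(itertools.product((0, 1), repeat=spec.n_items))
    else:
        initial = np.array([1.0])
        transition = np.ones((1, 1))
        paths = [(0,) * spec.n_items]
    sigma1 = params.effective_sigma1(spec) if two else 1.0
    delta1 = float(params.delta1) if two else 0.0
    # per-item, per-state emission factors on the grid axes
    total = 0.0
    for x_row, t_row in zip(responses, rt_cats):
        gx = np.ones((spec.n_items, 2, grid_points))  # over theta axis
        ht = np.ones((spec.n_items, 2, grid_points))  # over tau axis
        for i in range(spec.n_items):
            for c in (0, 1) if two else (0,):
                alpha = params.alpha0[i] if c == 0 else params.alpha1[i]
                beta = params.beta0[i] if c == 0 else params.beta1[i]
                if x_row[i] >= 0:
                    p = logistic(alpha * g + beta)
                    gx[i, c] = p if x_row[i] == 1 else 1 - p
                if t_row[i] >= 0:
                    probs = _pcm_probs_grid(g, params.nu[i], params.lam[i],
                                            0.0 if c == 0 else delta1,
                                            1.0 if c == 0 else sigma1)
                    ht[i, c] = probs[:, t_row[i]]
        like = np.zeros((grid_points, grid_points))
        for path in paths:
            prior = initial[path[0]]
            for i in range(1, len(path)):
                prior *= transition[path[i - 1], path[i]]
            term_theta = np.ones(grid_points)
            term_tau = np.ones(grid_points)
            for i, c in enumerate(path):
                term_theta = term_theta * gx[i, c]
                term_tau = term_tau * ht[i, c]
            like += prior * np.outer(term_theta, term_tau)
        total += np.log(np.sum(like * dens))
    return float(total)
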