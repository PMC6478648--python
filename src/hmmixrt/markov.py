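"""Two-state chain machinery over items.

States evolve across the items of a test according to a first-order,
time-homogeneous Markov chain (or collapse to independent draws when the
transition rows equal the initial distribution).  The scaled forward
recursion sums the chain out of a product of per-item state-conditional
emission values; the forward-backward pass yields per-item posterior state
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ModelSpec, ParameterSet


@dataclass(frozen=True)
class ChainSpec:
    """Initial distribution (P(state 0), P(state 1)) and 2x2 row-stochastic transitions."""

    initial: np.ndarray  # (2,)
    transition: np.ndarray  # (2, 2), rows = previous state

    def __post_init__(self) -> None:
        init = np.asarray(self.initial, dtype=float)
        trans = np.asarray(self.transition, dtype=float)
        if init.shape != (2,) or trans.shape != (2, 2):
            raise ValueError("initial must be length-2 and transition 2x2")
        if np.any(init < 0) or np.any(trans < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.isclose(init.sum(), 1.0) or not np.allclose(trans.sum(axis=1), 1.0):
            raise ValueError("initial and transition rows must sum to 1")
        object.__setattr__(self, "initial", init)
        object.__setattr__(self, "transition", trans)

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the transition matrix."""
        p01, p10 = self.transition[0, 1], self.transition[1, 0]
        if p01 + p10 == 0:
            return self.initial.copy()
        return np.array([p10, p01]) / (p01 + p10)


def chain_from_params(params: ParameterSet, spec: ModelSpec) -> ChainSpec:
    """Build the chain for a mixture variant; independent variants repeat the initial row."""
    if not spec.has_states:
        raise ValueError("baseline variant has no state chain")
    pi1 = float(params.pi1)
    initial = np.array([1.0 - pi1, pi1])
    if spec.is_markov:
        p10, p11 = float(params.pi1_given0), float(params.pi1_given1)
        transition = np.array([[1.0 - p10, p10], [1.0 - p11, p11]])
    else:
        transition = np.vstack([initial, initial])
    return ChainSpec(initial=initial, transition=transition)


def forward_loglik(emissions: np.ndarray, chain: ChainSpec) -> float:
    """Log of the state-summed emission product, by a scaled forward recursion.

    ``emissions[i, c]`` holds the state-conditional joint emission value of
    item i (a row of ones for a fully missing item).
    """
    e = np.asarray(emissions, dtype=float)
    if e.ndim != 2 or e.shape[1] != 2:
        raise ValueError("emissions must be n x 2")
    if np.any(e <= 0):
        raise ValueError("emissions must be positive (use 1.0 for missing items)")
    alpha = chain.initial * e[0]
    logc = np.log(alpha.sum())
    alpha = alpha / alpha.sum()
    for i in range(1, e.shape[0]):
        alpha = (alpha @ chain.transition) * e[i]
        s = alpha.sum()
        logc += np.log(s)
        alpha /= s
    return float(logc)


def forward_backward(emissions: np.ndarray, chain: ChainSpec):
    """Per-item posterior state probabilities (and pairwise transition posteriors).

    Returns ``(gamma, xi)`` where ``gamma[i, c] = P(state_i = c | all
    emissions)`` and ``xi[i, c, c'] = P(state_i = c, state_{i+1} = c' |
    all emissions)`` for i = 0..n-2.  Rows of ``gamma`` sum to 1; summing
    ``xi`` over either state margin reproduces the adjacent ``gamma``.
    """
    e = np.asarray(emissions, dtype=float)
    if e.ndim != 2 or e.shape[1] != 2:
        raise ValueError("emissions must be n x 2")
    if np.any(e <= 0):
        raise ValueError("emissions must be positive (use 1.0 for missing items)")
    n = e.shape[0]
    alphas = np.empty((n, 2))
    alpha = chain.initial * e[0]
    alphas[0] = alpha / alpha.sum()
    for i in range(1, n):
        alpha = (alphas[i - 1] @ chain.transition) * e[i]
        alphas[i] = alpha / alpha.sum()
    betas = np.empty((n, 2))
    betas[n - 1] = 1.0
    for i in range(n - 2, -1, -1):
        b = chain.transition @ (e[i + 1] * betas[i + 1])
        betas[i] = b / b.sum()
    gamma = alphas * betas
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = np.empty((max(n - 1, 0), 2, 2))
    for i in range(n - 1):
        j = alphas[i][:, None] * chain.transition * (e[i + 1] * betas[i + 1])[None, :]
        xi[i] = j / j.sum()
    return gamma, xi


__all__ = ["ChainSpec", "chain_from_params", "forward_loglik", "forward_backward"]
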