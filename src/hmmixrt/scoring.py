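"""Person-level outputs: EAP ability/speed scores, per-item posterior state
probabilities, and ad-hoc item-wise standardized response times."""

from __future__ import annotations

import numpy as np

from .core import Dataset, FitResult
from .inference import _sweep, build_grid


def _score_sweep(data: Dataset, fit_result: FitResult, Q: int = 10):
    g = build_grid(0.0, Q)
    return _sweep(data, fit_result.estimates, fit_result.spec, g.z, g.z_weights,
                  want_scores=True)


def eap_scores(data: Dataset, fit_result: FitResult, Q: int = 10):
    """Expected-a-posteriori (theta, tau) per person with posterior SDs.

    Posterior means over the quadrature grid with person-specific marginal
    likelihood weights; a person with no observed data gets the prior mean
    (0, 0) and prior SD (1, 1).
    """
    out = _score_sweep(data, fit_result, Q)
    Eth, Eth2, Eta, Eta2 = out[7], out[8], out[9], out[10]
    sd_theta = np.sqrt(np.maximum(Eth2 - Eth**2, 0.0))
    sd_tau = np.sqrt(np.maximum(Eta2 - Eta**2, 0.0))
    return {"theta": Eth, "tau": Eta, "sd_theta": sd_theta, "sd_tau": sd_tau}


def state_posteriors(data: Dataset, fit_result: FitResult, Q: int = 10) -> np.ndarray:
    """Per-person, per-item posterior state probabilities, shape (N, n, 2).

    Forward-backward posteriors averaged over the quadrature nodes with
    node-posterior weights; ``[..., 0]`` is the Class-0 (slower-state)
    probability.  Raises for a baseline fit, which has no states.
    """
    if not fit_result.spec.has_states:
        raise ValueError("baseline fit has no latent states")
    out = _score_sweep(data, fit_result, Q)
    return np.array(out[11])


def standardized_rts(raw_times: np.ndarray) -> np.ndarray:
    """Item-wise z-scores of raw response times, (t - item mean) / item SD.

    Missing values (NaN) are preserved; an item needs at least two observed
    times and a positive SD.
    """
    times = np.asarray(raw_times, dtype=float)
    out = np.full(times.shape, np.nan)
    for i in range(times.shape[1]):
        col = times[:, i]
        obs = ~np.isnan(col)
        if obs.sum() < 2:
            raise ValueError(f"item {i}: need at least 2 non-missing times")
        sd = col[obs].std(ddof=1)
        if sd == 0:
            raise ValueError(f"item {i}: zero standard deviation")
        out[obs, i] = (col[obs] - col[obs].mean()) / sd
    return out


__all__ = ["eap_scores", "state_posteriors", "standardized_rts"]
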