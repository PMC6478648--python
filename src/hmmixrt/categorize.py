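"""Item-wise conversion of continuous response times to ordered categories.

Cut points are placed at percentiles derived from equally spaced abscissae of
a standard normal distribution (for T = 5: -2, -2/3, 2/3, 2, i.e. percentiles
2.28, 25.25, 74.75, 97.73).  This spreads the partial-credit thresholds over
the latent-speed range so the information in the categorized times is roughly
constant on (-3, 3), unlike equidistant percentiles (20, 40, ...) which
concentrate information near the center.  Categorization is always per item:
each item's observed times are cut at that item's own empirical percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

# Preset abscissae and their conventional 2-decimal percentiles.  97.73 is
# kept as the standard printed value for z = 2 (via the 4-decimal cumulative
# probability .9773) even though direct 2-decimal rounding of 100*Phi(2)
# would give 97.72.
_PRESET_ABSCISSAE = {
    2: np.array([0.0]),
    3: np.array([-1.0, 1.0]),
    5: np.array([-2.0, -2.0 / 3.0, 2.0 / 3.0, 2.0]),
}
_PRESET_PERCENTILES = {
    2: np.array([50.0]),
    3: np.array([15.87, 84.13]),
    5: np.array([2.28, 25.25, 74.75, 97.73]),
}


@dataclass(frozen=True)
class CutScheme:
    """T-category cut scheme: T-1 strictly increasing percentiles in (0, 100)."""

    T: int
    percentiles: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.percentiles, dtype=float)
        if p.shape != (self.T - 1,):
            raise ValueError(f"need {self.T - 1} percentiles for T={self.T}")
        if np.any(p <= 0) or np.any(p >= 100) or np.any(np.diff(p) <= 0):
            raise ValueError("percentiles must be strictly increasing within (0, 100)")
        object.__setattr__(self, "percentiles", p)


def normal_quantile_percentiles(T: int, exact: bool = False) -> CutScheme:
    """Normal-quantile cut scheme for T categories.

    For T in {2, 3, 5} the preset abscissae are used ({0}, {-1, 1} and
    {-2, -2/3, 2/3, 2}); other T uses T-1 equally spaced abscissae on
    [-2, 2].  By default percentiles are rounded to 2 decimals (the printed
    convention); ``exact=True`` keeps the full CDF values.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if not exact and T in _PRESET_PERCENTILES:
        return CutScheme(T=T, percentiles=_PRESET_PERCENTILES[T].copy())
    z = _PRESET_ABSCISSAE.get(T, np.linspace(-2.0, 2.0, T - 1))
    pct = 100.0 * stats.norm.cdf(z)
    if not exact:
        pct = np.floor(pct * 100.0 + 0.5) / 100.0  # round half-up
    return CutScheme(T=T, percentiles=pct)


def equidistant_percentiles(T: int) -> CutScheme:
    """Equidistant percentile scheme (100/T, 200/T, ...), for comparison only."""
    if T < 2:
        raise ValueError("T must be >= 2")
    return CutScheme(T=T, percentiles=100.0 * np.arange(1, T) / T)


def categorize_item(times: np.ndarray, scheme: CutScheme, require_positive: bool = False) -> np.ndarray:
    """Categorize one item's response times at its own empirical percentiles.

    Cut values are linear-interpolation percentiles of the non-missing times;
    a time is assigned the count of cut values strictly below it, so ties at
    a cut value fall in the lower category.  NaN in gives NaN out.
    Because percentiles commute with strictly increasing transforms, the
    categories do not depend on whether raw or (e.g. log-) transformed times
    are supplied; positivity is therefore only enforced when
    ``require_positive`` is set (raw seconds at the file boundary).
    """
    times = np.asarray(times, dtype=float)
    obs = ~np.isnan(times)
    vals = times[obs]
    if vals.size < scheme.T:
        raise ValueError(f"need at least {scheme.T} non-missing times, got {vals.size}")
    if require_positive and np.any(vals <= 0):
        raise ValueError("response times must be positive")
    cuts = np.percentile(vals, scheme.percentiles)
    out = np.full(times.shape, np.nan)
    out[obs] = np.sum(cuts[None, :] < vals[:, None], axis=1)
    return out


def categorize_matrix(times: np.ndarray, scheme: CutScheme, require_positive: bool = False) -> np.ndarray:
    """Apply :func:`categorize_item` column-wise to an N x n matrix of times."""
    times = np.asarray(times, dtype=float)
    return np.column_stack(
        [categorize_item(times[:, i], scheme, require_positive) for i in range(times.shape[1])]
    )


__all__ = [
    "CutScheme", "normal_quantile_percentiles", "equidistant_percentiles",
    "categorize_item", "categorize_matrix",
]
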