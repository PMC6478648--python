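import numpy as np
import pytest

from hmmixrt import ModelSpec, ParameterSet
from hmmixrt.inference import FitOptions, fit
from hmmixrt.selection import simulate_categorized


def random_params(spec: ModelSpec, rng: np.random.Generator) -> ParameterSet:
    """A random valid parameter set for any variant (test utility)."""
    n, T = spec.n_items, spec.n_categories
    kw = dict(
        alpha0=rng.uniform(0.5, 2.0, n),
        beta0=rng.uniform(-2.0, 2.0, n),
        lam=rng.uniform(0.1, 1.0, n),
        nu=np.sort(rng.uniform(-2.0, 2.0, (n, T - 1)), axis=1)[:, ::-1].copy(),
        rho=rng.uniform(-0.9, 0.9),
    )
    if spec.has_states:
        kw.update(
            alpha1=rng.uniform(0.5, 2.0, n),
            beta1=rng.uniform(-2.0, 2.0, n),
            delta1=rng.uniform(0.1, 1.5),
            sigma1=rng.uniform(0.4, 2.0) if spec.is_hetero else None,
            pi1=rng.uniform(0.2, 0.8),
            pi1_given0=rng.uniform(0.1, 0.9) if spec.is_markov else None,
            pi1_given1=rng.uniform(0.1, 0.9) if spec.is_markov else None,
        )
    return ParameterSet(**kw)


@pytest.fixture(scope="session")
def small_hetero():
    """A small heteroscedastic-Markov replication: (data, truth, states, latents)."""
    return simulate_categorized("hetero_markov", N=300, n=8, T=3, seed=11)


@pytest.fixture(scope="session")
def small_hetero_fit(small_hetero):
    data, truth, states, latents = small_hetero
    spec = ModelSpec("hetero_markov", 8, 3)
    return fit(data, spec, FitOptions(seed=11))
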