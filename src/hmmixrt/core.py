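"""Shared data model: datasets, model variants, parameter containers.

The model family couples a two-state latent-class structure (states differ in
response-time location ``delta1`` and, optionally, residual scale ``sigma1``)
with a 2PL measurement model for binary responses and a heteroscedastic
partial-credit model for ordered response-time categories.  Five estimable
variants are supported:

``baseline``
    A single-state hierarchical model (no mixture).
``hetero_markov`` / ``homo_markov``
    Two states with first-order, time-homogeneous Markov transitions between
    consecutive items; ``homo_*`` fixes the residual-scale ratio sigma1 = 1.
``hetero_indep`` / ``homo_indep``
    Two states that are independent across items; the transition rows of the
    chain equal the marginal state probability pi1.

Missing responses and missing response-time categories are carried as an
explicit ``-1`` code in integer matrices and may occur independently of each
other (missing-at-random handling downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

MISSING = -1

VARIANTS = ("baseline", "hetero_markov", "homo_markov", "hetero_indep", "homo_indep")


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """A model variant together with its dimensions.

    Parameters
    ----------
    variant:
        One of :data:`VARIANTS`.
    n_items:
        Number of items n >= 1.
    n_categories:
        Number of ordered response-time categories T >= 2.  Category 0 is the
        fastest (smallest response time) bin.
    """

    variant: str
    n_items: int
    n_categories: int

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")

    @property
    def has_states(self) -> bool:
        return self.variant != "baseline"

    @property
    def is_markov(self) -> bool:
        return self.variant in ("hetero_markov", "homo_markov")

    @property
    def is_hetero(self) -> bool:
        return self.variant in ("hetero_markov", "hetero_indep")


def npar_of(spec: ModelSpec) -> int:
    """Number of free parameters implied by a model spec.

    Item parameters: the baseline model has one discrimination and one
    easiness per item; two-state models have one of each per state.  All
    models carry one RT loading per item and T-1 thresholds per item.
    Structural parameters: the Markov variants have {delta1, pi1, pi1|0,
    pi1|1, rho} plus sigma1 when heteroscedastic; the independent-state
    variants replace the three chain parameters with the single marginal pi1;
    the baseline model has only rho.
    """
    n, T = spec.n_items, spec.n_categories
    rt_measurement = n + (T - 1) * n  # lambda_i and nu_it
    if spec.variant == "baseline":
        return 2 * n + rt_measurement + 1
    base = 4 * n + rt_measurement  # two-state 2PL item parameters
    structural = 2 + (1 if spec.is_hetero else 0)  # delta1, rho (+ sigma1)
    structural += 3 if spec.is_markov else 1  # chain vs marginal probability
    return base + structural


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """All free parameters of a model variant on their natural scale.

    Arrays are per item; fields not used by a variant are ``None``.  State 0
    is the slower state (delta0 = 0, sigma0 = 1 are the identification
    anchors); ``delta1 > 0`` anchors state 1 as the faster state.
    """

    alpha0: np.ndarray  # (n,) state-0 discriminations
    beta0: np.ndarray  # (n,) state-0 easiness
    lam: np.ndarray  # (n,) RT loadings
    nu: np.ndarray  # (n, T-1) RT thresholds, nu_i0 = 0 implicit
    rho: float  # latent correlation of (theta, tau)
    alpha1: Optional[np.ndarray] = None
    beta1: Optional[np.ndarray] = None
    delta1: Optional[float] = None  # state-1 location shift
    sigma1: Optional[float] = None  # state-1 residual-scale ratio
    pi1: Optional[float] = None  # initial / marginal state-1 probability
    pi1_given0: Optional[float] = None
    pi1_given1: Optional[float] = None

    def copy(self) -> "ParameterSet":
        def c(v):
            return None if v is None else (np.array(v, dtype=float) if isinstance(v, np.ndarray) else float(v))

        return ParameterSet(**{k: c(getattr(self, k)) for k in self.__dataclass_fields__})

    def validate(self, spec: ModelSpec) -> None:
        n, T = spec.n_items, spec.n_categories
        for name in ("alpha0", "beta0", "lam"):
            arr = getattr(self, name)
            if arr is None or np.shape(arr) != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        if np.shape(self.nu) != (n, T - 1):
            raise ValueError(f"nu must have shape ({n}, {T - 1})")
        if not -1.0 < float(self.rho) < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if spec.variant == "baseline":
            return
        for name in ("alpha1", "beta1"):
            arr = getattr(self, name)
            if arr is None or np.shape(arr) != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        if self.delta1 is None:
            raise ValueError("delta1 required for mixture variants")
        sigma1 = self.sigma1 if spec.is_hetero else 1.0
        if sigma1 is None or sigma1 <= 0:
            raise ValueError("sigma1 must be > 0")
        probs = [self.pi1]
        if spec.is_markov:
            probs += [self.pi1_given0, self.pi1_given1]
        for p in probs:
            if p is None or not 0.0 < p < 1.0:
                raise ValueError("state probabilities must lie in the open unit interval")

    def effective_sigma1(self, spec: ModelSpec) -> float:
        return float(self.sigma1) if spec.is_hetero else 1.0


def parameter_labels(spec: ModelSpec) -> list[str]:
    """Flat labels matching the unconstrained-vector layout."""
    n, T = spec.n_items, spec.n_categories
    labels: list[str] = []
    if spec.variant == "baseline":
        labels += [f"alpha_{i + 1}" for i in range(n)]
        labels += [f"beta_{i + 1}" for i in range(n)]
    else:
        labels += [f"alpha0_{i + 1}" for i in range(n)]
        labels += [f"alpha1_{i + 1}" for i in range(n)]
        labels += [f"beta0_{i + 1}" for i in range(n)]
        labels += [f"beta1_{i + 1}" for i in range(n)]
    labels += [f"lambda_{i + 1}" for i in range(n)]
    labels += [f"nu_{i + 1}_{t}" for i in range(n) for t in range(1, T)]
    if spec.has_states:
        labels.append("delta1")
        if spec.is_hetero:
            labels.append("sigma1")
        labels.append("pi1")
        if spec.is_markov:
            labels += ["pi1_given0", "pi1_given1"]
    labels.append("rho")
    return labels


def _logit(p: float) -> float:
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability {p} on the constraint boundary")
    return float(np.log(p) - np.log1p(-p))


def _safe_log(x: float, name: str) -> float:
    if x <= 0.0:
        raise ValueError(f"{name} = {x} on the constraint boundary")
    return float(np.log(x))


def to_unconstrained(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    """Map parameters to the optimizer scale.

    log for delta1/sigma1, logit for probabilities, artanh for rho, identity
    for item parameters.  Inverted exactly by :func:`from_unconstrained`.
    """
    params.validate(spec)
    parts: list[np.ndarray] = []
    if spec.variant == "baseline":
        parts += [params.alpha0, params.beta0]
    else:
        parts += [params.alpha0, params.alpha1, params.beta0, params.beta1]
    parts += [params.lam, np.ravel(params.nu)]
    tail: list[float] = []
    if spec.has_states:
        tail.append(_safe_log(float(params.delta1), "delta1"))
        if spec.is_hetero:
            tail.append(_safe_log(float(params.sigma1), "sigma1"))
        tail.append(_logit(float(params.pi1)))
        if spec.is_markov:
            tail += [_logit(float(params.pi1_given0)), _logit(float(params.pi1_given1))]
    if not -1.0 < params.rho < 1.0:
        raise ValueError("rho on the constraint boundary")
    tail.append(float(np.arctanh(params.rho)))
    return np.concatenate([np.asarray(p, dtype=float) for p in parts] + [np.array(tail)])


def from_unconstrained(vec: np.ndarray, spec: ModelSpec) -> ParameterSet:
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (npar_of(spec),):
        raise ValueError(f"expected vector of length {npar_of(spec)}, got {vec.shape}")
    n, T = spec.n_items, spec.n_categories
    pos = 0

    def take(k: int) -> np.ndarray:
        nonlocal pos
        out = vec[pos : pos + k]
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
    expit = lambda u: 1.0 / (1.0 + np.exp(-u))  # noqa: E731
    if spec.has_states:
        delta1 = float(np.exp(take(1)[0]))
        if spec.is_hetero:
            sigma1 = float(np.exp(take(1)[0]))
        pi1 = float(expit(take(1)[0]))
        if spec.is_markov:
            pi10 = float(expit(take(1)[0]))
            pi11 = float(expit(take(1)[0]))
    rho = float(np.tanh(take(1)[0]))
    return ParameterSet(
        alpha0=alpha0, beta0=beta0, lam=lam, nu=nu, rho=rho,
        alpha1=alpha1, beta1=beta1, delta1=delta1, sigma1=sigma1,
        pi1=pi1, pi1_given0=pi10, pi1_given1=pi11,
    )


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """N x n binary responses and ordered RT categories with explicit missingness.

    ``responses`` holds {0, 1} with :data:`MISSING` (-1) for absent cells;
    ``rt_categories`` holds {0, ..., T-1} likewise.  Category 0 denotes the
    fastest response-time bin.
    """

    responses: np.ndarray  # int8 (N, n)
    rt_categories: np.ndarray  # int8 (N, n)
    n_items: int
    n_categories: int

    @property
    def n_persons(self) -> int:
        return int(self.responses.shape[0])


def _coerce(matrix, name: str) -> np.ndarray:
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix")
    return arr


def validate_dataset(raw_responses, raw_rt_categories, T: int) -> Dataset:
    """Validate and encode raw matrices into a :class:`Dataset`.

    NaN (or -1) cells are treated as missing; responses must otherwise lie in
    {0, 1} and RT categories in {0, ..., T-1}.  Errors name the offending
    row and column (0-based).
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    resp = _coerce(raw_responses, "responses")
    rts = _coerce(raw_rt_categories, "rt_categories")
    if resp.shape != rts.shape:
        raise ValueError(f"shape mismatch: responses {resp.shape} vs rt_categories {rts.shape}")
    if resp.shape[0] < 1 or resp.shape[1] < 1:
        raise ValueError("need at least one respondent and one item")

    def encode(arr: np.ndarray, valid_max: int, name: str) -> np.ndarray:
        out = np.full(arr.shape, MISSING, dtype=np.int8)
        obs = ~np.isnan(arr)
        vals = arr[obs]
        if vals.size and not np.allclose(vals, np.round(vals)):
            r, c = np.argwhere(obs)[np.nonzero(~np.isclose(vals, np.round(vals)))[0][0]]
            raise ValueError(f"{name} value {arr[r, c]} at row {r}, column {c} is not integer-coded")
        ivals = np.round(arr, 0)
        bad = obs & ((ivals < 0) | (ivals > valid_max)) & (ivals != MISSING)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"{name} value {int(ivals[r, c])} at row {r}, column {c} "
                f"outside valid range 0..{valid_max}"
            )
        out[obs] = ivals[obs].astype(np.int8)
        out[obs & (ivals == MISSING)] = MISSING
        return out

    responses = encode(resp, 1, "response")
    rt = encode(rts, T - 1, "RT category")
    return Dataset(responses=responses, rt_categories=rt, n_items=resp.shape[1], n_categories=T)


# ---------------------------------------------------------------------------
# Fit result container
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates and diagnostics from a marginal maximum-likelihood fit."""

    spec: ModelSpec
    estimates: ParameterSet
    loglik: float
    npar: int
    converged: bool
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    standard_errors: Optional[ParameterSet] = None
    n_em_iterations: int = 0
    degenerate: bool = False
    message: str = ""


def relabel_states(params: ParameterSet, spec: ModelSpec) -> ParameterSet:
    """Swap the two state labels, leaving the likelihood invariant.

    The reparameterization keeps the identification anchors delta0 = 0,
    sigma0 = 1: nu' = (nu - delta1)/sigma1, lambda' = lambda/sigma1,
    delta1' = -delta1/sigma1, sigma1' = 1/sigma1, response parameters and
    chain probabilities swap/complement accordingly.
    """
    if not spec.has_states:
        return params.copy()
    out = params.copy()
    s1 = params.effective_sigma1(spec)
    d1 = float(params.delta1)
    out.alpha0, out.alpha1 = params.alpha1.copy(), params.alpha0.copy()
    out.beta0, out.beta1 = params.beta1.copy(), params.beta0.copy()
    out.nu = (params.nu - d1) / s1
    out.lam = params.lam / s1
    out.delta1 = -d1 / s1
    if spec.is_hetero:
        out.sigma1 = 1.0 / s1
    out.pi1 = 1.0 - params.pi1
    if spec.is_markov:
        out.pi1_given0 = 1.0 - params.pi1_given1
        out.pi1_given1 = 1.0 - params.pi1_given0
    return out


def anchor_labels(params: ParameterSet, spec: ModelSpec) -> ParameterSet:
    """Apply the delta1 > 0 anchor (state 1 = faster state), relabeling if needed."""
    if spec.has_states and params.delta1 is not None and params.delta1 < 0:
        return relabel_states(params, spec)
    return params


__all__ = [
    "MISSING", "VARIANTS", "ModelSpec", "ParameterSet", "Dataset", "FitResult",
    "npar_of", "parameter_labels", "to_unconstrained", "from_unconstrained",
    "validate_dataset", "relabel_states", "anchor_labels",
]
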