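# Methods

## The model

`hmmixrt` fits joint psychometric models for binary item responses
`x_pi ∈ {0, 1}` and ordered response-time categories `t'_pi ∈ {0, …, T−1}`
of person `p = 1…N` on items `i = 1…n`.  Each person–item encounter occupies
one of two latent states `ζ_pi ∈ {0, 1}` — a slower process (state 0) and a
faster one (state 1).  Conditional on the latent ability `θ_p`, the latent
speed `τ_p` and the state, responses and response times are independent:

- **Responses** follow a state-specific 2PL model,
  `P(x_pi = 1 | θ_p, ζ_pi = c) = logistic(α_ci θ_p + β_ci)`,
  with discrimination `α_ci` and easiness `β_ci`.
- **Categorized response times** follow a partial-credit (adjacent-category
  logit) model subject to between-state heteroscedasticity: the adjacent
  log-odds of category `t` versus `t−1` are `(ν_it − δ_c − λ_i τ_p) / σ_c`,
  with item thresholds `ν_it` (`ν_i0 ≡ 0`), item loadings `λ_i`, a common
  state-1 location shift `δ_1` (`δ_0 ≡ 0`) and a state-1 residual-scale ratio
  `σ_1` (`σ_0 ≡ 1`).  Category 0 is the fastest bin, so `δ_1 > 0` means
  state 1 responds faster; `σ_1 ≠ 1` means the two processes differ in
  response-time variability.
- **States** evolve over the items of the test as a first-order,
  time-homogeneous Markov chain with initial probability `π_1` and
  transition probabilities `π_{1|0}`, `π_{1|1}`; the independent-state
  variants restrict both transition rows to the marginal `π_1`.
- `(θ_p, τ_p)` are bivariate standard normal with correlation `ρ`.

Five variants are estimable: `baseline` (single state), `hetero_markov`
(the full model), `homo_markov` (`σ_1 = 1`), `hetero_indep` and
`homo_indep`.  Free-parameter counts are `3n + (T−1)n + 1` for the baseline
and `5n + (T−1)n + s` for the mixtures with structural count `s` = 6
(hetero Markov), 5 (homo Markov), 4 (hetero independent), 3 (homo
independent): the independent variants merge the initial and transition
probabilities into the single marginal `π_1`.

## Categorization of response times

Continuous times are reduced to `T` ordered categories item by item, cutting
each item's observed times at its own empirical percentiles (linear
interpolation between order statistics; ties at a cut value fall in the
lower category).  The default percentiles derive from equally spaced
standard-normal abscissae — `{−2, −2/3, 2/3, 2}` for `T = 5`, i.e.
percentiles `{2.28, 25.25, 74.75, 97.73}`; `{15.87, 84.13}` for `T = 3`; a
median split for `T = 2` — which spreads the fitted thresholds over the
latent-speed range so the category information is roughly flat on (−3, 3).
The equidistant alternative (20/40/60/80) is available for comparison only;
it concentrates information near `τ = 0`.  Because percentiles commute with
strictly increasing transforms, categorizing raw or monotonically
transformed times is exactly equivalent.  The preset percentiles for
`T ∈ {2, 3, 5}` are stored as the conventional printed constants; other `T`
round the exact normal CDF values half-up to 2 decimals, and `exact=True`
bypasses rounding.

## Estimation

The marginal likelihood integrates `(θ, τ)` out by bivariate Gauss–Hermite
quadrature — 10 nodes per dimension by default — and sums the states out
with a scaled forward recursion over items.  The correlation is handled by
the transformation `θ = z₁`, `τ = ρ z₁ + √(1−ρ²) z₂` on a fixed independent
product grid, so the latent density is parameter-free and `ρ` enters only
through the `τ` node values; the quadrature cross-moment `∫θτ` reproduces
`ρ` to 1e−8 at 10 points.  Missing responses and missing RT categories are
handled under missing-at-random by dropping only the missing factor from the
item emission (a fully missing person contributes log 1 = 0).

Fitting proceeds in two phases:

1. **EM phase.**  The E-step is a fused compiled sweep that accumulates
   node/state posterior counts aggregated over persons (logistic counts per
   theta node, category counts per (θ, τ) node, chain counts).  The M-step
   solves per-item weighted logistic Newton updates (responses), per-item
   warm-started quasi-Newton updates of `(ν_i, λ_i)` on the aggregated
   adjacent-category likelihood, a small quasi-Newton step for
   `(δ_1, log σ_1, artanh ρ)`, and closed-form chain updates.  Every
   conditional step accepts only improvements, so the observed-data
   log-likelihood trace is non-decreasing.  Safeguarded SQUAREM
   extrapolation accelerates the sequence; an extrapolated candidate is kept
   only if it does not lower the log-likelihood.
2. **Quasi-Newton phase.**  L-BFGS-B on an unconstrained scale (`log σ_1`,
   logit probabilities, `artanh ρ`; `δ_1` stays free so the optimizer may
   cross the label boundary).  The exact gradient of the marginal
   log-likelihood comes from the EM (Fisher) identity — the posterior
   expectation of the complete-data score, assembled from one E-step sweep —
   verified against finite differences to 1e−7.  The phase stops when an
   iteration gains less than ~1e−4 in log-likelihood or the projected
   gradient falls below `newton_tol`.  If the optimizer exhausts its
   evaluation budget, one further full EM step is taken; the fit is flagged
   converged when that step gains less than 0.02 in log-likelihood (a
   relative change below ~1e−6 at the study's log-likelihood scale, with
   parameter movement well below 1e−3).  This verification matters for
   deliberately misspecified fits (e.g. a two-state model on single-state
   data), whose likelihood is nearly flat along the state-separation
   direction and crawls at ~1e−2 per EM step without approaching any
   model-selection-relevant improvement.

Label switching is resolved after fitting by the anchor `δ_1 > 0` (state 1
is the faster state).  The relabeling map that keeps the identification
anchors `δ_0 = 0, σ_0 = 1` is
`ν′ = (ν − δ_1)/σ_1, λ′ = λ/σ_1, δ_1′ = −δ_1/σ_1, σ_1′ = 1/σ_1`, with
response parameters swapped and chain probabilities complemented; it leaves
the likelihood invariant (tested).  A reflection anchor `Σλ_i ≥ 0` fixes the
sign of the speed axis (flipping `λ` and `ρ` jointly is likelihood-neutral).

Starting values are deterministic and data-driven: easiness from logit
proportions correct, thresholds from adjacent-category log-odds of the
marginal category frequencies, states separated by splitting person–item
pairs at the item's median RT category (motivating `δ_1 = 0.4` at start),
chain at (.6, .2, .8), `ρ = 0`.  Additional random perturbation starts are
available via `n_starts`; the default is a single start, which the
label-anchoring and nesting tests support for these well-separated designs.

**Standard errors.**  The default is the outer-product-of-gradients
estimator: per-person scores by central finite differences of the
per-person log-likelihood vector (one sweep per perturbed coordinate — ~2d
sweeps total), inverted and delta-method-mapped to the natural scale.  A
full central-difference Hessian (`method="hessian"`, step 1e−4 on the
unconstrained scale) is provided for small models; its cost grows with d²,
which is why it is not the default at d ≈ 186.  Both routes reproduce
closed-form Fisher information on a logistic sub-problem to 2%, and the two
agree on small models.  A non-invertible information matrix yields NaN
standard errors with a warning, never an exception.

## The simulator

`simulate_continuous` generates the study scenarios from the
*continuous-time* version of the model: within state `c`, `log t_pi` is
normal with mean `ν_i − δ_c − τ_p` and SD `σ_c` (loading 1).  Design values
(the heteroscedastic-Markov preset): `α_0i = 1.5`, `α_1i = 1`; `β_0i`
equally spaced on [−2, 0], `β_1i` on [0, 2]; `ν_i = 2`, `δ_1 = 0.5`;
`σ_0 = √0.39`, `σ_1 = √0.13`; `σ_τ = √0.13`; chain `π_1 = .666`,
`π_{1|0} = .231`, `π_{1|1} = .769`; latent correlation `ρ = −0.4` (the
signed value is recorded in `ScenarioTruth`, and recovery is always assessed
against the recorded value).  These imply log-scale communalities
`0.13/0.52 = .25` (state 0) and `0.13/0.26 = .5` (state 1).  The log times
are then passed through the centered Box–Cox transform
`((x+1)^0.3 − 1)/0.3` and exponentiated, which destroys within-state
log-normality and makes parametric continuous-time mixtures inappropriate —
the point of the categorized approach.  Draws violating the transform domain
(`log t ≤ −1`, probability ≈ `Φ(−3)` under the presets) are resampled and
counted.  Since the transform is strictly increasing, the categorized data
are bit-identical whether raw or pre-transform times are cut (asserted).

What the simulator does *not* emulate: real tests have item-varying
discriminations and time intensities, nonstationary strategies, and missing
data mechanisms; passing recovery tests here shows the estimator works when
the generating process matches the design, not that the two-state structure
is correct for any particular empirical test.

The fitted categorized models are never the generating model (the truth is
continuous), so the RT measurement parameters `ν_it`, `λ_i`, `δ_1`, `σ_1`
have no true comparators; recovery is assessed for `α_ci`, `β_ci`, the chain
parameters and `ρ` only.  Note the fitted model standardizes `Var(τ) = 1`
with `λ_i` free, while the truth uses `λ = 1` with `σ_τ = √0.13`, so fitted
loadings should be compared to `√0.13 ≈ .36` in spirit, not to 1.

## Model selection

All indices are `−2ℓ̂ + P` with penalties: AIC `2·npar`, BIC `ln(N)·npar`,
AIC3 `3·npar`, saBIC `ln((N+2)/24)·npar`, and CAIC
`2·npar(npar−1)/(N−npar−1)` (the printed small-sample form; the conventional
Bozdogan penalty `(ln N + 1)·npar` via `caic_convention="bozdogan"`).  At
`npar ≈ 185, N = 1000` the printed CAIC form adds less than one point per
extra parameter, so it ranks models essentially like AIC; our detection runs
show it selecting the heteroscedastic model on homoscedastic data, which the
published detection behavior of CAIC does not do.  The study harness
therefore tabulates CAIC under both conventions, and the behavioral checks
use the Bozdogan form.  Ties break toward fewer parameters, then a fixed
variant order.  A replication enters the detection table only if all fitted
models converged; exclusions are counted and rates renormalize over the
replications used.

## Desk-scale study sizes

The study harness keeps the design at full scale (N = 1000, n = 20, T = 5)
and reduces only the number of Monte-Carlo replications: the test suite uses
6 replications for the recovery/misspecification experiment and the
hetero-Markov detection row, and 4 each for the baseline and homo-Markov
scenarios; `scripts/acceptance.py` uses 4/3/3.  All comparison bands follow
from the replication counts: two-sample ±2 SE bands
(`2·SD·√(1/R_ours + 1/50)`) for comparing replication means with the
published 50-replication means, and one-sided binomial 95% bounds for
selection rates.  With more time, `detection_study` runs any replication
count over all five scenarios.

## Numerical choices and edge cases

- Quadrature: 10 points per dimension (Q² = 100 nodes); nodes with posterior
  weight below 1e−13 are skipped in the backward pass.
- Forward recursion: per-item normalization with accumulated log normalizers
  (exact for two states); zero-probability steps are floored at 1e−300.
- EM: `em_tol = 1e−6` on the plain-EM step gain (studies effectively stop at
  the quasi-Newton phase's ~1e−4 resolution); 500-sweep cap, 80-sweep cap
  for the EM phase when refinement follows.
- Chain updates clip probabilities to [1e−6, 1−1e−6]; a state whose total
  posterior mass falls below 1/N flags the fit `degenerate`.
- Probabilities in the PCM softmax are computed with max-shifted cumulative
  logits; item updates and structural updates only ever accept improvements,
  keeping the EM monotone to 1e−8 per step (tested).
- Degenerate inputs: empty items/persons are rejected at validation; an item
  with fewer observed times than categories cannot be categorized; ties at a
  cut value fall to the lower (faster) category.

## Known limitations

- Two states only, time-homogeneous transitions; no polytomous responses.
- The guessing parameter γ exists in the probability/information utilities
  but is never estimated (the estimable response model is 2PL).
- Standard errors ignore the categorization step's sampling variability (the
  cut points are treated as fixed), as is conventional for this design.
- OPG standard errors are asymptotically equivalent to Hessian-based ones
  but can differ in small samples; both are exposed.
- The baseline-scenario spurious-mixture log-likelihood gains in our runs
  (~50–70 points for the homoscedastic Markov model over the baseline) sit
  near the AIC3 decision boundary, so AIC3's baseline detection rate is less
  stable here than BIC's or saBIC's.
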