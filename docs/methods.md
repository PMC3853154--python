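# Methods

## Data model

A cohort is `n` subjects with follow-up time `t_i > 0`, event indicator
`δ_i ∈ {0,1}` and a complete numeric covariate row `x_i`. Right censoring is
assumed independent of the event process. The comparable-pair set **P**
contains ordered pairs `(i, j)` with `δ_i = 1` and `t_i < t_j`, strictly:
time-tied pairs are excluded from **P** altogether rather than shared, and a
censored subject can only appear as the later member. (Harrell's 0.5 credit
for *score*-tied pairs is available via `tie_policy="half"` in
`concordance_index`; the default counts a score tie as a miss, the literal
indicator definition.)

Scores are survival-time oriented everywhere in the public API: larger
score = longer predicted survival; the log relative hazard is its negation.

## Smoothed concordance and its gradient

`SCI(F) = (1/|P|) Σ σ(α (F_j − F_i))` with `σ` the logistic function.
Properties the tests rely on: `0 < SCI < 1`; SCI → CI as `α → ∞` on
tie-free scores and → 1/2 as `α → 0⁺`; adding a constant to all scores
changes nothing; `SCI(α, c·F) = SCI(cα, F)`. The gradient is computed
exactly per pair with the stable factorization `σ'(z) = σ(z)σ(−z)`, so no
exponential of a large positive argument is ever taken; components sum to
zero and are bounded by `α d_i / (4|P|)` (`d_i` = number of pairs containing
subject `i`). Pairwise sums are always over the explicit pair set — no
approximation — which is O(n²) and entirely affordable at the cohort sizes
this package targets (hundreds to a few thousand subjects).

`α` (default 1) trades approximation fidelity against gradient conditioning:
large `α` makes SCI hug CI but drives `σ'` to zero almost everywhere.

## GBMCI training loop

* **Initialization**: `f₀` is the prediction of an unpenalized linear Cox
  fit on the training subset. SCI is non-concave, so the starting point
  matters; the PH solution is a strong, cheap starting ranking. If the Cox
  fit is non-identifiable the initializer falls back to zero with a warning.
* **Stage**: draw `⌈subsample·n⌉` subjects without replacement (bagging-style
  subsample; default `subsample = 1`), compute the SCI gradient *within the
  bag's own pair set* at the current scores, and fit a least-squares tree
  (default depth 6, ≥ 10 subjects per leaf) to those pseudo-responses.
* **Line search**: `ρ_m` maximizes full-sample SCI along the tree direction
  on `[0, rho_max]` (default 100) — a 201-point uniform grid followed by
  bounded scalar refinement inside the best grid cell. The search is run on
  the full sample even when the tree was fitted on a bag: that is what makes
  the training-SCI sequence provably non-decreasing at `subsample = 1`,
  since `ρ = 0` is always a candidate. Grid ties are resolved to `ρ = 0`
  when no move ties the best value, otherwise to the largest tied `ρ` (a
  numerically saturated, flat objective resolves to the boundary). With the
  bounded range acting as implicit shrinkage, the default learning rate for
  this objective is `ν = 1`.
* **Stage count**: `cv` (default 5) seeded folds; each fold is trained to
  `n_estimators` (default cap 1500) recording held-out CI after every stage;
  the fold-average curve's argmax (ties → smallest) sets
  `selected_stages_`.
* A bag with no comparable pairs is redrawn once, then the stage is skipped
  with a warning; a fit in which every stage was skipped is an error.

## GBMCOX (boosted partial likelihood)

Same loop, different objective: the negative log partial likelihood with
Breslow handling of ties, `f₀ ≡ 0`, trees fitted to its negative gradient
`δ_i − e^{F_i} Σ_{k∈E: t_k ≤ t_i} 1/D_k` computed within the bag, each
terminal node refitted by one Newton step (node gradient sum over node
diagonal-Hessian sum, value 0 if the denominator is below 1e-12), stage
weight fixed at 1, and explicit shrinkage `ν = 0.002` doing the
regularization. Internal scores are on the log-relative-hazard scale;
`predict` negates them to the common orientation.

## Cox PH baseline

Newton–Raphson on the negative log partial likelihood (Breslow ties,
inclusive `t_j ≥ t_i` risk sets, no intercept, no regularization), with
step-halving so accepted iterations never increase the objective;
convergence when the decrease falls below `tol = 1e-8` (max 50 iterations).
All-constant covariates, singular Hessians, and divergence under separation
are flagged (`converged_ = False`) rather than raised.

## Regression-tree base learner

Exact greedy CART on squared error: candidates are midpoints between
consecutive distinct sorted values of each feature; a split must strictly
reduce SSE and leave ≥ `min_samples_leaf` subjects per child; ties among
equal-SSE splits go to the lowest feature index, then the lowest threshold,
making fits deterministic and row-order independent (up to float summation
order in leaf means). Rows route left on `x ≤ threshold`.

## Synthetic cohorts

Covariates are iid standard normal. Event times are exponential with rate
`baseline_rate · e^{log-hazard}`; `baseline_rate` defaults to 0.1 (an
arbitrary time unit — concordance is scale-free). Linear mode uses
`log-hazard = xᵀβ`; nonlinear mode uses `x₁x₂ + sin(πx₃)`, chosen so that
the risk has (a) a pure interaction with no marginal linear signal and (b) a
non-monotone single-feature effect — a regime where a linear PH fit sits
near chance while trees can rank well. Censoring times are exponential with
the rate solved (bisection) so that the *expected* censored fraction over
the cohort's realized hazards equals `censor_rate_target` (default 0.25,
a typical clinical-trial censoring level); this is exact for the
exponential race, so no Monte-Carlo calibration error enters. `true_scores`
(= −log-hazard) upper-bound the achievable ranking; note even the oracle's
CI is well below 1 because exponential racing is stochastic.

What the simulator does *not* emulate: correlated or high-dimensional
covariates, non-exponential baselines, informative censoring, competing
risks, or time-varying effects. Passing benchmarks here show the optimizer
and the ranking machinery work as specified — not that the method wins on
any particular clinical dataset.

## Problem sizes and numerical choices

The shipped benchmarks use cohorts of 150–400 subjects (2000 for Cox
coefficient recovery), 200–300 boosting stages at depth 2, and 5–10
simulation seeds; these sizes give stable medians while keeping a full run
in minutes on one core. Other fixed choices: finite-difference gradient
checks use central differences with step 1e-5 (relative error < 1e-6);
monotonicity of the training-SCI sequence is asserted up to 1e-12 float
summation roundoff; line-search refinement tolerance is 1e-12 in `ρ`; model
JSON uses shortest-repr float encoding so save → load → predict is exact.

## Known limitations

SCI is neither convex nor concave: the line search finds a local optimum
along each stage direction, and results depend on initialization (by
design, via the PH start). Training is O(stages · |P|) and single-threaded.
No missing-data handling, stratification, time-varying covariates, or
baseline-hazard estimation — the model ranks; it does not predict absolute
survival times.
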