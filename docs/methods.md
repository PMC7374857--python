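# Methods

## Model and assumptions

`seqpaf` treats the risk-factor/disease system as a causal Bayesian
network: a directed acyclic graph over categorical nodes — confounders,
risk factors and one binary outcome — together with one conditional
distribution per node given its parents. Three assumptions carry all the
causal weight:

1. **Known structure.** The DAG is supplied a priori (structure learning is
   out of scope). Estimates are only as good as the assumed graph.
2. **No unmeasured confounding.** Every common cause of two modelled nodes
   is itself a modelled node. Under this assumption an intervention
   `do(A_S = 0_S)` is identified by the truncated factorization: the
   intervened nodes' factors become point masses at their reference levels
   and every other conditional is unchanged.
3. **Correct component models.** Each non-root node follows a main-effects
   logistic (binary) or proportional-odds (ordinal) regression on its
   indicator-coded parents. An interaction hook exists at the API level
   (models are pluggable `NodeModel`s), but main effects are the default.

"Eliminating" a risk factor means fixing it at its declared reference
(lowest-risk) level for everyone — a degenerate intervention, not a
distributional shift. Sequential AFs are increments of counterfactual
prevalence along nested interventions; average AFs are Shapley-style means
of those increments over elimination orders.

## Estimation pipeline

1. **Weights.** Cohort data get unit weights. Case-control data get
   `incidence` per case and `1 − incidence` per control, so weighted
   maximum likelihood imitates estimation from a population random sample.
   A single crude pair of weights is used rather than per-stratum weights:
   individually varying case weights inflate the variance of the
   regression coefficients for little bias benefit at realistic sizes.
2. **Fitting.** Binary nodes: statsmodels GLM, binomial family,
   `var_weights` (= weighted MLE). Ordinal nodes: an in-package weighted
   cumulative-logit fit (see *Numerical choices*), because no available
   ordinal regression accepts observation weights. Root nodes are never
   modelled parametrically — their observed values are carried through
   every counterfactual dataset — but their weighted marginal tables are
   stored for the synthetic generator and the oracle.
3. **Intervention simulation.** `do_intervene` fixes the new targets at
   reference and re-draws every strict descendant of the full intervened
   set, in topological order, from the fitted conditionals. Each
   elimination step uses a fresh draw (no reuse of descendant draws across
   branches); both the "carry non-descendants of the newly fixed node"
   description and this all-descendants refresh are draws from the same
   truncated factorization, and the refresh keeps the engine stateless.
4. **AF estimators.** All AFs share the observed-data denominator
   `Σ w_i Y_i`, computed once per run, which makes the SAFs along an
   elimination order telescope *exactly* to the joint PAF of the set.
   Negative SAFs are reported, not clipped — mixed-sign mediated pathways
   (the package's synthetic alcohol-style node is an example) can genuinely
   attenuate or reverse an increment.
5. **Average AFs.** `average_af` samples m elimination orders i.i.d.
   uniformly (with replacement) and runs one sequential path per order.
   `AAF_j` is the across-order mean of `SAF_j`; its Monte-Carlo SE is the
   across-order SD over √m, the natural estimator when each order
   contributes one independent draw. Position-stratified means with
   normal-approximation 95% Monte-Carlo intervals summarise how increments
   depend on elimination position. Orders are independent work units with
   per-order rng substreams derived from `(master seed, order index)`, so
   results are invariant to execution order. The default m = 1000 is the
   smallest sample recommended for stable estimates; the examples use less
   for speed, production analyses commonly use 10,000.

## Disease-column handling

Counterfactual disease can be **sampled** (a Bernoulli draw per row — the
direct reading of "simulate a counterfactual dataset", and the default) or
stored as its **expected value** `P(Y=1 | parents)` per row
(`outcome_mode="expected"`). Both are unbiased for the same counterfactual
prevalence; the expectation mode is strictly lower-variance and is what the
test-suite uses. Intermediate risk factors are always sampled.

## The enumeration oracle

For small discrete networks the truncated factorization is evaluated
exactly by expanding node levels in topological order (configuration cap
10⁷). Two engines:

- **population** — roots follow a supplied root-configuration table (the
  product of declared root marginals, or a weighted empirical table). This
  is the ground truth of a *known generating network*, used for
  parameter-recovery checks.
- **empirical** — exact conditional expectations given an observed
  dataset: only descendants of the intervened set are integrated out, all
  other columns stay at their observed values, and the `do(∅)` prevalence
  is the observed weighted prevalence. This is exactly the conditional
  expectation of the simulation estimator in expected-outcome mode, so
  "estimate within k Monte-Carlo SEs of the oracle" is a calibrated test
  with no O(n^−½) offset from data sampling.

Exact average AFs use the permutation (Shapley) weights
`|S|!(K−1−|S|)!/K!` over the 2ᴷ cached subset prevalences — algebraically
identical to enumerating all K! orders and verified against brute-force
order enumeration in the tests; the API refuses K > 5 by default.

The **direct-effects projection** (`project_direct_effects`) computes the
probability limit of refitting on the graph with all risk-factor →
risk-factor edges removed: each affected node's new conditional is the
exact marginalisation of the original joint over its removed parents,
stored as a CPT. This isolates the mediation bias of single-regression
methods from fitting noise; the refit-on-pruned-graph route is also
available (`--direct-only`) and is exercised in the CLI tests.

## Monte-Carlo standard errors

Single AF estimates report a batch-means SE: rows are i.i.d. subjects, so
the SD of B row-block estimates over √B estimates the combined
data-sampling + simulation error of the ratio estimator (default B = 20).
Average-AF SEs are across-order SEs as above. The acceptance checks verify
both are calibrated (coverage against the empirical oracle; empirical SD
across master seeds within a factor 1.5 of the mean reported SE).

## Numerical choices

- **Proportional-odds convention.** `P(X ≤ level_k | x) = expit(c_k − x'β)`
  with strictly increasing cutpoints; positive coefficients push mass
  toward higher (riskier) levels. AF estimates are invariant to this
  internal convention because fitting and simulation share it; round-trip
  consistency is tested, and the fit matches statsmodels' ordinal model at
  unit weights to ~1e−3.
- **Optimisation.** The weighted cumulative-logit likelihood is maximised
  by L-BFGS-B with an analytic gradient; cutpoints are kept monotone by a
  log-difference reparameterisation; starting values are the weighted
  marginal cumulative logits with β = 0. Asymptotic SEs come from a
  central-difference Hessian at the optimum.
- **Dummy coding.** First declared level is the baseline for every parent;
  deterministic column order (`parent[level]`) makes fits reproducible.
- **Guards.** Predicted probabilities are clipped to
  `[1e−12, 1 − 1e−12]` and renormalised before sampling; |coefficient| > 30
  on the logit scale is treated as separation and raises `FitError` —
  non-convergence is an error, not a warning, because counterfactual
  simulation from a silently bad component model is misleading downstream.
  Empty parent-category cells are reported with the offending node named.
- **Tie-breaks.** Topological order resolves ties by node declaration
  order.
- **Seeding.** All randomness flows through numpy Generators;
  `estimate_paf(j)` *is* the length-1 sequential path, so a shared seed
  reproduces the identical number. Order-level substreams use
  `SeedSequence(seed, spawn_key=(1, order_index))`; permutation sampling
  uses `spawn_key=(0,)`.

## The synthetic scenario

`default_interstroke_like_scenario()` is a 14-node layered stroke-style
network: confounders (sex, region 3-level, education 4-level ordinal),
five behavioural risk factors (inactivity, diet tertiles, smoking, alcohol
3-level, stress), three physiological (high blood pressure, lipid-ratio
tertiles, waist-hip-ratio tertiles), two pre-clinical (cardiac risk
factors, diabetes) and a binary stroke outcome. Disease develops
stage-wise: every earlier-stage node is a potential cause of every
later-stage node (the published structure this emulates is only available
as a figure, so the fully layered version is an explicit, documented
idealisation). Effect sizes are fixed constants chosen so that

- the exact disease prevalence is ≈ 1.0% (large enough that a 5,000-case
  case-control draw exists in a 10⁶ population; the documented
  `incidence_target` equals this prevalence, and weighting by the true
  incidence is what makes the case-control pathway consistent);
- true average AFs span roughly 0.02–0.25 and the joint PAF of all ten
  risk factors is ≈ 0.87, so tolerance checks are meaningful;
- the alcohol-style pathways are mixed-sign (protective for lipids and
  cardiac disease, harmful for blood pressure and directly for the
  outcome), reproducing the qualitative phenomenon where mediation
  *attenuates* a direct effect.

What the generator deliberately does **not** emulate: matched case-control
sets (estimation uses crude case/control weights and covariate adjustment
instead — resampling treats rows independently), continuous exposures
(everything is categorical by design; categorisation is also a known
limitation of the method itself), measurement error, missing data and
reverse causation. Passing tests therefore demonstrate correctness of the
estimators *given the model class*, not robustness to those real-data
complications.

## Problem sizes in the test suite

Chosen as the smallest sizes at which the statistical checks are sharp:
oracle-coverage runs use 100,000-row simulations over 20 master seeds on a
5-node network; order-invariance and average-AF agreement use 20,000–30,000
rows with up to 2,000 sampled orders on 3-risk-factor toys; the
case-control recovery check simulates a 10⁶ population, draws
5,000 + 5,000, and bootstraps the refit 20 times; SE calibration repeats a
100-order average 50 times on a fixed 5,000-row dataset.

## Known limitations

- Bootstrap confidence intervals for AAFs (statistical, as opposed to
  Monte-Carlo, uncertainty) are not built in; rerunning fit + estimation on
  resampled data is straightforward with the public API (the recovery test
  does exactly that) but is left to the user.
- The enumeration oracle is exponential in the graph size and is meant for
  validation-scale networks only.
- Identification relies on *no hidden confounding*; front-door-style
  adjustments and soft/stochastic interventions are out of scope.
- Matched designs are handled only via the crude-weights approximation.
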