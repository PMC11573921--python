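# Methods

## Model and procedure

The package operates on a binary-outcome logistic model family. For a
declared set of sensitive variables `X_S` it enumerates every exclusion
case `S′ ⊆ S` (canonical order: subset size descending, then
lexicographic) and fits the case optimum by maximum likelihood. The
near-optimal set around each optimum is generated parametrically: because
the logistic MLE is asymptotically `N(β*, Σ*)` with `Σ*` the inverse
observed Fisher information, candidate coefficient vectors drawn from
`N(β*, k·Σ*)` with a scope-width `k ~ U(u1, u2)` concentrate exactly where
near-optimal models live, and a validation-set rejection step makes the
near-optimality exact rather than asymptotic: a candidate is kept iff its
validation AUC is at least `(1 − ε0)` times the case optimum's.

The intercept is sampled together with the slopes — the covariance couples
them, and excluding it would bias the candidate set toward miscalibrated
intercept/slope combinations.

**Admission and the ε0 calibration.** A case enters the integral Rashomon
set (IRS) only if its own optimum passes the same test against the
full-model anchor. The case-level slack is derived from the overall slack
as `ε0 = 1 − √(1 − ε)`, so the two multiplicative slacks compound to
exactly `(1 − ε)`: every IRS member provably has validation AUC
≥ `(1 − ε)` × full-model optimum. This calibration is a package design
choice (any `0 < ε0 ≤ ε` is accepted in the config); the square-root rule
is the tightest one that preserves the IRS-wide guarantee without
case-specific tuning. The draw budget is fixed per admitted case
(survivors are kept, no re-drawing to a target count), which makes the run
cost and the random stream deterministic.

With an AUC anchor the filter accepts generously when the sampling
covariance is small relative to the AUC's sensitivity (at large n nearly
all draws survive); the rejection step is what *guarantees* the bound
rather than what shapes the set. A mean-log-loss anchor (`metric: loss`,
rejection at `≤ (1 + ε0)` × optimum loss) is available for the loss-based
definition of near-optimality.

## Fairness metrics and ranking

Fairness is audited in the separation sense — error-rate profiles should
not depend on sensitive attributes given the true outcome. Subgroups are
the **joint (intersectional)** level combinations of all audited sensitive
variables; marginal per-variable gaps (ΔTPR, ΔTNR) are reported separately
in the evaluation layer. Groups smaller than `min_count` (default 20) are
pooled into `(other)` before rates are computed; a subgroup missing one
outcome class has the affected rates undefined and is skipped by the range
metrics (a range over undefined values is meaningless, and pooling makes
this rare).

Each candidate gets its own Youden threshold on the validation split
(candidate thresholds are the observed scores, rule `ŷ = 1 iff p ≥ t`,
ties in J broken toward the largest threshold; J comparisons use the
integer-exact form `tp·n_neg − fp·n_pos` so ties are detected without
floating-point ambiguity). The three metrics (equal opportunity, equalized
odds, BER equality — in this circular order) aggregate into
`FRI = 1/Σ mⱼmⱼ₊₁`; a model perfect on all metrics receives `+inf` and
ranks first. Sorting is FRI descending with deterministic tie-breaks
(equalized odds ascending, then candidate id), so the ranking is invariant
to input order and to a global rescaling of all metrics.

## Thresholds, evaluation, inference

* Classification thresholds are **model policy**: fit on the validation
  split, applied unchanged to the test split (no test-set re-fitting).
* AUC is the Mann–Whitney probability with half credit for ties, computed
  by rank sums.
* Confidence intervals are seeded nonparametric percentile bootstraps
  (default B = 1000); sensitivity/specificity CIs resample the thresholded
  predictions with the threshold held fixed. Resamples on which a
  statistic is undefined (single-class draws) are redrawn and tallied.
* Odds ratios use Wald inference with the 95% normal quantile 1.959964;
  for the selected coefficients `β̃` the covariance is the inverse
  observed information evaluated *at `β̃`* on the training design —
  the same machinery as for the optimum. (These intervals inherit the
  usual caveat that `β̃` was selected, not estimated; they describe
  curvature, not selection-adjusted coverage.)
* SHAP attributions use the exact closed form for linear models with an
  independence baseline, `φⱼ = βⱼ(xⱼ − μⱼ)` on the log-odds scale, with
  dummy columns summed to their parent variable; background = 500-row
  training subsample, explained set = 500-row validation subsample, seeded.

## Numerical choices

* Logistic fits: Newton iterations with monotone step-halving, start at
  zero, convergence at score max-norm < 1e-8, ≤ 100 iterations.
  Separation is flagged by either signature: a coefficient exceeding 30 in
  magnitude during iteration, or an exploded Wald SE (> 100) at the
  optimum — the latter catches quasi-separation that "converges" via
  sigmoid saturation with |β| ≈ 20.
* Covariance sampling uses a Cholesky factor; a non-PD matrix gets one
  diagonal jitter of `1e-10·trace/dim` before failing.
* Splits use largest-remainder apportionment of `n·fraction` (exact,
  deterministic counts; e.g. n = 1000 at 70/10/20 gives 700/100/200) over
  a seeded permutation, unstratified by default with an optional
  stratify-by-outcome flag.
* Case rank bins in the per-case tabulation are contiguous near-equal
  quarters of the rank range (default 4 bins).

## Synthetic cohort generator

The generator emulates an ED triage-to-admission cohort: a four-level
`race` and binary `sex` (sensitive), five standardized continuous
vitals-like predictors, and a three-level `triage` score; the outcome is a
single logistic law over these covariates. Bias is injected through the
mechanisms that separation metrics actually respond to: per-race-level
intercept shifts `δ_g`, per-race-level label-flip rates `ρ_g`, and a proxy
correlation `r` tying `pain_score` to race so bias survives race exclusion.
Presets: `none` (all knobs zero), `mild` (δ = ±0.4, ρ = 0.05, r = 0.3),
`strong` (δ = ±0.8, ρ = 0.1 on one group, r = 0.6).

Default design parameters were chosen by an a-priori precision analysis:
equal race-group probabilities (0.25 each), balanced sex, moderate effect
sizes (continuous |β| ≤ 0.4, triage effects −0.3/−0.6) and marginal
prevalence ≈ 0.45, so that at n = 20,000 every design coefficient has
standard error ≲ 0.034 and parameter-recovery checks have a ≥ 3σ margin
against a ±0.1 bound on estimator bias. What this generator deliberately
does **not** emulate: skewed subgroup sizes, realistic vital-sign
marginals and correlations, missingness, or calibration drift — so
passing tests demonstrate the correctness and internal logic of the
pipeline, not performance on real ED data, where subgroup imbalance and
covariate structure will make admission and fairness patterns differ.

Ground-truth subgroup prevalences are obtained by large-n Monte Carlo
(default 10⁶ rows, fixed seed) rather than closed form, since label flips
and the proxy make closed forms awkward.

## Problem sizes used in the checks

The test suite and the acceptance script run the full pipeline at
n = 10,000–20,000 rows with 2,000 draws per case (IRS sizes of a few
thousand, the same order as typical published near-optimal sets), 10–20
seeds for the stochastic end-to-end properties, 200 replicate datasets for
bootstrap-coverage studies, and 100,000 draws for the sampling-law check.
Noise-floor facts discovered during design: the equalized-odds range over
8 intersectional subgroups has a per-draw floor of ≈ 0.04 at n = 50,000
(hence vanishing-gap checks use multi-seed means), and a per-draw
max-|error| bound of 0.1 on all coefficients is only a ≈ 3σ statement at
n = 20,000 (hence recovery checks bound the across-seed bias and the
pooled Wald coverage instead).

## Known limitations

* Only binary outcomes and the logistic family; no penalization, no mixed
  models, no tree/NN Rashomon variants.
* The AUC anchor makes within-case rejection nearly vacuous at large n;
  fairness diversity then comes from the sampled coefficient spread, and
  whole-case exclusion enters only through the admission rule. On strongly
  biased cohorts a sensitive variable with genuine signal can keep its
  exclusion cases inadmissible — the admission record makes this visible,
  and a contextual `must_exclude` constraint (with a larger ε) is the
  intended override.
* Wald CIs for the selected model ignore the selection step.
* Fairness metrics are threshold-dependent; a different operating point
  yields different gaps.
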