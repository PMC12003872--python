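# Methods

## Cohort generator

Each of `n` subjects is assigned independently to one of the four
(marker, treatment) cells.  The joint distribution is determined by the
margins `p_M` (high-marker prevalence) and `p_T` (experimental-arm
fraction) together with the odds ratio `OR_MT`: the joint probability
`p11` solves the quadratic `OR·(p_M − p11)(p_T − p11) = p11·(1 − p_M −
p_T + p11)`, whose admissible root inside `(max(0, p_M + p_T − 1),
min(p_M, p_T))` is unique for any finite positive odds ratio.
Configurations whose implied cells are not all strictly positive are
rejected at construction.  Assignment is i.i.d. multinomial rather than
exact quota allocation: per-dataset variation in cell counts is part of the
small-sample behaviour being studied.

Event times are inverse-CDF samples from a proportional hazards model,
`t_e = −log(U_e) / (λ_e · exp(β_M M + β_T T + β_I M T))`, with the
exponential baseline rate `λ_e = −log(1 − q_e)/t_end` calibrated so that a
fraction `q_e` of reference-group subjects (M=0, T=0) fail by the
follow-up horizon.  Censoring times come from the same family with **all
covariate effects set to zero** (non-differential censoring; the censoring
code never reads M or T) and rate calibrated to `q_c`; `q_c = 0` disables
random censoring.  A subject is an event at `t_e` iff
`t_e < min(t_c, t_end)`, otherwise censored at `min(t_c, t_end)`;
boundary ties (probability zero) are censored.

Defaults mirror the study conditions the generator emulates: `p_T = 0.5`,
`q_e = q_c = 0.2`, `t_end = 5` years, `HR_T = 1`, with grids over
`n ∈ {200..1000}`, `p_M ∈ {0.25, 0.5, 0.75}`, `HR_M ∈ {0.6..6}`,
`OR_MT ∈ {0.5, 1, 2}`, `HR_I ∈ {0.25..1}` and 10000 replicates.  A Weibull
baseline (shape > 1 increasing hazard, < 1 decreasing) is available for
sensitivity analyses; no reference shape values exist, so the defaults
(0.5, 1.5) are this package's own choice and the scale is always
recalibrated so the reference-group event fraction at `t_end` stays `q_e`.

What the generator does *not* emulate: covariate-dependent or informative
censoring, time-varying treatment, more than two marker levels, or
non-proportional hazards.  Passing tests therefore demonstrate correctness
of the estimators under the generating model, not robustness of the
case-only design to violations of its assumptions beyond the ones
deliberately varied (event rate, marker effect direction, marker-treatment
dependence).

## Case-only construction

One row per event.  The offset is `log(p_e/(1−p_e))` with `p_e` the
experimental-arm fraction of the full-cohort risk set at the case's event
time; risk-set membership is `follow-up time ≥ t`, so the failing case is
in its own risk set (the standard risk-set convention; simulations show
the alternative makes no practical difference).  Tied event times share a
risk set.  A degenerate fraction (`p_e ∈ {0, 1}`, infinite offset —
typically the last event when the tail of the risk set is single-armed) is
uninformative for the logistic likelihood; such cases are dropped, counted
and logged.  Offsets are a function of arms and times only, which is the
design's cost argument: non-cases never need a marker measurement.

## Firth-penalized fitters

Both fitters maximize a Jeffreys-prior penalized likelihood
`ℓ*(θ) = ℓ(θ) + ½ log det I(θ)`.

**Logistic.**  `I = X'WX`; the modified score adds `h_i(½ − μ_i)` to each
residual, with `h_i` the weighted-hat-matrix leverages.  Fisher scoring
with step-halving; the variance estimate is the inverse Fisher information
at the penalized optimum.  The penalty shrinks *all* parameters including
the intercept-like term, which is why a few percent of shrinkage bias
remains even at large sample sizes.

**Cox.**  Breslow partial likelihood (simulated times are continuous, so
ties have probability zero and the tie method is immaterial); `I` is the
partial-likelihood information and the modified score term
`½ tr(I⁻¹ ∂I/∂β_r)` is assembled from the risk-set moments S0–S3, which
requires third derivatives of the partial likelihood.  Designs built from
two binary factors take at most four distinct covariate rows, so the
moments are accumulated per unique pattern and a fit costs
O(#event-times × #patterns) per iteration regardless of cohort size.
Newton steps are clipped element-wise to `max_step = 0.01` with at most
1000 iterations — the deliberately conservative solver configuration used
for monotone-likelihood problems; a fit counts as converged only if it
used strictly fewer iterations than the cap.

Numerical safeguards shared by both solvers, each triggered by a concrete
failure mode observed during development:

- *Ascent repair*: element-wise clipping can turn a Newton step into a
  descent direction (its inner product with the score goes negative); the
  whole vector is then rescaled to the cap instead.
- *Adaptive trust region*: the per-iteration cap shrinks when step-halving
  fires (overshooting along a weakly identified ridge) and relaxes back to
  `max_step` after clean steps.
- *Stopping rules*: score max-norm below `tol` (1e-8 logistic, 1e-6 Cox),
  or Newton-step max-norm below `step_tol` (the score scales with the
  number of events, so on very large cohorts the parameter change is the
  sharper criterion), or the objective flat to machine precision for three
  consecutive iterations (quasi-separation ridges where float64 cannot
  resolve further improvement).
- Maximum-likelihood fits (`firth=False`) on separated data report
  `converged=False` or visibly diverged coefficients rather than raising.

**Profile-likelihood intervals.**  A bound `b` for coefficient `k` solves
`2[ℓ*(θ̂) − max_{θ: θ_k = b} ℓ*(θ)] = χ²₁(level)`.  The inner maximization
re-runs the constrained solver warm-started from the previous solution;
the outer root is bracketed by geometric expansion from the Wald bound and
solved by Brent's method.  A bound is flagged unconverged after 200
profile evaluations or if bracketing fails.  The likelihood-ratio test for
`θ_k = 0` is the dual quantity (signed-root penalized LR), so `p ≤ α`
iff the PL interval at level `1 − α` excludes zero, up to root-finder
tolerance.

## Performance measures

Per scenario × method × coefficient: bias and (for nonzero truth) relative
bias in %, empirical SE (denominator `N_c − 1`), model SE
(root-mean of model variances), relative ModSE error
`100(ModSE/EmpSE − 1)`, CI coverage, and rejection rate of the interaction
null — labelled type-I error when the generating interaction is zero,
power otherwise.  Filters: datasets must have events in at least three of
the four (M, T) cells, and only converged fits enter (`N_c`); PL coverage
and power are computed over the subset with both profile bounds converged
(`N_c_pl_bounds`), Wald measures over all of `N_c`.  Case-only
coefficients are evaluated against the generating Cox-scale truths
(γ ≈ β under the design's assumptions), so the reported "bias" of the
case-only estimator includes the approximation error of that
correspondence — which is precisely what makes the harmful-marker and
dependent-assignment scenarios informative.

## Seeding and reproducibility

A scenario's seed sequence combines the master seed with a CRC-32
fingerprint of its parameter string, and replicate `j` draws from spawned
substream `j`.  Grid output is therefore invariant to scenario ordering,
any single dataset can be regenerated in isolation, and `run_scenario` is
a pure function of (config, options).

## Problem sizes

The bundled reruns use desk-scale replication chosen once: 3000 replicates
for case-only power targets, 1500 for the Firth-Cox target, 500 cohorts
per scenario for event-rate summaries, and 800–1000 replicates inside the
test suite.  At these sizes a coverage or power estimate carries a Monte
Carlo SE of roughly 0.5–1.5 percentage points, and comparisons against
10000-replicate reference values are made within three combined Monte
Carlo SEs.

## Known limitations

- The case-only model estimates treatment and interaction effects only;
  the marker main effect is not identifiable from cases alone.
- Convergence *counts* can differ slightly from other implementations of
  the same models, since iteration caps and stopping rules are
  solver-specific; they are reported but should be read as soft
  diagnostics.
- The augmented case-only / case-control hybrid design and adjustment for
  a third factor explaining marker-treatment dependence are out of scope.
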