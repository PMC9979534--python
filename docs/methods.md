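# Methods

This note records the statistical model the package implements, the
conventions chosen where the design family leaves room, and what the
simulator does and does not emulate.

## Model and decision rule

Let φ be the target DLT probability and (*j*, *k*) the current dose
combination on a J × K grid.  Toxicity is assumed non-decreasing in each
agent separately; no assumption is made about diagonal comparisons
(partial ordering).  With y DLTs among n patients at the current
combination, the design escalates when y/n ≤ λ_e(n), de-escalates when
y/n ≥ λ_d(n), and otherwise stays.  Both comparisons are inclusive; the
de-escalation convention matters only on the null set where y/n equals a
boundary exactly, which cannot occur for the irrational boundaries the
closed forms produce.

λ_e and λ_d are the optimal-interval cut-points for the bracket
(φ₁, φ, φ₂), taken as given closed forms (see the
`asboincomb.boundaries` docstring).  The adaptive design evaluates them
at the shrunk bracket

φ₁(n) = φ − Δ₁/((n−1)/t₁ + 1),  φ₂(n) = φ + Δ₂/((n−1)/t₂ + 1),

where Δ₁ = φ − φ₁_init and Δ₂ = φ₂_init − φ are the *initial deviations*.
The parameters exposed to users are the initial bracket probabilities
φ₁_init/φ₂_init (the scale on which recommended values such as 0.3 φ and
1.7 φ are quoted); the formulas consume the deviations.  This
parameterisation is the one that reproduces the published boundary table
for φ = 0.3, t₁ = t₂ = 100 at every printed n ≥ 6 to three decimals; the
table's first printed column equals the n = 1 (pre-data) boundaries, and
the package reproduces it at n = 1.

The shrinkage index n is the cumulative count at the **current dose**
(`boundary_n="dose"`), which is what makes the rule tabulable per dose; a
`"total"` option indexes by overall enrollment for sensitivity analyses.

### Candidate ranking and ties

Admissible escalations are the in-grid members of
{(j+1, k), (j, k+1)}; de-escalations of {(j−1, k), (j, k−1)}.  Grid-edge
behaviour falls out of in-grid filtering: at an edge only the remaining
neighbour is available, at a corner the set is empty and the dose is
retained.  Candidates are ranked by the Jeffreys-posterior interval
probability Pr{p ∈ (λ_e, λ_d) | y} with p ~ Beta(0.5 + y, 0.5 + n − y)
(the prior itself when the candidate is untried).  The interval used for
a candidate is evaluated at that candidate's own cumulative count
(`candidate_boundary="candidate"`, consistent with per-dose adaptive
boundaries; `"current"` reuses the current dose's interval).  Score ties
within 1e-12 — typical when both escalation candidates are untried — are
broken uniformly at random from the trial's seeded generator, and the
draw is recorded in the decision's rationale.

### Safety stop

The design family does not pin down an early-termination criterion; the
package uses the standard interval-design convention: terminate, and
select no MTDC, when the lowest combination has n ≥ 3 patients and
Pr(p₁₁ > φ | Beta(0.5 + y, 0.5 + n − y)) > 0.95.  Both constants are
`DesignParams` fields.  Per-dose elimination of over-toxic non-lowest
combinations is available behind `dose_elimination` but off by default,
since only lowest-dose termination is part of the core design.

### MTDC selection

At trial end (no early stop), per-combination Jeffreys posterior means
(y + 0.5)/(n + 1) are smoothed by weighted two-dimensional isotonic
regression with weights n + 1.  The projection onto the intersection of
the row-monotone and column-monotone cones is computed with **Dykstra's
alternating projections** (column- and row-wise PAVA passes with
correction increments).  Plain alternating PAVA was rejected: it
converges to *a* monotone matrix but not the weighted least-squares
projection, and on random inputs it can fit worse than a constant; the
Dykstra fit matches an independent quadratic-programming solution to
1e-14.  Sweeps stop when an iteration moves the estimate by ≤ 1e-14
(cap 500; ~200 sweeps worst case on small grids).  Untried combinations
enter the smoothing with weight 1e-8 purely so the monotone completion is
defined; they are never selectable.  Among tried combinations the
smoothed estimate nearest φ is selected, ties resolved toward the larger
sample and then uniformly at random.

## Simulator

`run_trial` starts at (1, 1), draws each patient's DLT as an independent
Bernoulli at the assigned combination's true rate (patients are
exchangeable; no accrual or waiting-time modelling — every cohort is
fully observed before the next decision), applies the safety stop and
then the transition rule after each cohort, and stops when `max_n`
patients are enrolled.  Replicate *i* of `simulate` uses the *i*-th child
stream spawned from the master `SeedSequence`, so results are exactly
reproducible and increasing the replicate count never perturbs earlier
replicates.

Operating characteristics: PCS = % of replicates whose selection is a
true MTDC (early-stopped replicates count in the denominator and select
nothing); PNMTDC = 100 × (patients treated at true-MTDC cells) / (all
treated patients), pooled over replicates; NDLTs = mean DLT count per
trial.  When a scenario has several cells at the target rate, selecting
any of them counts as correct.

Default study conditions mirror the reference simulation setting: target
φ = 0.3, initial bracket 0.3 φ / 1.7 φ, t₁ = t₂ = 100, cohorts of 3,
N = 60, 1000 replicates.  The eleven packaged scenarios are the ten
realistic 5 × 3 matrices (φ = 0.3) and the PF-03084014 + doxorubicin
3 × 2 matrix (φ = 0.33); `generate_scenario` builds random monotone
matrices with a unique MTDC at a requested cell for property testing.

The boundary-range contrast computed by `scripts/acceptance.py`
(wide 0.1 φ/1.9 φ bracket vs classic 0.6 φ/1.4 φ on the extreme scenario
whose only MTDC is the lowest combination) runs both arms on a common
master seed: with common random numbers the Monte-Carlo error of the
*difference* is roughly halved relative to independent arms.  Across
master seeds the PCS difference is about +4 points (SD ≈ 1) and the
PNMTDC difference about +16.5 points (SD ≈ 0.7).  These contrasts are
sensitive to conventions the design family leaves open — in particular
the early-termination rule (disabling it gives ≈ +5.5/+15) and whether
the comparison arm shrinks its boundaries (a fixed-boundary comparator
gives ≈ +4/+14.3) — so single published values for this quantity carry
both Monte-Carlo and specification uncertainty of a few points.

## What the simulator does not emulate

Real combination trials involve staggered accrual, incomplete follow-up,
non-binary and late-onset toxicity, and clinician overrides of the
algorithmic recommendation; none are modelled.  Scenario matrices are
exactly monotone with exact-φ MTDC cells, so simulator-based checks
validate the decision logic and its operating characteristics under the
stated generative model, not performance on misspecified toxicity
surfaces.  MTDC-contour estimation (several equi-toxic combinations
reported jointly) is out of scope: the design returns a single MTDC.

## Numerical notes

- Boundaries are kept at full double precision; 3-decimal rounding is for
  display only.
- `t = inf` is accepted and yields exactly the fixed design; t around
  1e15 matches it to ~12 significant digits over n ≤ 200.
- Decision-table thresholds are derived by exact enumeration of y at each
  n, so the table is equivalent to rule evaluation by construction.
- Posterior quantities use `scipy.special.betainc`/`betaincc` rather than
  distribution objects; quadrature cross-checks in the tests agree to
  1e-8 or better.
- User-facing files are 1-based with matrix rows = agent-2 levels
  (declared in each file header); all internal indices are 0-based with
  arrays indexed [agent-1, agent-2].
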