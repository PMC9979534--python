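# asboincomb

Phase I drug-combination dose finding with **adaptively shrinking
Bayesian optimal-interval boundaries** (the asBOINcomb design), plus the
fixed-boundary two-agent interval design (BOINcomb) it generalises, and a
Monte-Carlo simulator for trial operating characteristics.

The package is aimed at trial biostatisticians designing two-agent dose
escalation studies: it tabulates the complete escalate/stay/de-escalate
rule in advance, evaluates interim decisions from observed data, selects
the maximum tolerated dose combination (MTDC) at the end of a trial, and
benchmarks design parameters by simulation.

## The design in brief

A two-agent trial explores a J × K grid of dose combinations whose true
DLT (dose-limiting toxicity) probabilities are monotone in each agent but
only partially ordered overall.  After each cohort at combination
(*j*, *k*), the observed DLT fraction p̂ = y/n is compared with an
escalation boundary λ_e and a de-escalation boundary λ_d.  For a target
DLT rate φ bracketed by φ₁ < φ < φ₂, the decision-error-minimising
boundaries are

    λ_e = log((1−φ₁)/(1−φ)) / log{ φ(1−φ₁) / (φ₁(1−φ)) }
    λ_d = log((1−φ)/(1−φ₂)) / log{ φ₂(1−φ) / (φ(1−φ₂)) }

The adaptive variant shrinks the bracket toward φ as patients accumulate
at the current dose.  With initial deviations Δ₁ = φ − φ₁ init and
Δ₂ = φ₂ init − φ,

    φ₁(n) = φ − Δ₁ / ((n−1)/t₁ + 1),    φ₂(n) = φ + Δ₂ / ((n−1)/t₂ + 1)

so λ_e(n) rises and λ_d(n) falls toward φ, and the acceleration factors
t₁, t₂ > 0 control the shrink rate (t → ∞ recovers the fixed design;
t₁ > t₂ makes de-escalation increasingly easy relative to escalation,
penalising dosing above target).  Boundaries depend only on n, so the
whole rule can be printed as a decision table before the trial starts.

When a move is indicated, the admissible candidates — one dose level up
or down in exactly one agent — are ranked by the Jeffreys-posterior
probability Pr{p ∈ (λ_e, λ_d) | y} under Beta(0.5 + y, 0.5 + n − y), with
exact ties broken at random.  The trial stops early when the lowest
combination is too toxic (Pr(p₁₁ > φ | data) > 0.95 with n₁₁ ≥ 3).  At
the end, per-combination Jeffreys posterior means are projected onto the
row/column-monotone cone by weighted two-dimensional isotonic regression
(Dykstra's alternating PAVA) and the tried combination nearest φ is
selected as the MTDC.

## Worked example

Tabulate the shrinking boundaries for target φ = 0.3 (initial bracket
0.3 φ / 1.7 φ, t₁ = t₂ = 100):

```text
$ asboincomb boundaries --phi 0.3 --n-max 9
n,lambda_e,lambda_d,escalate_max_y,deescalate_min_y
1,0.178925,0.401976,0,1
2,0.180457,0.400964,0,1
3,0.181946,0.399972,0,2
...
6,0.186169,0.397112,1,3
9,0.190066,0.394416,1,4
```

Row n = 3 says: with 3 patients at the current combination, escalate on
0 DLTs, stay on 1, de-escalate on 2 or more.  As n grows the interval
(λ_e, λ_d) tightens around 0.3, so larger samples are judged more
strictly.

Replay one simulated trial of the packaged PF-03084014 + doxorubicin
example (3 doxorubicin × 2 PF levels, φ = 0.33, 30 patients, cohorts of
3, t₁ = 300, t₂ = 1):

```text
$ asboincomb replay --scenario pf_doxorubicin --phi 0.33 \
      --max-n 30 --t1 300 --t2 1 --seed 2
cohort 1: dose (1,1)  -> escalate
cohort 2: dose (1,2)  -> stay
...
cohort 7: dose (2,2)  -> stay
cohort 10: dose (2,2)  -> end
enrolled: 30  DLTs: 8
selected MTDC: (2, 2)
```

The trial escalates away from the safe lowest dose, settles on the
combination whose true DLT rate equals the 0.33 target, and selects it.
Simulating 1000 replicates (`asboincomb simulate --scenario
pf_doxorubicin --phi 0.33 --max-n 30 --t1 300 --t2 1 --reps 1000
--seed 0 --out report/`) shows (2, 2) is the modal selection.

Operating characteristics of a scenario, e.g. the extreme case where the
lowest combination is the only MTDC:

```text
$ asboincomb simulate --scenario s04 --phi 0.3 --reps 200 --seed 1 --out report/
{"pcs": 69.0, "pnmtdc": 77.0328, "ndlts": 18.08, "early_stop_pct": 19.5}
```

PCS is the percentage of replicates selecting a true MTDC, PNMTDC the
percentage of patients treated at a true MTDC, NDLTs the mean number of
DLTs per trial.  The report directory holds the config snapshot, OC JSON,
allocation/selection matrices and a per-cohort decision audit log.

The same functionality is available as a library
(`asboincomb.adaptive_boundaries`, `next_dose`, `select_mtdc`,
`simulate`, `tune_parameters`, ...); see the module docstrings and
`docs/methods.md`.

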