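"""Two-dimensional trial state and dose-transition logic.

Doses form a J x K grid (J levels of agent 1, K levels of agent 2);
toxicity is assumed monotone in each agent separately, so from the current
combination ``(j, k)`` only the one-step neighbours ``(j+1, k)``/``(j, k+1)``
are admissible escalations and ``(j-1, k)``/``(j, k-1)`` admissible
de-escalations.  The observed DLT fraction at the current combination is
compared against the boundary pair in force (see
:mod:`asboincomb.boundaries`); when a move is indicated, candidates are
ranked by the Jeffreys-posterior probability that their true DLT rate lies
inside the open interval ``(lambda_e, lambda_d)``, with exact ties broken
uniformly at random.  Grid-edge cases reduce to filtering candidates to
the grid: an empty candidate set keeps the current combination.

All indices are 0-based here; user-facing files are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.special import betainc, betaincc

from .boundaries import DesignParams, adaptive_boundaries

__all__ = [
    "TrialState",
    "Decision",
    "admissible_sets",
    "interval_probability",
    "posterior_toxic_prob",
    "next_dose",
    "safety_stop",
]

_TIE_TOL = 1e-12


@dataclass
class TrialState:
    """Per-combination enrollment/DLT counts plus the current position.

    ``n[j, k]`` and ``y[j, k]`` count patients treated and DLTs observed at
    combination ``(j, k)``; ``current`` is the combination the next cohort
    would receive.
    """

    J: int
    K: int
    n: np.ndarray
    y: np.ndarray
    current: tuple[int, int] = (0, 0)
    terminated_early: bool = False

    @classmethod
    def empty(cls, J: int, K: int) -> "TrialState":
        if J < 1 or K < 1:
            raise ValueError("grid dimensions must be positive")
        return cls(J=J, K=K, n=np.zeros((J, K), dtype=int), y=np.zeros((J, K), dtype=int))

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=int)
        self.y = np.asarray(self.y, dtype=int)
        if self.n.shape != (self.J, self.K) or self.y.shape != (self.J, self.K):
            raise ValueError("count matrices must have shape (J, K)")
        self.validate()

    def validate(self, max_n: int | None = None) -> None:
        if (self.n < 0).any() or (self.y < 0).any() or (self.y > self.n).any():
            raise ValueError("require 0 <= y[j,k] <= n[j,k] for all combinations")
        j, k = self.current
        if not (0 <= j < self.J and 0 <= k < self.K):
            raise ValueError(f"current dose {self.current} outside the {self.J}x{self.K} grid")
        if max_n is not None and self.enrolled > max_n:
            raise ValueError(f"enrolled {self.enrolled} exceeds max_n {max_n}")

    @property
    def enrolled(self) -> int:
        return int(self.n.sum())

    @property
    def total_dlts(self) -> int:
        return int(self.y.sum())

    def add_cohort(self, dose: tuple[int, int], outcomes: np.ndarray) -> None:
        """Record a fully observed cohort of binary DLT outcomes at ``dose``."""
        outcomes = np.asarray(outcomes)
        self.n[dose] += outcomes.size
        self.y[dose] += int(outcomes.sum())


@dataclass
class Decision:
    """A single dose-transition decision with its audit trail.

    ``action`` is the move actually taken ("escalate", "stay",
    "de-escalate" or "terminate"); ``rationale`` records the observed DLT
    fraction, the boundaries in force, the boundary verdict before edge
    handling, candidate scores, and any tie-break draw.
    """

    action: str
    next: tuple[int, int]
    rationale: dict[str, Any] = field(default_factory=dict)


def admissible_sets(
    current: tuple[int, int], J: int, K: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """In-grid escalation and de-escalation candidate sets at ``current``."""
    j, k = current
    if not (0 <= j < J and 0 <= k < K):
        raise ValueError(f"current dose {current} outside the {J}x{K} grid")
    a_e = [(jj, kk) for jj, kk in ((j + 1, k), (j, k + 1)) if jj < J and kk < K]
    a_d = [(jj, kk) for jj, kk in ((j - 1, k), (j, k - 1)) if jj >= 0 and kk >= 0]
    return a_e, a_d


def interval_probability(y: int, n: int, lambda_e: float, lambda_d: float) -> float:
    """Posterior probability that a DLT rate lies in ``(lambda_e, lambda_d)``.

    Under the Jeffreys prior Beta(0.5, 0.5) the posterior after ``y`` DLTs
    in ``n`` patients is Beta(0.5 + y, 0.5 + n - y); with ``n = 0`` this
    reduces to the prior measure of the interval.
    """
    if not 0 <= y <= n:
        raise ValueError(f"require 0 <= y <= n, got y={y}, n={n}")
    if not 0.0 <= lambda_e < lambda_d <= 1.0:
        raise ValueError(
            f"interval bounds out of order: ({lambda_e}, {lambda_d})"
        )
    a, b = 0.5 + y, 0.5 + n - y
    return float(betainc(a, b, lambda_d) - betainc(a, b, lambda_e))


def posterior_toxic_prob(y: int, n: int, phi: float) -> float:
    """``Pr(p > phi)`` under the Beta(0.5 + y, 0.5 + n - y) posterior."""
    return float(betaincc(0.5 + y, 0.5 + n - y, phi))


def _is_over_toxic(state: TrialState, params: DesignParams, dose: tuple[int, int]) -> bool:
    n = int(state.n[dose])
    if n < max(params.safety_min_n, 1):
        return False
    return posterior_toxic_prob(int(state.y[dose]), n, params.phi) > params.safety_prob_cutoff


def safety_stop(state: TrialState, params: DesignParams) -> bool:
    """Early-termination check at the lowest combination (0, 0).

    Returns True when at least ``safety_min_n`` patients have been treated
    there and the posterior probability that its DLT rate exceeds the
    target is above ``safety_prob_cutoff``.
    """
    n = int(state.n[0, 0])
    if n < params.safety_min_n or n == 0:
        return False
    return posterior_toxic_prob(int(state.y[0, 0]), n, params.phi) > params.safety_prob_cutoff


def next_dose(
    state: TrialState, params: DesignParams, rng: np.random.Generator | None = None
) -> Decision:
    """Dose-transition decision for the next cohort.

    The current combination must have at least one observed patient.  The
    boundary pair is evaluated at the per-dose cumulative count (or total
    enrollment, per ``params.boundary_n``); candidate moves are ranked by
    :func:`interval_probability`, by default with each candidate's own
    boundaries.  Exact score ties are broken uniformly at random with
    ``rng`` (deterministically toward the lexicographically smallest index
    when no generator is supplied).
    """
    j, k = state.current
    n_cur = int(state.n[j, k])
    y_cur = int(state.y[j, k])
    if n_cur < 1:
        raise ValueError("next_dose requires at least one observed patient at the current dose")

    n_index = n_cur if params.boundary_n == "dose" else state.enrolled
    bnd = adaptive_boundaries(params, n_index)
    p_hat = y_cur / n_cur

    a_e, a_d = admissible_sets((j, k), state.J, state.K)
    if p_hat <= bnd.lambda_e:
        verdict = "escalate"
        candidates = a_e
        if params.dose_elimination:
            candidates = [c for c in candidates if not _is_over_toxic(state, params, c)]
    elif p_hat >= bnd.lambda_d:
        verdict = "de-escalate"
        candidates = a_d
    else:
        verdict = "stay"
        candidates = []

    rationale: dict[str, Any] = {
        "p_hat": p_hat,
        "n": n_cur,
        "y": y_cur,
        "boundary_n": n_index,
        "lambda_e": bnd.lambda_e,
        "lambda_d": bnd.lambda_d,
        "verdict": verdict,
        "candidates": [],
        "tie_break": None,
    }

    if verdict == "stay" or not candidates:
        # No admissible move (grid corner/edge): the current dose is kept.
        action = "stay"
        chosen = (j, k)
    else:
        scored = []
        for cand in candidates:
            n_c = int(state.n[cand])
            y_c = int(state.y[cand])
            if params.candidate_boundary == "candidate":
                cb = adaptive_boundaries(params, max(n_c, 1))
            else:
                cb = bnd
            score = interval_probability(y_c, n_c, cb.lambda_e, cb.lambda_d)
            scored.append((cand, score))
        rationale["candidates"] = [
            {"dose": list(c), "n": int(state.n[c]), "y": int(state.y[c]), "score": s}
            for c, s in scored
        ]
        best = max(s for _, s in scored)
        ties = sorted(c for c, s in scored if s >= best - _TIE_TOL)
        if len(ties) == 1 or rng is None:
            chosen = ties[0]
        else:
            draw = int(rng.integers(len(ties)))
            chosen = ties[draw]
            rationale["tie_break"] = draw
        action = verdict

    return Decision(action=action, next=chosen, rationale=rationale)
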