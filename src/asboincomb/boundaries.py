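"""Closed-form escalation/de-escalation boundaries for interval designs.

A BOIN-type design steers a trial by comparing the observed DLT
(dose-limiting toxicity) fraction at the current dose, ``p_hat = y/n``,
against an escalation boundary ``lambda_e`` and a de-escalation boundary
``lambda_d``.  For a target DLT probability ``phi`` bracketed by a highest
sub-therapeutic rate ``phi1`` and a lowest over-toxic rate ``phi2``
(``phi1 < phi < phi2``), the decision-error-minimising boundaries have the
closed forms

    lambda_e = log((1 - phi1)/(1 - phi))
               / log(phi (1 - phi1) / (phi1 (1 - phi)))

    lambda_d = log((1 - phi)/(1 - phi2))
               / log(phi2 (1 - phi) / (phi (1 - phi2)))

The adaptively shrinking variant replaces the fixed bracket with one that
tightens as patients accumulate at the current dose.  Writing
``d1 = phi - phi1_init`` and ``d2 = phi2_init - phi`` for the initial
deviations, the bracket after ``n`` patients at the dose is

    phi1(n) = phi - d1 / ((n - 1)/t1 + 1)
    phi2(n) = phi + d2 / ((n - 1)/t2 + 1)

so that ``phi1(1) = phi1_init``, ``phi2(1) = phi2_init`` and both converge
to ``phi`` as ``n`` grows.  The acceleration factors ``t1, t2 > 0`` set the
shrink rate: larger ``t`` means slower shrinkage, and ``t -> inf`` freezes
the boundaries at their initial (fixed-design) values.  Choosing
``t1 > t2`` makes the de-escalation boundary shrink faster than the
escalation boundary, which penalises dosing above the target.

Because the boundaries depend only on ``n``, the complete escalate/stay/
de-escalate rule can be tabulated in advance; see :func:`decision_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

__all__ = [
    "DesignParams",
    "BoundaryPair",
    "boin_boundaries",
    "shrunk_phis",
    "adaptive_boundaries",
    "decision_table",
]


class BoundaryPair(NamedTuple):
    """An (escalation, de-escalation) boundary pair.

    ``n`` records the cumulative patient count the pair was evaluated at;
    it is ``None`` for a plain fixed-boundary computation.
    """

    lambda_e: float
    lambda_d: float
    n: int | None = None


@dataclass(frozen=True)
class DesignParams:
    """Design parameters for a (adaptively shrinking) interval combination trial.

    Parameters
    ----------
    phi
        Target DLT probability, in (0, 1).
    phi1_init
        Initial highest sub-therapeutic DLT probability, in (0, phi).
        Defaults to ``0.3 * phi``.
    phi2_init
        Initial lowest over-toxic DLT probability, in (phi, 1).
        Defaults to ``1.7 * phi``.
    t1, t2
        Acceleration factors controlling how fast the escalation and
        de-escalation boundaries shrink toward ``phi``; must be > 0
        (``math.inf`` is allowed and freezes the boundary).
    cohort_size
        Patients enrolled per cohort.
    max_n
        Maximum total sample size of the trial.
    safety_prob_cutoff
        Posterior probability threshold for the early-termination rule at
        the lowest combination: stop when
        ``Pr(p_{11} > phi | data) > safety_prob_cutoff``.
    safety_min_n
        Minimum number of patients at the lowest combination before the
        safety rule may trigger.
    adaptive
        ``True`` for shrinking boundaries, ``False`` for the fixed-boundary
        (classic combination) design.
    dose_elimination
        If ``True``, combinations whose own posterior satisfies the safety
        rule are excluded from the escalation candidate set.  Off by
        default: only lowest-dose termination is applied.
    candidate_boundary
        ``"candidate"`` evaluates the interval used to rank escalation /
        de-escalation candidates at each candidate's own cumulative count;
        ``"current"`` reuses the current dose's boundaries.
    boundary_n
        ``"dose"`` indexes the shrinkage by the per-dose cumulative count
        (the default, matching the tabulated boundaries); ``"total"``
        indexes it by total trial enrollment.
    """

    phi: float
    phi1_init: float | None = None
    phi2_init: float | None = None
    t1: float = 100.0
    t2: float = 100.0
    cohort_size: int = 3
    max_n: int = 60
    safety_prob_cutoff: float = 0.95
    safety_min_n: int = 3
    adaptive: bool = True
    dose_elimination: bool = False
    candidate_boundary: str = "candidate"
    boundary_n: str = "dose"

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise ValueError(f"phi must lie in (0, 1), got {self.phi}")
        if self.phi1_init is None:
            object.__setattr__(self, "phi1_init", 0.3 * self.phi)
        if self.phi2_init is None:
            object.__setattr__(self, "phi2_init", 1.7 * self.phi)
        if not 0.0 < self.phi1_init < self.phi:
            raise ValueError(
                f"phi1_init must lie in (0, phi): got phi1_init={self.phi1_init}, phi={self.phi}"
            )
        if not self.phi < self.phi2_init < 1.0:
            raise ValueError(
                f"phi2_init must lie in (phi, 1): got phi2_init={self.phi2_init}, phi={self.phi}"
            )
        if not (self.t1 > 0 and self.t2 > 0):
            raise ValueError(f"t1 and t2 must be positive, got t1={self.t1}, t2={self.t2}")
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be a positive integer")
        if self.max_n < 1:
            raise ValueError("max_n must be a positive integer")
        if not 0.0 < self.safety_prob_cutoff < 1.0:
            raise ValueError("safety_prob_cutoff must lie in (0, 1)")
        if self.safety_min_n < 0:
            raise ValueError("safety_min_n must be non-negative")
        if self.candidate_boundary not in ("candidate", "current"):
            raise ValueError("candidate_boundary must be 'candidate' or 'current'")
        if self.boundary_n not in ("dose", "total"):
            raise ValueError("boundary_n must be 'dose' or 'total'")

    @property
    def d1(self) -> float:
        """Initial deviation of the escalation bracket: ``phi - phi1_init``."""
        return self.phi - self.phi1_init

    @property
    def d2(self) -> float:
        """Initial deviation of the de-escalation bracket: ``phi2_init - phi``."""
        return self.phi2_init - self.phi


def boin_boundaries(phi: float, phi1: float, phi2: float) -> BoundaryPair:
    """Fixed escalation/de-escalation boundaries for target ``phi``.

    Parameters must satisfy ``0 < phi1 < phi < phi2 < 1``.  The returned
    pair satisfies ``phi1 < lambda_e < phi < lambda_d < phi2``.
    """
    if not (0.0 < phi1 < phi < phi2 < 1.0):
        raise ValueError(
            f"require 0 < phi1 < phi < phi2 < 1, got phi1={phi1}, phi={phi}, phi2={phi2}"
        )
    lambda_e = math.log((1 - phi1) / (1 - phi)) / math.log(
        phi * (1 - phi1) / (phi1 * (1 - phi))
    )
    lambda_d = math.log((1 - phi) / (1 - phi2)) / math.log(
        phi2 * (1 - phi) / (phi * (1 - phi2))
    )
    return BoundaryPair(lambda_e, lambda_d, None)


def shrunk_phis(params: DesignParams, n: int) -> tuple[float, float]:
    """Bracket probabilities after ``n`` patients at the current dose.

    ``phi1(n)`` increases and ``phi2(n)`` decreases strictly in ``n``
    (for finite ``t``), both converging to ``phi``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    f1 = (n - 1) / params.t1 + 1.0
    f2 = (n - 1) / params.t2 + 1.0
    return params.phi - params.d1 / f1, params.phi + params.d2 / f2


def adaptive_boundaries(params: DesignParams, n: int) -> BoundaryPair:
    """Boundary pair in force after ``n`` patients at the current dose.

    In adaptive mode the shrunk bracket is plugged into the closed-form
    boundary expressions; in fixed mode the initial bracket is used for
    every ``n``.
    """
    if params.adaptive:
        phi1_n, phi2_n = shrunk_phis(params, n)
    else:
        if n < 1:
            raise ValueError(f"n must be >= 1, got {n}")
        phi1_n, phi2_n = params.phi1_init, params.phi2_init
    pair = boin_boundaries(params.phi, phi1_n, phi2_n)
    return BoundaryPair(pair.lambda_e, pair.lambda_d, n)


def decision_table(params: DesignParams, n_max: int | None = None) -> pd.DataFrame:
    """Pre-tabulated escalate/stay/de-escalate rule for ``n = 1..n_max``.

    Per row: ``escalate_max_y`` is the largest DLT count with
    ``y/n <= lambda_e(n)`` and ``deescalate_min_y`` the smallest with
    ``y/n >= lambda_d(n)``; counts strictly between the two leave the dose
    unchanged.  The table is exactly equivalent to evaluating the rule on
    each ``(y, n)`` pair, so a trial can be run from the printed table
    alone.
    """
    if n_max is None:
        n_max = params.max_n
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    rows = []
    for n in range(1, n_max + 1):
        lam = adaptive_boundaries(params, n)
        esc = max(y for y in range(n + 1) if y / n <= lam.lambda_e)
        dee = min(y for y in range(n + 1) if y / n >= lam.lambda_d)
        rows.append(
            {
                "n": n,
                "lambda_e": lam.lambda_e,
                "lambda_d": lam.lambda_d,
                "escalate_max_y": esc,
                "deescalate_min_y": dee,
            }
        )
    table = pd.DataFrame(rows)
    table[["n", "escalate_max_y", "deescalate_min_y"]] = table[
        ["n", "escalate_max_y", "deescalate_min_y"]
    ].astype(int)
    return table
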