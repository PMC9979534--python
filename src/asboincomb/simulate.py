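"""Scenario-driven Monte-Carlo simulation of combination dose-finding trials.

A scenario is a J x K matrix of true DLT probabilities, monotone
non-decreasing in each agent, with the MTDC set being every cell whose
probability equals the target.  Each simulated trial starts at the lowest
combination, enrolls cohorts of exchangeable patients whose DLT outcomes
are independent Bernoulli draws at the assigned combination, applies the
lowest-dose safety stop and the dose-transition rule after each cohort,
and selects an MTDC when the sample size is exhausted.

Operating characteristics follow the usual definitions: PCS is the
percentage of replicates selecting a true MTDC, PNMTDC the percentage of
all treated patients allocated at a true MTDC, and NDLTs the mean number
of DLTs per trial.  Replicates use independent child streams spawned from
the master seed, so results are reproducible and extending the replicate
count leaves earlier replicates unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .boundaries import DesignParams
from .engine import Decision, TrialState, next_dose, safety_stop
from .selection import select_mtdc

__all__ = [
    "Scenario",
    "TrialResult",
    "OperatingCharacteristics",
    "run_trial",
    "simulate",
    "tune_parameters",
    "generate_scenario",
]

_MTDC_ATOL = 1e-9


@dataclass(frozen=True)
class Scenario:
    """True-toxicity scenario on a J x K combination grid.

    ``p_true[j, k]`` is the DLT probability at agent-1 level ``j`` and
    agent-2 level ``k`` (0-based); it must be non-decreasing along both
    axes.  ``mtdc_set`` holds every cell whose probability equals ``phi``
    (it may be empty when no combination sits exactly at the target).
    """

    p_true: np.ndarray
    phi: float
    name: str = ""
    mtdc_set: frozenset[tuple[int, int]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        p = np.asarray(self.p_true, dtype=float)
        if p.ndim != 2:
            raise ValueError("p_true must be a 2-D matrix")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("p_true entries must lie in [0, 1]")
        if (np.diff(p, axis=0) < -1e-12).any() or (np.diff(p, axis=1) < -1e-12).any():
            raise ValueError("p_true must be non-decreasing along each row and column")
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must lie in (0, 1)")
        p.setflags(write=False)
        object.__setattr__(self, "p_true", p)
        derived = frozenset(
            (int(j), int(k)) for j, k in np.argwhere(np.abs(p - self.phi) <= _MTDC_ATOL)
        )
        if self.mtdc_set is not None and frozenset(self.mtdc_set) != derived:
            raise ValueError(
                f"declared mtdc_set {sorted(self.mtdc_set)} is inconsistent with "
                f"p_true == phi cells {sorted(derived)}"
            )
        object.__setattr__(self, "mtdc_set", derived)

    @property
    def J(self) -> int:
        return self.p_true.shape[0]

    @property
    def K(self) -> int:
        return self.p_true.shape[1]


@dataclass
class TrialResult:
    """Outcome of a single simulated trial."""

    state: TrialState
    decisions: list[Decision]
    path: list[tuple[int, int]]
    selection: tuple[int, int] | None
    n_dlts: int


@dataclass
class OperatingCharacteristics:
    """Aggregated operating characteristics over simulation replicates.

    Percentages are on the 0-100 scale.  ``selection_pct`` sums with
    ``early_stop_pct`` (no selection) to 100; ``allocation_pct`` sums to
    100 over treated patients.
    """

    pcs: float
    pnmtdc: float
    ndlts: float
    selection_pct: np.ndarray
    allocation_pct: np.ndarray
    early_stop_pct: float
    n_reps: int
    mean_enrolled: float

    def to_dict(self, ndigits: int = 4) -> dict[str, Any]:
        return {
            "pcs": round(self.pcs, ndigits),
            "pnmtdc": round(self.pnmtdc, ndigits),
            "ndlts": round(self.ndlts, ndigits),
            "early_stop_pct": round(self.early_stop_pct, ndigits),
            "mean_enrolled": round(self.mean_enrolled, ndigits),
            "n_reps": self.n_reps,
            "selection_pct": np.round(self.selection_pct, ndigits).tolist(),
            "allocation_pct": np.round(self.allocation_pct, ndigits).tolist(),
        }


def run_trial(
    scenario: Scenario, params: DesignParams, rng: np.random.Generator
) -> TrialResult:
    """Simulate one complete trial under ``scenario``.

    The first cohort is treated at the lowest combination (1, 1).  After
    each fully observed cohort the safety stop is checked, then the
    transition rule sets the next cohort's combination.  The trial runs
    until ``max_n`` patients are enrolled or early termination; an
    early-terminated trial selects no MTDC.
    """
    state = TrialState.empty(scenario.J, scenario.K)
    decisions: list[Decision] = []
    path: list[tuple[int, int]] = []

    while True:
        dose = state.current
        path.append(dose)
        m = min(params.cohort_size, params.max_n - state.enrolled)
        outcomes = rng.random(m) < scenario.p_true[dose]
        state.add_cohort(dose, outcomes)

        if safety_stop(state, params):
            state.terminated_early = True
            decisions.append(
                Decision(action="terminate", next=dose, rationale={"reason": "safety_stop"})
            )
            break
        if state.enrolled >= params.max_n:
            break
        decision = next_dose(state, params, rng)
        decisions.append(decision)
        state.current = decision.next

    selection = select_mtdc(state, params, rng)
    return TrialResult(
        state=state,
        decisions=decisions,
        path=path,
        selection=selection,
        n_dlts=state.total_dlts,
    )


def simulate(
    scenario: Scenario,
    params: DesignParams,
    n_reps: int,
    seed: int | np.random.SeedSequence = 0,
    collect_decisions: bool = False,
) -> OperatingCharacteristics | tuple[OperatingCharacteristics, list[list[Decision]]]:
    """Monte-Carlo operating characteristics over ``n_reps`` replicates.

    Replicate ``i`` runs on the ``i``-th child stream of the master seed.
    With ``collect_decisions=True`` the per-cohort decision records of
    every replicate are returned alongside the aggregate (for audit logs).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    master = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    alloc = np.zeros((scenario.J, scenario.K))
    sel_counts = np.zeros((scenario.J, scenario.K))
    n_correct = 0
    n_early = 0
    total_dlts = 0
    total_enrolled = 0
    patients_at_mtdc = 0
    audit: list[list[Decision]] = []

    for child in master.spawn(n_reps):
        res = run_trial(scenario, params, np.random.default_rng(child))
        alloc += res.state.n
        total_dlts += res.n_dlts
        total_enrolled += res.state.enrolled
        for cell in scenario.mtdc_set:
            patients_at_mtdc += int(res.state.n[cell])
        if res.state.terminated_early:
            n_early += 1
        if res.selection is not None:
            sel_counts[res.selection] += 1
            if res.selection in scenario.mtdc_set:
                n_correct += 1
        if collect_decisions:
            audit.append(res.decisions)

    oc = OperatingCharacteristics(
        pcs=100.0 * n_correct / n_reps,
        pnmtdc=100.0 * patients_at_mtdc / total_enrolled,
        ndlts=total_dlts / n_reps,
        selection_pct=100.0 * sel_counts / n_reps,
        allocation_pct=100.0 * alloc / total_enrolled,
        early_stop_pct=100.0 * n_early / n_reps,
        n_reps=n_reps,
        mean_enrolled=total_enrolled / n_reps,
    )
    if collect_decisions:
        return oc, audit
    return oc


def tune_parameters(
    scenarios: Sequence[Scenario],
    param_grid: Iterable[Mapping[str, float]],
    base_params: DesignParams,
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank boundary/shrinkage settings by average operating characteristics.

    ``param_grid`` is a sequence of overrides for any of ``phi1_init``,
    ``phi2_init``, ``t1``, ``t2`` (and other design fields).  Each grid
    point is evaluated on every scenario with a seed derived from
    ``(seed, scenario index)`` only, so identical grid points yield
    identical results.  Ranking: mean PCS descending, ties by lower mean
    NDLTs.
    """
    grid = list(param_grid)
    if not grid:
        raise ValueError("param_grid must be non-empty")
    rows = []
    for gi, overrides in enumerate(grid):
        params = replace(base_params, **dict(overrides))
        pcs, pnmtdc, ndlts = [], [], []
        for si, scenario in enumerate(scenarios):
            oc = simulate(scenario, params, n_reps, seed=np.random.SeedSequence([seed, si]))
            pcs.append(oc.pcs)
            pnmtdc.append(oc.pnmtdc)
            ndlts.append(oc.ndlts)
        rows.append(
            {
                "grid_index": gi,
                **{k: v for k, v in overrides.items()},
                "mean_pcs": float(np.mean(pcs)),
                "mean_pnmtdc": float(np.mean(pnmtdc)),
                "mean_ndlts": float(np.mean(ndlts)),
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["mean_pcs", "mean_ndlts"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def generate_scenario(
    J: int,
    K: int,
    phi: float,
    rng: np.random.Generator,
    mtdc_position: tuple[int, int] | None = None,
    name: str = "synthetic",
) -> Scenario:
    """Random monotone scenario with the target rate at a chosen cell.

    Builds an additive surface of cumulative positive increments in each
    agent, then rescales it around ``phi`` at ``mtdc_position`` (0-based;
    defaults to the grid centre) while keeping all probabilities inside
    (0, 1).  The construction guarantees strictly increasing rows and
    columns, so the MTDC cell is unique.
    """
    if J < 1 or K < 1:
        raise ValueError("grid dimensions must be positive")
    if mtdc_position is None:
        mtdc_position = (J // 2, K // 2)
    jm, km = mtdc_position
    if not (0 <= jm < J and 0 <= km < K):
        raise ValueError(f"mtdc_position {mtdc_position} outside the {J}x{K} grid")
    if not 0.01 < phi < 0.97:
        raise ValueError("phi too extreme to embed a monotone scenario around it")

    a = np.concatenate([[0.0], np.cumsum(rng.uniform(0.2, 1.0, J - 1))])
    b = np.concatenate([[0.0], np.cumsum(rng.uniform(0.2, 1.0, K - 1))])
    surface = a[:, None] + b[None, :]
    surface -= surface[jm, km]

    up = surface.max()
    down = -surface.min()
    scale_limits = []
    if up > 0:
        scale_limits.append((0.97 - phi) / up)
    if down > 0:
        scale_limits.append((phi - 0.01) / down)
    scale = min(scale_limits) if scale_limits else 1.0
    if scale <= 0:
        raise ValueError(f"cannot place phi={phi} at {mtdc_position} on a {J}x{K} grid")
    p = phi + surface * scale
    return Scenario(p_true=p, phi=phi, name=name)
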