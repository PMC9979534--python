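"""End-of-trial MTDC selection via two-dimensional isotonic smoothing.

Raw Jeffreys posterior means of the per-combination DLT rates are not
guaranteed to respect the partial order of the dose grid (non-decreasing
toxicity in each agent), so before selection they are projected onto the
set of row- and column-monotone matrices by weighted least squares.  The
projection is computed by alternating pool-adjacent-violators (PAVA)
passes over the columns and rows until a fixed point.  The maximum
tolerated dose combination (MTDC) is the tried combination whose smoothed
estimate is closest to the target rate, with ties broken toward the larger
sample and then at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boundaries import DesignParams
from .engine import TrialState

__all__ = ["IsotonicFit", "posterior_means", "isotonic_2d", "select_mtdc"]

# Untried cells participate in the smoothing with negligible weight so that
# the monotone completion is defined everywhere without influencing tried
# cells; they are never eligible for selection.
_MISSING_WEIGHT = 1e-8


@dataclass
class IsotonicFit:
    """Result of the alternating-PAVA projection."""

    estimates: np.ndarray
    weights: np.ndarray
    converged: bool
    iterations: int


def posterior_means(state: TrialState) -> np.ndarray:
    """Jeffreys posterior mean DLT rate per combination, NaN where untried."""
    with np.errstate(invalid="ignore"):
        m = (state.y + 0.5) / (state.n + 1.0)
    return np.where(state.n > 0, m, np.nan)


def _pava(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted non-decreasing isotonic regression of a 1-D array (PAVA)."""
    # blocks: [weight sum, weighted value sum, length, raw value sum]
    blocks: list[list[float]] = []
    for v, w in zip(values, weights):
        blocks.append([w, w * v, 1, v])
        while len(blocks) > 1 and _block_mean(blocks[-2]) > _block_mean(blocks[-1]):
            w2, wv2, c2, v2 = blocks.pop()
            blocks[-1][0] += w2
            blocks[-1][1] += wv2
            blocks[-1][2] += c2
            blocks[-1][3] += v2
    out = np.empty(len(values))
    i = 0
    for blk in blocks:
        out[i : i + blk[2]] = _block_mean(blk)
        i += blk[2]
    return out


def _block_mean(blk: list[float]) -> float:
    # Zero-weight blocks fall back to the unweighted mean so the projection
    # stays defined when some cells carry no data.
    if blk[0] > 0:
        return blk[1] / blk[0]
    return blk[3] / blk[2]


def isotonic_2d(
    matrix: np.ndarray,
    weights: np.ndarray | None = None,
    tol: float = 1e-14,
    max_iter: int = 500,
) -> IsotonicFit:
    """Weighted projection onto row- and column-monotone matrices.

    Uses Dykstra's alternating-projection scheme: column-wise and row-wise
    PAVA passes with correction increments, which converges to the exact
    weighted least-squares projection onto the intersection of the two
    monotone cones (plain alternating PAVA only finds *some* monotone
    matrix).  Iteration stops when a full sweep changes the iterate by at
    most ``tol`` or after ``max_iter`` sweeps.  The result is
    non-decreasing along each row and column; on 1-D grids it is the exact
    PAVA solution; already-monotone input is returned unchanged and the
    projection is idempotent.
    """
    x = np.asarray(matrix, dtype=float).copy()
    if not np.isfinite(x).all():
        raise ValueError("matrix must be finite; impute untried cells before smoothing")
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape:
            raise ValueError("weights must match the matrix shape")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")

    p_inc = np.zeros_like(x)  # Dykstra corrections for each cone
    q_inc = np.zeros_like(x)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        prev = x.copy()
        z = x + p_inc
        y = z.copy()
        for k in range(y.shape[1]):  # monotone in agent 1 within each agent-2 level
            y[:, k] = _pava(z[:, k], w[:, k])
        p_inc = z - y
        z = y + q_inc
        x = z.copy()
        for j in range(x.shape[0]):  # monotone in agent 2 within each agent-1 level
            x[j, :] = _pava(z[j, :], w[j, :])
        q_inc = z - x
        if np.max(np.abs(x - prev)) <= tol:
            converged = True
            break
    return IsotonicFit(estimates=x, weights=w, converged=converged, iterations=iterations)


def select_mtdc(
    state: TrialState,
    params: DesignParams,
    rng: np.random.Generator | None = None,
) -> tuple[int, int] | None:
    """Select the MTDC at the end of a trial, or None.

    Returns None when the trial terminated early for safety or no
    combination was ever tried.  Otherwise the tried combination whose
    isotonically smoothed posterior mean is nearest the target ``phi`` is
    selected; ties go to the larger sample size, then uniformly at random.
    """
    if state.terminated_early:
        return None
    tried = state.n > 0
    if not tried.any():
        return None

    raw = posterior_means(state)
    fill = float(np.nanmean(raw))
    values = np.where(tried, raw, fill)
    weights = np.where(tried, state.n + 1.0, _MISSING_WEIGHT)
    fit = isotonic_2d(values, weights)

    dist = np.abs(fit.estimates - params.phi)
    cells = [(int(a), int(b)) for a, b in np.argwhere(tried)]
    best = min(dist[c] for c in cells)
    nearest = [c for c in cells if dist[c] <= best + 1e-12]
    max_n = max(state.n[c] for c in nearest)
    pool = sorted(c for c in nearest if state.n[c] == max_n)
    if len(pool) == 1 or rng is None:
        return pool[0]
    return pool[int(rng.integers(len(pool)))]
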