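"""Run configuration and report I/O.

A run configuration is a flat YAML or JSON mapping: design-parameter keys
(``phi``, ``phi1_init``, ``phi2_init``, ``t1``, ``t2``, ``cohort_size``,
``max_n``, ``safety_prob_cutoff``, ``safety_min_n``, ``adaptive``,
``dose_elimination``, ``candidate_boundary``, ``boundary_n``) plus run
keys (``scenario``, ``n_reps``, ``seed``, ``outdir``).  Unknown keys are
rejected so typos fail loudly, and all design invariants are enforced at
load time.  Configurations round-trip losslessly through disk, and every
report directory contains the config snapshot that produced it.

Matrix files written here follow the package convention: rows = agent-2
levels (level 1 at the top), columns = agent-1 levels; user-facing indices
are 1-based.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .boundaries import DesignParams
from .engine import Decision, TrialState
from .simulate import OperatingCharacteristics

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "load_state",
    "save_state",
    "write_report",
]

_DESIGN_KEYS = {f.name for f in dataclasses.fields(DesignParams)}
_RUN_KEYS = {"scenario", "n_reps", "seed", "outdir"}


@dataclass(frozen=True)
class RunConfig:
    """A validated simulation-run configuration."""

    design: DesignParams
    scenario: str | None = None
    n_reps: int = 1000
    seed: int = 0
    outdir: str | None = None

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self.design)
        out.update(
            {"scenario": self.scenario, "n_reps": self.n_reps, "seed": self.seed,
             "outdir": self.outdir}
        )
        return out


def config_from_mapping(raw: dict[str, Any]) -> RunConfig:
    unknown = set(raw) - _DESIGN_KEYS - _RUN_KEYS
    if unknown:
        raise ValueError(
            f"unknown configuration keys: {sorted(unknown)} "
            f"(known: {sorted(_DESIGN_KEYS | _RUN_KEYS)})"
        )
    if "phi" not in raw:
        raise ValueError("configuration must set the target DLT probability 'phi'")
    design = DesignParams(**{k: v for k, v in raw.items() if k in _DESIGN_KEYS})
    n_reps = int(raw.get("n_reps", 1000))
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    return RunConfig(
        design=design,
        scenario=raw.get("scenario"),
        n_reps=n_reps,
        seed=int(raw.get("seed", 0)),
        outdir=raw.get("outdir"),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return config_from_mapping(raw)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return path


def load_state(path: str | Path) -> TrialState:
    """Read an observed trial state from JSON.

    Expected keys: ``J``, ``K``, ``n``, ``y`` (matrices with rows =
    agent-2 levels, columns = agent-1 levels), ``current`` (1-based
    ``[agent-1 level, agent-2 level]``), optional ``terminated_early``.
    """
    raw = json.loads(Path(path).read_text())
    J, K = int(raw["J"]), int(raw["K"])
    n = np.asarray(raw["n"], dtype=int).T  # file rows are agent-2 levels
    y = np.asarray(raw["y"], dtype=int).T
    cj, ck = raw.get("current", [1, 1])
    return TrialState(
        J=J, K=K, n=n, y=y,
        current=(int(cj) - 1, int(ck) - 1),
        terminated_early=bool(raw.get("terminated_early", False)),
    )


def save_state(state: TrialState, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "J": state.J,
        "K": state.K,
        "n": state.n.T.tolist(),
        "y": state.y.T.tolist(),
        "current": [state.current[0] + 1, state.current[1] + 1],
        "terminated_early": state.terminated_early,
    }
    path.write_text(json.dumps(payload, indent=1) + "\n")
    return path


def _write_matrix_csv(matrix: np.ndarray, path: Path, title: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {title}\n")
        fh.write(
            f"# rows = agent-2 levels 1..{matrix.shape[1]} (top to bottom), "
            f"columns = agent-1 levels 1..{matrix.shape[0]}\n"
        )
        for k in range(matrix.shape[1]):
            fh.write(",".join(f"{matrix[j, k]:.4f}" for j in range(matrix.shape[0])) + "\n")


def _decision_record(rep: int, cohort: int, decision: Decision) -> dict[str, Any]:
    rationale = dict(decision.rationale)
    if "candidates" in rationale:
        rationale["candidates"] = [
            {**c, "dose": [c["dose"][0] + 1, c["dose"][1] + 1]}
            for c in rationale["candidates"]
        ]
    return {
        "rep": rep,
        "cohort": cohort,
        "action": decision.action,
        "next": [decision.next[0] + 1, decision.next[1] + 1],
        **rationale,
    }


def write_report(
    oc: OperatingCharacteristics,
    config: RunConfig,
    outdir: str | Path,
    decisions: list[list[Decision]] | None = None,
) -> Path:
    """Write a simulation report directory.

    Contents: ``config.yaml`` (snapshot), ``oc.json`` (operating
    characteristics, floats rounded to 4 d.p.), ``allocation.csv`` and
    ``selection.csv`` (percentage matrices), and ``decisions.jsonl`` (one
    line per cohort decision across the audited replicates).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(config, outdir / "config.yaml")
    with open(outdir / "oc.json", "w") as fh:
        json.dump(oc.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    _write_matrix_csv(oc.allocation_pct, outdir / "allocation.csv",
                      "percentage of treated patients per combination")
    _write_matrix_csv(oc.selection_pct, outdir / "selection.csv",
                      "percentage of replicates selecting each combination as MTDC")
    with open(outdir / "decisions.jsonl", "w") as fh:
        for rep, trial in enumerate(decisions or []):
            for cohort, decision in enumerate(trial):
                fh.write(json.dumps(_decision_record(rep, cohort, decision)) + "\n")
    return outdir
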