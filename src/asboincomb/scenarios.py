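"""Built-in and on-disk scenario handling.

Scenario files are a plain CSV matrix plus a JSON sidecar.  The CSV holds
the true DLT probabilities with rows = agent-2 levels (level 1 at the top)
and columns = agent-1 levels, matching the conventional presentation of
combination-trial scenario tables; lines starting with ``#`` are comments.
The sidecar (same stem, ``.json``) records the target rate ``phi``, a
name, agent labels and the 1-based MTDC cells.

The packaged fixtures comprise ten realistic 5x3 two-agent scenarios with
target rate 0.3 (``s01`` .. ``s10``) and the 3x2
PF-03084014 + doxorubicin trial-example matrix with target rate 0.33
(``pf_doxorubicin``).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np

from .simulate import Scenario

__all__ = ["list_builtin", "load_scenario", "save_scenario"]

_DATA = resources.files("asboincomb") / "data" / "scenarios"


def list_builtin() -> list[str]:
    """Names of the packaged scenario fixtures."""
    return sorted(p.name[: -len(".json")] for p in _DATA.iterdir() if p.name.endswith(".json"))


def load_scenario(source: str | Path) -> Scenario:
    """Load a scenario from a CSV path or a built-in fixture name.

    A ``source`` naming an existing ``.csv`` file (or its stem) is read
    from disk together with its JSON sidecar; otherwise it is looked up
    among the built-in fixtures.
    """
    path = Path(source)
    if path.suffix == "" and not path.exists():
        candidate = path.with_suffix(".csv")
        if candidate.exists():
            path = candidate
    if path.exists():
        csv_text = path.read_text()
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    else:
        name = str(source)
        csv_res = _DATA / f"{name}.csv"
        try:
            csv_text = csv_res.read_text()
        except FileNotFoundError:
            raise FileNotFoundError(
                f"scenario {source!r} is neither a file nor a built-in "
                f"fixture (available: {', '.join(list_builtin())})"
            ) from None
        meta = json.loads((_DATA / f"{name}.json").read_text())

    rows = [
        [float(v) for v in line.split(",")]
        for line in csv_text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    # file rows are agent-2 levels; internally p_true is indexed [agent1, agent2]
    p = np.asarray(rows, dtype=float).T
    mtdc = meta.get("mtdc")
    declared = (
        frozenset((j - 1, k - 1) for j, k in mtdc) if mtdc is not None else None
    )
    return Scenario(
        p_true=p,
        phi=float(meta.get("phi", 0.3)),
        name=str(meta.get("name", Path(str(source)).stem)),
        mtdc_set=declared,
    )


def save_scenario(scenario: Scenario, csv_path: str | Path) -> Path:
    """Write a scenario as CSV + JSON sidecar; returns the CSV path."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    with open(csv_path, "w") as fh:
        fh.write(f"# {scenario.name}: true DLT probabilities\n")
        fh.write(
            f"# rows = agent-2 levels 1..{scenario.K} (top to bottom), "
            f"columns = agent-1 levels 1..{scenario.J}\n"
        )
        for k in range(scenario.K):
            fh.write(",".join(f"{scenario.p_true[j, k]:g}" for j in range(scenario.J)) + "\n")
    meta = {
        "name": scenario.name,
        "phi": scenario.phi,
        "mtdc": sorted([j + 1, k + 1] for j, k in scenario.mtdc_set),
    }
    with open(csv_path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")
    return csv_path
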