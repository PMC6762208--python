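"""Trajectory and battery-report serialization.

Trajectories go to CSV with full-precision (repr-faithful) numbers so a
round trip reproduces every value bit-identically; battery reports go to
JSON with a stable key order.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .effects import BatteryReport, EffectResult
from .runner import Trajectory

__all__ = ["write_trajectory", "read_trajectory", "write_report", "read_report"]


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write one condition's trajectory as CSV (header always present)."""
    trajectory.frame.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV back into a :class:`Trajectory`."""
    frame = pd.read_csv(path)
    cues = tuple(
        col[len("strength_") :] for col in frame.columns if col.startswith("strength_")
    )
    condition = str(frame["condition"].iloc[0]) if len(frame) else ""
    return Trajectory(frame=frame, condition=condition, cue_universe=cues)


def write_report(report: BatteryReport, path: str | Path) -> None:
    """Write a battery report as JSON: model label plus ordered results."""
    doc = {
        "model": report.model,
        "results": [
            {
                "id": r.experiment,
                "passed": bool(r.passed),
                "statistic": float(r.statistic),
                "margin": float(r.margin),
            }
            for r in report.results
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_report(path: str | Path) -> BatteryReport:
    """Read a battery-report JSON back into a :class:`BatteryReport`."""
    doc = json.loads(Path(path).read_text())
    results = tuple(
        EffectResult(
            experiment=r["id"],
            passed=bool(r["passed"]),
            statistic=float(r["statistic"]),
            margin=float(r["margin"]),
        )
        for r in doc["results"]
    )
    return BatteryReport(model=doc["model"], results=results)
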