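"""Directional effect checks and the experiment battery.

Each classical experiment has an associated signed statistic computed
from the trajectories of its conditions; the effect is reproduced when
the statistic strictly exceeds a decision margin (default 0.01 on the
reward scale).  The statistics operate on reported associative strengths
(the expected reward for a cue presented alone) except for the renewal
checks, which use the marginal reward prediction so that context
contributions are included for models that encode context as a cue.

The battery runs every experiment for one model and returns one result
per experiment, plus a supplementary context-shift statistic for the
renewal design (whether extinction in a different context strengthens
the return of responding).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .params import ModelParams, RWParams
from .runner import Trajectory, run_schedule
from .schedules import EXPERIMENT_IDS, build_schedule

__all__ = [
    "EffectResult",
    "BatteryReport",
    "check_effect",
    "run_battery",
    "CHECK_IDS",
    "DEFAULT_MARGIN",
]

DEFAULT_MARGIN = 0.01

#: All check identifiers: the experiments plus the renewal context-shift
#: supplement.
CHECK_IDS: tuple[str, ...] = EXPERIMENT_IDS + ("renewal_context_shift",)


@dataclass(frozen=True)
class EffectResult:
    """Outcome of one directional check: reproduced iff statistic > margin."""

    experiment: str
    passed: bool
    statistic: float
    margin: float


@dataclass(frozen=True)
class BatteryReport:
    """Ordered effect results for one model over the whole battery."""

    model: str
    results: tuple[EffectResult, ...]

    def __post_init__(self) -> None:
        ids = [r.experiment for r in self.results]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate experiment ids in battery report")

    @property
    def passed_ids(self) -> tuple[str, ...]:
        return tuple(r.experiment for r in self.results if r.passed)

    def result(self, experiment: str) -> EffectResult:
        for r in self.results:
            if r.experiment == experiment:
                return r
        raise KeyError(f"no result for experiment {experiment!r}")


def _require(trajectories: Mapping[str, Trajectory], *names: str) -> list[Trajectory]:
    out = []
    for name in names:
        if name not in trajectories:
            raise KeyError(f"missing condition {name!r}; have {sorted(trajectories)!r}")
        out.append(trajectories[name])
    return out


def _end_of_stage(traj: Trajectory, cue: str, stage: int) -> float:
    return float(traj.stage_frame(stage)[f"strength_{cue}"].iloc[-1])


def _stage_mean(traj: Trajectory, cue: str, stage: int) -> float:
    return float(traj.stage_frame(stage)[f"strength_{cue}"].mean())


def _first_k_prediction_mean(traj: Trajectory, stage: int, k: int) -> float:
    return float(traj.stage_frame(stage)["prediction"].head(k).mean())


def _renewal_rapid_return(traj: Trajectory, k: int = 3) -> float:
    """Mean prediction over the first reacquisition trials minus the same
    average at the start of acquisition."""
    return _first_k_prediction_mean(traj, stage=2, k=k) - _first_k_prediction_mean(
        traj, stage=0, k=k
    )


def check_effect(
    id: str, trajectories: Mapping[str, Trajectory], margin: float = DEFAULT_MARGIN
) -> EffectResult:
    """Compute the signed statistic for one experiment and compare to the margin.

    ``trajectories`` maps condition names (as produced by
    :func:`~lslearn.schedules.build_schedule`) to their runs.
    """
    if id in ("blocking",):
        (t,) = _require(trajectories, "main")
        stat = _end_of_stage(t, "A", 1) - _end_of_stage(t, "B", 1)
    elif id == "overexpectation":
        (t,) = _require(trajectories, "main")
        stat = _end_of_stage(t, "A", 0) - _end_of_stage(t, "A", 1)
    elif id == "conditioned_inhibition":
        (t,) = _require(trajectories, "main")
        stat = min(_end_of_stage(t, "A", 0), -_end_of_stage(t, "B", 0))
    elif id == "wilson1992":
        group_c, group_e = _require(trajectories, "C", "E")
        stat = _stage_mean(group_e, "A", 2) - _stage_mean(group_c, "A", 2)
    elif id == "rescorla2000_1A":
        (t,) = _require(trajectories, "main")
        gain_b = _end_of_stage(t, "B", 1) - _end_of_stage(t, "B", 0)
        gain_a = _end_of_stage(t, "A", 1) - _end_of_stage(t, "A", 0)
        stat = gain_b - gain_a
    elif id == "rescorla2000_1B":
        (t,) = _require(trajectories, "main")
        drop_a = abs(_end_of_stage(t, "A", 1) - _end_of_stage(t, "A", 0))
        drop_b = abs(_end_of_stage(t, "B", 1) - _end_of_stage(t, "B", 0))
        stat = drop_a - drop_b
    elif id in ("partial_reinforcement_1", "partial_reinforcement_2"):
        partial, continuous = _require(trajectories, "partial", "continuous")
        extinction_stage = 1 if id == "partial_reinforcement_1" else 2
        stat = _stage_mean(partial, "A", extinction_stage) - _stage_mean(
            continuous, "A", extinction_stage
        )
    elif id == "backwards_blocking":
        (t,) = _require(trajectories, "main")
        stat = _end_of_stage(t, "X", 0) - _end_of_stage(t, "X", 1)
    elif id == "renewal":
        same, shift = _require(trajectories, "same", "shift")
        stat = min(_renewal_rapid_return(same), _renewal_rapid_return(shift))
    elif id == "renewal_context_shift":
        same, shift = _require(trajectories, "same", "shift")
        stat = _first_k_prediction_mean(shift, stage=2, k=3) - _first_k_prediction_mean(
            same, stage=2, k=3
        )
    elif id == "spontaneous_recovery":
        delay, control = _require(trajectories, "delay", "no_delay")
        stat = float(delay.stage_frame(2)["strength_A"].iloc[0]) - float(
            control.stage_frame(2)["strength_A"].iloc[0]
        )
    elif id == "memory_modification":
        runs = _require(trajectories, "delay_1", "delay_5", "delay_100")
        # test readout: strength after the post-extinction delay, i.e. the
        # last extinction row (recorded post-event), per condition
        s1, s5, s100 = (float(t.stage_frame(2)["strength_A"].iloc[-1]) for t in runs)
        stat = min(s1, s100) - s5
    else:
        raise ValueError(f"unknown effect id {id!r}; valid ids: {', '.join(CHECK_IDS)}")
    return EffectResult(experiment=id, passed=stat > margin, statistic=stat, margin=margin)


def run_battery(
    model: str = "latent_state",
    params: ModelParams | RWParams | None = None,
    margin: float = DEFAULT_MARGIN,
    seed: int = 0,
    shuffle: bool = False,
) -> BatteryReport:
    """Build, run and check every experiment for one model."""
    if model not in ("latent_state", "rescorla_wagner"):
        raise ValueError(f"unknown model {model!r}")
    results: list[EffectResult] = []
    for exp_id in EXPERIMENT_IDS:
        exp = build_schedule(exp_id, seed=seed, shuffle=shuffle)
        trajectories = {
            name: run_schedule(sched, model=model, params=params)
            for name, sched in exp.conditions.items()
        }
        results.append(check_effect(exp_id, trajectories, margin=margin))
        if exp_id == "renewal":
            results.append(check_effect("renewal_context_shift", trajectories, margin=margin))
    return BatteryReport(model=model, results=tuple(results))
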