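"""Run a schedule through a model and record a per-trial trajectory.

The trajectory is the model-agnostic table the effect checks consume: one
row per trial with the reported associative strength of every raw cue,
the within-trial marginal reward prediction, padded per-state beliefs,
the number of latent states, the pooled variance, the change statistic
and a spawn flag.  Strengths and beliefs are recorded at the end of the
trial (after any between-trial context event), so a post-phase delay is
visible on the row of the trial that carries it.
"""

from __future__ import annotations

from dataclasses import dataclass

import logging

import numpy as np
import pandas as pd

from .features import FeatureVector, expand_cues, feature_names
from .learner import (
    LearnerState,
    center_reward,
    report_associative_strength,
    step_trial,
)
from .params import ModelParams, RWParams
from .rw import RWState, rw_step
from .schedules import Schedule

__all__ = ["Trajectory", "run_schedule", "rw_run"]

logger = logging.getLogger(__name__)

MODEL_LABELS = ("latent_state", "rescorla_wagner")


@dataclass(frozen=True)
class Trajectory:
    """Per-trial record of a model run over one condition.

    ``frame`` columns: ``trial``, ``condition``, ``stage``, one
    ``strength_<cue>`` column per raw cue, ``prediction``,
    ``belief_1 .. belief_<max>`` (padded with NaN), ``n_states``,
    ``sigma2``, ``q`` and ``state_added``.
    """

    frame: pd.DataFrame
    condition: str
    cue_universe: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.frame)

    def strength(self, cue: str) -> pd.Series:
        col = f"strength_{cue}"
        if col not in self.frame.columns:
            raise KeyError(f"no strength column for cue {cue!r}")
        return self.frame[col]

    @property
    def prediction(self) -> pd.Series:
        return self.frame["prediction"]

    def stage_frame(self, stage: int) -> pd.DataFrame:
        sub = self.frame[self.frame["stage"] == stage]
        if sub.empty:
            raise ValueError(f"stage {stage} is empty in condition {self.condition!r}")
        return sub


def _columns(cue_universe: tuple[str, ...], max_beliefs: int) -> list[str]:
    return (
        ["trial", "condition", "stage"]
        + [f"strength_{cue}" for cue in cue_universe]
        + ["prediction"]
        + [f"belief_{i + 1}" for i in range(max_beliefs)]
        + ["n_states", "sigma2", "q", "state_added"]
    )


def run_schedule(
    schedule: Schedule,
    model: str = "latent_state",
    params: ModelParams | RWParams | None = None,
    context_as_cue: bool = True,
) -> Trajectory:
    """Feed a schedule through a model, trial by trial.

    ``model`` is ``"latent_state"`` or ``"rescorla_wagner"``.  For the
    Rescorla-Wagner comparator, rewards are uncentered (1/0), interaction
    features are off, temporal events are no-ops and -- when
    ``context_as_cue`` is set and the schedule carries context labels --
    each distinct spatial context contributes an always-on indicator cue.
    """
    if model == "latent_state":
        if params is None:
            params = ModelParams()
        if not isinstance(params, ModelParams):
            raise TypeError("latent_state model requires ModelParams")
        return _run_latent(schedule, params)
    if model == "rescorla_wagner":
        if params is None:
            params = RWParams()
        if not isinstance(params, RWParams):
            raise TypeError("rescorla_wagner model requires RWParams")
        return _run_rw(schedule, params, context_as_cue)
    raise ValueError(f"unknown model {model!r}; valid labels: {', '.join(MODEL_LABELS)}")


def _run_latent(schedule: Schedule, params: ModelParams) -> Trajectory:
    universe = schedule.cue_universe
    dim = len(feature_names(universe, params.include_interactions))
    state = LearnerState.initial(dim, params)
    template = expand_cues([], universe, params.include_interactions)
    rows = []
    for t, trial in enumerate(schedule.trials):
        cues = expand_cues(trial.cues, universe, params.include_interactions)
        reward = center_reward(trial.reinforced, params.center_rewards)
        out = step_trial(state, cues, reward, trial.post_event, params)
        if out.state_added:
            logger.info(
                "condition %s trial %d: spawned latent state %d (q=%.4f)",
                schedule.label,
                t,
                out.new_state_index,
                out.candidate_q,
            )
        beliefs = np.full(params.max_states, np.nan)
        beliefs[: state.n_states] = state.beliefs
        rows.append(
            [t, schedule.label, trial.stage]
            + [report_associative_strength(state, template, cue) for cue in universe]
            + [out.marginal_prediction]
            + list(beliefs)
            + [state.n_states, state.variance, state.change_stat, out.state_added]
        )
    frame = pd.DataFrame(rows, columns=_columns(universe, params.max_states))
    return Trajectory(frame=frame, condition=schedule.label, cue_universe=universe)


def _run_rw(schedule: Schedule, params: RWParams, context_as_cue: bool) -> Trajectory:
    universe = schedule.cue_universe
    context_cues: tuple[str, ...] = ()
    if context_as_cue and schedule.context_labels is not None:
        seen: list[str] = []
        for label in schedule.context_labels:
            if label not in seen:
                seen.append(label)
        context_cues = tuple(f"ctx_{label}" for label in seen)
    full_universe = universe + context_cues
    state = RWState.initial(len(full_universe))
    rows = []
    for t, trial in enumerate(schedule.trials):
        present = set(trial.cues)
        if context_cues:
            present.add(f"ctx_{schedule.context_labels[t]}")
        cues = expand_cues(present, full_universe, include_interactions=False)
        reward = center_reward(trial.reinforced, center_rewards=False)
        prediction = float(cues.values @ state.strengths)
        rw_step(state, cues, reward, params)
        beliefs = np.full(1, 1.0)
        rows.append(
            [t, schedule.label, trial.stage]
            + [float(state.strengths[i]) for i in range(len(universe))]
            + [prediction]
            + list(beliefs)
            + [1, np.nan, np.nan, False]
        )
    frame = pd.DataFrame(rows, columns=_columns(universe, 1))
    return Trajectory(frame=frame, condition=schedule.label, cue_universe=universe)


def rw_run(
    schedule: Schedule, params: RWParams | None = None, context_as_cue: bool = True
) -> Trajectory:
    """Rescorla-Wagner run over a schedule (see :func:`run_schedule`)."""
    return run_schedule(
        schedule, model="rescorla_wagner", params=params or RWParams(), context_as_cue=context_as_cue
    )
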