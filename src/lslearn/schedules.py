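"""Trial schedules for the classical-conditioning experiment battery.

Each experiment is a set of named conditions; each condition is an ordered
sequence of trials (cue set, reinforcement flag, optional post-trial
context event) partitioned into stages.  The builders below realize the
canonical designs of eleven classical experiments:

====================== =====================================================
blocking               A+ then AB+: prior conditioning of A blocks B.
overexpectation        A+ and B+ separately, then AB+ with a single reward.
conditioned_inhibition A+ interleaved with non-reinforced AB compounds.
wilson1992             Alternating AB+/AB- with the tone (B) omitted on
                       middle-stage non-reinforced trials for Group E,
                       then light (A) alone reinforced (Hall-Pearce style
                       associability effect).
rescorla2000_1A        A+/B- pretraining then AB+ (B gains more than A).
rescorla2000_1B        A+/B- pretraining then AB- (A loses more than B).
partial_reinforcement_1  Partial (alternating A+/A-) vs continuous (A+)
                       reinforcement followed by extinction (PREE).
partial_reinforcement_2  As above with an interposed continuous block.
backwards_blocking     AX+ then A+ (X loses strength while absent).
renewal                A+ / A- / A+ with extinction either in the same
                       spatial context or in a different one.
spontaneous_recovery   A+ / A- / A+ with a long inter-phase delay before
                       reacquisition, vs an ITI = 1 control.
memory_modification    Monfils-Schiller: acquisition, a single retrieval
                       trial, a delay of 1/5/100 steps, extinction, a long
                       delay, then test trials.
====================== =====================================================

Alternation within a stage is strict and deterministic by default so that
the whole battery is reproducible; a seeded shuffled variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .learner import ContextEvent

__all__ = ["TrialSpec", "Schedule", "ExperimentDef", "EXPERIMENT_IDS", "build_schedule"]

NO_EVENT = ContextEvent("none")

#: Canonical experiment identifiers, in battery order.
EXPERIMENT_IDS: tuple[str, ...] = (
    "blocking",
    "overexpectation",
    "conditioned_inhibition",
    "wilson1992",
    "rescorla2000_1A",
    "rescorla2000_1B",
    "partial_reinforcement_1",
    "partial_reinforcement_2",
    "backwards_blocking",
    "renewal",
    "spontaneous_recovery",
    "memory_modification",
)


@dataclass(frozen=True)
class TrialSpec:
    """One trial: which raw cues are present, whether reward follows, and
    any context event occurring after the trial."""

    cues: frozenset[str]
    reinforced: bool
    post_event: ContextEvent = NO_EVENT
    stage: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cues", frozenset(self.cues))
        if not self.cues:
            raise ValueError("a trial must present at least one cue")


@dataclass(frozen=True)
class Schedule:
    """One experimental condition: an ordered trial list over a cue universe.

    ``context_labels`` tags each trial with a spatial-context label; the
    Rescorla-Wagner comparator encodes each distinct label as an
    always-on indicator cue (the latent-state learner instead receives
    the spatial events carried by the trials themselves).
    """

    label: str
    trials: tuple[TrialSpec, ...]
    cue_universe: tuple[str, ...]
    context_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        object.__setattr__(self, "cue_universe", tuple(self.cue_universe))
        universe = set(self.cue_universe)
        for t in self.trials:
            if not t.cues <= universe:
                raise ValueError(
                    f"trial cues {sorted(t.cues)} not within universe {self.cue_universe}"
                )
        if self.context_labels is not None:
            object.__setattr__(self, "context_labels", tuple(self.context_labels))
            if len(self.context_labels) != len(self.trials):
                raise ValueError("context_labels must have one entry per trial")

    def __len__(self) -> int:
        return len(self.trials)

    def stage_slice(self, stage: int) -> slice:
        """Row slice of the given stage within the trial sequence."""
        idx = [i for i, t in enumerate(self.trials) if t.stage == stage]
        if not idx:
            raise ValueError(f"stage {stage} is empty in schedule {self.label!r}")
        return slice(idx[0], idx[-1] + 1)


@dataclass(frozen=True)
class ExperimentDef:
    """A named experiment: its conditions and the stage lengths used."""

    id: str
    conditions: Mapping[str, Schedule]
    stage_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        universes = {s.cue_universe for s in self.conditions.values()}
        if len(universes) != 1:
            raise ValueError("all conditions of an experiment must share one cue universe")


def _interleave(
    blocks: Sequence[tuple[frozenset[str], bool]],
    n_each: int,
    stage: int,
    rng: np.random.Generator | None,
) -> list[TrialSpec]:
    """n_each repetitions of each trial type, strictly alternated (or
    shuffled when an rng is supplied)."""
    order: list[int] = []
    for _ in range(n_each):
        order.extend(range(len(blocks)))
    if rng is not None:
        order = list(rng.permutation(order))
    return [TrialSpec(cues=blocks[i][0], reinforced=blocks[i][1], stage=stage) for i in order]


def _repeat(cues: Iterable[str], reinforced: bool, n: int, stage: int) -> list[TrialSpec]:
    cue_set = frozenset(cues)
    return [TrialSpec(cues=cue_set, reinforced=reinforced, stage=stage) for _ in range(n)]


def _with_final_event(trials: list[TrialSpec], event: ContextEvent) -> list[TrialSpec]:
    """Attach a context event to the last trial of a block."""
    if not trials:
        return trials
    last = trials[-1]
    trials[-1] = TrialSpec(
        cues=last.cues, reinforced=last.reinforced, post_event=event, stage=last.stage
    )
    return trials


def _resolve_lengths(
    defaults: Sequence[int], overrides: Mapping[int, int] | Sequence[int] | None
) -> tuple[int, ...]:
    lengths = list(defaults)
    if overrides is None:
        return tuple(lengths)
    if isinstance(overrides, Mapping):
        for k, v in overrides.items():
            if not 0 <= int(k) < len(lengths):
                raise ValueError(f"stage index {k} out of range for {len(lengths)} stages")
            lengths[int(k)] = int(v)
    else:
        if len(overrides) != len(lengths):
            raise ValueError(
                f"expected {len(lengths)} stage lengths, got {len(overrides)}"
            )
        lengths = [int(v) for v in overrides]
    if any(v < 0 for v in lengths):
        raise ValueError("stage lengths must be non-negative")
    return tuple(lengths)


def build_schedule(
    id: str,
    stage_lengths: Mapping[int, int] | Sequence[int] | None = None,
    seed: int = 0,
    shuffle: bool = False,
) -> ExperimentDef:
    """Build the canonical design for one experiment.

    Parameters
    ----------
    id:
        One of :data:`EXPERIMENT_IDS`.
    stage_lengths:
        Optional overrides of the per-stage trial counts (a mapping from
        stage index, or a full sequence).  For stages built from
        alternating trial types the length counts repetitions of *each*
        type.
    seed, shuffle:
        With ``shuffle=True`` the interleaved stages are randomly
        permuted using ``seed``; the default is strict deterministic
        alternation.

    Deterministic given ``(id, stage_lengths, seed, shuffle)``.
    """
    try:
        builder = _BUILDERS[id]
    except KeyError:
        raise ValueError(
            f"unknown experiment id {id!r}; valid ids: {', '.join(EXPERIMENT_IDS)}"
        ) from None
    rng = np.random.default_rng(seed) if shuffle else None
    return builder(stage_lengths, rng)


# --- individual designs ----------------------------------------------------


def _blocking(overrides, rng) -> ExperimentDef:
    n1, n2 = _resolve_lengths((20, 20), overrides)
    trials = _repeat("A", True, n1, stage=0) + _repeat("AB", True, n2, stage=1)
    sched = Schedule(label="main", trials=tuple(trials), cue_universe=("A", "B"))
    return ExperimentDef("blocking", {"main": sched}, (n1, n2))


def _overexpectation(overrides, rng) -> ExperimentDef:
    n1, n2 = _resolve_lengths((20, 20), overrides)
    stage1 = _interleave(
        [(frozenset("A"), True), (frozenset("B"), True)], n1, stage=0, rng=rng
    )
    trials = stage1 + _repeat("AB", True, n2, stage=1)
    sched = Schedule(label="main", trials=tuple(trials), cue_universe=("A", "B"))
    return ExperimentDef("overexpectation", {"main": sched}, (n1, n2))


def _conditioned_inhibition(overrides, rng) -> ExperimentDef:
    (n1,) = _resolve_lengths((20,), overrides)
    trials = _interleave(
        [(frozenset("A"), True), (frozenset("AB"), False)], n1, stage=0, rng=rng
    )
    sched = Schedule(label="main", trials=tuple(trials), cue_universe=("A", "B"))
    return ExperimentDef("conditioned_inhibition", {"main": sched}, (n1,))


def _wilson1992(overrides, rng) -> ExperimentDef:
    # Cue A is the light, cue B the tone.  Group E's middle stage omits
    # the tone on non-reinforced trials; stage 3 reinforces the light alone.
    # The first discrimination stage is short: compound-only exposure
    # drives the effort matrix toward rank one, and after long exposure its
    # inverse amplifies the light-alone direction so strongly for both
    # groups that the belief-driven group difference is swamped.  The
    # middle stage -- where Group E receives the light-alone omission
    # trials -- is longer, giving E time to learn the discrimination that
    # later makes the light-alone reinforcement surprising.
    n1, n2, n3 = _resolve_lengths((5, 12, 20), overrides)
    ab_plus_minus = [(frozenset("AB"), True), (frozenset("AB"), False)]
    e_middle = [(frozenset("AB"), True), (frozenset("A"), False)]
    conds = {}
    for group, middle in (("C", ab_plus_minus), ("E", e_middle)):
        trials = (
            _interleave(ab_plus_minus, n1, stage=0, rng=rng)
            + _interleave(middle, n2, stage=1, rng=rng)
            + _repeat("A", True, n3, stage=2)
        )
        conds[group] = Schedule(label=group, trials=tuple(trials), cue_universe=("A", "B"))
    return ExperimentDef("wilson1992", conds, (n1, n2, n3))


def _rescorla2000(id: str, compound_reinforced: bool, overrides, rng) -> ExperimentDef:
    n1, n2 = _resolve_lengths((20, 20), overrides)
    stage1 = _interleave(
        [(frozenset("A"), True), (frozenset("B"), False)], n1, stage=0, rng=rng
    )
    trials = stage1 + _repeat("AB", compound_reinforced, n2, stage=1)
    sched = Schedule(label="main", trials=tuple(trials), cue_universe=("A", "B"))
    return ExperimentDef(id, {"main": sched}, (n1, n2))


def _partial_reinforcement_1(overrides, rng) -> ExperimentDef:
    n1, n2 = _resolve_lengths((20, 20), overrides)
    partial = _interleave(
        [(frozenset("A"), True), (frozenset("A"), False)], n1, stage=0, rng=rng
    ) + _repeat("A", False, n2, stage=1)
    continuous = _repeat("A", True, 2 * n1, stage=0) + _repeat("A", False, n2, stage=1)
    conds = {
        "partial": Schedule("partial", tuple(partial), ("A",)),
        "continuous": Schedule("continuous", tuple(continuous), ("A",)),
    }
    return ExperimentDef("partial_reinforcement_1", conds, (n1, n2))


def _partial_reinforcement_2(overrides, rng) -> ExperimentDef:
    n1, n2, n3 = _resolve_lengths((20, 20, 20), overrides)
    partial = (
        _interleave([(frozenset("A"), True), (frozenset("A"), False)], n1, stage=0, rng=rng)
        + _repeat("A", True, n2, stage=1)
        + _repeat("A", False, n3, stage=2)
    )
    continuous = (
        _repeat("A", True, 2 * n1, stage=0)
        + _repeat("A", True, n2, stage=1)
        + _repeat("A", False, n3, stage=2)
    )
    conds = {
        "partial": Schedule("partial", tuple(partial), ("A",)),
        "continuous": Schedule("continuous", tuple(continuous), ("A",)),
    }
    return ExperimentDef("partial_reinforcement_2", conds, (n1, n2, n3))


def _backwards_blocking(overrides, rng) -> ExperimentDef:
    n1, n2 = _resolve_lengths((20, 20), overrides)
    trials = _repeat("AX", True, n1, stage=0) + _repeat("A", True, n2, stage=1)
    sched = Schedule(label="main", trials=tuple(trials), cue_universe=("A", "X"))
    return ExperimentDef("backwards_blocking", {"main": sched}, (n1, n2))


def _renewal(overrides, rng) -> ExperimentDef:
    n1, n2, n3 = _resolve_lengths((20, 20, 20), overrides)
    spatial = ContextEvent("spatial")

    def phases(shift: bool) -> tuple[list[TrialSpec], list[str]]:
        acq = _repeat("A", True, n1, stage=0)
        ext = _repeat("A", False, n2, stage=1)
        reacq = _repeat("A", True, n3, stage=2)
        if shift:
            acq = _with_final_event(acq, spatial)
            ext = _with_final_event(ext, spatial)
        labels = ["acq"] * n1 + (["ext"] if shift else ["acq"]) * n2 + ["acq"] * n3
        return acq + ext + reacq, labels

    conds = {}
    for name, shift in (("same", False), ("shift", True)):
        trials, labels = phases(shift)
        conds[name] = Schedule(name, tuple(trials), ("A",), context_labels=tuple(labels))
    return ExperimentDef("renewal", conds, (n1, n2, n3))


def _spontaneous_recovery(overrides, rng) -> ExperimentDef:
    n1, n2, n3 = _resolve_lengths((20, 20, 20), overrides)

    def phases(iti: int) -> list[TrialSpec]:
        acq = _repeat("A", True, n1, stage=0)
        ext = _with_final_event(
            _repeat("A", False, n2, stage=1), ContextEvent("temporal", iti=iti)
        )
        reacq = _repeat("A", True, n3, stage=2)
        return acq + ext + reacq

    conds = {
        "delay": Schedule("delay", tuple(phases(100)), ("A",)),
        "no_delay": Schedule("no_delay", tuple(phases(1)), ("A",)),
    }
    return ExperimentDef("spontaneous_recovery", conds, (n1, n2, n3))


#: Retrieval-to-extinction delays probed in the memory-modification design.
MEMORY_MODIFICATION_DELAYS: tuple[int, ...] = (1, 5, 100)


def _memory_modification(overrides, rng) -> ExperimentDef:
    # stages: acquisition, single retrieval trial, extinction, test.
    # Fear acquisition runs to near-asymptote (40 trials at alpha0=0.05
    # reaches ~87% of the asymptotic strength); with weaker acquisition the
    # pooled uncertainty stays so large that beliefs abandon the
    # acquisition state within a couple of extinction trials in every
    # delay condition, and no reconsolidation window can appear.
    n1, n_ret, n3, n4 = _resolve_lengths((40, 1, 20, 3), overrides)
    conds = {}
    for delay in MEMORY_MODIFICATION_DELAYS:
        trials = _repeat("A", True, n1, stage=0)
        trials += _with_final_event(
            _repeat("A", False, n_ret, stage=1), ContextEvent("temporal", iti=delay)
        )
        trials += _with_final_event(
            _repeat("A", False, n3, stage=2), ContextEvent("temporal", iti=100)
        )
        trials += _repeat("A", False, n4, stage=3)
        conds[f"delay_{delay}"] = Schedule(f"delay_{delay}", tuple(trials), ("A",))
    return ExperimentDef("memory_modification", conds, (n1, n_ret, n3, n4))


_BUILDERS: dict[str, Callable] = {
    "blocking": _blocking,
    "overexpectation": _overexpectation,
    "conditioned_inhibition": _conditioned_inhibition,
    "wilson1992": _wilson1992,
    "rescorla2000_1A": lambda o, r: _rescorla2000("rescorla2000_1A", True, o, r),
    "rescorla2000_1B": lambda o, r: _rescorla2000("rescorla2000_1B", False, o, r),
    "partial_reinforcement_1": _partial_reinforcement_1,
    "partial_reinforcement_2": _partial_reinforcement_2,
    "backwards_blocking": _backwards_blocking,
    "renewal": _renewal,
    "spontaneous_recovery": _spontaneous_recovery,
    "memory_modification": _memory_modification,
}
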