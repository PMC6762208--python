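"""Randomized-schedule fuzzing shared by the invariant and acceptance tests.

Runs the latent-state learner over random trial schedules (random cue
subsets, +-1/2 rewards, random between-trial context events) and checks
the structural invariants after every trial: beliefs on the simplex,
effort matrices symmetric positive definite, q >= 0, sigma^2 > 0, and
that every spawned component predicts its spawning reward exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lslearn import ContextEvent, LearnerState, ModelParams, expand_cues, feature_names, step_trial

SIMPLEX_TOL = 1e-12
SPAWN_TOL = 1e-14


@dataclass
class FuzzReport:
    n_schedules: int = 0
    n_trials: int = 0
    n_spawns: int = 0
    max_simplex_dev: float = 0.0
    max_spawn_dev: float = 0.0
    min_effort_eig: float = field(default=float("inf"))


def run_fuzz(n_schedules: int, seed: int = 0, params: ModelParams | None = None) -> FuzzReport:
    rng = np.random.default_rng(seed)
    params = params or ModelParams()
    report = FuzzReport()
    for _ in range(n_schedules):
        universe = tuple("ABC"[: rng.integers(1, 4)])
        dim = len(feature_names(universe, params.include_interactions))
        state = LearnerState.initial(dim, params)
        for _ in range(int(rng.integers(30, 61))):
            subset = [cue for cue in universe if rng.random() < 0.5]
            if not subset:
                subset = [universe[int(rng.integers(len(universe)))]]
            cues = expand_cues(subset, universe, params.include_interactions)
            reward = 0.5 if rng.random() < 0.5 else -0.5
            kind = rng.choice(["none", "none", "none", "temporal", "spatial"])
            event = (
                ContextEvent("temporal", iti=int(rng.integers(1, 7)))
                if kind == "temporal"
                else ContextEvent(kind)
            )
            out = step_trial(state, cues, reward, event, params)
            report.n_trials += 1

            beliefs = state.beliefs
            dev = abs(float(beliefs.sum()) - 1.0)
            report.max_simplex_dev = max(report.max_simplex_dev, dev)
            assert dev <= SIMPLEX_TOL, f"beliefs off the simplex by {dev:g}"
            assert (beliefs >= 0).all(), "negative belief"
            for comp in state.components:
                assert np.array_equal(comp.effort, comp.effort.T), "effort not symmetric"
                eig = float(np.linalg.eigvalsh(comp.effort)[0])
                report.min_effort_eig = min(report.min_effort_eig, eig)
                assert eig > 0, f"effort matrix not positive definite (min eig {eig:g})"
            assert state.change_stat >= 0, "negative change statistic"
            assert state.variance > 0, "non-positive variance"
            if out.state_added:
                report.n_spawns += 1
                new = state.components[out.new_state_index]
                pred = float(cues.values @ new.strengths)
                dev = abs(pred - reward)
                report.max_spawn_dev = max(report.max_spawn_dev, dev)
                assert dev <= SPAWN_TOL, (
                    f"spawned state prediction {pred!r} != reward {reward!r}"
                )
        report.n_schedules += 1
    return report
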