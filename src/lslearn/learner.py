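"""The online latent-state learner.

The agent entertains ``L`` latent states, each indexing its own linear
(Rescorla-Wagner-style) association between cue features and reward.  On
every trial it:

1. computes a per-state prediction error ``E_l = R - c'V_l``;
2. filters its beliefs ``p_l`` over latent states with an approximate
   Bayesian (HMM forward) update, using a standard-normal density of the
   standardized error as the emission weight;
3. accumulates a change statistic ``q`` (a Page/CUSUM-style log-likelihood
   ratio against a perfectly predicting alternative) and recruits a fresh
   latent state when ``q`` crosses the threshold ``nu``;
4. updates each state's strengths ``V_l`` with associability
   ``alpha0 * p_l * B_l^{-1}``, where ``B_l`` is that state's "effort"
   matrix -- a running estimate of the cue second-moment matrix;
5. updates the effort matrices and the pooled error variance ``sigma^2``.

Between trials, a context shift corrodes beliefs toward uniform (fully for
a spatial/visual shift, geometrically in the inter-trial interval for a
temporal shift) and a temporal shift additionally triggers bounded
"rumination": replaying the last trial's value update up to ``chi`` times.

All computation here is deterministic; randomness only ever lives in
schedule construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureVector
from .params import ModelParams

__all__ = [
    "ContextEvent",
    "LatentComponent",
    "LearnerState",
    "StepOutput",
    "center_reward",
    "predict_rewards",
    "compute_errors",
    "update_beliefs",
    "update_change_stat",
    "spawn_state",
    "update_strengths",
    "update_effort",
    "update_variance",
    "apply_context_shift",
    "ruminate",
    "step_trial",
    "report_associative_strength",
]

logger = logging.getLogger(__name__)

#: Standard normal density at zero, the numerator of the change-statistic
#: likelihood ratio.
PHI0 = 1.0 / math.sqrt(2.0 * math.pi)

#: Below this, the belief normalizer is treated as underflowed: beliefs
#: fall back to the Markov prior and the change statistic uses the clamped
#: value.  The standard normal density underflows for |E|/sigma >~ 38.
L0_FLOOR = 1e-300

#: Lower clamp on the pooled variance; perfect prediction would otherwise
#: drive sigma^2 to zero and degenerate the belief filter.
VARIANCE_FLOOR = 1e-8


def _phi(x: np.ndarray | float) -> np.ndarray | float:
    """Standard normal probability density."""
    return np.exp(-0.5 * np.square(x)) / math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class ContextEvent:
    """A between-trial context change.

    ``kind`` is one of ``"none"``, ``"temporal"`` or ``"spatial"``.  For a
    temporal shift ``iti`` is the number of elapsed time steps between
    trials (>= 1); a spatial/visual shift behaves as an infinite interval
    and ignores ``iti``.
    """

    kind: str = "none"
    iti: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("none", "temporal", "spatial"):
            raise ValueError(f"unknown context event kind {self.kind!r}")
        if self.kind == "temporal" and (not isinstance(self.iti, int) or self.iti < 1):
            raise ValueError(f"temporal event requires integer iti >= 1, got {self.iti!r}")


@dataclass
class LatentComponent:
    """One latent state: strengths, effort matrix and current belief."""

    strengths: np.ndarray
    effort: np.ndarray
    belief: float


@dataclass
class LearnerState:
    """The evolving agent: latent components plus pooled uncertainty.

    ``variance`` is the pooled reward variance sigma^2 (> 0) and
    ``change_stat`` the running change statistic q (>= 0).
    """

    components: list[LatentComponent]
    variance: float
    change_stat: float
    dim: int

    @classmethod
    def initial(cls, dim: int, params: ModelParams, n_states: int = 1) -> "LearnerState":
        """Fresh learner: V = 0, B = I, uniform beliefs, sigma^2 = sigma0^2, q = 0."""
        if not 1 <= n_states <= params.max_states:
            raise ValueError(f"n_states must be in [1, {params.max_states}], got {n_states}")
        comps = [
            LatentComponent(
                strengths=np.zeros(dim),
                effort=np.eye(dim),
                belief=1.0 / n_states,
            )
            for _ in range(n_states)
        ]
        return cls(
            components=comps,
            variance=params.sigma0**2,
            change_stat=0.0,
            dim=dim,
        )

    @property
    def n_states(self) -> int:
        return len(self.components)

    @property
    def beliefs(self) -> np.ndarray:
        return np.array([c.belief for c in self.components])

    def set_beliefs(self, beliefs: np.ndarray) -> None:
        for comp, p in zip(self.components, beliefs):
            comp.belief = float(p)


@dataclass
class StepOutput:
    """Per-trial record produced by :func:`step_trial`.

    ``marginal_prediction`` is the belief-weighted expected reward using
    the beliefs reached at the end of the trial's inference stage (after
    the belief filter, before any context shift).
    """

    errors: np.ndarray
    state_predictions: np.ndarray
    marginal_prediction: float
    norm_const: float
    mean_sq_error: float
    state_added: bool = False
    new_state_index: int | None = None
    candidate_q: float = field(default=0.0)


def center_reward(reinforced: bool, center_rewards: bool = True) -> float:
    """Reward coding: +-1/2 when centering, 1/0 otherwise."""
    if center_rewards:
        return 0.5 if reinforced else -0.5
    return 1.0 if reinforced else 0.0


def _cue_values(state: LearnerState, cues: FeatureVector) -> np.ndarray:
    c = np.asarray(cues.values, dtype=float)
    if c.shape[0] != state.dim:
        raise ValueError(f"cue dimension {c.shape[0]} does not match learner dimension {state.dim}")
    return c


def predict_rewards(state: LearnerState, cues: FeatureVector) -> tuple[np.ndarray, float]:
    """Per-state expected rewards ``c'V_l`` and their belief-weighted marginal.

    Pure function; does not mutate the state.
    """
    c = _cue_values(state, cues)
    preds = np.array([float(c @ comp.strengths) for comp in state.components])
    marginal = float(state.beliefs @ preds)
    return preds, marginal


def compute_errors(state: LearnerState, cues: FeatureVector, reward: float) -> np.ndarray:
    """Per-state prediction errors ``E_l = R - c'V_l`` (pre-update strengths)."""
    preds, _ = predict_rewards(state, cues)
    return reward - preds


def update_beliefs(
    state: LearnerState, errors: np.ndarray, params: ModelParams
) -> tuple[np.ndarray, float]:
    """Approximate Bayesian filter over latent states.

    The Markov prior mixes each belief with uniform,
    ``prior_l = (1 - gamma) p_l + gamma / L``, then reweights by the
    standard-normal density of the standardized error.  Beliefs are
    replaced in place; the normalizer ``l0`` is returned for the change
    statistic.

    If ``l0`` underflows (every state's error is astronomically
    surprising), beliefs fall back to the Markov prior and the clamped
    ``l0`` is returned, with a warning.
    """
    if state.variance <= 0:
        raise ValueError("variance must be > 0 before belief update")
    L = state.n_states
    prior = (1.0 - params.gamma) * state.beliefs + params.gamma / L
    sigma = math.sqrt(state.variance)
    weights = prior * _phi(np.asarray(errors) / sigma)
    l0 = float(np.sum(weights))
    if l0 < L0_FLOOR:
        logger.warning(
            "belief normalizer underflowed (l0=%.3g); falling back to the Markov prior", l0
        )
        state.set_beliefs(prior)
        return prior, L0_FLOOR
    posterior = weights / l0
    state.set_beliefs(posterior)
    return posterior, l0


def update_change_stat(state: LearnerState, norm_const: float, params: ModelParams) -> float:
    """Candidate change statistic ``max(q + log(phi(0)/l0) - delta, 0)``.

    ``phi(0)/l0`` is the likelihood ratio of a hypothetical state that
    predicts the current reward exactly against the current model.  Does
    not mutate the state; the caller commits either the candidate or a
    post-spawn reset.
    """
    if not norm_const > 0:
        raise ValueError(f"norm_const must be > 0, got {norm_const!r}")
    return max(state.change_stat + math.log(PHI0 / norm_const) - params.delta, 0.0)


def spawn_state(state: LearnerState, cues: FeatureVector, reward: float) -> LearnerState:
    """Recruit a new latent state whose prediction on the current cues is the reward.

    The new component gets strengths ``R * c / (c'c)``, an identity effort
    matrix and belief 0; the change statistic resets to 0.  Existing
    beliefs are untouched (they still sum to one).
    """
    c = _cue_values(state, cues)
    cc = float(c @ c)
    if cc == 0.0:
        raise ValueError("cannot spawn a latent state from an all-zero cue vector")
    comp = LatentComponent(strengths=reward * c / cc, effort=np.eye(state.dim), belief=0.0)
    state.components.append(comp)
    state.change_stat = 0.0
    return state


def update_strengths(
    state: LearnerState, cues: FeatureVector, errors: np.ndarray, params: ModelParams
) -> LearnerState:
    """Value update ``V_l += alpha0 * p_l * B_l^{-1} c * E_l``.

    Beliefs must be the current trial's post-inference beliefs; the effort
    matrices are those held at the start of the trial (the value update
    precedes the effort update).  ``B_l^{-1} c`` is realized as a linear
    solve, never an explicit inverse.
    """
    c = _cue_values(state, cues)
    for idx, (comp, err) in enumerate(zip(state.components, errors)):
        if comp.belief == 0.0 or err == 0.0:
            continue
        try:
            direction = np.linalg.solve(comp.effort, c)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"effort matrix of latent state {idx} is numerically singular"
            ) from exc
        comp.strengths = comp.strengths + params.alpha0 * comp.belief * direction * float(err)
    return state


def update_effort(state: LearnerState, cues: FeatureVector, params: ModelParams) -> LearnerState:
    """Effort update ``B_l <- (1 - alpha0) B_l + alpha0 * p_l * c c'``.

    A convex combination toward the belief-weighted cue outer product;
    re-symmetrized to cancel floating-point drift.
    """
    c = _cue_values(state, cues)
    outer = np.outer(c, c)
    for comp in state.components:
        B = (1.0 - params.alpha0) * comp.effort + params.alpha0 * comp.belief * outer
        comp.effort = 0.5 * (B + B.T)
    return state


def update_variance(state: LearnerState, errors: np.ndarray, params: ModelParams) -> LearnerState:
    """Pooled variance update toward the belief-weighted mean squared error."""
    mean_sq = float(state.beliefs @ np.square(np.asarray(errors)))
    state.variance = max(
        state.variance + params.beta0 * (mean_sq - state.variance), VARIANCE_FLOOR
    )
    return state


def apply_context_shift(
    state: LearnerState, event: ContextEvent, params: ModelParams
) -> LearnerState:
    """Corrode beliefs toward uniform after a context change.

    Temporal: ``p_l <- (1-gamma)^(ITI-1) p_l + (1 - (1-gamma)^(ITI-1))/L``
    (the Markov prior iterated over the elapsed interval).  Spatial or
    visual: uniform beliefs, the infinite-interval limit.
    """
    if event.kind == "none":
        raise ValueError("apply_context_shift requires a temporal or spatial event")
    L = state.n_states
    if event.kind == "spatial":
        state.set_beliefs(np.full(L, 1.0 / L))
        return state
    w = (1.0 - params.gamma) ** (event.iti - 1)
    state.set_beliefs(w * state.beliefs + (1.0 - w) / L)
    return state


def ruminate(
    state: LearnerState,
    cues: FeatureVector,
    reward: float,
    event: ContextEvent,
    params: ModelParams,
) -> LearnerState:
    """Replay the last trial's value update during a temporal gap.

    Runs ``min(chi, ITI - 1)`` iterations, each recomputing the errors
    with the current strengths and applying only the value update.
    Beliefs, effort matrices, variance and the change statistic are held
    fixed throughout.
    """
    if event.kind != "temporal":
        raise ValueError("rumination applies only to temporal context shifts")
    n_iter = min(params.chi, event.iti - 1)
    for _ in range(n_iter):
        errors = compute_errors(state, cues, reward)
        update_strengths(state, cues, errors, params)
    return state


def step_trial(
    state: LearnerState,
    cues: FeatureVector,
    reward: float,
    post_event: ContextEvent,
    params: ModelParams,
) -> StepOutput:
    """One full trial, in the fixed stage order.

    (1) errors from pre-update strengths; (2) belief filter;
    (3) change statistic, spawning a state iff the candidate exceeds
    ``nu`` strictly; (4) value update; (5) effort update; (6) variance
    update; (7) the post-trial context event: rumination then belief
    corrosion for a temporal shift, corrosion only for a spatial one.
    """
    c = _cue_values(state, cues)

    # (1) state inference inputs
    errors = compute_errors(state, cues, reward)
    preds = reward - errors

    # (2) belief filter
    beliefs, l0 = update_beliefs(state, errors, params)
    marginal = float(beliefs @ preds)

    # (3) change-point detection
    candidate_q = update_change_stat(state, l0, params)
    state_added = False
    new_index: int | None = None
    if candidate_q > params.nu:
        if state.n_states >= params.max_states:
            logger.warning(
                "change statistic %.3f exceeds nu but the state cap (%d) is reached; "
                "keeping the candidate statistic",
                candidate_q,
                params.max_states,
            )
            state.change_stat = candidate_q
        else:
            spawn_state(state, cues, reward)
            state_added = True
            new_index = state.n_states - 1
            # the fresh component predicts the reward exactly: error 0
            errors = np.append(errors, reward - float(c @ state.components[-1].strengths))
    else:
        state.change_stat = candidate_q

    # (4)-(6) value, effort and variance learning
    update_strengths(state, cues, errors, params)
    update_effort(state, cues, params)
    mean_sq = float(state.beliefs @ np.square(errors))
    update_variance(state, errors, params)

    # (7) between-trial context
    if post_event.kind == "temporal":
        ruminate(state, cues, reward, post_event, params)
        apply_context_shift(state, post_event, params)
    elif post_event.kind == "spatial":
        apply_context_shift(state, post_event, params)

    return StepOutput(
        errors=errors,
        state_predictions=preds,
        marginal_prediction=marginal,
        norm_const=l0,
        mean_sq_error=mean_sq,
        state_added=state_added,
        new_state_index=new_index,
        candidate_q=candidate_q,
    )


def report_associative_strength(
    state: LearnerState, cues_template: FeatureVector, cue_label: str, uncenter: bool = False
) -> float:
    """Expected reward if *cue_label* were presented alone.

    With the cue alone every interaction feature is zero, so this is the
    belief-weighted raw coefficient ``sum_l p_l V_l[cue]``.  ``uncenter``
    shifts by +1/2 to the 0/1 reward scale.
    """
    try:
        idx = cues_template.names.index(cue_label)
    except ValueError:
        raise KeyError(
            f"unknown cue label {cue_label!r}; known features are {cues_template.names!r}"
        ) from None
    value = float(sum(comp.belief * comp.strengths[idx] for comp in state.components))
    return value + 0.5 if uncenter else value
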