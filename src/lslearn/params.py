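"""Learner parameters.

The latent-state learner is governed by seven behavioural parameters
(``alpha0``, ``beta0``, ``gamma``, ``sigma0``, ``nu``, ``delta``, ``chi``)
plus a handful of engineering knobs (state cap, feature expansion and
reward-centering toggles).  Defaults are the fixed set used for every
simulated experiment.  The Rescorla-Wagner comparator has a single constant
learning rate.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ModelParams", "RWParams"]


def _check_unit_interval(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


def _check_positive(name: str, value: float) -> None:
    if not value > 0.0:
        raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the latent-state learner.

    Attributes
    ----------
    alpha0:
        Associative-strength learning rate, in [0, 1].  Scales both the
        value update (through the associability matrix) and the decay of
        the effort matrices.
    beta0:
        Learning rate for the pooled reward variance, in [0, 1].
    gamma:
        Latent-state transition parameter, in [0, 1].  A latent state
        persists from one trial to the next with probability
        ``1 - gamma * (L - 1) / L``.
    sigma0:
        Initial reward standard deviation (> 0); the pooled variance
        starts at ``sigma0 ** 2``.
    nu:
        Threshold on the change statistic above which a new latent state
        is recruited (> 0).
    delta:
        Per-trial drift subtracted from the change statistic (> 0).
    chi:
        Maximum number of rumination iterations during a temporal
        context shift (non-negative integer).
    max_states:
        Cap on the number of latent states entertained simultaneously.
    include_interactions:
        If true, the feature vector carries one extra feature per
        unordered pair of raw cues (their product).
    center_rewards:
        If true, rewards are coded +1/2 (reinforced) and -1/2 (omitted)
        instead of 1 / 0, so that zero strength means a 50-50 expectation.
    """

    alpha0: float = 0.05
    beta0: float = 0.05
    gamma: float = 0.05
    sigma0: float = 0.5
    nu: float = 0.2
    delta: float = 0.6
    chi: int = 5
    max_states: int = 15
    include_interactions: bool = True
    center_rewards: bool = True

    def __post_init__(self) -> None:
        _check_unit_interval("alpha0", self.alpha0)
        _check_unit_interval("beta0", self.beta0)
        _check_unit_interval("gamma", self.gamma)
        _check_positive("sigma0", self.sigma0)
        _check_positive("nu", self.nu)
        _check_positive("delta", self.delta)
        if not (isinstance(self.chi, int) and self.chi >= 0):
            raise ValueError(f"chi must be a non-negative integer, got {self.chi!r}")
        if not (isinstance(self.max_states, int) and self.max_states >= 1):
            raise ValueError(f"max_states must be a positive integer, got {self.max_states!r}")


@dataclass(frozen=True)
class RWParams:
    """Rescorla-Wagner parameters: a single constant learning rate."""

    alpha: float = 0.15

    def __post_init__(self) -> None:
        _check_unit_interval("alpha", self.alpha)
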