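"""Rescorla-Wagner comparator.

A single linear association between cues and reward with constant
associability: ``V <- V + alpha * c * (R - c'V)``.  This is exactly the
latent-state learner restricted to one state with its effort matrix held
at the identity -- the reduction is checked numerically in the test suite.

Per the simulation conventions, the comparator sees uncentered rewards
(1/0), no interaction features, and spatial context encoded as one
always-on indicator cue per distinct context label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureVector
from .params import RWParams

__all__ = ["RWState", "rw_step"]


@dataclass
class RWState:
    """Associative strengths, one per feature; initialized to zero."""

    strengths: np.ndarray

    @classmethod
    def initial(cls, dim: int) -> "RWState":
        return cls(strengths=np.zeros(dim))


def rw_step(
    state: RWState, cues: FeatureVector, reward: float, params: RWParams
) -> tuple[RWState, float]:
    """One Rescorla-Wagner update; returns the mutated state and the error.

    Absent cues (loading zero) are untouched.
    """
    c = np.asarray(cues.values, dtype=float)
    if c.shape[0] != state.strengths.shape[0]:
        raise ValueError(
            f"cue dimension {c.shape[0]} does not match state dimension "
            f"{state.strengths.shape[0]}"
        )
    error = float(reward - c @ state.strengths)
    state.strengths = state.strengths + params.alpha * c * error
    return state, error
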