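import numpy as np
import pytest

from lslearn import FeatureVector, LearnerState, ModelParams


@pytest.fixture
def params() -> ModelParams:
    """The fixed simulation parameter set."""
    return ModelParams()


@pytest.fixture
def scalar_cue() -> FeatureVector:
    """A single always-on cue (one raw feature, no interactions)."""
    return FeatureVector(values=np.array([1.0]), names=("A",))


def make_state(
    strengths_list, params: ModelParams, beliefs=None, variance=None, efforts=None
) -> LearnerState:
    """Build a learner state with prescribed components for unit tests."""
    strengths_list = [np.asarray(v, dtype=float) for v in strengths_list]
    dim = strengths_list[0].shape[0]
    state = LearnerState.initial(dim, params, n_states=len(strengths_list))
    for comp, v in zip(state.components, strengths_list):
        comp.strengths = v
    if efforts is not None:
        for comp, B in zip(state.components, efforts):
            comp.effort = np.asarray(B, dtype=float)
    if beliefs is not None:
        state.set_beliefs(np.asarray(beliefs, dtype=float))
    if variance is not None:
        state.variance = float(variance)
    return state
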