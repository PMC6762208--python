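"""Cue feature expansion.

A trial presents a subset of raw cues out of a fixed, ordered universe.
The learner represents a trial as a real feature vector: the raw-cue
loadings first (in the universe's declared order), followed, when
interaction features are enabled, by one feature per unordered pair of raw
cues in lexicographic order, whose loading is the product of the pair's
raw loadings.  For indicator cues the pair feature is therefore the
indicator of the compound being present.

The ordering is canonical so that stored strength vectors and effort
matrices are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["FeatureVector", "feature_names", "expand_cues"]


@dataclass(frozen=True)
class FeatureVector:
    """A named, ordered vector of feature loadings for one trial."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.shape[0] != len(self.names):
            raise ValueError(
                f"feature values ({self.values.shape}) do not match names ({len(self.names)})"
            )

    def __len__(self) -> int:
        return len(self.names)


def pair_name(a: str, b: str) -> str:
    """Canonical label of the interaction feature for raw cues *a* and *b*."""
    lo, hi = sorted((a, b))
    return f"{lo}*{hi}"


def feature_names(universe: Sequence[str], include_interactions: bool = True) -> tuple[str, ...]:
    """Feature labels: raw cues in declared order, then lexicographic pairs."""
    universe = list(universe)
    if len(set(universe)) != len(universe):
        raise ValueError(f"duplicate cue labels in universe {universe!r}")
    names = list(universe)
    if include_interactions:
        names.extend(pair_name(a, b) for a, b in combinations(sorted(universe), 2))
    return tuple(names)


def expand_cues(
    raw_cues: Iterable[str] | Mapping[str, float],
    universe: Sequence[str],
    include_interactions: bool = True,
) -> FeatureVector:
    """Expand the cues present on a trial into the full feature vector.

    Parameters
    ----------
    raw_cues:
        Either an iterable of cue labels (treated as indicators with
        loading 1) or a mapping from label to a real loading.
    universe:
        Ordered labels of all raw cues in the task.
    include_interactions:
        Whether to append the pairwise product features.

    Raises
    ------
    KeyError
        If a cue label is not part of the universe.
    """
    if isinstance(raw_cues, Mapping):
        loadings = dict(raw_cues)
    else:
        loadings = {label: 1.0 for label in raw_cues}
    unknown = set(loadings) - set(universe)
    if unknown:
        raise KeyError(f"unknown cue label(s) {sorted(unknown)!r}; universe is {list(universe)!r}")

    names = feature_names(universe, include_interactions)
    raw = np.array([loadings.get(label, 0.0) for label in universe], dtype=float)
    if include_interactions:
        by_label = dict(zip(universe, raw))
        pairs = [by_label[a] * by_label[b] for a, b in combinations(sorted(universe), 2)]
        values = np.concatenate([raw, np.asarray(pairs, dtype=float)])
    else:
        values = raw
    return FeatureVector(values=values, names=names)
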