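"""Run configuration: structured-text (YAML/JSON) parsing and validation.

A config selects a model, overrides any subset of its parameters (the
defaults are the fixed simulation set), picks one experiment or the whole
battery, and sets the decision margin, seed and output locations.
Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .effects import DEFAULT_MARGIN
from .params import ModelParams, RWParams
from .schedules import EXPERIMENT_IDS

__all__ = ["RunConfig", "load_config", "dump_config"]

_MODEL_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}
_RW_PARAM_FIELDS = {f.name for f in dataclasses.fields(RWParams)}
_TOP_LEVEL_KEYS = {
    "model",
    "experiment",
    "params",
    "stage_lengths",
    "margin",
    "seed",
    "shuffle",
    "out",
    "verbose",
}


@dataclass(frozen=True)
class RunConfig:
    """A validated run request."""

    model: str = "latent_state"
    experiment: str = "battery"
    params: ModelParams | RWParams = field(default_factory=ModelParams)
    stage_lengths: tuple[int, ...] | None = None
    margin: float = DEFAULT_MARGIN
    seed: int = 0
    shuffle: bool = False
    out: str | None = None
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("latent_state", "rescorla_wagner"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.experiment != "battery" and self.experiment not in EXPERIMENT_IDS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; valid: battery, "
                + ", ".join(EXPERIMENT_IDS)
            )
        expected = ModelParams if self.model == "latent_state" else RWParams
        if not isinstance(self.params, expected):
            raise TypeError(f"model {self.model!r} requires {expected.__name__}")
        if not self.margin >= 0:
            raise ValueError(f"margin must be >= 0, got {self.margin!r}")


def _build_params(model: str, raw: Mapping[str, Any]) -> ModelParams | RWParams:
    allowed = _MODEL_PARAM_FIELDS if model == "latent_state" else _RW_PARAM_FIELDS
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(
            f"unknown parameter key(s) {sorted(unknown)!r} for model {model!r}; "
            f"allowed: {sorted(allowed)!r}"
        )
    cls = ModelParams if model == "latent_state" else RWParams
    return cls(**raw)


def load_config(source: str | Path | Mapping[str, Any]) -> RunConfig:
    """Load and validate a run config.

    ``source`` may be a path to a YAML/JSON file, inline YAML/JSON text,
    or an already-parsed mapping.  Omitted fields take the fixed
    simulation defaults.  Parse failures carry the parser's line
    information; out-of-range values name the offending field.
    """
    if isinstance(source, Mapping):
        doc: Any = dict(source)
    else:
        path = Path(source)
        try:
            is_file = path.is_file()
        except (OSError, ValueError):  # inline text can be an invalid path
            is_file = False
        text = path.read_text() if is_file else str(source)
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ValueError(f"could not parse config: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError(f"config must be a mapping, got {type(doc).__name__}")

    unknown = set(doc) - _TOP_LEVEL_KEYS
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)!r}; allowed: {sorted(_TOP_LEVEL_KEYS)!r}"
        )
    model = doc.get("model", "latent_state")
    params = _build_params(model, doc.get("params", {}))
    stage_lengths = doc.get("stage_lengths")
    if stage_lengths is not None:
        stage_lengths = tuple(int(v) for v in stage_lengths)
    return RunConfig(
        model=model,
        experiment=doc.get("experiment", "battery"),
        params=params,
        stage_lengths=stage_lengths,
        margin=float(doc.get("margin", DEFAULT_MARGIN)),
        seed=int(doc.get("seed", 0)),
        shuffle=bool(doc.get("shuffle", False)),
        out=doc.get("out"),
        verbose=bool(doc.get("verbose", False)),
    )


def dump_config(config: RunConfig) -> str:
    """Render a config as YAML; ``load_config`` of the result is identity."""
    doc: dict[str, Any] = {
        "model": config.model,
        "experiment": config.experiment,
        "params": dataclasses.asdict(config.params),
        "margin": config.margin,
        "seed": config.seed,
        "shuffle": config.shuffle,
        "verbose": config.verbose,
    }
    if config.stage_lengths is not None:
        doc["stage_lengths"] = list(config.stage_lengths)
    if config.out is not None:
        doc["out"] = config.out
    return yaml.safe_dump(doc, sort_keys=True)
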