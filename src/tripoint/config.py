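"""Run configuration: nested YAML-backed dataclasses with typo safety.

A :class:`RunConfig` bundles the generator, preprocessing, training and
loss settings plus a global seed.  Loading validates every key against the
dataclass fields and rejects unknown ones with a nearest-match suggestion;
a short content hash of the canonicalized config stamps every artifact a
run produces.
"""

from __future__ import annotations

import difflib
import hashlib
import json
from dataclasses import dataclass, field, fields, is_dataclass

import yaml

from .losses import LossWeights
from .preprocessing import PreprocessConfig
from .synthetic import SyntheticConfig
from .training import TrainConfig

__all__ = ["RunConfig", "load_config", "save_config", "config_hash", "ConfigError"]


class ConfigError(ValueError):
    """A configuration file violated the schema."""


@dataclass
class RunConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    out_dir: str = "runs"


def _coerce(cls, data: dict, path: str = ""):
    if not isinstance(data, dict):
        raise ConfigError(f"section {path or cls.__name__!r} must be a mapping, "
                          f"got {type(data).__name__}")
    valid = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        where = f"{path}.{key}" if path else key
        if key not in valid:
            hint = difflib.get_close_matches(key, valid, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown config key {where!r}{suggestion}")
        ftype = valid[key].type
        target = _NESTED.get((cls, key))
        if target is not None:
            kwargs[key] = _coerce(target, value, where)
        elif key == "loss_weights":
            kwargs[key] = _coerce(LossWeights, value, where)
        else:
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section {path or 'top level'}: {exc}")


_NESTED = {
    (RunConfig, "synthetic"): SyntheticConfig,
    (RunConfig, "preprocess"): PreprocessConfig,
    (RunConfig, "train"): TrainConfig,
    (TrainConfig, "loss_weights"): LossWeights,
}


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; an empty file is all-defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return RunConfig()
    return _coerce(RunConfig, data)


def _as_plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    return obj


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_as_plain(config), fh, sort_keys=True)


def config_hash(config) -> str:
    """Short stable digest of a (possibly nested) config dataclass."""
    blob = json.dumps(_as_plain(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
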