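"""Config (YAML) serialization for the pipeline parameter dataclasses.

A run's effective configuration round-trips exactly: dataclass → dict →
YAML → dict → dataclass gives an equal object, so a config echo written
next to outputs can be re-fed as input and reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .spots import DetectionParams
from .synth import PopulationSpec, SceneSpec

__all__ = [
    "spec_to_dict",
    "scene_spec_from_dict",
    "population_spec_from_dict",
    "detection_params_from_dict",
    "load_config",
    "save_config",
    "config_hash",
]

_TUPLE_FIELDS = {"field_shape", "cell_radius_range", "true_counts"}


def spec_to_dict(spec) -> dict:
    """Plain-scalar dict of any parameter dataclass (tuples become lists)."""
    out = {}
    for f in dataclasses.fields(spec):
        v = getattr(spec, f.name)
        out[f.name] = list(v) if isinstance(v, tuple) else v
    return out


def _from_dict(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in d.items():
        if k in _TUPLE_FIELDS and v is not None:
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def scene_spec_from_dict(d: dict) -> SceneSpec:
    return _from_dict(SceneSpec, d)


def population_spec_from_dict(d: dict) -> PopulationSpec:
    return _from_dict(PopulationSpec, d)


def detection_params_from_dict(d: dict) -> DetectionParams:
    return _from_dict(DetectionParams, d)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config dict, for run manifests."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
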