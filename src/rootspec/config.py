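"""Structured pipeline configuration loaded from YAML.

A single file configures the whole pipeline; unknown keys are rejected so
typos fail loudly, and every value is range-checked on load.  An empty file
yields all documented defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import InvalidInputError
from .pipeline import DemoSizes
from .scene import SceneConfig

__all__ = ["PipelineConfig", "validate_config", "load_config", "dump_config"]


@dataclass
class PipelineConfig:
    """Top-level configuration aggregating all stage parameters."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    sizes: DemoSizes = field(default_factory=DemoSizes)
    trim_lo_nm: float = 450.0
    trim_hi_nm: float = 950.0
    max_lv: int = 16
    train_frac: float = 0.8
    seed: int = 1
    baseline_form: str = "power"
    output_dir: str = "demo_out"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_frac < 1.0:
            raise InvalidInputError("train_frac must be in (0, 1)")
        if self.max_lv < 1:
            raise InvalidInputError("max_lv must be >= 1")
        if not self.trim_lo_nm < self.trim_hi_nm:
            raise InvalidInputError("trim_lo_nm must be < trim_hi_nm")
        if self.baseline_form not in ("power", "saturating_exp", "linear"):
            raise InvalidInputError(f"unknown baseline_form {self.baseline_form!r}")


def _build(cls, data: dict, path: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise InvalidInputError(f"unknown config keys at {path}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        if name == "scene":
            value = _build(SceneConfig, value or {}, f"{path}.scene")
        elif name == "sizes":
            value = _build(DemoSizes, value or {}, f"{path}.sizes")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


def validate_config(path: str) -> PipelineConfig:
    """Load, default and range-check a YAML config file."""
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    if not isinstance(data, dict):
        raise InvalidInputError("config root must be a mapping")
    return _build(PipelineConfig, data, "config")


def load_config(path: str) -> PipelineConfig:
    return validate_config(path)


def dump_config(config: PipelineConfig, path: str) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(asdict(config), f, sort_keys=True)
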