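"""Run configuration: nested, validated, YAML-loadable, unknown keys rejected."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Any

import numpy as np
import yaml

from .exceptions import ConfigError
from .hough import HoughSearchSpace
from .preprocess import PreprocessConfig
from .shapes import GielisParams


@dataclass
class ShapeConfig:
    """Superformula parameters and template sampling density."""

    a: float = 1.0
    b: float = 1.0
    m: float = 2.0
    n1: float = 1.0
    n2: float = 1.0
    n3: float = 1.0
    n_points: int = 512

    def gielis_params(self) -> GielisParams:
        return GielisParams(a=self.a, b=self.b, m=self.m, n1=self.n1, n2=self.n2, n3=self.n3)


@dataclass
class HoughConfig:
    """Pose-search configuration.

    Scale ranges are in pixels (semi-axis extents).  When left as None they
    resolve per image to ``scale_frac_range`` × half the corresponding image
    dimension — the eye occupies most of the frame in slit-lamp imaging.
    """

    row_scale_range: tuple[float, float] | None = None
    col_scale_range: tuple[float, float] | None = None
    scale_frac_range: tuple[float, float] = (0.25, 0.75)
    scale_steps: int = 12
    rotation_range: tuple[float, float] = (-np.pi / 18.0, np.pi / 18.0)
    rotation_steps: int = 5
    center_stride: int = 2
    min_vote_fraction: float = 0.15

    def search_space(self, image_shape: tuple[int, int]) -> HoughSearchSpace:
        h, w = image_shape[:2]
        lo, hi = self.scale_frac_range
        row = self.row_scale_range or (lo * h / 2.0, hi * h / 2.0)
        col = self.col_scale_range or (lo * w / 2.0, hi * w / 2.0)
        return HoughSearchSpace(
            row_scale_range=tuple(row),
            col_scale_range=tuple(col),
            scale_steps=self.scale_steps,
            rotation_range=tuple(self.rotation_range),
            rotation_steps=self.rotation_steps,
            center_stride=self.center_stride,
        )


@dataclass
class CorneaConfig:
    radius_mode: str = "half_semi_minor"

    def __post_init__(self) -> None:
        if self.radius_mode not in ("half_semi_minor", "semi_minor"):
            raise ConfigError(f"unknown cornea.radius_mode {self.radius_mode!r}")


@dataclass
class ExtractConfig:
    """Eyelid-stain rejection: a candidate segment is discarded iff it touches
    the fitted border (after dilation by ``border_dilation_px``) AND its
    moment-ellipse axis ratio exceeds ``ratio_threshold``."""

    ratio_threshold: float = 3.0
    border_dilation_px: int = 2

    def __post_init__(self) -> None:
        if self.ratio_threshold < 1:
            raise ConfigError("extract.ratio_threshold must be >= 1")
        if self.border_dilation_px < 0:
            raise ConfigError("extract.border_dilation_px must be >= 0")


@dataclass
class IOConfig:
    input: str | None = None
    truth: str | None = None
    output_dir: str = "."
    save_stages: bool = False
    log_level: str = "INFO"


@dataclass
class RunConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    shape: ShapeConfig = field(default_factory=ShapeConfig)
    hough: HoughConfig = field(default_factory=HoughConfig)
    cornea: CorneaConfig = field(default_factory=CorneaConfig)
    extract: ExtractConfig = field(default_factory=ExtractConfig)
    io: IOConfig = field(default_factory=IOConfig)


_BLOCKS = {
    "preprocess": PreprocessConfig,
    "shape": ShapeConfig,
    "hough": HoughConfig,
    "cornea": CorneaConfig,
    "extract": ExtractConfig,
    "io": IOConfig,
}


def _build_block(cls, data: dict[str, Any], block: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in '{block}': {sorted(unknown)}")
    coerced = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if isinstance(val, list):
            val = tuple(val)
        coerced[f.name] = val
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in '{block}': {exc}") from exc


def config_from_dict(data: dict[str, Any] | None) -> RunConfig:
    """Build a RunConfig from nested dicts, rejecting unknown keys."""
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(data) - set(_BLOCKS)
    if unknown:
        raise ConfigError(f"unknown configuration block(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _BLOCKS.items():
        block = data.get(name, {})
        if not isinstance(block, dict):
            raise ConfigError(f"block '{name}' must be a mapping")
        kwargs[name] = _build_block(cls, block, name)
    return RunConfig(**kwargs)


def load_config(path: str) -> RunConfig:
    """Load a YAML configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def apply_overrides(config_dict: dict[str, Any], overrides: list[str]) -> dict[str, Any]:
    """Apply ``block.key=value`` override strings onto a nested config dict."""
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override {item!r} is not of the form key=value")
        key, raw = item.split("=", 1)
        parts = key.split(".")
        if len(parts) != 2:
            raise ConfigError(f"override key {key!r} must be 'block.field'")
        value = yaml.safe_load(raw)
        config_dict.setdefault(parts[0], {})[parts[1]] = value
    return config_dict
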