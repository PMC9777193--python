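"""Shared fixtures: configs, synthetic scenes, and the evaluation search space."""

from __future__ import annotations

import numpy as np
import pytest

from ulcerseg import EyeBorderFit, PreprocessConfig
from ulcerseg.config import RunConfig, config_from_dict
from ulcerseg.synthetic import EyelidArc, SceneParams, UlcerBlob, generate_scene

# Hough search grid used for evaluating 240x320 suite scenes: semi-axis ranges
# bracket the generator's sampling distributions, rotation-free (suite eyes are
# horizontal below the "hard" difficulty).
SUITE_HOUGH = {
    "row_scale_range": [54.0, 76.0],
    "col_scale_range": [88.0, 117.0],
    "scale_steps": 8,
    "rotation_steps": 1,
    "center_stride": 2,
}


def suite_config() -> RunConfig:
    return config_from_dict({"hough": dict(SUITE_HOUGH)})


@pytest.fixture(scope="session")
def run_cfg() -> RunConfig:
    return suite_config()


@pytest.fixture()
def pp_cfg() -> PreprocessConfig:
    return PreprocessConfig()


@pytest.fixture(scope="session")
def ulcer_scene():
    """One medium-style scene: single ulcer blob, eyelid arc, reflections."""
    params = SceneParams(
        border=EyeBorderFit(center=(120.0, 160.0), semi_major=105.0, semi_minor=66.0),
        ulcer_blobs=[UlcerBlob(center=(118.0, 150.0), semi_axes=(11.0, 13.0), peak=0.9)],
        eyelid_arc=EyelidArc(extent=1.2),
        noise_sigma=0.02,
        seed=1,
    )
    return generate_scene(params)


@pytest.fixture(scope="session")
def healthy_scene():
    params = SceneParams(
        border=EyeBorderFit(center=(121.0, 159.0), semi_major=108.0, semi_minor=63.0),
        ulcer_blobs=[],
        eyelid_arc=None,
        noise_sigma=0.01,
        seed=2,
    )
    return generate_scene(params)


@pytest.fixture(scope="session")
def arc_only_scene():
    """Eyelid stain but no ulcer: the rejection path must fire, mask stays empty."""
    params = SceneParams(
        border=EyeBorderFit(center=(119.0, 161.0), semi_major=102.0, semi_minor=68.0),
        ulcer_blobs=[],
        eyelid_arc=EyelidArc(extent=1.3),
        noise_sigma=0.02,
        seed=3,
    )
    return generate_scene(params)


def rgb_canvas(h: int = 64, w: int = 64, value=(0.5, 0.5, 0.5)) -> np.ndarray:
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = value
    return img
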