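"""Shared fixtures: rendered scenes and full tracking runs (session-scoped,
generated programmatically — nothing is stored in the repository)."""

import numpy as np
import pytest

from blurtrack.pipeline import RunConfig, Tracker
from blurtrack.synthetic_scenes import (
    _Renderer,
    default_scene,
    make_fixture_suite,
    simulate_trajectory,
)


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """The on-disk fixture suite at reduced test scale (512x512, 100 frames)."""
    out = tmp_path_factory.mktemp("fixtures")
    produced = make_fixture_suite(out, n_frames=100, resolution=(512, 512), seed=0)
    return produced


def run_tracker(kind, n_frames=100, resolution=(512, 512), seed=0,
                config=None):
    spec = default_scene(kind, n_frames=n_frames, resolution=resolution, seed=seed)
    truth = simulate_trajectory(spec)
    renderer = _Renderer(spec)
    tracker = Tracker(spec.rig, config or RunConfig(use_kalman=False, seed=1))
    for f in range(spec.n_frames):
        img0, img1 = renderer.frame_pair(truth, f)
        tracker.process_frame_pair(img0, img1)
    return spec, truth, tracker


@pytest.fixture(scope="session")
def single_object_run():
    """Full pipeline over the feature-rich single-object scene (in memory)."""
    return run_tracker("feature_rich", n_frames=100)


@pytest.fixture(scope="session")
def two_object_run():
    return run_tracker("two_object", n_frames=80)


@pytest.fixture(scope="session")
def static_run():
    return run_tracker("static", n_frames=50)
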