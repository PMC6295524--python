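"""Shared fixtures: small synthetic sessions reused across test modules.

Session-scoped fixtures hold the expensive artifacts (long trajectories,
rendered multi-camera sessions) so each is built once per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from arenatrack import synth


@pytest.fixture(scope="session")
def small_arena() -> synth.ArenaSpec:
    return synth.ArenaSpec(60.0, 60.0)


@pytest.fixture(scope="session")
def foraging(small_arena):
    """600-s foraging path plus its 30-Hz frame-grid samples."""
    traj = synth.simulate_trajectory(small_arena, 600.0, mean_speed=12.0, seed=11)
    frame_times = np.arange(0.0, 600.0, 1.0 / 30.0)
    positions, head_directions = traj.at(frame_times)
    d = np.gradient(positions, frame_times, axis=0)
    speeds = np.hypot(d[:, 0], d[:, 1])
    return {
        "arena": small_arena,
        "traj": traj,
        "frame_times": frame_times,
        "positions": positions,
        "head_directions": head_directions,
        "speeds": speeds,
    }


@pytest.fixture(scope="session")
def place_cell_spikes(foraging):
    """A clearly tuned place cell recorded on the foraging session."""
    spec = synth.NeuronSpec("place", peak_rate=12.0, baseline_rate=0.1,
                            center_cm=(20.0, 40.0), sigma_cm=7.0)
    spikes, _ = synth.simulate_spikes(foraging["traj"], spec, seed=21)
    return spec, spikes


@pytest.fixture(scope="session")
def four_camera_rig(small_arena):
    return synth.make_camera_grid(small_arena, 2, 2, image_size=(320, 240),
                                  overlap=0.4, seed=5)


def ground_truth_registrations(cameras):
    """Pixel->cm registrations from the cameras' known homographies."""
    from arenatrack.registration import CameraRegistration
    return {cam.camera_id: CameraRegistration(cam.camera_id,
                                              np.linalg.inv(cam.homography))
            for cam in cameras}
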