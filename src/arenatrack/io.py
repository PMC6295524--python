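"""On-disk session layout.

Each recording subunit produces three files: a video (here a PNG frame
stack under ``frames/`` or, optionally, an FFV1/AVI container via
imageio) plus ``frametimes.csv`` (frame_index, device_time_s) and
``ttl.csv`` (transition_index, state, device_time_s).  Synthetic sessions
additionally write ``groundtruth.csv`` (time_s, x_cm, y_cm, hd_deg) and a
``scene.yaml`` config for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .timesync import FrameTimestampSeries


def write_frametimes_csv(path, series: FrameTimestampSeries) -> None:
    pd.DataFrame({
        "frame_index": np.arange(len(series)),
        "device_time_s": series.times,
    }).to_csv(path, index=False)


def read_frametimes_csv(path, camera_id: str, nominal_rate: float) -> FrameTimestampSeries:
    df = pd.read_csv(path)
    return FrameTimestampSeries(camera_id, df["device_time_s"].to_numpy(), nominal_rate)


def write_ttl_csv(path, times: np.ndarray, states: np.ndarray) -> None:
    pd.DataFrame({
        "transition_index": np.arange(len(times)),
        "state": np.asarray(states, dtype=int),
        "device_time_s": np.asarray(times, dtype=float),
    }).to_csv(path, index=False)


def read_ttl_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["device_time_s"].to_numpy(), df["state"].to_numpy()


def write_groundtruth_csv(path, times, positions, head_directions) -> None:
    pd.DataFrame({
        "time_s": times,
        "x_cm": np.asarray(positions)[:, 0],
        "y_cm": np.asarray(positions)[:, 1],
        "hd_deg": head_directions,
    }).to_csv(path, index=False)


def write_camera_dir(outdir, recording, write_video: bool = True,
                     video_format: str = "png") -> Path:
    """Write one camera's triple (video + frametimes + ttl) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_frametimes_csv(outdir / "frametimes.csv", recording.device_frames)
    write_ttl_csv(outdir / "ttl.csv", recording.ttl_device, recording.ttl_states)
    if write_video:
        if video_format == "png":
            frames_dir = outdir / "frames"
            frames_dir.mkdir(exist_ok=True)
            for i in range(len(recording)):
                iio.imwrite(frames_dir / f"frame_{i:06d}.png", recording.frame(i))
        else:
            iio.imwrite(outdir / "video.avi",
                        np.stack([recording.frame(i) for i in range(len(recording))]),
                        plugin="pyav", codec="ffv1")
    return outdir


class FrameStackReader:
    """Reads a PNG frame stack written by :func:`write_camera_dir`."""

    def __init__(self, frames_dir):
        self.paths = sorted(Path(frames_dir).glob("frame_*.png"))
        if not self.paths:
            raise FileNotFoundError(f"no frames found under {frames_dir}")

    def __len__(self) -> int:
        return len(self.paths)

    def frame(self, i: int) -> np.ndarray:
        return iio.imread(self.paths[i])


def write_session(outdir, recordings: dict, trajectory=None, config: dict | None = None,
                  write_video: bool = True) -> Path:
    """Write a full multi-camera synthetic session directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cam_id, rec in recordings.items():
        write_camera_dir(outdir / cam_id, rec, write_video=write_video)
    if trajectory is not None:
        write_groundtruth_csv(outdir / "groundtruth.csv", trajectory.times,
                              trajectory.positions, trajectory.head_directions)
    if config is not None:
        with open(outdir / "scene.yaml", "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=False)
    return outdir


def write_json(path, obj: dict, schema: str | None = None) -> None:
    if schema is not None:
        obj = {"schema": schema, **obj}
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
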