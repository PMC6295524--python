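"""Frame-timestamp synchronization and interframe-interval diagnostics.

Each camera subunit logs its frame times on its own device clock together
with the times of shared TTL transitions.  The acquisition system logs the
same TTL transitions on its clock.  Pairing transitions by index yields a
piecewise-linear map from device time to acquisition time, which corrects
both the gross start offset and any residual clock drift.

The module also quantifies timing quality: interframe-interval (IFI)
deviations from the nominal interval, jitter (the min/max deviation range),
dropped frames, and the relative frame-time lag across cameras.  A
jitter-injection resampler replaces a camera's IFIs with draws from an
empirical IFI pool, which is how the degradation experiments emulate a
noisier camera on top of real (or synthetic) tracking data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class FrameTimestampSeries:
    """Per-camera frame times (seconds) on some clock, with nominal rate."""

    camera_id: str
    times: np.ndarray
    nominal_rate: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def expected_ifi(self) -> float:
        return 1.0 / self.nominal_rate

    def __len__(self) -> int:
        return self.times.size


@dataclass
class ClockMap:
    """Paired TTL transition times: device clock vs acquisition clock.

    Transitions are paired by index.  The map is piecewise linear between
    pairs; outside the covered interval the offset of the nearest pair is
    held constant.
    """

    device_times: np.ndarray
    acquisition_times: np.ndarray

    def __post_init__(self) -> None:
        self.device_times = np.asarray(self.device_times, dtype=float)
        self.acquisition_times = np.asarray(self.acquisition_times, dtype=float)
        if self.device_times.size == 0:
            raise ValueError("ClockMap needs at least one TTL pair")
        if self.device_times.shape != self.acquisition_times.shape:
            raise ValueError("device and acquisition logs must pair one-to-one")
        for name, t in (("device", self.device_times),
                        ("acquisition", self.acquisition_times)):
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"{name} TTL times must be strictly increasing")

    @property
    def offsets(self) -> np.ndarray:
        """acquisition − device at each TTL pair."""
        return self.acquisition_times - self.device_times

    @property
    def first_offset(self) -> float:
        """Instantaneous offset at the first logged transition."""
        return float(self.offsets[0])

    def to_acquisition(self, device_t: np.ndarray) -> np.ndarray:
        """Map device-clock times onto the acquisition clock."""
        device_t = np.asarray(device_t, dtype=float)
        # np.interp holds the edge values, giving constant-offset
        # extrapolation outside the TTL-covered interval.
        offset = np.interp(device_t, self.device_times, self.offsets)
        return device_t + offset


@dataclass
class JitterReport:
    """IFI deviation diagnostics for one timestamp series."""

    camera_id: str
    expected_ifi: float
    deviations: np.ndarray
    jitter_range: tuple[float, float]
    dropped_frames: int
    threshold_fractions: dict[float, float] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "camera_id": self.camera_id,
            "expected_ifi_s": self.expected_ifi,
            "jitter_min_s": self.jitter_range[0],
            "jitter_max_s": self.jitter_range[1],
            "dropped_frames": self.dropped_frames,
            "n_intervals": int(self.deviations.size),
            "fraction_beyond": {str(k): v for k, v in self.threshold_fractions.items()},
        }


def build_clock_map(device_ttl: np.ndarray, daq_ttl: np.ndarray,
                    device_states: np.ndarray | None = None,
                    daq_states: np.ndarray | None = None) -> ClockMap:
    """Pair TTL transition logs by index into a :class:`ClockMap`.

    Unequal transition counts are truncated to the common prefix with a
    warning; non-alternating state sequences raise a warning but do not
    invalidate the pairing.
    """
    device_ttl = np.asarray(device_ttl, dtype=float)
    daq_ttl = np.asarray(daq_ttl, dtype=float)
    if device_ttl.size == 0 or daq_ttl.size == 0:
        raise ValueError("TTL transition logs must be nonempty")
    n = min(device_ttl.size, daq_ttl.size)
    if device_ttl.size != daq_ttl.size:
        warnings.warn(
            f"TTL logs have {device_ttl.size} vs {daq_ttl.size} transitions; "
            f"truncating to common prefix of {n}", stacklevel=2)
    for name, states in (("device", device_states), ("acquisition", daq_states)):
        if states is not None:
            states = np.asarray(states)[:n]
            if states.size > 1 and np.any(states[1:] == states[:-1]):
                warnings.warn(f"{name} TTL states do not alternate", stacklevel=2)
    return ClockMap(device_ttl[:n], daq_ttl[:n])


def align_timestamps(frames: FrameTimestampSeries, clock_map: ClockMap) -> FrameTimestampSeries:
    """Re-express frame times on the acquisition clock.

    With a single TTL pair this degenerates to a pure offset correction;
    with two or more pairs the correction is exact whenever the device
    clock is an affine function of the acquisition clock.
    """
    aligned = clock_map.to_acquisition(frames.times)
    return FrameTimestampSeries(frames.camera_id, aligned, frames.nominal_rate)


def ifi_report(frames: FrameTimestampSeries,
               thresholds: tuple[float, ...] = (0.001,),
               drop_tolerance: float = 0.25) -> JitterReport:
    """IFI deviations, jitter range and dropped-frame count.

    deviation_i = (t_{i+1} − t_i) − expected IFI.  An IFI within
    ``drop_tolerance`` (default ±25%) of k × expected IFI for integer
    k ≥ 2 is counted as k − 1 dropped frames, and its deviation is not
    folded into the jitter range (a drop is a loss, not jitter).
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames to compute IFIs")
    ifis = np.diff(frames.times)
    expected = frames.expected_ifi
    deviations = ifis - expected

    k = np.rint(ifis / expected).astype(int)
    is_drop = (k >= 2) & (np.abs(ifis - k * expected) <= drop_tolerance * expected)
    dropped = int(np.sum(k[is_drop] - 1))

    jitter_devs = deviations[~is_drop]
    if jitter_devs.size:
        jrange = (float(jitter_devs.min()), float(jitter_devs.max()))
    else:
        jrange = (0.0, 0.0)
    fractions = {
        float(th): float(np.mean(np.abs(jitter_devs) > th)) if jitter_devs.size else 0.0
        for th in thresholds
    }
    return JitterReport(frames.camera_id, expected, deviations, jrange, dropped, fractions)


def inject_jitter(frames: FrameTimestampSeries, ifi_pool: np.ndarray,
                  seed: int | np.random.Generator = 0) -> FrameTimestampSeries:
    """Replace a series' IFIs with resampled draws from an empirical pool.

    IFIs are drawn i.i.d. with replacement from ``ifi_pool`` and rescaled
    by a single factor so that the total duration matches the input,
    keeping downstream spike times inside the video span.  Frame count is
    conserved and the first frame time is unchanged.
    """
    pool = np.asarray(ifi_pool, dtype=float)
    if pool.size == 0:
        raise ValueError("IFI pool must be nonempty")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_ifis = len(frames) - 1
    if n_ifis <= 0:
        return FrameTimestampSeries(frames.camera_id, frames.times.copy(), frames.nominal_rate)
    draws = rng.choice(pool, size=n_ifis, replace=True)
    span = frames.times[-1] - frames.times[0]
    draws *= span / draws.sum()
    times = frames.times[0] + np.concatenate([[0.0], np.cumsum(draws)])
    return FrameTimestampSeries(frames.camera_id, times, frames.nominal_rate)


def sample_empirical_ifis(pool: np.ndarray, n: int,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``n`` IFIs i.i.d. with replacement from an empirical pool."""
    pool = np.asarray(pool, dtype=float)
    if pool.size == 0:
        raise ValueError("IFI pool must be nonempty")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.choice(pool, size=n, replace=True)


def intercamera_lag_report(series: list[FrameTimestampSeries]) -> dict:
    """Start lag and per-frame time difference vs the earliest-starting camera.

    Frames are compared index-matched after alignment; unequal frame counts
    are truncated to the common prefix (reported as ``truncated_to``).
    """
    if len(series) < 2:
        raise ValueError("need at least two cameras")
    starts = [s.times[0] for s in series]
    ref_idx = int(np.argmin(starts))
    ref = series[ref_idx]
    n_common = min(len(s) for s in series)
    truncated = any(len(s) != n_common for s in series)
    report = {
        "reference_camera": ref.camera_id,
        "truncated_to": n_common if truncated else None,
        "cameras": {},
    }
    for s in series:
        if s is ref:
            continue
        diff = s.times[:n_common] - ref.times[:n_common]
        report["cameras"][s.camera_id] = {
            "start_lag_s": float(s.times[0] - ref.times[0]),
            "frame_diffs_s": diff,
            "median_s": float(np.median(diff)),
            "min_s": float(diff.min()),
            "max_s": float(diff.max()),
        }
    return report
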