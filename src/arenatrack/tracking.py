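"""LED position tracking across one or more registered cameras.

Detection follows an intensity-threshold-then-color scheme: pixels whose
brightest channel crosses a predefined intensity threshold are converted
to HSV, red and green masks are taken over configurable HSV ranges (hue
on the 0-180 scale), and the centroid of the largest connected component
of each mask gives that camera's LED estimate for the frame.  Per-camera
estimates are warped onto the shared canvas and averaged; thresholding
unaveraged per-camera frames before averaging positions is what makes the
tracker robust to occlusions that hide the LED from some cameras but not
others.  Head direction is the angle of the green-to-red (posterior to
anterior) vector; speed is a smoothed central difference of the merged
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .registration import CameraRegistration, warp_point
from .timesync import FrameTimestampSeries


@dataclass
class HsvRange:
    """HSV acceptance window; hue may wrap (union of two intervals).

    Hue is on the 0-180 scale, saturation and value on 0-255.
    """

    hue: tuple[tuple[float, float], ...]
    sat: tuple[float, float] = (0.0, 255.0)
    val: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        for lo, hi in self.hue:
            if not (0 <= lo <= hi <= 180):
                raise ValueError("hue bounds must lie in [0, 180]")
        for lo, hi in (self.sat, self.val):
            if not (0 <= lo <= hi <= 255):
                raise ValueError("sat/val bounds must lie in [0, 255]")

    def mask(self, h: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
        hue_ok = np.zeros(h.shape, dtype=bool)
        for lo, hi in self.hue:
            hue_ok |= (h >= lo) & (h <= hi)
        return (hue_ok & (s >= self.sat[0]) & (s <= self.sat[1])
                & (v >= self.val[0]) & (v <= self.val[1]))


# the published detection windows for the two head LEDs
RED_HSV = HsvRange(hue=((0.0, 10.0), (160.0, 180.0)), sat=(100.0, 255.0), val=(50.0, 255.0))
GREEN_HSV = HsvRange(hue=((50.0, 70.0),), sat=(50.0, 255.0), val=(100.0, 255.0))

DEFAULT_INTENSITY_THRESHOLD = 50.0
MIN_CLUSTER_PX = 3


@dataclass
class LedDetection:
    """One LED's detection in one camera frame."""

    camera_id: str
    frame_index: int
    color: str
    centroid_px: tuple[float, float] | None
    pixel_count: int

    @property
    def present(self) -> bool:
        return self.centroid_px is not None and self.pixel_count >= MIN_CLUSTER_PX


@dataclass
class TrackedSession:
    """Merged tracking output, one row per reference-camera frame."""

    data: pd.DataFrame = field(repr=False)

    COLUMNS = ("time_s", "red_x_cm", "red_y_cm", "green_x_cm", "green_y_cm",
               "x_cm", "y_cm", "hd_deg", "speed_cms", "n_cameras")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"TrackedSession missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return self.data["time_s"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.data[["x_cm", "y_cm"]].to_numpy()

    @property
    def speeds(self) -> np.ndarray:
        return self.data["speed_cms"].to_numpy()

    @property
    def head_directions(self) -> np.ndarray:
        return self.data["hd_deg"].to_numpy()

    @property
    def coverage(self) -> float:
        """Fraction of frames with a tracked (non-missing) position."""
        return float(np.isfinite(self.positions[:, 0]).mean())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrackedSession":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# per-frame detection


def rgb_to_hsv_cv(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RGB (uint8) -> HSV with hue 0-180, sat/val 0-255."""
    arr = rgb.astype(float) / 255.0
    maxc = arr.max(axis=-1)
    minc = arr.min(axis=-1)
    delta = maxc - minc
    h = np.zeros_like(maxc)
    nz = delta > 0
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    rmax = nz & (maxc == r)
    gmax = nz & ~rmax & (maxc == g)
    bmax = nz & ~rmax & ~gmax
    h[rmax] = ((g - b)[rmax] / delta[rmax]) % 6.0
    h[gmax] = (b - r)[gmax] / delta[gmax] + 2.0
    h[bmax] = (r - g)[bmax] / delta[bmax] + 4.0
    h *= 30.0  # 60 deg per sextant on the halved OpenCV-style scale
    s = np.where(maxc > 0, delta / np.where(maxc > 0, maxc, 1.0), 0.0) * 255.0
    v = maxc * 255.0
    return h, s, v


def detect_leds(frame: np.ndarray,
                intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD,
                red: HsvRange = RED_HSV, green: HsvRange = GREEN_HSV,
                camera_id: str = "", frame_index: int = 0,
                ) -> dict[str, LedDetection]:
    """Detect the red and green LED in one color frame.

    Candidate pixels are those whose maximum channel reaches the
    intensity threshold; within candidates the HSV windows select each
    color, and the centroid of the largest connected component (8-conn)
    is reported.  Components below 3 px are treated as absent.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("frame must be a 3-channel color image")
    candidates = frame.max(axis=2) >= intensity_threshold
    out: dict[str, LedDetection] = {}
    if not candidates.any():
        for color in ("red", "green"):
            out[color] = LedDetection(camera_id, frame_index, color, None, 0)
        return out
    # HSV conversion restricted to candidate pixels (LED blobs are tiny
    # relative to the frame, so this dominates per-frame cost otherwise)
    ys, xs = np.nonzero(candidates)
    h, s, v = rgb_to_hsv_cv(frame[ys, xs].astype(float))
    for color, rng_ in (("red", red), ("green", green)):
        sel = rng_.mask(h, s, v)
        if not sel.any():
            out[color] = LedDetection(camera_id, frame_index, color, None, 0)
            continue
        # label within the bounding box of the color mask only
        cy, cx = ys[sel], xs[sel]
        y0, x0 = cy.min(), cx.min()
        mask = np.zeros((cy.max() - y0 + 1, cx.max() - x0 + 1), dtype=bool)
        mask[cy - y0, cx - x0] = True
        centroid, count = _largest_component_centroid(mask)
        if centroid is not None:
            centroid = (centroid[0] + x0, centroid[1] + y0)
        out[color] = LedDetection(camera_id, frame_index, color, centroid, count)
    return out


def _largest_component_centroid(mask: np.ndarray
                                ) -> tuple[tuple[float, float] | None, int]:
    if not mask.any():
        return None, 0
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    count = int(sizes[best - 1])
    if count < MIN_CLUSTER_PX:
        return None, count
    ys, xs = np.nonzero(labels == best)
    return (float(xs.mean()), float(ys.mean())), count


# ---------------------------------------------------------------------------
# merging across cameras


def merge_positions(detections: dict[str, LedDetection],
                    regs: dict[str, CameraRegistration],
                    ) -> tuple[np.ndarray, int]:
    """Average the canvas-warped centroids of the cameras that saw an LED.

    Returns ``(merged_xy_cm, n_contributing)``; the position is NaN when
    no camera detected the LED.  A camera with no detection never
    influences the merge.
    """
    pts = []
    for cam_id, det in detections.items():
        if det.present:
            pts.append(warp_point(np.asarray(det.centroid_px), regs[cam_id])[0])
    if not pts:
        return np.array([np.nan, np.nan]), 0
    return np.mean(pts, axis=0), len(pts)


def head_direction(red_cm: np.ndarray, green_cm: np.ndarray) -> float:
    """Heading (deg, CCW from +x) of the green->red (posterior->anterior) vector."""
    red_cm = np.asarray(red_cm, dtype=float)
    green_cm = np.asarray(green_cm, dtype=float)
    d = red_cm - green_cm
    if not np.all(np.isfinite(d)) or np.hypot(*d) == 0:
        return np.nan
    return float(np.rad2deg(np.arctan2(d[1], d[0])) % 360.0)


# ---------------------------------------------------------------------------
# speed


def compute_speed(times: np.ndarray, positions: np.ndarray,
                  smoothing_window: int = 5) -> np.ndarray:
    """Central-difference speed (cm/s), boxcar smoothed.

    Missing positions propagate to missing speed.
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least two tracked frames")
    vx = np.gradient(positions[:, 0], times)
    vy = np.gradient(positions[:, 1], times)
    speed = np.hypot(vx, vy)
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        finite = np.isfinite(speed)
        filled = np.where(finite, speed, 0.0)
        num = np.convolve(filled, kernel, mode="same")
        den = np.convolve(finite.astype(float), kernel, mode="same")
        with np.errstate(invalid="ignore"):
            smooth = num / den
        smooth[~finite] = np.nan
        speed = smooth
    return speed


# ---------------------------------------------------------------------------
# session orchestration


def track_session(recordings: dict, regs: dict[str, CameraRegistration],
                  aligned_times: dict[str, np.ndarray] | None = None,
                  intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD,
                  red: HsvRange = RED_HSV, green: HsvRange = GREEN_HSV,
                  max_gap_frames: int = 5,
                  reference_camera: str | None = None,
                  speed_window: int = 5) -> TrackedSession:
    """Full pipeline: detect per camera, warp, merge, derive HD and speed.

    ``recordings`` maps camera id to an object with ``frame(i)`` and
    ``__len__``  (e.g. a synthetic :class:`~arenatrack.synth.CameraRecording`
    or a frame-stack reader).  ``aligned_times`` gives each camera's frame
    times on the acquisition clock; if omitted, synthetic recordings'
    true acquisition times are used.  Frames from non-reference cameras
    are associated to each reference frame by nearest aligned timestamp
    within half an expected IFI.

    Gaps in the merged position up to ``max_gap_frames`` are linearly
    interpolated (set to 0 to disable).
    """
    if not recordings:
        raise ValueError("no recordings supplied")
    if aligned_times is None:
        aligned_times = {cid: rec.acquisition_times for cid, rec in recordings.items()}
    for cid, rec in recordings.items():
        if len(rec) == 0:
            raise ValueError(f"camera {cid} has no frames")

    if reference_camera is None:
        reference_camera = min(aligned_times, key=lambda c: aligned_times[c][0])
    ref_times = aligned_times[reference_camera]
    n = len(ref_times)
    rates = [getattr(rec, "camera", None) for rec in recordings.values()]
    nominal_rate = next((c.frame_rate for c in rates if c is not None), 30.0)
    half_ifi = 0.5 / nominal_rate

    # index of the nearest frame of each camera for each reference time
    frame_idx: dict[str, np.ndarray] = {}
    for cid, t in aligned_times.items():
        pos = np.searchsorted(t, ref_times)
        pos = np.clip(pos, 1, len(t) - 1)
        left, right = t[pos - 1], t[pos]
        idx = np.where(ref_times - left <= right - ref_times, pos - 1, pos)
        dt = np.abs(t[idx] - ref_times)
        idx = idx.astype(float)
        idx[dt > half_ifi] = np.nan
        frame_idx[cid] = idx

    rows = np.full((n, 7), np.nan)  # red_x, red_y, green_x, green_y, x, y, hd
    n_cams = np.zeros(n, dtype=int)
    for i in range(n):
        dets_red: dict[str, LedDetection] = {}
        dets_green: dict[str, LedDetection] = {}
        for cid, rec in recordings.items():
            j = frame_idx[cid][i]
            if np.isnan(j):
                continue
            d = detect_leds(rec.frame(int(j)), intensity_threshold, red, green,
                            camera_id=cid, frame_index=int(j))
            dets_red[cid] = d["red"]
            dets_green[cid] = d["green"]
        red_cm, n_red = merge_positions(dets_red, regs)
        green_cm, n_green = merge_positions(dets_green, regs)
        rows[i, 0:2] = red_cm
        rows[i, 2:4] = green_cm
        n_cams[i] = max(n_red, n_green)
        if np.all(np.isfinite(red_cm)) and np.all(np.isfinite(green_cm)):
            rows[i, 4:6] = (red_cm + green_cm) / 2.0
            rows[i, 6] = head_direction(red_cm, green_cm)
        elif np.all(np.isfinite(red_cm)):
            rows[i, 4:6] = red_cm
        elif np.all(np.isfinite(green_cm)):
            rows[i, 4:6] = green_cm

    if max_gap_frames > 0:
        for col in range(6):
            rows[:, col] = _interpolate_gaps(ref_times, rows[:, col], max_gap_frames)

    speed = compute_speed(ref_times, rows[:, 4:6], smoothing_window=speed_window)
    df = pd.DataFrame({
        "time_s": ref_times,
        "red_x_cm": rows[:, 0], "red_y_cm": rows[:, 1],
        "green_x_cm": rows[:, 2], "green_y_cm": rows[:, 3],
        "x_cm": rows[:, 4], "y_cm": rows[:, 5],
        "hd_deg": rows[:, 6], "speed_cms": speed,
        "n_cameras": n_cams,
    })
    return TrackedSession(df)


def _interpolate_gaps(times: np.ndarray, values: np.ndarray,
                      max_gap: int) -> np.ndarray:
    """Linearly fill NaN runs of length <= max_gap (interior only)."""
    out = values.copy()
    isnan = np.isnan(values)
    if not isnan.any() or isnan.all():
        return out
    idx = np.flatnonzero(isnan)
    # split into consecutive runs
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    good = ~isnan
    for run in runs:
        lo, hi = run[0] - 1, run[-1] + 1
        if lo < 0 or hi >= len(values) or len(run) > max_gap:
            continue
        if good[lo] and good[hi]:
            out[run] = np.interp(times[run], [times[lo], times[hi]],
                                 [values[lo], values[hi]])
    return out
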