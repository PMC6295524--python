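"""Synthetic recording sessions with known ground truth.

Everything the tracking and analysis pipeline consumes can be generated
here: a foraging trajectory in a rectangular arena, two head-mounted LEDs
rendered into overlapping camera views under known homographies,
per-camera clocks with configurable offset/drift/IFI jitter and frame
drops, TTL synchronization logs, calibration scenes with matchable
texture, and Poisson spike trains from place, head-direction and
theta-phase-precessing cells.

The generators are deterministic under a fixed seed, and each returns the
ground truth (true LED canvas positions, true feature coordinates, true
tuning parameters) alongside the rendered data so that every downstream
estimate can be checked against what generated it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .registration import apply_homography
from .timesync import FrameTimestampSeries

# ---------------------------------------------------------------------------
# domain types


@dataclass
class Occluder:
    """Axis-aligned rectangle (cm) that blocks the listed cameras' view."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    blocks: tuple[str, ...] = ()

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return ((xy[:, 0] >= self.x_min) & (xy[:, 0] <= self.x_max)
                & (xy[:, 1] >= self.y_min) & (xy[:, 1] <= self.y_max))


@dataclass
class ArenaSpec:
    """Rectangular arena in canvas centimetres."""

    width: float
    height: float
    occluders: list[Occluder] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("arena dimensions must be positive")
        for occ in self.occluders:
            if not (0 <= occ.x_min < occ.x_max <= self.width
                    and 0 <= occ.y_min < occ.y_max <= self.height):
                raise ValueError("occluders must lie inside the arena")


@dataclass
class CameraModel:
    """A single overhead camera: geometry plus clock behaviour.

    ``homography`` maps canvas cm -> image pixels.  The device clock runs
    as ``device_t = clock_offset + (1 + drift_rate) * acquisition_t``.
    ``ifi_sampler(rng, n)``, if given, returns n interframe intervals (s);
    otherwise intervals are exactly 1/frame_rate.
    """

    camera_id: str
    homography: np.ndarray
    image_size: tuple[int, int] = (640, 480)  # (width, height) px
    frame_rate: float = 30.0
    clock_offset: float = 0.0
    drift_rate: float = 0.0
    ifi_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None
    frame_drop_prob: float = 0.0

    def __post_init__(self) -> None:
        self.homography = np.asarray(self.homography, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(self.homography)) < 1e-15:
            raise ValueError("camera homography must be invertible")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        if not 0 <= self.frame_drop_prob < 1:
            raise ValueError("frame_drop_prob must be in [0, 1)")

    def project(self, canvas_xy: np.ndarray) -> np.ndarray:
        """Canvas cm -> image px."""
        return apply_homography(self.homography, canvas_xy)

    def in_view(self, canvas_xy: np.ndarray, margin: float = 0.0) -> np.ndarray:
        px = self.project(canvas_xy)
        w, h = self.image_size
        return ((px[:, 0] >= -margin) & (px[:, 0] <= w - 1 + margin)
                & (px[:, 1] >= -margin) & (px[:, 1] <= h - 1 + margin))


@dataclass
class Trajectory:
    """Ground-truth animal path on a uniform fine time grid."""

    times: np.ndarray        # s
    positions: np.ndarray    # (n, 2) cm
    head_directions: np.ndarray  # deg [0, 360)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.head_directions = np.asarray(self.head_directions, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def at(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Interpolated (positions, head directions) at times ``t``."""
        t = np.asarray(t, dtype=float)
        x = np.interp(t, self.times, self.positions[:, 0])
        y = np.interp(t, self.times, self.positions[:, 1])
        # circular interpolation of heading via unwrap
        hd_unwrapped = np.unwrap(np.deg2rad(self.head_directions))
        hd = np.rad2deg(np.interp(t, self.times, hd_unwrapped)) % 360.0
        return np.column_stack([x, y]), hd

    def speeds(self) -> np.ndarray:
        """Instantaneous ground-truth speed (cm/s), same length as times."""
        d = np.gradient(self.positions, self.times, axis=0)
        return np.hypot(d[:, 0], d[:, 1])


@dataclass
class NeuronSpec:
    """Ground-truth tuning of a simulated neuron.

    kind 'place': Gaussian spatial field (center_cm, sigma_cm).
    kind 'head_direction': von Mises tuning (preferred_deg, kappa).
    kind 'phase_precessing': place field whose spikes' theta phase falls
    linearly with signed distance traversed through the field
    (phase_slope_deg_per_cm, typically negative).
    """

    kind: str
    peak_rate: float
    baseline_rate: float = 0.0
    center_cm: tuple[float, float] | None = None
    sigma_cm: float | None = None
    preferred_deg: float | None = None
    kappa: float = 4.0
    phase_slope_deg_per_cm: float = -10.0
    phase_offset_deg: float = 180.0
    phase_kappa: float = 1.5

    def __post_init__(self) -> None:
        if self.kind not in ("place", "head_direction", "phase_precessing"):
            raise ValueError(f"unknown neuron kind {self.kind!r}")
        if self.peak_rate < 0 or self.baseline_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.kind in ("place", "phase_precessing"):
            if self.center_cm is None or self.sigma_cm is None or self.sigma_cm <= 0:
                raise ValueError("place-type neurons need center_cm and sigma_cm > 0")
        if self.kind == "head_direction" and self.preferred_deg is None:
            raise ValueError("head_direction neurons need preferred_deg")


# ---------------------------------------------------------------------------
# trajectory simulation


def simulate_trajectory(arena: ArenaSpec, duration: float, mean_speed: float = 10.0,
                        seed: int | np.random.Generator = 0, dt: float = 0.02,
                        tau: float = 1.0, start: tuple[float, float] | None = None,
                        ) -> Trajectory:
    """Smoothed random-walk foraging path, reflected at the arena walls.

    Velocity follows an Ornstein-Uhlenbeck process with relaxation time
    ``tau`` whose stationary speed distribution (2D Rayleigh) has the
    requested mean.  The walk reflects off walls, which preserves the
    speed distribution and yields dense, near-uniform occupancy over long
    sessions -- the regime the rate-map analysis assumes.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if mean_speed < 0:
        raise ValueError("mean_speed must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration / dt)) + 1
    times = np.arange(n) * dt
    if start is None:
        start = (arena.width / 2.0, arena.height / 2.0)
    pos = np.empty((n, 2))
    pos[0] = start
    if mean_speed == 0:
        pos[:] = start
        hd = np.zeros(n)
        return Trajectory(times, pos, hd)

    # stationary per-axis sd so that E[speed] = sigma_v * sqrt(pi/2) = mean_speed
    sigma_v = mean_speed / np.sqrt(np.pi / 2.0)
    noise_sd = sigma_v * np.sqrt(2.0 * dt / tau)
    v = rng.normal(0.0, sigma_v, size=2)
    vel = np.empty((n, 2))
    vel[0] = v
    for i in range(1, n):
        v = v + (-v / tau) * dt + rng.normal(0.0, noise_sd, size=2)
        p = pos[i - 1] + v * dt
        # reflect at walls (possibly repeatedly for large steps)
        for ax, lim in ((0, arena.width), (1, arena.height)):
            while p[ax] < 0 or p[ax] > lim:
                if p[ax] < 0:
                    p[ax] = -p[ax]
                else:
                    p[ax] = 2 * lim - p[ax]
                v[ax] = -v[ax]
        pos[i] = p
        vel[i] = v
    hd = np.rad2deg(np.arctan2(vel[:, 1], vel[:, 0])) % 360.0
    return Trajectory(times, pos, hd)


def simulate_circular_trajectory(center: tuple[float, float], radius: float,
                                 duration: float, mean_speed: float = 10.0,
                                 seed: int | np.random.Generator = 0,
                                 dt: float = 0.02) -> Trajectory:
    """Unidirectional run around a circular track (for phase precession).

    Angular speed fluctuates slowly around mean_speed/radius but never
    reverses, so linearized position is monotone within each lap.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration / dt)) + 1
    times = np.arange(n) * dt
    omega0 = mean_speed / radius
    # smooth positive modulation of angular speed
    omega = omega0 * np.clip(1.0 + 0.2 * np.convolve(
        rng.normal(0, 1, n), np.ones(50) / 50.0, mode="same"), 0.3, None)
    theta = np.concatenate([[0.0], np.cumsum(omega[:-1]) * dt])
    pos = np.column_stack([center[0] + radius * np.cos(theta),
                           center[1] + radius * np.sin(theta)])
    hd = np.rad2deg(theta + np.pi / 2.0) % 360.0  # tangential, counterclockwise
    return Trajectory(times, pos, hd)


# ---------------------------------------------------------------------------
# clocks and TTL


def uniform_jitter_sampler(nominal_ifi: float, half_width_s: float
                           ) -> Callable[[np.random.Generator, int], np.ndarray]:
    """IFIs uniform in nominal ± half_width."""
    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return nominal_ifi + rng.uniform(-half_width_s, half_width_s, size=n)
    return sample


def pool_jitter_sampler(pool: np.ndarray
                        ) -> Callable[[np.random.Generator, int], np.ndarray]:
    """IFIs resampled with replacement from an empirical pool."""
    pool = np.asarray(pool, dtype=float)

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(pool, size=n, replace=True)
    return sample


def commercial_ifi_pool(nominal_ifi: float = 1.0 / 25.0, n: int = 20000,
                        seed: int | np.random.Generator = 12345) -> np.ndarray:
    """Synthetic stand-in for a frame-grabber camera's IFI distribution.

    The reference measurements characterize that camera only by a ±7 ms
    jitter range and ~40% of frames deviating by more than 1 ms, so this
    pool is a two-component mixture calibrated to those facts: 60% of
    IFIs tightly clustered (|dev| < 1 ms) and 40% spread uniformly over
    1-7 ms magnitude deviations of either sign.  It is approximate by
    construction; the full empirical distribution is not published.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_tight = int(round(0.6 * n))
    tight = rng.uniform(-0.0009, 0.0009, size=n_tight)
    mag = rng.uniform(0.001, 0.007, size=n - n_tight)
    sign = rng.choice([-1.0, 1.0], size=n - n_tight)
    dev = np.concatenate([tight, mag * sign])
    rng.shuffle(dev)
    return nominal_ifi + dev


def picamera_ifi_pool(nominal_ifi: float = 1.0 / 30.0, n: int = 20000,
                      seed: int | np.random.Generator = 54321) -> np.ndarray:
    """Synthetic low-jitter pool: deviations uniform within ±0.025 ms."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return nominal_ifi + rng.uniform(-2.5e-5, 2.5e-5, size=n)


def make_ttl_log(duration: float, period: float = 1.0,
                 start: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Regular TTL on/off transition train on the acquisition clock.

    Returns (transition_times_s, states) with states alternating 1, 0, ...
    """
    times = np.arange(start, duration, period / 2.0)
    states = np.tile([1, 0], (len(times) + 1) // 2)[:len(times)]
    return times, states


def device_clock(cam: CameraModel, acquisition_t: np.ndarray) -> np.ndarray:
    """Acquisition-clock times as read on this camera's device clock."""
    return cam.clock_offset + (1.0 + cam.drift_rate) * np.asarray(acquisition_t, float)


# ---------------------------------------------------------------------------
# rendering


LED_RED_RGB = (255, 0, 0)
LED_GREEN_RGB = (0, 255, 0)


@dataclass
class LedGeometry:
    """Head-mounted LED layout: red anterior, green posterior (cm)."""

    anterior_offset_cm: float = 2.5
    posterior_offset_cm: float = 2.5

    def led_positions(self, pos: np.ndarray, hd_deg: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
        """(red, green) canvas positions for animal positions + headings."""
        u = np.column_stack([np.cos(np.deg2rad(hd_deg)), np.sin(np.deg2rad(hd_deg))])
        red = pos + self.anterior_offset_cm * u
        green = pos - self.posterior_offset_cm * u
        return red, green


@dataclass
class CameraRecording:
    """One camera's synthetic output: frames on demand, timestamps, truth.

    Frames are rendered lazily (``frame(i)``) to keep long multi-camera
    sessions within memory.  ``device_frames`` carries the device-clock
    timestamps exactly as the recording subunit would log them;
    ``acquisition_times`` is the hidden truth used only for validation.
    """

    camera: CameraModel
    device_frames: FrameTimestampSeries
    acquisition_times: np.ndarray
    led_px: dict[str, np.ndarray]        # color -> (n, 2) px, NaN when not visible
    led_canvas: dict[str, np.ndarray]    # color -> (n, 2) cm ground truth
    ttl_device: np.ndarray
    ttl_states: np.ndarray
    noise_sd: float = 0.0
    led_radius_px: float = 3.0
    _noise_seed: int = 0

    def __len__(self) -> int:
        return len(self.acquisition_times)

    def frame(self, i: int) -> np.ndarray:
        w, h = self.camera.image_size
        img = np.zeros((h, w, 3), dtype=np.uint8)
        if self.noise_sd > 0:
            rng = np.random.default_rng((self._noise_seed, i))
            noise = rng.normal(0.0, self.noise_sd, size=(h, w, 3))
            img = np.clip(noise, 0, 80).astype(np.uint8)
        for color, rgb in (("red", LED_RED_RGB), ("green", LED_GREEN_RGB)):
            cx, cy = self.led_px[color][i]
            if np.isnan(cx):
                continue
            _draw_disc(img, cx, cy, self.led_radius_px, rgb)
        return img

    def frames(self):
        for i in range(len(self)):
            yield self.frame(i)


def _draw_disc(img: np.ndarray, cx: float, cy: float, radius: float,
               rgb: tuple[int, int, int]) -> None:
    h, w = img.shape[:2]
    x0, x1 = int(np.floor(cx - radius)) - 1, int(np.ceil(cx + radius)) + 2
    y0, y1 = int(np.floor(cy - radius)) - 1, int(np.ceil(cy + radius)) + 2
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
    img[y0:y1, x0:x1][mask] = rgb


def render_session(traj: Trajectory, cameras: Sequence[CameraModel],
                   led_geometry: LedGeometry | None = None,
                   arena: ArenaSpec | None = None,
                   ttl_period: float = 1.0,
                   noise_sd: float = 0.0,
                   seed: int | np.random.Generator = 0,
                   ) -> dict[str, CameraRecording]:
    """Render a tracked session into per-camera frames + timestamp logs.

    Each camera's frame times follow its own clock model (offset + drift
    + IFI jitter + frame drops).  Every frame shows the red and green LED
    discs at their homography-projected location, unless that LED is
    outside the camera's view or inside an occluder that blocks this
    camera.  TTL logs are generated on both the acquisition clock and
    each device clock for downstream synchronization.
    """
    if len(cameras) == 0:
        raise ValueError("need at least one camera")
    led_geometry = led_geometry or LedGeometry()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    duration = traj.duration
    ttl_acq, ttl_states = make_ttl_log(duration, period=ttl_period)

    recordings: dict[str, CameraRecording] = {}
    for cam in cameras:
        cam_rng = np.random.default_rng(rng.integers(2**31))
        nominal = 1.0 / cam.frame_rate
        n_frames = int(np.floor(duration / nominal)) + 1
        if cam.ifi_sampler is None:
            acq_times = traj.times[0] + np.arange(n_frames) * nominal
        else:
            ifis = cam.ifi_sampler(cam_rng, n_frames - 1)
            acq_times = traj.times[0] + np.concatenate([[0.0], np.cumsum(ifis)])
        acq_times = acq_times[acq_times <= traj.times[-1] + 1e-12]
        if cam.frame_drop_prob > 0:
            keep = cam_rng.random(len(acq_times)) >= cam.frame_drop_prob
            keep[0] = True
            acq_times = acq_times[keep]

        pos, hd = traj.at(acq_times)
        red_cm, green_cm = led_geometry.led_positions(pos, hd)
        led_px: dict[str, np.ndarray] = {}
        led_cm = {"red": red_cm, "green": green_cm}
        for color, cm_pos in led_cm.items():
            px = cam.project(cm_pos)
            visible = cam.in_view(cm_pos)
            if arena is not None:
                for occ in arena.occluders:
                    if cam.camera_id in occ.blocks:
                        visible &= ~occ.contains(cm_pos)
            px = px.copy()
            px[~visible] = np.nan
            led_px[color] = px

        recordings[cam.camera_id] = CameraRecording(
            camera=cam,
            device_frames=FrameTimestampSeries(
                cam.camera_id, device_clock(cam, acq_times), cam.frame_rate),
            acquisition_times=acq_times,
            led_px=led_px,
            led_canvas=led_cm,
            ttl_device=device_clock(cam, ttl_acq),
            ttl_states=ttl_states,
            noise_sd=noise_sd,
            _noise_seed=int(cam_rng.integers(2**31)),
        )
    return recordings


# ---------------------------------------------------------------------------
# calibration scenes


def make_camera_grid(arena: ArenaSpec, n_x: int, n_y: int,
                     image_size: tuple[int, int] = (640, 480),
                     overlap: float = 0.4,
                     perspective: float = 0.0,
                     margin: float = 0.05,
                     frame_rate: float = 30.0,
                     seed: int | np.random.Generator = 0,
                     **camera_kwargs) -> list[CameraModel]:
    """Regular n_x × n_y rig of overhead cameras covering the arena.

    Each camera images a rectangular patch (patches overlap by ``overlap``
    fraction in each direction, and extend ``margin`` fraction beyond
    their nominal tile so the union covers the arena robustly);
    ``perspective`` adds a small random projective component per camera
    so homographies are genuinely projective rather than affine.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    w_img, h_img = image_size
    cams = []
    patch_w = arena.width / (n_x - (n_x - 1) * overlap) if n_x > 1 else arena.width
    patch_h = arena.height / (n_y - (n_y - 1) * overlap) if n_y > 1 else arena.height
    step_x = patch_w * (1 - overlap)
    step_y = patch_h * (1 - overlap)
    for iy in range(n_y):
        for ix in range(n_x):
            x0 = ix * step_x - margin * patch_w
            y0 = iy * step_y - margin * patch_h
            pw = patch_w * (1 + 2 * margin)
            ph = patch_h * (1 + 2 * margin)
            sx = (w_img - 1) / pw
            sy = (h_img - 1) / ph
            H = np.array([[sx, 0.0, -sx * x0],
                          [0.0, sy, -sy * y0],
                          [0.0, 0.0, 1.0]])
            if perspective > 0:
                P = np.eye(3)
                P[2, :2] = rng.uniform(-perspective, perspective, size=2)
                # renormalize around the patch centre to keep it in frame
                H = H @ P
                H /= H[2, 2]
            cams.append(CameraModel(
                camera_id=f"cam{iy * n_x + ix + 1}",
                homography=H, image_size=image_size, frame_rate=frame_rate,
                **camera_kwargs))
    return cams


def generate_calibration_scene(cameras: Sequence[CameraModel], arena: ArenaSpec,
                               n_features: int = 120,
                               seed: int | np.random.Generator = 0,
                               texel_cm: float = 0.5,
                               ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """High-contrast textured floor imaged by every camera.

    A random grayscale texture ("patterned bedsheet") is laid over the
    arena and sampled through each camera's homography, giving frames
    with abundant locally unique features.  Additionally ``n_features``
    feature points are marked with bright discs at known canvas
    coordinates, which are returned as ground truth.

    Returns ``(frames_by_camera, feature_canvas_cm)``.
    """
    import warnings as _warnings

    from skimage.transform import ProjectiveTransform, warp

    if len(cameras) == 0:
        raise ValueError("need at least one camera")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    tex_w = int(np.ceil(arena.width / texel_cm)) + 1
    tex_h = int(np.ceil(arena.height / texel_cm)) + 1
    # blocky binary noise gives corners at many scales
    base = rng.random((tex_h // 4 + 1, tex_w // 4 + 1)) > 0.5
    texture = np.kron(base, np.ones((4, 4)))[:tex_h, :tex_w].astype(float)
    texture = 0.15 + 0.55 * texture
    fine = rng.random((tex_h, tex_w)) > 0.5
    texture = np.where(rng.random((tex_h, tex_w)) < 0.25, 0.15 + 0.7 * fine, texture)

    features = np.column_stack([rng.uniform(0, arena.width, n_features),
                                rng.uniform(0, arena.height, n_features)])
    for fx, fy in features:
        tx, ty = int(round(fx / texel_cm)), int(round(fy / texel_cm))
        y0, y1 = max(ty - 2, 0), min(ty + 3, tex_h)
        x0, x1 = max(tx - 2, 0), min(tx + 3, tex_w)
        texture[y0:y1, x0:x1] = 1.0

    S_tex = np.diag([1.0 / texel_cm, 1.0 / texel_cm, 1.0])
    frames: dict[str, np.ndarray] = {}
    for cam in cameras:
        # output image px -> canvas cm -> texture px
        M = S_tex @ np.linalg.inv(cam.homography)
        tform = ProjectiveTransform(matrix=M)
        w, h = cam.image_size
        img = warp(texture, inverse_map=tform, output_shape=(h, w), order=1,
                   mode="constant", cval=0.0)
        frames[cam.camera_id] = (img * 255).astype(np.uint8)

    # warn about disconnected overlap (no shared features between a camera
    # pair partition) -- registration would be impossible for such rigs
    vis = {cam.camera_id: set(np.flatnonzero(cam.in_view(features)))
           for cam in cameras}
    ids = [c.camera_id for c in cameras]
    if len(ids) > 1:
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(ids)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if len(vis[a] & vis[b]) >= 4:
                    g.add_edge(a, b)
        if not nx.is_connected(g):
            _warnings.warn("camera overlap graph is disconnected; "
                           "registration will be disconnected", stacklevel=2)
    return frames, features


# ---------------------------------------------------------------------------
# spike simulation


def _place_rate(traj_pos: np.ndarray, neuron: NeuronSpec) -> np.ndarray:
    d2 = ((traj_pos - np.asarray(neuron.center_cm)) ** 2).sum(axis=1)
    return neuron.baseline_rate + neuron.peak_rate * np.exp(-d2 / (2 * neuron.sigma_cm ** 2))


def instantaneous_rate(traj: Trajectory, neuron: NeuronSpec,
                       theta_peaks: np.ndarray | None = None) -> np.ndarray:
    """Ground-truth firing rate (Hz) evaluated on the trajectory grid."""
    if neuron.kind == "place":
        return _place_rate(traj.positions, neuron)
    if neuron.kind == "head_direction":
        dtheta = np.deg2rad(traj.head_directions - neuron.preferred_deg)
        return (neuron.baseline_rate
                + neuron.peak_rate * np.exp(neuron.kappa * (np.cos(dtheta) - 1.0)))
    # phase_precessing: place envelope gated by theta phase preference
    envelope = _place_rate(traj.positions, neuron)
    if theta_peaks is None:
        raise ValueError("phase_precessing rate needs theta peaks")
    phase = theta_phase_at(traj.times, theta_peaks)
    # signed distance through the field along the direction of travel
    u = np.column_stack([np.cos(np.deg2rad(traj.head_directions)),
                         np.sin(np.deg2rad(traj.head_directions))])
    d_along = ((traj.positions - np.asarray(neuron.center_cm)) * u).sum(axis=1)
    pref = neuron.phase_offset_deg + neuron.phase_slope_deg_per_cm * d_along
    dphi = np.deg2rad(phase - pref)
    gate = np.exp(neuron.phase_kappa * (np.cos(dphi) - 1.0))
    return neuron.baseline_rate + (envelope - neuron.baseline_rate) * gate


def theta_phase_at(t: np.ndarray, theta_peaks: np.ndarray) -> np.ndarray:
    """Phase (deg, 0-360) by linear interpolation between consecutive peaks."""
    t = np.asarray(t, dtype=float)
    idx = np.searchsorted(theta_peaks, t, side="right") - 1
    idx = np.clip(idx, 0, len(theta_peaks) - 2)
    t0 = theta_peaks[idx]
    t1 = theta_peaks[idx + 1]
    return 360.0 * np.clip((t - t0) / (t1 - t0), 0.0, 1.0)


def simulate_spikes(traj: Trajectory, neuron: NeuronSpec,
                    seed: int | np.random.Generator = 0,
                    theta_rate_hz: float = 8.0,
                    ) -> tuple[np.ndarray, np.ndarray | None]:
    """Inhomogeneous-Poisson spike train along a trajectory (thinning).

    Returns ``(spike_times, theta_peaks)``; theta peaks (a perfectly
    periodic train at ``theta_rate_hz``) are returned only for
    phase-precessing neurons, else None.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    theta_peaks = None
    if neuron.kind == "phase_precessing":
        theta_peaks = np.arange(traj.times[0], traj.times[-1] + 1.0 / theta_rate_hz,
                                1.0 / theta_rate_hz)
    rate = instantaneous_rate(traj, neuron, theta_peaks)
    lam_max = float(rate.max())
    if lam_max <= 0:
        return np.array([]), theta_peaks
    span = traj.times[-1] - traj.times[0]
    n_cand = rng.poisson(lam_max * span)
    cand = np.sort(traj.times[0] + rng.random(n_cand) * span)
    rate_at = np.interp(cand, traj.times, rate)
    keep = rng.random(n_cand) < rate_at / lam_max
    return cand[keep], theta_peaks
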