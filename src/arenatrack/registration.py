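"""Multi-camera registration onto a shared arena canvas.

Overhead cameras imaging a planar arena floor are related to the floor
plane (and to each other) by plane projective homographies.  Registration
proceeds in two steps, mirroring a stitching pipeline: features detected
in per-camera calibration frames are matched between overlapping cameras;
RANSAC then rejects geometrically inconsistent matches and fits a pairwise
homography.  Pairwise homographies are chained along a spanning tree of
the camera-overlap graph to express every camera in the reference camera's
image plane, and a declared landmark distance converts that plane to
centimetres.

Alignment quality is quantified by the projection error of landmarks seen
by several cameras: the distance between one camera's canvas-mapped
estimate of a point and the mean estimate over all cameras observing it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from skimage.feature import ORB, match_descriptors


@dataclass
class CorrespondenceSet:
    """Matched pixel pairs between two cameras' calibration frames."""

    camera_a: str
    camera_b: str
    points_a: np.ndarray  # (n, 2) pixel coords in A
    points_b: np.ndarray  # (n, 2) pixel coords in B
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points_a = np.asarray(self.points_a, dtype=float).reshape(-1, 2)
        self.points_b = np.asarray(self.points_b, dtype=float).reshape(-1, 2)
        if len(self.points_a) != len(self.points_b):
            raise ValueError("point lists must pair one-to-one")

    def __len__(self) -> int:
        return len(self.points_a)

    @property
    def registrable(self) -> bool:
        return len(self) >= 4


@dataclass
class CameraRegistration:
    """Homography from a camera's image pixels into the shared canvas (cm)."""

    camera_id: str
    homography: np.ndarray  # 3x3, image px -> canvas cm
    inlier_count: int = 0
    canvas_bounds: tuple[float, float, float, float] | None = None  # xmin,xmax,ymin,ymax
    cm_per_px: float | None = None

    def __post_init__(self) -> None:
        self.homography = np.asarray(self.homography, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(self.homography)) < 1e-15:
            raise ValueError("homography must be invertible")

    def to_dict(self) -> dict:
        return {
            "camera_id": self.camera_id,
            "homography": self.homography.ravel().tolist(),
            "inlier_count": self.inlier_count,
            "canvas_bounds": list(self.canvas_bounds) if self.canvas_bounds else None,
            "cm_per_px": self.cm_per_px,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraRegistration":
        return cls(
            camera_id=d["camera_id"],
            homography=np.array(d["homography"], dtype=float).reshape(3, 3),
            inlier_count=d.get("inlier_count", 0),
            canvas_bounds=tuple(d["canvas_bounds"]) if d.get("canvas_bounds") else None,
            cm_per_px=d.get("cm_per_px"),
        )


@dataclass
class ProjectionErrorReport:
    """Per-camera distances from canvas-mapped landmarks to their consensus."""

    per_camera_errors: dict[str, np.ndarray]
    skipped_points: list = field(default_factory=list)

    @property
    def per_camera_median(self) -> dict[str, float]:
        return {c: float(np.median(e)) for c, e in self.per_camera_errors.items() if e.size}

    @property
    def per_camera_max(self) -> dict[str, float]:
        return {c: float(np.max(e)) for c, e in self.per_camera_errors.items() if e.size}

    @property
    def overall_median(self) -> float:
        allerr = np.concatenate([e for e in self.per_camera_errors.values() if e.size])
        return float(np.median(allerr))

    @property
    def overall_max(self) -> float:
        allerr = np.concatenate([e for e in self.per_camera_errors.values() if e.size])
        return float(np.max(allerr))


# ---------------------------------------------------------------------------
# point transforms

def apply_homography(H: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 3x3 projective transform to (n, 2) points."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    hom = np.column_stack([points, np.ones(len(points))])
    out = hom @ np.asarray(H, dtype=float).T
    w = out[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise ValueError("point maps to infinity (w ~ 0) under this homography")
    return out[:, :2] / w[:, None]


def warp_point(p: np.ndarray, reg: CameraRegistration) -> np.ndarray:
    """Map image pixel(s) into canvas cm."""
    return apply_homography(reg.homography, p)


def unwarp_point(p: np.ndarray, reg: CameraRegistration) -> np.ndarray:
    """Map canvas cm point(s) back into image pixels."""
    return apply_homography(np.linalg.inv(reg.homography), p)


# ---------------------------------------------------------------------------
# feature matching

def match_features(frame_a: np.ndarray, frame_b: np.ndarray,
                   camera_a: str = "A", camera_b: str = "B",
                   n_keypoints: int = 800, max_ratio: float = 0.8,
                   seed: int = 0) -> CorrespondenceSet:
    """Detect ORB features in two frames and match them.

    Matches are mutual nearest neighbours in descriptor space passing a
    Lowe-style ratio test, ordered by descriptor distance.  Colour frames
    are collapsed to luminance first.
    """
    a = _as_gray(frame_a)
    b = _as_gray(frame_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("frames must be nonempty")
    kp, desc = [], []
    for img in (a, b):
        orb = ORB(n_keypoints=n_keypoints, fast_threshold=0.05)
        orb.detect_and_extract(img)
        kp.append(orb.keypoints)     # (row, col)
        desc.append(orb.descriptors)
    matches = match_descriptors(desc[0], desc[1], cross_check=True, max_ratio=max_ratio)
    # hamming distance of matched descriptor pairs, for score ordering
    d = np.sum(desc[0][matches[:, 0]] != desc[1][matches[:, 1]], axis=1).astype(float)
    order = np.argsort(d)
    matches = matches[order]
    pts_a = kp[0][matches[:, 0]][:, ::-1]  # to (x, y)
    pts_b = kp[1][matches[:, 1]][:, ::-1]
    corr = CorrespondenceSet(camera_a, camera_b, pts_a, pts_b, scores=d[order])
    if not corr.registrable:
        warnings.warn(
            f"only {len(corr)} matches between {camera_a} and {camera_b}; "
            "pair is unregistrable", stacklevel=2)
    return corr


def _as_gray(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 3:
        frame = frame.astype(float).mean(axis=2)
    return frame.astype(float)


# ---------------------------------------------------------------------------
# homography estimation

def fit_homography_dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares homography (normalized DLT) mapping src -> dst.

    Exact for 4 point pairs; total least squares via SVD for more.
    Returned matrix is normalized to H[2, 2] = 1.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    n = len(src)
    if n < 4:
        raise ValueError("need at least 4 correspondences")
    Ts, src_n = _normalize_points(src)
    Td, dst_n = _normalize_points(dst)
    A = np.zeros((2 * n, 9))
    x, y = src_n[:, 0], src_n[:, 1]
    u, v = dst_n[:, 0], dst_n[:, 1]
    A[0::2, 0] = -x
    A[0::2, 1] = -y
    A[0::2, 2] = -1
    A[0::2, 6] = u * x
    A[0::2, 7] = u * y
    A[0::2, 8] = u
    A[1::2, 3] = -x
    A[1::2, 4] = -y
    A[1::2, 5] = -1
    A[1::2, 6] = v * x
    A[1::2, 7] = v * y
    A[1::2, 8] = v
    _, _, vt = np.linalg.svd(A)
    Hn = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    if abs(H[2, 2]) < 1e-12:
        raise ValueError("degenerate homography (H[2,2] ~ 0)")
    return H / H[2, 2]


def _normalize_points(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hartley normalization: centroid at origin, mean distance sqrt(2)."""
    centroid = pts.mean(axis=0)
    d = np.sqrt(((pts - centroid) ** 2).sum(axis=1)).mean()
    s = np.sqrt(2) / d if d > 0 else 1.0
    T = np.array([[s, 0, -s * centroid[0]],
                  [0, s, -s * centroid[1]],
                  [0, 0, 1]])
    return T, (pts - centroid) * s


def estimate_homography_ransac(corr: CorrespondenceSet, inlier_threshold: float = 2.0,
                               max_iter: int = 2000,
                               seed: int | np.random.Generator = 0
                               ) -> tuple[np.ndarray, np.ndarray]:
    """RANSAC homography mapping corr.points_a -> corr.points_b.

    Minimal 4-point hypotheses are sampled; consensus is reprojection
    error below ``inlier_threshold`` pixels; the final homography is refit
    by least squares on the largest consensus set.

    Returns ``(H, inlier_mask)`` with H normalized to H[2, 2] = 1.
    """
    if len(corr) < 4:
        raise ValueError("need at least 4 correspondences for RANSAC")
    src, dst = corr.points_a, corr.points_b
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = len(src)
    best_mask = None
    best_count = 0
    for _ in range(max_iter):
        idx = rng.choice(n, size=4, replace=False)
        if _collinear(src[idx]) or _collinear(dst[idx]):
            continue
        try:
            H = fit_homography_dlt(src[idx], dst[idx])
        except (ValueError, np.linalg.LinAlgError):
            continue
        try:
            proj = apply_homography(H, src)
        except ValueError:
            continue
        err = np.sqrt(((proj - dst) ** 2).sum(axis=1))
        mask = err < inlier_threshold
        count = int(mask.sum())
        if count > best_count:
            best_count, best_mask = count, mask
            if count == n:
                break
    if best_mask is None or best_count < 4:
        raise RuntimeError(
            f"RANSAC failed: no hypothesis reached 4 inliers over {max_iter} "
            f"iterations ({n} correspondences, threshold {inlier_threshold} px)")
    H = fit_homography_dlt(src[best_mask], dst[best_mask])
    # one consensus re-evaluation after the refit
    err = np.sqrt(((apply_homography(H, src) - dst) ** 2).sum(axis=1))
    final_mask = err < inlier_threshold
    if final_mask.sum() >= 4:
        H = fit_homography_dlt(src[final_mask], dst[final_mask])
    else:
        final_mask = best_mask
    return H, final_mask


def _collinear(pts: np.ndarray, tol: float = 1e-8) -> bool:
    """True if any 3 of the 4 points are (nearly) collinear."""
    from itertools import combinations
    for i, j, k in combinations(range(len(pts)), 3):
        v1 = pts[j] - pts[i]
        v2 = pts[k] - pts[i]
        if abs(v1[0] * v2[1] - v1[1] * v2[0]) < tol * (1 + np.abs(pts).max()) ** 2:
            return True
    return False


# ---------------------------------------------------------------------------
# canvas construction

def build_canvas(correspondences: list[CorrespondenceSet], reference_camera: str,
                 landmark_px: np.ndarray | None = None,
                 landmark_cm: float | None = None,
                 image_sizes: dict[str, tuple[int, int]] | None = None,
                 inlier_threshold: float = 2.0, seed: int = 0,
                 pairwise_h: dict[tuple[str, str], np.ndarray] | None = None,
                 ) -> dict[str, CameraRegistration]:
    """Chain pairwise homographies into one canvas per camera.

    The reference camera's image plane defines the canvas axes; a declared
    landmark (two pixel points in the reference image, ``landmark_px``,
    spanning a known ``landmark_cm`` distance) sets the cm-per-pixel
    scale.  Pairwise homographies are estimated per overlapping pair
    (unless supplied precomputed through ``pairwise_h``) and chained
    along a shortest-path spanning tree of the overlap graph.

    ``image_sizes`` maps camera id -> (width, height) px and is used to
    compute canvas bounds from warped image corners.
    """
    graph = nx.Graph()
    inliers: dict[str, int] = {}
    for corr in correspondences:
        if not corr.registrable:
            continue
        if pairwise_h is not None and (corr.camera_a, corr.camera_b) in pairwise_h:
            H_ab = np.asarray(pairwise_h[(corr.camera_a, corr.camera_b)], dtype=float)
            n_in = len(corr)
        else:
            H_ab, mask = estimate_homography_ransac(
                corr, inlier_threshold=inlier_threshold, seed=seed)
            n_in = int(mask.sum())
        graph.add_edge(corr.camera_a, corr.camera_b, H_ab=H_ab,
                       src=corr.camera_a, n_inliers=n_in)
        inliers[corr.camera_a] = max(inliers.get(corr.camera_a, 0), n_in)
        inliers[corr.camera_b] = max(inliers.get(corr.camera_b, 0), n_in)

    cameras = set(graph.nodes) | {reference_camera}
    if reference_camera not in graph.nodes and len(cameras) > 1:
        raise ValueError(f"reference camera {reference_camera!r} has no registrable overlap")
    if len(cameras) > 1 and not nx.is_connected(graph):
        comps = [sorted(c) for c in nx.connected_components(graph)]
        raise ValueError(f"camera overlap graph is disconnected: components {comps}")

    # homography from each camera's pixels into the reference camera's pixels
    to_ref: dict[str, np.ndarray] = {reference_camera: np.eye(3)}
    if len(cameras) > 1:
        paths = nx.shortest_path(graph, target=reference_camera)
        for cam, path in paths.items():
            H = np.eye(3)
            for a, b in zip(path[:-1], path[1:]):
                edge = graph.edges[a, b]
                H_ab = edge["H_ab"] if edge["src"] == a else np.linalg.inv(edge["H_ab"])
                H = H_ab @ H
            to_ref[cam] = H / H[2, 2]

    # cm scale from the declared landmark in the reference image
    if landmark_px is not None and landmark_cm is not None:
        p = np.asarray(landmark_px, dtype=float)
        d_px = float(np.hypot(*(p[1] - p[0])))
        scale = landmark_cm / d_px
    else:
        scale = 1.0
    S = np.diag([scale, scale, 1.0])

    regs = {
        cam: CameraRegistration(cam, S @ H, inlier_count=inliers.get(cam, 0),
                                cm_per_px=scale)
        for cam, H in to_ref.items()
    }

    if image_sizes:
        corners = []
        for cam, reg in regs.items():
            if cam not in image_sizes:
                continue
            w, h = image_sizes[cam]
            pts = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=float)
            corners.append(warp_point(pts, reg))
        if corners:
            allc = np.vstack(corners)
            bounds = (float(allc[:, 0].min()), float(allc[:, 0].max()),
                      float(allc[:, 1].min()), float(allc[:, 1].max()))
            for reg in regs.values():
                reg.canvas_bounds = bounds
    return regs


# ---------------------------------------------------------------------------
# projection-error QC

def projection_error(observations: dict[str, dict[int, np.ndarray]],
                     regs: dict[str, CameraRegistration]) -> ProjectionErrorReport:
    """Fig-of-merit for stitching: landmark spread across cameras.

    ``observations[camera][point_id]`` is the pixel position at which that
    camera sees grid-intersection ``point_id``.  For each intersection seen
    by >= 2 cameras, each camera's error is the distance (cm) from its
    warped observation to the mean warped position across all observing
    cameras.  Intersections seen once are skipped and noted.
    """
    point_ids = sorted({pid for obs in observations.values() for pid in obs})
    errors: dict[str, list[float]] = {cam: [] for cam in observations}
    skipped = []
    for pid in point_ids:
        seen = [(cam, obs[pid]) for cam, obs in observations.items() if pid in obs]
        if len(seen) < 2:
            skipped.append(pid)
            continue
        warped = {cam: warp_point(np.asarray(px, dtype=float), regs[cam])[0]
                  for cam, px in seen}
        mean_pos = np.mean(list(warped.values()), axis=0)
        for cam, w in warped.items():
            errors[cam].append(float(np.hypot(*(w - mean_pos))))
    return ProjectionErrorReport(
        per_camera_errors={c: np.asarray(e) for c, e in errors.items()},
        skipped_points=skipped)


# ---------------------------------------------------------------------------
# serialization

def save_registrations(regs: dict[str, CameraRegistration], path) -> None:
    with open(path, "w") as fh:
        json.dump({"schema": "arenatrack.registration/1",
                   "cameras": [r.to_dict() for r in regs.values()]}, fh, indent=2)


def load_registrations(path) -> dict[str, CameraRegistration]:
    with open(path) as fh:
        data = json.load(fh)
    regs = [CameraRegistration.from_dict(d) for d in data["cameras"]]
    return {r.camera_id: r for r in regs}
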