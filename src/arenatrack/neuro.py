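"""Spatial-coding analysis: rate maps, tuning curves, phase precession.

The analysis chain mirrors standard rodent spatial-coding practice:
position samples and spikes are filtered by running speed (< 2 cm/s
excluded), binned into square spatial bins (4 cm in large rooms, 2 cm
otherwise), and bins occupied < 0.4 s are invalidated.  Firing rate per
bin is spikes / dwell time.  Gaussian-smoothed maps (sigma = 1.25 bins)
supply peak rates and place-field segmentation; adaptive-binned maps
supply the Skaggs spatial-information score, whose significance is
assessed by cyclically shifting the spike train relative to the position
data.  Head-direction tuning uses 5-degree bins with circular Gaussian
smoothing; theta phase precession is quantified by a straight-line fit of
spike phase on linearized position and the variance of the per-spike
position residuals around that line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

SPEED_MIN_CMS = 2.0     # running-speed inclusion threshold
OCC_MIN_S = 0.4         # minimum dwell per spatial bin
SMOOTH_SIGMA_BINS = 1.25
HD_BIN_DEG = 5.0
FIELD_MIN_BINS = 7
FIELD_RATE_FRACTION = 0.15   # of the field's own peak
FIELD_PEAK_FRACTION = 0.25   # of the map peak
ADAPTIVE_ALPHA = 1.0e6


# ---------------------------------------------------------------------------
# rate maps


@dataclass
class RateMap:
    """Binned occupancy, spike counts and firing rate on a spatial grid."""

    bin_size: float
    x_edges: np.ndarray
    y_edges: np.ndarray
    occupancy_s: np.ndarray       # (ny, nx) seconds
    occupancy_samples: np.ndarray  # (ny, nx) position-sample counts
    spike_counts: np.ndarray
    rate: np.ndarray              # Hz; NaN on invalid bins
    valid: np.ndarray             # bool mask

    @property
    def peak_rate(self) -> float:
        r = self.rate[self.valid]
        return float(np.nanmax(r)) if r.size else np.nan

    @property
    def mean_rate(self) -> float:
        """Occupancy-weighted mean rate over valid bins."""
        occ = self.occupancy_s[self.valid]
        return float(np.sum(self.rate[self.valid] * occ) / occ.sum())

    def copy_with_rate(self, rate: np.ndarray) -> "RateMap":
        return RateMap(self.bin_size, self.x_edges, self.y_edges,
                       self.occupancy_s, self.occupancy_samples,
                       self.spike_counts, rate, self.valid)


def _dwell_times(times: np.ndarray) -> np.ndarray:
    """Per-sample dwell: interval to the next sample (median for the last)."""
    d = np.diff(times)
    return np.concatenate([d, [np.median(d)]]) if d.size else np.array([0.0])


def assign_spike_samples(spike_times: np.ndarray, sample_times: np.ndarray) -> np.ndarray:
    """Index of the nearest position sample for each spike (no interpolation).

    This assignment is deliberately the raw nearest-timestamp rule: frame
    timing errors propagate into spatial metrics exactly through it.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    pos = np.searchsorted(sample_times, spike_times)
    pos = np.clip(pos, 1, len(sample_times) - 1)
    left = sample_times[pos - 1]
    right = sample_times[pos]
    return np.where(spike_times - left <= right - spike_times, pos - 1, pos)


def _prepare_samples(times, positions, speeds, speed_min):
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    ok = np.isfinite(positions).all(axis=1)
    if speeds is not None:
        speeds = np.asarray(speeds, dtype=float)
        ok &= np.isfinite(speeds) & (speeds >= speed_min)
    return times, positions, ok


def compute_rate_map(times: np.ndarray, positions: np.ndarray,
                     spike_times: np.ndarray, bin_size: float,
                     speeds: np.ndarray | None = None,
                     speed_min: float = SPEED_MIN_CMS,
                     occ_min: float = OCC_MIN_S,
                     extent: tuple[float, float, float, float] | None = None,
                     ) -> RateMap:
    """Unsmoothed firing-rate map.

    Each tracked sample contributes its dwell interval to its bin; each
    spike takes the position of the nearest sample in time.  Samples (and
    the spikes assigned to them) during running speed < ``speed_min`` are
    excluded; bins with residual occupancy < ``occ_min`` are invalid.
    ``extent`` is (xmin, xmax, ymin, ymax) cm; it defaults to the data
    bounding box.
    """
    times, positions, ok = _prepare_samples(times, positions, speeds, speed_min)
    if extent is None:
        fin = positions[np.isfinite(positions).all(axis=1)]
        if not len(fin):
            raise ValueError("no finite positions")
        extent = (fin[:, 0].min(), fin[:, 0].max(), fin[:, 1].min(), fin[:, 1].max())
    x_edges = _edges(extent[0], extent[1], bin_size)
    y_edges = _edges(extent[2], extent[3], bin_size)
    dwell = _dwell_times(times)

    ix = np.clip(np.digitize(positions[:, 0], x_edges) - 1, 0, len(x_edges) - 2)
    iy = np.clip(np.digitize(positions[:, 1], y_edges) - 1, 0, len(y_edges) - 2)
    shape = (len(y_edges) - 1, len(x_edges) - 1)
    flat = iy * shape[1] + ix

    occ = np.bincount(flat[ok], weights=dwell[ok], minlength=shape[0] * shape[1])
    occ_n = np.bincount(flat[ok], minlength=shape[0] * shape[1])
    occ = occ.reshape(shape)
    occ_n = occ_n.reshape(shape).astype(float)

    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size:
        si = assign_spike_samples(spike_times, times)
        keep = ok[si]
        spk = np.bincount(flat[si[keep]], minlength=shape[0] * shape[1]).reshape(shape)
    else:
        spk = np.zeros(shape)
    spk = spk.astype(float)

    valid = occ >= occ_min
    if not valid.any():
        raise ValueError("no valid bins after speed and occupancy filters")
    rate = np.full(shape, np.nan)
    rate[valid] = spk[valid] / occ[valid]
    return RateMap(bin_size, x_edges, y_edges, occ, occ_n, spk, rate, valid)


def _edges(lo: float, hi: float, step: float) -> np.ndarray:
    n = max(int(np.ceil((hi - lo) / step - 1e-9)), 1)
    return lo + np.arange(n + 1) * step


def smooth_map_gaussian(rmap: RateMap, sigma: float = SMOOTH_SIGMA_BINS) -> RateMap:
    """Mask-normalized Gaussian smoothing.

    Invalid bins are excluded from both the numerator and the kernel
    normalization so that missing coverage does not drag rates down at
    the edges of the sampled region.
    """
    rate = np.where(rmap.valid, rmap.rate, 0.0)
    w = rmap.valid.astype(float)
    num = ndimage.gaussian_filter(rate * w, sigma, mode="constant")
    den = ndimage.gaussian_filter(w, sigma, mode="constant")
    out = np.full_like(rate, np.nan)
    nz = rmap.valid & (den > 0)
    out[nz] = num[nz] / den[nz]
    return rmap.copy_with_rate(out)


def adaptive_rate_map(times: np.ndarray, positions: np.ndarray,
                      spike_times: np.ndarray, bin_size: float,
                      speeds: np.ndarray | None = None,
                      alpha: float = ADAPTIVE_ALPHA,
                      speed_min: float = SPEED_MIN_CMS,
                      occ_min: float = OCC_MIN_S,
                      extent: tuple[float, float, float, float] | None = None,
                      ) -> RateMap:
    """Adaptive-binning rate map (expanding-circle smoothing).

    For each valid bin, a circle centred on the bin expands until the
    spike count inside exceeds ``alpha / (n_occ^2 r^2)``, where n_occ is
    the number of position samples inside the circle and r the radius in
    bins; the bin's rate is then spikes-in-circle / dwell-in-circle.  The
    radius is capped at the map diagonal (a cap reached only where there
    are essentially no spikes, where the rate tends to zero).
    """
    base = compute_rate_map(times, positions, spike_times, bin_size,
                            speeds=speeds, speed_min=speed_min, occ_min=occ_min,
                            extent=extent)
    rate = adaptive_rates_from_counts(base.occupancy_samples, base.occupancy_s,
                                      base.spike_counts, base.valid, alpha)
    return base.copy_with_rate(rate)


def _disc_kernel(r: int) -> np.ndarray:
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (xx ** 2 + yy ** 2 <= r ** 2).astype(float)


class AdaptiveBinner:
    """Expanding-circle smoother with fixed occupancy, reusable across spike maps.

    Occupancy-dependent quantities (disc sums of sample counts and dwell,
    and the per-radius spike-count requirement alpha / (n_occ^2 r^2)) are
    precomputed once; smoothing a new spike map (e.g. one cyclic shuffle)
    then costs one forward FFT plus one small inverse FFT per radius
    actually visited.
    """

    def __init__(self, occ_samples: np.ndarray, occ_s: np.ndarray,
                 valid: np.ndarray, alpha: float = ADAPTIVE_ALPHA):
        from scipy import fft as sfft
        self._sfft = sfft
        self.valid = valid
        self.alpha = alpha
        self.shape = occ_samples.shape
        self.r_max = int(np.ceil(np.hypot(*self.shape)))
        ny, nx = self.shape
        self._fshape = (sfft.next_fast_len(ny + 2 * self.r_max),
                        sfft.next_fast_len(nx + 2 * self.r_max))
        occ_w = np.where(valid, occ_samples, 0.0)
        dwell_w = np.where(valid, occ_s, 0.0)
        occ_f = sfft.rfft2(occ_w, self._fshape)
        dwell_f = sfft.rfft2(dwell_w, self._fshape)
        self._kernel_f: dict[int, np.ndarray] = {}
        self._need: dict[int, np.ndarray] = {}
        self._dwell_r: dict[int, np.ndarray] = {}
        self._occ_f, self._dwell_f = occ_f, dwell_f

    def _prepare_radius(self, r: int) -> None:
        if r in self._need:
            return
        sfft = self._sfft
        k = _disc_kernel(r)
        kf = sfft.rfft2(k, self._fshape)
        self._kernel_f[r] = kf
        n_occ = self._crop(sfft.irfft2(self._occ_f * kf, self._fshape), r)
        self._dwell_r[r] = self._crop(sfft.irfft2(self._dwell_f * kf, self._fshape), r)
        with np.errstate(divide="ignore"):
            self._need[r] = self.alpha / np.where(n_occ > 1e-9,
                                                  n_occ ** 2 * r ** 2, np.inf)

    def _crop(self, full: np.ndarray, r: int) -> np.ndarray:
        ny, nx = self.shape
        return full[r:r + ny, r:r + nx]

    def rates(self, spike_counts: np.ndarray) -> np.ndarray:
        sfft = self._sfft
        spk_w = np.where(self.valid, spike_counts, 0.0)
        spk_f = sfft.rfft2(spk_w, self._fshape)
        rate = np.full(self.shape, np.nan)
        unresolved = self.valid.copy()
        for r in range(1, self.r_max + 1):
            if not unresolved.any():
                return rate
            self._prepare_radius(r)
            n_spk = self._crop(sfft.irfft2(spk_f * self._kernel_f[r], self._fshape), r)
            done = unresolved & (n_spk > self._need[r])
            if done.any():
                rate[done] = np.maximum(n_spk[done], 0.0) / self._dwell_r[r][done]
                unresolved &= ~done
        if unresolved.any():
            # radius hit the cap: essentially no spikes reachable
            r = self.r_max
            self._prepare_radius(r)
            n_spk = self._crop(sfft.irfft2(spk_f * self._kernel_f[r], self._fshape), r)
            dwell = self._dwell_r[r]
            with np.errstate(invalid="ignore"):
                rate[unresolved] = np.where(dwell[unresolved] > 0,
                                            np.maximum(n_spk[unresolved], 0.0)
                                            / dwell[unresolved], 0.0)
        return rate


def adaptive_rates_from_counts(occ_samples: np.ndarray, occ_s: np.ndarray,
                               spikes: np.ndarray, valid: np.ndarray,
                               alpha: float = ADAPTIVE_ALPHA) -> np.ndarray:
    """Adaptive-binning smoothing given per-bin counts (see adaptive_rate_map)."""
    return AdaptiveBinner(occ_samples, occ_s, valid, alpha).rates(spikes)


# ---------------------------------------------------------------------------
# spatial information and its significance


def spatial_information(rmap: RateMap) -> float:
    """Skaggs information score, bits per spike.

    I = sum_i p_i (lambda_i / lambda) log2(lambda_i / lambda), with p_i
    the occupancy share of valid bin i and lambda the occupancy-weighted
    mean rate.  Zero-rate bins contribute zero.
    """
    occ = rmap.occupancy_s[rmap.valid]
    lam = rmap.rate[rmap.valid]
    return _skaggs(occ, lam)


def _skaggs(occ: np.ndarray, lam: np.ndarray) -> float:
    p = occ / occ.sum()
    lbar = float(np.sum(p * lam))
    if lbar <= 0:
        raise ValueError("mean rate is zero; information undefined")
    nz = lam > 0
    ratio = lam[nz] / lbar
    return float(np.sum(p[nz] * ratio * np.log2(ratio)))


def cyclic_shift_spikes(spike_times: np.ndarray, t_start: float, t_end: float,
                        shift: float) -> np.ndarray:
    """Shift a spike train cyclically within [t_start, t_end)."""
    span = t_end - t_start
    return (np.asarray(spike_times, float) - t_start + shift) % span + t_start


def shuffle_significance(times: np.ndarray, positions: np.ndarray,
                         spike_times: np.ndarray, bin_size: float,
                         speeds: np.ndarray | None = None,
                         n_shuffles: int = 1000, margin_s: float = 30.0,
                         seed: int | np.random.Generator = 0,
                         estimator: str = "adaptive",
                         alpha: float = ADAPTIVE_ALPHA,
                         speed_min: float = SPEED_MIN_CMS,
                         occ_min: float = OCC_MIN_S,
                         extent=None) -> tuple[float, np.ndarray, float]:
    """Cyclic-shuffle significance of the spatial-information score.

    The spike train is shifted cyclically relative to the position data
    ``n_shuffles`` times by uniform random offsets in
    [margin, duration - margin]; the p-value is the fraction of shuffled
    information scores >= the observed score (significant at p < 0.01).

    ``estimator`` selects the per-shuffle information estimator:
    'adaptive' (adaptive-binned rates, the default analysis path) or
    'raw' (unsmoothed rates; the p-value is a rank among exchangeable
    scores, so calibration is estimator-independent, and 'raw' is much
    cheaper for large calibration sweeps).

    Returns ``(p_value, null_scores, observed_score)``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    times = np.asarray(times, dtype=float)
    t0, t1 = float(times[0]), float(times[-1])
    duration = t1 - t0
    if duration <= 2 * margin_s:
        raise ValueError(f"session ({duration:.1f} s) must exceed twice the "
                         f"{margin_s:.0f}-s shuffle margin")
    if estimator not in ("adaptive", "raw"):
        raise ValueError("estimator must be 'adaptive' or 'raw'")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    base = compute_rate_map(times, positions, spike_times, bin_size, speeds=speeds,
                            speed_min=speed_min, occ_min=occ_min, extent=extent)

    binner = (AdaptiveBinner(base.occupancy_samples, base.occupancy_s,
                             base.valid, alpha)
              if estimator == "adaptive" else None)

    def info_for(spk_map: np.ndarray) -> float:
        if binner is not None:
            lam = binner.rates(spk_map)
        else:
            with np.errstate(invalid="ignore"):
                lam = np.where(base.valid, spk_map / base.occupancy_s, np.nan)
        return _skaggs(base.occupancy_s[base.valid], lam[base.valid])

    observed = info_for(base.spike_counts)

    # precompute bin index per sample, and sample validity, once
    _, _, ok = _prepare_samples(times, positions, speeds, speed_min)
    x_edges, y_edges = base.x_edges, base.y_edges
    ix = np.clip(np.digitize(positions[:, 0], x_edges) - 1, 0, len(x_edges) - 2)
    iy = np.clip(np.digitize(positions[:, 1], y_edges) - 1, 0, len(y_edges) - 2)
    shape = base.rate.shape
    flat = iy * shape[1] + ix

    shifts = rng.uniform(margin_s, duration - margin_s, size=n_shuffles)
    null = np.empty(n_shuffles)
    nbins = shape[0] * shape[1]
    for j, shift in enumerate(shifts):
        shifted = cyclic_shift_spikes(spike_times, t0, t1, shift)
        si = assign_spike_samples(np.sort(shifted), times)
        keep = ok[si]
        spk = np.bincount(flat[si[keep]], minlength=nbins).reshape(shape).astype(float)
        null[j] = info_for(spk)
    p = float(np.mean(null >= observed))
    return p, null, observed


# ---------------------------------------------------------------------------
# place fields


@dataclass
class PlaceField:
    """Contiguous suprathreshold region of a smoothed rate map."""

    bins: np.ndarray          # (n, 2) array of (row, col)
    peak_rate: float

    @property
    def size_bins(self) -> int:
        return len(self.bins)


_CONN4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


def detect_place_fields(smoothed: RateMap) -> list[PlaceField]:
    """Segment place fields on a smoothed rate map.

    Fields grow from local maxima: the working peak's field is the
    4-connected component (containing the peak) of bins whose rate
    exceeds 15% of that field's own peak.  Fields whose peak is <= 25%
    of the map peak, or smaller than 7 bins, are discarded.  Returned
    in descending size order.  The rule is scale-invariant: multiplying
    the map by any positive constant yields identical fields.
    """
    rate = np.where(smoothed.valid, smoothed.rate, np.nan)
    if not np.any(np.nan_to_num(rate) > 0):
        return []
    map_peak = np.nanmax(rate)
    unassigned = smoothed.valid & np.isfinite(rate)
    fields: list[PlaceField] = []
    while True:
        masked = np.where(unassigned, rate, -np.inf)
        peak_val = masked.max()
        if not np.isfinite(peak_val) or peak_val <= 0:
            break
        peak_idx = np.unravel_index(np.argmax(masked), rate.shape)
        member_mask = unassigned & (rate > FIELD_RATE_FRACTION * peak_val)
        labels, _ = ndimage.label(member_mask, structure=_CONN4)
        comp = labels == labels[peak_idx]
        unassigned &= ~comp
        if peak_val > FIELD_PEAK_FRACTION * map_peak and comp.sum() >= FIELD_MIN_BINS:
            fields.append(PlaceField(np.argwhere(comp), float(peak_val)))
        if peak_val <= FIELD_PEAK_FRACTION * map_peak:
            break  # every remaining peak is below the inclusion cutoff
    fields.sort(key=lambda f: -f.size_bins)
    return fields


# ---------------------------------------------------------------------------
# head-direction tuning


@dataclass
class TuningCurve:
    """Angular firing-rate tuning in 5-degree bins."""

    bin_edges_deg: np.ndarray
    occupancy_s: np.ndarray
    spike_counts: np.ndarray
    rate: np.ndarray          # unsmoothed Hz
    rate_smoothed: np.ndarray
    peak_rate: float = field(init=False)
    fwhm_deg: float = field(init=False)

    def __post_init__(self) -> None:
        self.peak_rate = float(np.max(self.rate_smoothed))
        self.fwhm_deg = _fwhm_circular(self.bin_edges_deg, self.rate_smoothed)

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:]) / 2.0


def _fwhm_circular(edges: np.ndarray, rate: np.ndarray) -> float:
    """Full width at half maximum by linear interpolation on both flanks.

    Returns NaN when the curve never falls below half peak (no defined
    width, e.g. uniform firing).
    """
    n = len(rate)
    peak_idx = int(np.argmax(rate))
    peak = rate[peak_idx]
    if peak <= 0:
        return np.nan
    half = peak / 2.0
    width_bins = 0.0
    found_left = found_right = False
    # walk outward from the peak on the circular curve
    for direction in (-1, 1):
        for step in range(1, n):
            i_prev = (peak_idx + direction * (step - 1)) % n
            i_cur = (peak_idx + direction * step) % n
            if rate[i_cur] <= half:
                frac = ((rate[i_prev] - half) / (rate[i_prev] - rate[i_cur])
                        if rate[i_prev] != rate[i_cur] else 1.0)
                width_bins += (step - 1) + frac
                if direction < 0:
                    found_left = True
                else:
                    found_right = True
                break
    if not (found_left and found_right):
        return np.nan
    bin_w = float(edges[1] - edges[0])
    return width_bins * bin_w


def hd_tuning(times: np.ndarray, head_directions: np.ndarray,
              spike_times: np.ndarray,
              speeds: np.ndarray | None = None,
              speed_min: float = SPEED_MIN_CMS,
              bin_deg: float = HD_BIN_DEG,
              sigma_bins: float = SMOOTH_SIGMA_BINS) -> TuningCurve:
    """Head-direction tuning curve: spikes per angular bin / dwell per bin.

    Smoothing is a circular (wrap-around) Gaussian with sigma = 1.25
    bins; peak rate and full width at half maximum are computed on the
    smoothed curve.
    """
    times = np.asarray(times, dtype=float)
    hd = np.asarray(head_directions, dtype=float)
    ok = np.isfinite(hd)
    if speeds is not None:
        speeds = np.asarray(speeds, dtype=float)
        ok &= np.isfinite(speeds) & (speeds >= speed_min)
    if not ok.any():
        raise ValueError("no valid head-direction samples")
    n_bins = int(round(360.0 / bin_deg))
    edges = np.arange(n_bins + 1) * bin_deg
    dwell = _dwell_times(times)
    bins = np.clip((hd % 360.0 / bin_deg).astype(int), 0, n_bins - 1)
    occ = np.bincount(bins[ok], weights=dwell[ok], minlength=n_bins)

    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size:
        si = assign_spike_samples(spike_times, times)
        keep = ok[si]
        spk = np.bincount(bins[si[keep]], minlength=n_bins).astype(float)
    else:
        spk = np.zeros(n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ > 0, spk / occ, 0.0)
    smoothed = ndimage.gaussian_filter1d(rate, sigma_bins, mode="wrap")
    return TuningCurve(edges, occ, spk, rate, smoothed)


# ---------------------------------------------------------------------------
# theta phase precession


def assign_theta_phase(spike_times: np.ndarray, theta_peaks: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, int]:
    """Assign each spike a phase in [0, 360) between consecutive theta peaks.

    Returns ``(phases_deg, in_span_mask, n_dropped)``; spikes outside the
    peak-covered span are dropped (mask False).
    """
    theta_peaks = np.asarray(theta_peaks, dtype=float)
    if theta_peaks.size < 2:
        raise ValueError("need at least two theta peaks")
    spike_times = np.asarray(spike_times, dtype=float)
    in_span = (spike_times >= theta_peaks[0]) & (spike_times < theta_peaks[-1])
    idx = np.searchsorted(theta_peaks, spike_times[in_span], side="right") - 1
    t0 = theta_peaks[idx]
    t1 = theta_peaks[idx + 1]
    phases = 360.0 * (spike_times[in_span] - t0) / (t1 - t0)
    return phases, in_span, int((~in_span).sum())


def linearize_circular(positions: np.ndarray, center: tuple[float, float],
                       ref_deg: float = 0.0) -> np.ndarray:
    """Angular position on a circular track, unwrapped across laps (deg).

    The angle of (position - center), counterclockwise from +x (or from
    ``ref_deg``), unwrapped so that successive laps continue past 360.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    d = positions - np.asarray(center, dtype=float)
    r = np.hypot(d[:, 0], d[:, 1])
    if np.any(r < 1e-9):
        raise ValueError("position coincides with the track center")
    ang = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    return np.rad2deg(ang) - ref_deg


@dataclass
class PhasePrecessionFit:
    """Straight-line fit of theta phase on linearized position."""

    slope: float               # deg phase per position unit
    intercept: float
    phases_deg: np.ndarray
    positions: np.ndarray
    d_p: np.ndarray | None     # per-spike position residuals
    residual_variance: float   # unbiased (n-1); NaN when degenerate
    degenerate_slope: bool


def fit_phase_precession(phases_deg: np.ndarray, positions: np.ndarray,
                         slope_tol: float = 1e-8) -> PhasePrecessionFit:
    """Least-squares line of phase on position, and its d_p residuals.

    d_p for each spike is the position implied by inverting the fitted
    line at the spike's phase, minus the actual position; the unbiased
    variance of d_p across spikes measures the tightness of the
    precession cloud.  Near-zero slopes make the inversion unstable and
    are reported with ``degenerate_slope=True`` and no variance.
    """
    phases_deg = np.asarray(phases_deg, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if len(phases_deg) < 3:
        raise ValueError("need at least 3 spikes to fit phase precession")
    if np.ptp(positions) == 0:
        raise ValueError("zero position spread; cannot fit")
    slope, intercept = np.polyfit(positions, phases_deg, 1)
    if abs(slope) < slope_tol:
        return PhasePrecessionFit(float(slope), float(intercept), phases_deg,
                                  positions, None, np.nan, True)
    d_p = (phases_deg - intercept) / slope - positions
    var = float(np.var(d_p, ddof=1))
    return PhasePrecessionFit(float(slope), float(intercept), phases_deg,
                              positions, d_p, var, False)
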