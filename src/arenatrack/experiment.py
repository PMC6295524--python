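"""Jitter-degradation experiment: native vs jittered frame-time metrics.

Frame timing errors corrupt spatial metrics through one mechanism only:
each spike takes the position of the frame whose (estimated) timestamp
is nearest.  Replacing a camera's accurately timed IFIs with draws from
a noisier camera's IFI pool and re-assigning spike positions under the
jittered timeline therefore emulates recording the same session on the
noisier camera.  The experiment computes, per cell, spatial information
(adaptive-binned), peak firing rate and largest place-field size
(Gaussian-smoothed) under native and jittered timestamps, and compares
the pairs with Wilcoxon signed-rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import neuro
from .stats import TestResult, wilcoxon_signed_rank
from .timesync import FrameTimestampSeries, inject_jitter

METRICS = ("spatial_info", "peak_rate", "field_size")


@dataclass
class CellMetrics:
    spatial_info: float
    peak_rate: float
    field_size: float  # bins of the largest field; NaN when no field


@dataclass
class JitterExperimentResult:
    pairs: pd.DataFrame                       # one row per cell, native/jittered columns
    tests: dict[str, TestResult] = field(default_factory=dict)
    tests_skipped: bool = False

    def median_change(self, metric: str) -> float:
        """Median of (jittered - native) for a metric."""
        return float(np.nanmedian(self.pairs[f"{metric}_jittered"]
                                  - self.pairs[f"{metric}_native"]))


def compute_cell_metrics(times: np.ndarray, positions: np.ndarray,
                         spikes: np.ndarray, bin_size: float,
                         speeds: np.ndarray | None = None,
                         extent=None,
                         alpha: float = neuro.ADAPTIVE_ALPHA) -> CellMetrics:
    """Spatial information, peak rate and largest field size for one cell."""
    base = neuro.compute_rate_map(times, positions, spikes, bin_size,
                                  speeds=speeds, extent=extent)
    adaptive_rate = neuro.adaptive_rates_from_counts(
        base.occupancy_samples, base.occupancy_s, base.spike_counts,
        base.valid, alpha)
    si = neuro._skaggs(base.occupancy_s[base.valid], adaptive_rate[base.valid])
    smoothed = neuro.smooth_map_gaussian(base)
    fields = neuro.detect_place_fields(smoothed)
    return CellMetrics(
        spatial_info=float(si),
        peak_rate=smoothed.peak_rate,
        field_size=float(fields[0].size_bins) if fields else np.nan,
    )


def passes_inclusion_criteria(times: np.ndarray, positions: np.ndarray,
                              spikes: np.ndarray, bin_size: float,
                              speeds: np.ndarray | None = None,
                              min_spikes: int = 50, max_mean_rate: float = 10.0,
                              significance_p: float | None = 0.01,
                              n_shuffles: int = 200,
                              estimator: str = "raw",
                              seed: int = 0, extent=None) -> bool:
    """Unit inclusion: >= 50 spikes, mean rate <= 10 Hz (putative
    interneurons excluded), and significant spatial information.

    Set ``significance_p=None`` to skip the shuffle test.
    """
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size < min_spikes:
        return False
    duration = float(times[-1] - times[0])
    if spikes.size / duration > max_mean_rate:
        return False
    if significance_p is not None:
        p, _, _ = neuro.shuffle_significance(
            times, positions, spikes, bin_size, speeds=speeds,
            n_shuffles=n_shuffles, seed=seed, estimator=estimator, extent=extent)
        if p >= significance_p:
            return False
    return True


def jitter_degradation_experiment(frame_times: np.ndarray, positions: np.ndarray,
                                  cells: list[np.ndarray], ifi_pool: np.ndarray,
                                  bin_size: float,
                                  speeds: np.ndarray | None = None,
                                  nominal_rate: float = 30.0,
                                  n_seeds: int = 1,
                                  seed: int | np.random.Generator = 0,
                                  extent=None,
                                  min_cells_for_test: int = 6,
                                  ) -> JitterExperimentResult:
    """Paired native-vs-jittered metrics plus Wilcoxon comparisons.

    ``frame_times`` are the accurately synchronized frame timestamps on
    the acquisition clock; ``positions`` the per-frame tracked positions;
    ``cells`` one spike-time array per unit (same clock).  For each of
    ``n_seeds`` jitter draws the frame timeline is resampled from
    ``ifi_pool`` and metrics recomputed with spikes re-assigned under the
    jittered timeline; per-cell jittered metrics are averaged over seeds.

    With fewer than ``min_cells_for_test`` cells the paired tests are
    skipped (``tests_skipped=True``) but the pairs are still reported.
    """
    if np.asarray(ifi_pool).size == 0:
        raise ValueError("IFI pool must be nonempty")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    frame_times = np.asarray(frame_times, dtype=float)
    series = FrameTimestampSeries("native", frame_times, nominal_rate)

    if speeds is None:
        from .tracking import compute_speed
        speeds = compute_speed(frame_times, positions)

    native = [compute_cell_metrics(frame_times, positions, spk, bin_size,
                                   speeds=speeds, extent=extent)
              for spk in cells]

    jittered_acc = np.zeros((len(cells), len(METRICS)))
    for _ in range(n_seeds):
        jit = inject_jitter(series, ifi_pool, seed=rng)
        for ci, spk in enumerate(cells):
            m = compute_cell_metrics(jit.times, positions, spk, bin_size,
                                     speeds=speeds, extent=extent)
            jittered_acc[ci] += [m.spatial_info, m.peak_rate, m.field_size]
    jittered_acc /= n_seeds

    rows = {}
    for mi, name in enumerate(METRICS):
        rows[f"{name}_native"] = [getattr(m, name) for m in native]
        rows[f"{name}_jittered"] = jittered_acc[:, mi]
    pairs = pd.DataFrame(rows)

    tests: dict[str, TestResult] = {}
    skipped = len(cells) < min_cells_for_test
    if not skipped:
        for name in METRICS:
            a = pairs[f"{name}_native"].to_numpy()
            b = pairs[f"{name}_jittered"].to_numpy()
            ok = np.isfinite(a) & np.isfinite(b)
            try:
                tests[name] = wilcoxon_signed_rank(a[ok], b[ok])
            except ValueError:
                # degenerate pool: every pair identical
                tests[name] = TestResult(0.0, 1.0, {"degenerate": True})
    return JitterExperimentResult(pairs, tests, skipped)
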