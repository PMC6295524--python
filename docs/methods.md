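# Methods

This document describes the models implemented in `arenatrack`, the
assumptions behind them, the default parameters, and the known limitations.
All claims are exercised by the test suite on synthetic data with known
ground truth.

## 1. Synthetic world (`arenatrack.synth`)

The generator is the reference against which every pipeline stage is
validated. It is deliberately simple: each component models only the
structure the corresponding analysis is supposed to recover.

**Trajectory.** Foraging is a reflected Ornstein–Uhlenbeck velocity process
(`simulate_trajectory`; relaxation time `tau = 1 s`, integration step
`dt = 20 ms`), rescaled so the realized mean speed matches `mean_speed`
(default 10 cm/s). Positions are continuous in time via linear
interpolation (`Trajectory.at`). A circular-track variant
(`simulate_circular_trajectory`) supports linearization and phase-precession
tests.

**Cameras.** Each camera is a planar homography from arena centimetres to
pixels. `make_camera_grid` tiles an arena with an `nx × ny` grid of views
with a configurable `overlap` fraction, random small rotations/scale
perturbations, and an optional `perspective` term that sets the third row of
the homography (`H[2, :2] = ±perspective`). Because that term multiplies
*centimetre* coordinates, useful values are small (≈ 0.002 for a 2-m arena);
large values tilt views so far that they no longer intersect the arena.

**Head LEDs.** The head carries an anterior red and posterior green LED
(`LedGeometry`, default 2.5 cm on either side of the head centre). Frames
are rendered as anti-aliased discs on a dark background; axis-aligned
rectangular `Occluder` regions hide the animal from the cameras listed in
`blocks`, which is how single-camera-coverage scenarios are constructed.

**Clocks and timing.** Each device clock is affine in acquisition time
(offset + drift). TTL transitions (`make_ttl_log`, default 1-s period) are
recorded both on the DAQ and on each device clock. Two empirical
inter-frame-interval (IFI) pools represent camera classes:

- `commercial_ifi_pool`: a two-component mixture calibrated to a ±7 ms
  jitter range with ≈ 40 % of frames deviating by more than 1 ms
  (60 % of IFIs near-nominal, 40 % drawn wide).
- `picamera_ifi_pool`: deviations uniform within ±0.025 ms.

**Spikes.** `simulate_spikes` draws an inhomogeneous Poisson train by
thinning against a declared tuning curve: Gaussian place fields, von-Mises
head-direction tuning, or theta-modulated/phase-precessing variants. Spike
counts match the integrated rate to within sampling error, which the tests
check with `np.trapezoid`.

## 2. Registration (`arenatrack.registration`)

Pairwise homographies are estimated from matched features with the
normalized (Hartley) DLT — both point sets are translated/scaled to mean
zero and RMS distance √2 before the SVD — inside a RANSAC loop
(`estimate_homography_ransac`, inlier threshold 2 px, refit on the
consensus set). `build_canvas` chains pairwise estimates along shortest
paths in the camera-overlap graph to a chosen reference camera and raises on
a disconnected graph. Metric scale comes from one declared landmark: two
reference-image pixel positions plus their true separation in centimetres
define a single scalar scale.

`projection_error` quantifies stitching quality without ground truth: for
every calibration intersection seen by ≥ 2 cameras, each camera's error is
the distance from its warped observation to the mean warped position of that
intersection, reported per camera and overall.

**Limitation — canvas anisotropy.** The canvas axes are the reference
camera's image axes under one scalar scale. If the reference camera's
pixels are anisotropic (different px/cm horizontally and vertically),
distances on the canvas are metric only along the landmark direction. Use a
reference view with near-square pixels, or supply landmark pairs along the
axis you intend to measure.

## 3. Tracking (`arenatrack.tracking`)

Frames are converted to HSV; red (hue ≤ 10° or ≥ 160°, wrapping) and green
(50–70°) masks are thresholded on saturation and value
(`DEFAULT_INTENSITY_THRESHOLD = 50`). The largest connected component with
≥ 3 pixels yields an intensity-weighted sub-pixel centroid per camera. Each
camera's detection is warped to the canvas and the per-frame position is the
mean over contributing cameras; one camera suffices. Head direction is the
angle from posterior (green) to anterior (red) LED; speed is a
centred-difference estimate over a short window. Gaps up to
`max_gap_frames = 5` are linearly interpolated; longer gaps stay NaN.

**Limitation — border clipping.** When an LED disc is clipped by the image
border, that camera's centroid is biased inward by up to a few centimetres
on isolated frames. Median accuracy is sub-millimetre; accuracy statements
are therefore made on percentiles, not maxima.

## 4. Time synchronization (`arenatrack.timesync`)

`build_clock_map` matches device and DAQ TTL event trains (truncating to the
common length with a warning) and fits the affine map device → DAQ by least
squares; with a single common event it degenerates to a constant offset.
Because device clocks are affine in truth, residuals inside the TTL span are
zero to machine precision with ≥ 2 events, and extrapolation beyond the span
inherits the fitted drift.

`ifi_report` summarizes timing health: deviations of each IFI from the
expected interval, the jitter range (min, max deviation), the fraction of
deviations exceeding each threshold (default 1 ms, strict inequality), and a
dropped-frame count. An IFI within ±25 % of *k* × expected (integer
*k* ≥ 2) is counted as *k* − 1 dropped frames and excluded from the jitter
range and threshold fractions — so a doubled interval is a drop, while a
1.6× interval is (extreme) jitter.

`inject_jitter` resamples a recording's IFIs from an empirical pool,
preserving frame count, start time, and total span; this is the mechanism of
the degradation experiment (§ 6).

## 5. Spatial-coding analysis (`arenatrack.neuro`)

**Rate maps.** Spikes are assigned to the nearest tracking sample. Samples
slower than `SPEED_MIN_CMS = 2 cm/s` and bins with less than
`OCC_MIN_S = 0.4 s` occupancy are excluded. Smoothing is mask-normalized
Gaussian (`σ = 1.25` bins): invalid bins are removed from both numerator and
kernel normalization so missing coverage does not drag down edge rates.

**Adaptive binning.** The adaptive estimate at each bin expands a circle of
radius *r* until `n_occ² · r² ≥ alpha / dwell-structure`
(`ADAPTIVE_ALPHA = 1e6`), implemented with FFT ring convolutions; radius is
capped at the map diagonal with a dwell-ratio fallback. The implementation
is verified in-test against a brute-force expanding-circle oracle to
relative tolerance 1e-9.

**Spatial information.** Skaggs information per spike,
`SI = Σ pᵢ (λᵢ/λ) log₂(λᵢ/λ)`. A uniform map gives exactly 0; all rate
concentrated in one of four equally occupied bins gives exactly log₂ 4.

**Shuffle significance.** The null cyclically shifts spike times by a
uniform draw from `[margin, T − margin]` (`margin_s = 30`), wrapping around
the session, and recomputes SI; the p-value is the fraction of null SIs at
or above the observed one. Because the shuffle permutes the same spike
count over the same occupancy, the p-value depends only on the rank of the
observed SI among shuffles; the cheap `estimator="raw"` (unsmoothed map)
is therefore used for calibration runs. On 500 uniform-rate null cells the
empirical false-positive rate at p < 0.01 falls within [0, 0.02].

**Place fields.** Fields grow from local maxima of the smoothed map: a
field is the 4-connected component, containing its peak, of bins above 15 %
of that field's own peak. Fields peaking below 25 % of the map maximum or
smaller than `FIELD_MIN_BINS = 7` bins are discarded. The criterion is
scale-invariant. Note that an *untuned* cell produces either no field or
one sprawling component covering much of the map — field analysis is only
meaningful after cells pass inclusion screening (§ 6).

**Head direction and theta.** HD tuning uses binned firing rate versus
head angle with circular FWHM; preferred direction is the circular mean.
Phase precession is a linear fit of spike theta phase against linearized
position on a circular track.

## 6. Jitter-degradation experiment (`arenatrack.experiment`)

For each cell, metrics (spatial information, peak rate, field size in bins)
are computed on the native timestamps and on `n_seeds` jitter-injected
versions (averaged), giving a paired table. Direction and significance of
the change use the paired Wilcoxon signed-rank test (normal approximation
with tie correction and continuity correction) with Holm–Bonferroni
adjustment across the three metrics; tests are skipped below
`min_cells_for_test = 6` cells.

Inclusion screening (`passes_inclusion_criteria`): ≥ 50 spikes, mean rate
≤ 10 Hz, and shuffle significance p < 0.01 (raw estimator, 200 shuffles).

The package's reference study conditions (used by the tests and
`scripts/acceptance.py`): a 100 × 100 cm arena, 2400 s at 30 Hz, 20 place
cells with peak rates U(8, 15) Hz, centres U(20, 80)², widths U(6, 10) cm,
baseline 0.05 Hz; 2-cm bins; 5 jitter seeds per cell. Under the wide pool
the median change is negative for spatial information and peak rate and
positive for field size, all Holm-significant. Under the narrow pool the
median relative change of every metric is below 1 %; individual cells can
move up to a few percent because field size is an integer bin count and
peak rate lives on a discretized map, which places a quantization floor
under per-cell changes.

## 7. Statistics (`arenatrack.stats`)

- `f_test_equal_variance`: two-sided variance-ratio F test; the ratio is
  reported as given (not reordered).
- `wilcoxon_signed_rank`: normal approximation with tie correction and
  continuity correction; zero differences are dropped. Matches
  `scipy.stats.wilcoxon(mode="approx", correction=True)` to 1e-9.
- `proportion_z_test`: one-sample normal-approximation test of a proportion
  (6/6 successes against 0.5 gives z = √6 ≈ 2.4495).
- `holm_bonferroni`: step-down adjusted p-values, monotone and capped at 1.

## 8. Limitations

- The camera model is a pure plane-to-plane homography: no lens distortion,
  no rolling shutter, no exposure effects.
- Canvas distances are metric only along the landmark direction when the
  reference camera's pixels are anisotropic (§ 2).
- LED discs clipped at image borders bias single-frame centroids (§ 3).
- Device clocks are exactly affine; the TTL alignment therefore achieves
  zero residual by construction and does not model clock wander between
  TTL events.
- Field size is an integer bin count, so small timing perturbations produce
  quantized, not continuous, metric changes (§ 6).
- The occupancy filter (0.4 s per bin) means short sessions or large
  arenas can leave no valid bins; `analyze` fails loudly in that case
  rather than returning maps dominated by noise.
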