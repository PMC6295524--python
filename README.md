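# arenatrack

Multi-camera rodent tracking and spatial-coding analysis, built around a fully
synthetic test bed.

Large arenas cannot be covered by a single inexpensive camera, so the package
stitches several overlapping views into one metric canvas: pairwise planar
homographies are estimated from matched calibration features (normalized DLT
inside RANSAC), chained to a reference camera, and scaled to centimetres by a
single declared landmark distance. Head position comes from two colored LEDs
detected per camera in HSV space, warped to the canvas and merged across
whichever cameras see them — so an animal occluded in three of four views is
still tracked from the fourth. Per-camera frame timestamps are mapped onto a
shared DAQ clock through an affine fit to common TTL events, which removes
both offset and drift between free-running device clocks.

On top of the tracker sit standard spatial-coding analyses: occupancy and
rate maps (fixed-bin and adaptive-binned), Skaggs spatial information,
cyclic-shift shuffle significance, place-field detection, head-direction
tuning, and theta-phase precession fits. A built-in degradation experiment
quantifies what frame-timing jitter does to these metrics: resampling
inter-frame intervals from a wide (±7 ms-scale) pool measurably lowers
spatial information and peak rate and inflates field size, while a
narrow (±25 µs) pool leaves them essentially unchanged.

Everything is validated against synthetic sessions with known ground truth:
the `synth` module generates trajectories, camera rigs, rendered LED frames,
occluders, device clocks, TTL logs, and Poisson spike trains from declared
tuning curves, so every pipeline stage can be checked against the quantity it
is supposed to recover.

## Worked example

```python
import numpy as np

from arenatrack import neuro, synth, tracking
from arenatrack.registration import CameraRegistration

# --- 1. simulate a 2x2 camera rig watching a 60x60 cm arena for 60 s ---
arena = synth.ArenaSpec(60.0, 60.0)
rig = synth.make_camera_grid(arena, 2, 2, image_size=(320, 240), overlap=0.4,
                             seed=1)
traj = synth.simulate_trajectory(arena, 60.0, mean_speed=12.0, seed=2)
recordings = synth.render_session(traj, rig, arena=arena, seed=3)

# --- 2. track the head LEDs and merge across cameras ---
regs = {c.camera_id: CameraRegistration(c.camera_id, np.linalg.inv(c.homography))
        for c in rig}
sess = tracking.track_session(
    recordings, regs,
    aligned_times={cid: r.acquisition_times for cid, r in recordings.items()})
truth, _ = traj.at(sess.times)
err = np.linalg.norm(sess.positions - truth, axis=1)
print(f"frames tracked : {len(sess)}  (coverage {sess.coverage:.3f})")
print(f"median error   : {np.nanmedian(err):.3f} cm")

# --- 3. a synthetic place cell on a longer foraging session ---
traj2 = synth.simulate_trajectory(arena, 600.0, mean_speed=12.0, seed=11)
frame_times = np.arange(0.0, 600.0, 1.0 / 30.0)
positions, _ = traj2.at(frame_times)
spec = synth.NeuronSpec("place", peak_rate=12.0, baseline_rate=0.1,
                        center_cm=(20.0, 40.0), sigma_cm=7.0)
spikes, _ = synth.simulate_spikes(traj2, spec, seed=21)

rm = neuro.compute_rate_map(frame_times, positions, spikes, bin_size=4.0,
                            extent=(0, 60, 0, 60))
si = neuro.spatial_information(rm)
p, observed, null = neuro.shuffle_significance(frame_times, positions, spikes,
                                               4.0, n_shuffles=200, seed=5)
fields = neuro.detect_place_fields(neuro.smooth_map_gaussian(rm))
print(f"spikes         : {len(spikes)}")
print(f"spatial info   : {si:.3f} bits/spike (shuffle p = {p:.4f})")
print(f"peak rate      : {np.nanmax(rm.rate):.2f} Hz")
print(f"place fields   : {len(fields)}, largest {fields[0].size_bins} bins, "
      f"peak {fields[0].peak_rate:.2f} Hz")
```

Output:

```
frames tracked : 1801  (coverage 1.000)
median error   : 0.011 cm
spikes         : 439
spatial info   : 2.117 bits/spike (shuffle p = 0.0000)
peak rate      : 12.58 Hz
place fields   : 1, largest 55 bins, peak 7.90 Hz
```

## Command line

The same pipeline is available as a CLI (`arenatrack --help`):

| command     | purpose                                                        |
|-------------|----------------------------------------------------------------|
| `simulate`  | render a synthetic session (frames, timestamps, TTL, calibration scene) to disk |
| `register`  | match calibration features and build the canvas registrations  |
| `track`     | detect, warp, merge, and align a recorded session → tracking CSV |
| `analyze`   | rate map, spatial information, shuffle test, HD tuning → summary JSON |
| `benchmark` | run the jitter-degradation experiment from a YAML config       |

Example:

```bash
arenatrack simulate --out sess --arena-cm 50 50 --cameras 2 1 --duration-s 3 --seed 5
arenatrack register --calib-dir sess/calibration --ref-camera cam1 --out regs.json
arenatrack track --session-dir sess --registration regs.json --out track.csv
```

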