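"""Rate maps, spatial information, place fields, HD tuning, phase precession."""

import numpy as np
import pytest
from scipy import ndimage

from arenatrack import neuro, synth
from arenatrack.neuro import (RateMap, adaptive_rate_map, adaptive_rates_from_counts,
                              assign_spike_samples, assign_theta_phase,
                              compute_rate_map, cyclic_shift_spikes,
                              detect_place_fields, fit_phase_precession, hd_tuning,
                              linearize_circular, shuffle_significance,
                              smooth_map_gaussian, spatial_information)


def make_rate_map(occ_s, rate, bin_size=4.0):
    occ_s = np.asarray(occ_s, dtype=float)
    rate = np.asarray(rate, dtype=float)
    valid = occ_s > 0
    ny, nx = occ_s.shape
    return RateMap(bin_size,
                   np.arange(nx + 1) * bin_size, np.arange(ny + 1) * bin_size,
                   occ_s, occ_s * 30.0, rate * occ_s, np.where(valid, rate, np.nan),
                   valid)


class TestSampleAssignment:
    def test_spikes_take_nearest_sample(self):
        samples = np.array([0.0, 1.0, 2.0, 3.0])
        spikes = np.array([0.1, 0.9, 1.6, 2.49, 2.51])
        assert assign_spike_samples(spikes, samples).tolist() == [0, 1, 2, 2, 3]


class TestComputeRateMap:
    def test_known_occupancy_and_rates(self):
        # 1-s dwell per sample, two bins on the x axis
        times = np.arange(8.0)
        positions = np.array([[1.0, 1.0]] * 4 + [[5.0, 1.0]] * 4)
        spikes = np.array([0.1, 0.2, 4.1])  # 2 spikes in bin 0, 1 in bin 1
        rmap = compute_rate_map(times, positions, spikes, 4.0,
                                extent=(0, 8, 0, 4), occ_min=0.4, speed_min=0.0)
        assert rmap.occupancy_s.shape == (1, 2)
        assert np.allclose(rmap.occupancy_s, [[4.0, 4.0]])
        assert np.allclose(rmap.spike_counts, [[2.0, 1.0]])
        assert np.allclose(rmap.rate, [[0.5, 0.25]])

    def test_slow_samples_and_their_spikes_excluded(self):
        times = np.arange(8.0)
        positions = np.tile([[1.0, 1.0]], (8, 1))
        positions[4:] = [5.0, 1.0]
        speeds = np.array([5.0] * 4 + [0.5] * 4)  # second half below 2 cm/s
        spikes = np.array([0.1, 4.1, 5.1])
        rmap = compute_rate_map(times, positions, spikes, 4.0,
                                speeds=speeds, extent=(0, 8, 0, 4), occ_min=0.4)
        assert rmap.valid.tolist() == [[True, False]]
        assert rmap.spike_counts[0, 0] == 1.0

    def test_low_occupancy_bins_invalid(self):
        times = np.arange(0, 3, 0.1)
        positions = np.tile([[1.0, 1.0]], (len(times), 1))
        positions[-1] = [5.0, 1.0]  # 0.1 s in the second bin
        rmap = compute_rate_map(times, positions, np.array([]), 4.0,
                                extent=(0, 8, 0, 4), speed_min=0.0)
        assert rmap.valid[0, 0]
        assert not rmap.valid[0, 1]
        assert np.isnan(rmap.rate[0, 1])

    def test_all_bins_filtered_raises(self):
        times = np.arange(3.0)
        positions = np.tile([[1.0, 1.0]], (3, 1))
        with pytest.raises(ValueError, match="no valid bins"):
            compute_rate_map(times, positions, np.array([]), 4.0,
                             speeds=np.zeros(3), extent=(0, 8, 0, 4))


class TestSmoothing:
    def test_uniform_map_unchanged_despite_invalid_holes(self):
        occ = np.full((9, 9), 1.0)
        occ[4, 4] = 0.0  # invalid hole
        rmap = make_rate_map(occ, np.full((9, 9), 3.0))
        sm = smooth_map_gaussian(rmap)
        assert np.allclose(sm.rate[rmap.valid], 3.0)
        assert np.isnan(sm.rate[4, 4])

    def test_smoothing_conserves_peak_location(self):
        occ = np.full((15, 15), 1.0)
        rate = np.zeros((15, 15))
        rate[7, 7] = 10.0
        sm = smooth_map_gaussian(make_rate_map(occ, rate))
        assert np.unravel_index(np.nanargmax(sm.rate), (15, 15)) == (7, 7)


class TestSpatialInformation:
    def test_uniform_rate_is_zero_information(self):
        rmap = make_rate_map(np.full((5, 5), 2.0), np.full((5, 5), 4.0))
        assert abs(spatial_information(rmap)) < 1e-12

    def test_concentration_in_one_of_four_bins_is_two_bits(self):
        occ = np.full((2, 2), 1.0)
        rate = np.array([[8.0, 0.0], [0.0, 0.0]])
        assert spatial_information(make_rate_map(occ, rate)) == pytest.approx(2.0)

    def test_concentration_in_one_of_two_bins_is_one_bit(self):
        occ = np.full((1, 2), 1.0)
        rate = np.array([[6.0, 0.0]])
        assert spatial_information(make_rate_map(occ, rate)) == pytest.approx(1.0)

    def test_unequal_occupancy_weighting(self):
        # p = (0.75, 0.25), lambda = (0, 4): mean rate 1, I = 0.25*4*log2(4) = 2
        occ = np.array([[3.0, 1.0]])
        rate = np.array([[0.0, 4.0]])
        assert spatial_information(make_rate_map(occ, rate)) == pytest.approx(2.0)


def brute_force_adaptive(occ_samples, occ_s, spikes, valid, alpha):
    """Independent expanding-circle implementation used as an oracle."""
    ny, nx = occ_s.shape
    r_max = int(np.ceil(np.hypot(ny, nx)))
    occ_w = np.where(valid, occ_samples, 0.0)
    dwell_w = np.where(valid, occ_s, 0.0)
    spk_w = np.where(valid, spikes, 0.0)
    rate = np.full((ny, nx), np.nan)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for iy in range(ny):
        for ix in range(nx):
            if not valid[iy, ix]:
                continue
            for r in range(1, r_max + 1):
                disc = (yy - iy) ** 2 + (xx - ix) ** 2 <= r ** 2
                n_occ = occ_w[disc].sum()
                n_spk = spk_w[disc].sum()
                need = alpha / (n_occ ** 2 * r ** 2) if n_occ > 1e-9 else np.inf
                if n_spk > need:
                    rate[iy, ix] = n_spk / dwell_w[disc].sum()
                    break
            else:
                disc = (yy - iy) ** 2 + (xx - ix) ** 2 <= r_max ** 2
                dwell = dwell_w[disc].sum()
                rate[iy, ix] = spk_w[disc].sum() / dwell if dwell > 0 else 0.0
    return rate


class TestAdaptiveBinning:
    def test_fft_implementation_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        occ_samples = rng.poisson(60, size=(12, 12)).astype(float)
        occ_s = occ_samples / 30.0
        spikes = rng.poisson(1.2, size=(12, 12)).astype(float)
        valid = occ_s >= 0.4
        got = adaptive_rates_from_counts(occ_samples, occ_s, spikes, valid,
                                         alpha=1e6)
        want = brute_force_adaptive(occ_samples, occ_s, spikes, valid, 1e6)
        assert np.allclose(got[valid], want[valid], rtol=1e-9)
        assert np.isnan(got[~valid]).all()

    def test_zero_spikes_give_zero_rates(self):
        occ_samples = np.full((8, 8), 100.0)
        got = adaptive_rates_from_counts(occ_samples, occ_samples / 30.0,
                                         np.zeros((8, 8)),
                                         np.ones((8, 8), dtype=bool))
        assert np.allclose(got, 0.0)

    def test_adaptive_map_close_to_truth_on_simulated_cell(self, foraging,
                                                           place_cell_spikes):
        spec, spikes = place_cell_spikes
        rmap = adaptive_rate_map(foraging["frame_times"], foraging["positions"],
                                 spikes, 4.0, speeds=foraging["speeds"],
                                 extent=(0, 60, 0, 60))
        iy, ix = np.unravel_index(np.nanargmax(np.where(rmap.valid, rmap.rate,
                                                        -np.inf)), rmap.rate.shape)
        cx = (rmap.x_edges[ix] + rmap.x_edges[ix + 1]) / 2
        cy = (rmap.y_edges[iy] + rmap.y_edges[iy + 1]) / 2
        assert np.hypot(cx - spec.center_cm[0], cy - spec.center_cm[1]) < 8.0


class TestShuffleSignificance:
    def test_place_cell_significant(self, foraging, place_cell_spikes):
        _, spikes = place_cell_spikes
        p, null, obs = shuffle_significance(
            foraging["frame_times"], foraging["positions"], spikes, 4.0,
            speeds=foraging["speeds"], n_shuffles=200, seed=1)
        assert p < 0.01
        assert obs > np.percentile(null, 99)

    def test_position_independent_cell_not_significant(self, foraging):
        rng = np.random.default_rng(31)
        spikes = np.sort(rng.uniform(40.0, 560.0, 900))
        p, _, _ = shuffle_significance(
            foraging["frame_times"], foraging["positions"], spikes, 4.0,
            speeds=foraging["speeds"], n_shuffles=200, seed=2)
        assert p > 0.05

    def test_raw_and_adaptive_estimators_agree_on_strong_cell(self, foraging,
                                                              place_cell_spikes):
        _, spikes = place_cell_spikes
        p_raw, _, _ = shuffle_significance(
            foraging["frame_times"], foraging["positions"], spikes, 4.0,
            speeds=foraging["speeds"], n_shuffles=100, seed=3, estimator="raw")
        assert p_raw < 0.01

    def test_short_session_rejected(self):
        t = np.arange(0, 50, 0.1)
        pos = np.tile([[1.0, 1.0]], (len(t), 1))
        with pytest.raises(ValueError, match="margin"):
            shuffle_significance(t, pos, np.array([1.0]), 4.0, speed_min=0.0)

    def test_cyclic_shift_wraps_and_preserves_count(self):
        spikes = np.array([1.0, 5.0, 9.0])
        shifted = cyclic_shift_spikes(spikes, 0.0, 10.0, 3.0)
        assert np.allclose(np.sort(shifted), [2.0, 4.0, 8.0])


class TestPlaceFields:
    def test_single_gaussian_blob_is_one_field(self):
        yy, xx = np.mgrid[0:20, 0:20]
        rate = 8.0 * np.exp(-((xx - 10.0) ** 2 + (yy - 10.0) ** 2) / (2 * 3.0 ** 2))
        sm = make_rate_map(np.full((20, 20), 1.0), rate)
        fields = detect_place_fields(sm)
        assert len(fields) == 1
        # bins above 15% of the peak within a radius sqrt(2 ln(1/0.15)) sigma
        r15 = 3.0 * np.sqrt(2 * np.log(1 / 0.15))
        expected = np.sum((xx - 10.0) ** 2 + (yy - 10.0) ** 2 < r15 ** 2)
        assert fields[0].size_bins == pytest.approx(expected, rel=0.15)

    def test_secondary_peak_below_quarter_of_map_peak_excluded(self):
        rate = np.zeros((20, 20))
        yy, xx = np.mgrid[0:20, 0:20]
        rate += 10.0 * np.exp(-((xx - 5) ** 2 + (yy - 5) ** 2) / 8.0)
        rate += 2.0 * np.exp(-((xx - 15) ** 2 + (yy - 15) ** 2) / 8.0)  # 20% of peak
        fields = detect_place_fields(make_rate_map(np.ones((20, 20)), rate))
        assert len(fields) == 1
        assert fields[0].peak_rate == pytest.approx(10.0, rel=0.01)

    def test_two_comparable_peaks_both_detected(self):
        rate = np.zeros((24, 24))
        yy, xx = np.mgrid[0:24, 0:24]
        rate += 10.0 * np.exp(-((xx - 6) ** 2 + (yy - 6) ** 2) / 8.0)
        rate += 7.0 * np.exp(-((xx - 17) ** 2 + (yy - 17) ** 2) / 8.0)
        fields = detect_place_fields(make_rate_map(np.ones((24, 24)), rate))
        assert len(fields) == 2
        assert fields[0].size_bins >= fields[1].size_bins

    def test_tiny_blob_below_seven_bins_excluded(self):
        rate = np.zeros((15, 15))
        rate[7, 7] = 10.0
        rate[7, 8] = 9.0
        fields = detect_place_fields(make_rate_map(np.ones((15, 15)), rate))
        assert fields == []

    def test_scale_invariance(self):
        yy, xx = np.mgrid[0:20, 0:20]
        rate = 5.0 * np.exp(-((xx - 10.0) ** 2 + (yy - 8.0) ** 2) / 18.0)
        f1 = detect_place_fields(make_rate_map(np.ones((20, 20)), rate))
        f2 = detect_place_fields(make_rate_map(np.ones((20, 20)), 37.0 * rate))
        assert [f.size_bins for f in f1] == [f.size_bins for f in f2]


class TestHdTuning:
    def test_preferred_direction_recovered(self, foraging):
        spec = synth.NeuronSpec("head_direction", peak_rate=18.0, baseline_rate=0.2,
                                preferred_deg=135.0, kappa=4.0)
        spikes, _ = synth.simulate_spikes(foraging["traj"], spec, seed=41)
        tc = hd_tuning(foraging["frame_times"], foraging["head_directions"],
                       spikes, speeds=foraging["speeds"])
        peak_dir = tc.bin_centers_deg[np.argmax(tc.rate_smoothed)]
        assert abs((peak_dir - 135.0 + 180) % 360 - 180) <= 15.0
        assert 30.0 < tc.fwhm_deg < 180.0

    def test_uniform_firing_has_undefined_fwhm(self):
        t = np.arange(0, 400, 0.1)
        hd = (t * 37.0) % 360.0
        rng = np.random.default_rng(5)
        spikes = np.sort(rng.uniform(0, 400, 2000))
        tc = hd_tuning(t, hd, spikes, speeds=None)
        assert np.isnan(tc.fwhm_deg)

    def test_triangular_curve_fwhm_exact(self):
        from arenatrack.neuro import _fwhm_circular
        edges = np.arange(0, 365, 5.0)
        rate = np.zeros(72)
        rate[10] = 10.0
        rate[9] = rate[11] = 5.0  # exactly half peak one bin away on each side
        assert _fwhm_circular(edges, rate) == pytest.approx(10.0)


class TestPhasePrecession:
    def test_phase_assignment_between_peaks(self):
        peaks = np.array([0.0, 0.1, 0.2, 0.3])
        phases, mask, dropped = assign_theta_phase(np.array([0.05, 0.125, 0.35]),
                                                   peaks)
        assert np.allclose(phases, [180.0, 90.0])
        assert dropped == 1
        assert mask.tolist() == [True, True, False]

    def test_linearization_unwraps_laps(self):
        theta = np.linspace(0, 4 * np.pi, 200)  # two laps
        pos = np.column_stack([50 + 30 * np.cos(theta), 50 + 30 * np.sin(theta)])
        lin = linearize_circular(pos, (50.0, 50.0))
        assert np.all(np.diff(lin) >= 0)
        assert lin[-1] - lin[0] == pytest.approx(720.0)

    def test_center_coincidence_rejected(self):
        with pytest.raises(ValueError):
            linearize_circular(np.array([[50.0, 50.0]]), (50.0, 50.0))

    def test_perfect_line_recovered_exactly(self):
        pos = np.linspace(0, 20, 40)
        phases = 300.0 - 8.0 * pos
        fit = fit_phase_precession(phases, pos)
        assert fit.slope == pytest.approx(-8.0)
        assert fit.intercept == pytest.approx(300.0)
        assert np.allclose(fit.d_p, 0.0, atol=1e-9)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-12)

    def test_flat_phase_flagged_degenerate(self):
        pos = np.linspace(0, 20, 30)
        fit = fit_phase_precession(np.full(30, 180.0), pos)
        assert fit.degenerate_slope
        assert np.isnan(fit.residual_variance)

    def test_simulated_precessing_cell_has_negative_slope(self):
        traj = synth.simulate_circular_trajectory((50.0, 50.0), 30.0, 300.0,
                                                  mean_speed=15.0, seed=43)
        spec = synth.NeuronSpec("phase_precessing", peak_rate=15.0,
                                baseline_rate=0.0, center_cm=(80.0, 50.0),
                                sigma_cm=8.0, phase_slope_deg_per_cm=-10.0)
        spikes, peaks = synth.simulate_spikes(traj, spec, seed=44)
        phases, mask, _ = assign_theta_phase(spikes, peaks)
        pos, _ = traj.at(spikes[mask])
        lin = linearize_circular(pos, (50.0, 50.0))
        # fold each pass through the field to its angle within the lap
        ang = lin % 360.0
        # keep spikes inside the field (field center at angle 0)
        in_field = np.minimum(ang, 360 - ang) < 25.0
        signed = np.where(ang[in_field] > 180, ang[in_field] - 360, ang[in_field])
        arc_cm = signed * np.pi * 30.0 / 180.0
        fit = fit_phase_precession(phases[in_field], arc_cm)
        assert fit.slope < -2.0
        assert not fit.degenerate_slope
        assert fit.residual_variance > 0
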