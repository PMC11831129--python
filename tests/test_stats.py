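"""Tests of trajectory statistics and size/amplitude comparisons."""

import numpy as np
import pandas as pd
import pytest

from driftvision.diffusion import DiffusionParams, Trajectory, generate_trajectories
from driftvision.stats import (compare_consecutive_trials,
                               compare_path_lengths_across_sizes,
                               displacement_autocorrelation, end_to_end_length,
                               estimate_D, msd_curve, path_length,
                               power_spectrum)


def _diffusion_ensemble(D, n, duration=0.5, dt=0.05, seed=0):
    return generate_trajectories(DiffusionParams(D=D, dt=dt), duration, n, seed=seed)


# ---------------------------------------------------------------------------
# diffusion coefficient
# ---------------------------------------------------------------------------

class TestEstimateD:
    def test_static_ensemble_gives_zero(self):
        est = estimate_D(_diffusion_ensemble(0.0, 10))
        assert est.D == 0.0

    def test_recovers_generating_D_within_5_percent(self):
        est = estimate_D(_diffusion_ensemble(200.0, 500, seed=11))
        assert est.D == pytest.approx(200.0, rel=0.05)
        assert est.D == pytest.approx(est.D_x + est.D_y, rel=1e-12)

    def test_isotropy_of_generated_drift(self):
        est = estimate_D(_diffusion_ensemble(200.0, 500, seed=11))
        assert 0.9 < est.D_x / est.D_y < 1.1

    def test_too_short_trajectory_named_in_error(self):
        bad = Trajectory(times=[0.0, 0.01], xs=[0.0, 0.1], ys=[0.0, 0.1],
                         meta={"trial": 17})
        with pytest.raises(ValueError, match="17"):
            estimate_D([bad], lag=0.05)


# ---------------------------------------------------------------------------
# power spectrum
# ---------------------------------------------------------------------------

class TestPowerSpectrum:
    def test_sinusoid_peaks_at_its_frequency(self):
        fs, f0 = 960.0, 32.0
        t = np.arange(int(0.5 * fs)) / fs
        traj = Trajectory(times=t, xs=np.sin(2 * np.pi * f0 * t), ys=np.zeros_like(t))
        spec = power_spectrum([traj], fit_band=(4.0, 200.0))
        assert spec.frequencies[np.argmax(spec.power)] == pytest.approx(f0, abs=2.0)

    def test_diffusion_slope_is_minus_two(self):
        """Random-walk position power falls as 1/f^2 (tracker-rate sampling)."""
        trajs = generate_trajectories(DiffusionParams(D=25.0, dt=1.0 / 960.0),
                                      0.5, 200, seed=5)
        spec = power_spectrum(trajs)
        assert -2.3 < spec.loglog_slope < -1.7

    def test_white_noise_positions_are_flat(self):
        rng = np.random.default_rng(0)
        t = np.arange(480) / 960.0
        trajs = [Trajectory(times=t, xs=rng.normal(size=480), ys=rng.normal(size=480))
                 for _ in range(100)]
        spec = power_spectrum(trajs)
        assert abs(spec.loglog_slope) < 0.3

    def test_fit_band_excludes_outer_octaves(self):
        trajs = generate_trajectories(DiffusionParams(D=25.0, dt=1.0 / 960.0),
                                      0.5, 5, seed=5)
        spec = power_spectrum(trajs, fit_band=(2.0, 100.0))
        assert spec.fit_band == (4.0, 50.0)

    def test_too_few_samples_rejected(self):
        traj = Trajectory(times=np.arange(4) * 0.05, xs=np.zeros(4), ys=np.zeros(4))
        with pytest.raises(ValueError, match="8 samples"):
            power_spectrum([traj])


# ---------------------------------------------------------------------------
# MSD curve
# ---------------------------------------------------------------------------

class TestMSD:
    def test_static_ensemble_is_identically_zero(self):
        df = msd_curve(_diffusion_ensemble(0.0, 20))
        assert np.all(df["msd_2d"] == 0.0)
        assert df.attrs["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_slope_estimates_D_intercept_near_zero(self):
        df = msd_curve(_diffusion_ensemble(100.0, 800, seed=21))
        assert df.attrs["slope"] == pytest.approx(100.0, rel=0.1)
        assert abs(df.attrs["intercept"]) < 0.1 * 100.0 * 0.5
        assert np.all(df["msd_2d"] >= 0.0)
        assert df.loc[0, "msd_2d"] == 0.0

    def test_agrees_with_estimate_D(self):
        trajs = _diffusion_ensemble(60.0, 400, seed=22)
        df = msd_curve(trajs)
        est = estimate_D(trajs)
        assert df.attrs["slope"] == pytest.approx(est.D, rel=0.1)


# ---------------------------------------------------------------------------
# path length and autocorrelation
# ---------------------------------------------------------------------------

class TestPathLength:
    def test_static_trajectory_is_zero(self):
        traj = Trajectory(times=[0.0, 0.05, 0.1], xs=[1.0] * 3, ys=[2.0] * 3)
        assert path_length(traj) == 0.0

    def test_straight_segment_has_its_length(self):
        traj = Trajectory(times=[0.0, 0.05, 0.1], xs=[0.0, 1.5, 3.0],
                          ys=[0.0, 2.0, 4.0])
        assert path_length(traj) == pytest.approx(5.0)
        assert end_to_end_length(traj) == pytest.approx(5.0)

    def test_mean_path_length_grows_with_D(self):
        means = [np.mean([path_length(t) for t in _diffusion_ensemble(D, 200, seed=int(D))])
                 for D in (10.0, 50.0, 200.0)]
        assert means[0] < means[1] < means[2]

    def test_fine_sampling_does_not_inflate(self):
        """Path length is computed on the 50 ms decoder base regardless of rate."""
        from driftvision.diffusion import upsample_trajectory
        traj = _diffusion_ensemble(100.0, 1, seed=3)[0]
        fine = upsample_trajectory(traj, 960.0)
        assert path_length(fine) == pytest.approx(path_length(traj), rel=1e-6)


class TestDisplacementAutocorrelation:
    def test_lag_zero_is_one_and_diffusion_is_uncorrelated(self):
        df = displacement_autocorrelation(_diffusion_ensemble(100.0, 300, duration=2.0),
                                          max_lag=4)
        assert df.loc[0, "autocorrelation"] == pytest.approx(1.0)
        assert np.all(np.abs(df.loc[1:, "autocorrelation"]) < 0.05)

    def test_ar1_steps_show_positive_lag_one(self):
        """AR(1) step process: lag-1 step autocorrelation ~ phi (closed form)."""
        rng = np.random.default_rng(8)
        phi, n = 0.6, 200
        trajs = []
        for _ in range(n):
            steps = np.empty((40, 2))
            steps[0] = rng.normal(size=2)
            for k in range(1, 40):
                steps[k] = phi * steps[k - 1] + rng.normal(size=2) * np.sqrt(1 - phi**2)
            pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
            trajs.append(Trajectory(times=np.arange(41) * 0.05,
                                    xs=pos[:, 0], ys=pos[:, 1]))
        df = displacement_autocorrelation(trajs, max_lag=2)
        assert df.loc[1, "autocorrelation"] == pytest.approx(phi, abs=0.1)


# ---------------------------------------------------------------------------
# comparisons across sizes
# ---------------------------------------------------------------------------

def _trial_table(rng, effect=0.0, n_per_bin=40, sizes=(1.5, 2.5, 4.0),
                 time_trend=0.0):
    rows = []
    for eye in ("A", "B"):
        order = rng.permutation(len(sizes) * n_per_bin)
        k = 0
        for size in sizes:
            for _ in range(n_per_bin):
                base = 2.0 + effect * size
                rows.append({"subject_eye": eye, "trial": int(order[k]),
                             "stim_size_arcmin": size,
                             "path_length_arcmin": base * rng.lognormal(0, 0.25),
                             "end_to_end_arcmin": base * rng.lognormal(0, 0.25)
                             + time_trend * order[k]})
                k += 1
    return pd.DataFrame(rows)


class TestComparePathLengths:
    def test_null_distributions_not_significant(self):
        table = _trial_table(np.random.default_rng(1), effect=0.0)
        res = compare_path_lengths_across_sizes(table)
        assert res.p_value > 0.01
        assert res.H < 15.0

    def test_size_dependent_D_detected(self):
        table = _trial_table(np.random.default_rng(2), effect=1.0)
        res = compare_path_lengths_across_sizes(table, per_subject_eye=True)
        assert res.p_value < 1e-6
        assert len(res.medians) == 3
        assert (res.per_subject_eye["p_value"] < 0.05).all()

    def test_permuting_labels_destroys_significance(self):
        rng = np.random.default_rng(3)
        table = _trial_table(rng, effect=1.0)
        permuted = table.copy()
        permuted["stim_size_arcmin"] = rng.permutation(
            permuted["stim_size_arcmin"].to_numpy())
        assert compare_path_lengths_across_sizes(permuted).p_value > 0.01

    def test_small_bins_dropped_with_warning(self):
        table = _trial_table(np.random.default_rng(4), effect=0.0)
        lone = pd.DataFrame([{"subject_eye": "A", "trial": 999,
                              "stim_size_arcmin": 9.9, "path_length_arcmin": 1.0,
                              "end_to_end_arcmin": 1.0}])
        with pytest.warns(UserWarning, match="dropped"):
            res = compare_path_lengths_across_sizes(pd.concat([table, lone]))
        assert 9.9 not in res.medians.index


class TestCompareConsecutiveTrials:
    def test_no_size_increase_gives_empty_result(self):
        table = pd.DataFrame({
            "subject_eye": ["A"] * 3, "trial": [0, 1, 2],
            "stim_size_arcmin": [4.0, 3.0, 2.0],
            "end_to_end_arcmin": [1.0, 1.1, 0.9]})
        res = compare_consecutive_trials(table)
        assert res.empty and res.n_pairs == 0
        assert res.mean_difference is None

    def test_size_dependent_amplitude_detected_as_increase(self):
        rng = np.random.default_rng(5)
        table = _trial_table(rng, effect=1.0)
        res = compare_consecutive_trials(table)
        assert res.n_pairs > 10
        assert res.mean_difference > 0
        assert res.p_value < 0.05

    def test_time_decreasing_amplitude_detected_as_decrease(self):
        """Negative control: fatigue-like decay without any size effect."""
        rng = np.random.default_rng(6)
        table = _trial_table(rng, effect=0.0, time_trend=-0.2)
        res = compare_consecutive_trials(table)
        assert res.mean_difference < 0
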