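"""Tests of the RGC mosaic, overlap tables, rates and spiking."""

import numpy as np
import pytest

from driftvision.diffusion import DiffusionParams, Trajectory, generate_trajectory
from driftvision.retina import (HETEROGENEOUS_JITTER, RGCMosaic, RGCParams,
                                SpikeTrain, _embed_raster, build_mosaic, encode,
                                firing_rate, overlap_table, read_spikes, rf_maps,
                                sample_spikes, simulate_trial, write_spikes)
from driftvision.stimulus import render_E


class TestParamsAndMosaic:
    def test_param_validation(self):
        with pytest.raises(ValueError):
            RGCParams(w=1.5)
        with pytest.raises(ValueError):
            RGCParams(r0=-1.0)
        with pytest.raises(ValueError):
            RGCParams(dt=0.0)

    def test_mosaic_validation(self):
        with pytest.raises(ValueError, match="sigmas"):
            RGCMosaic(centers=np.zeros((2, 2)), sigmas=np.array([0.5, -0.1]),
                      params=RGCParams())
        with pytest.raises(ValueError, match="equal lengths"):
            RGCMosaic(centers=np.zeros((2, 2)), sigmas=np.array([0.5]),
                      params=RGCParams())

    def test_build_mosaic_lattice(self):
        mosaic = build_mosaic(n_per_side=11, spacing=0.5, sigma=0.25,
                              jitter_frac=0.1, seed=0)
        assert mosaic.n_cells == 121
        # centered on the origin, jitter bounded by 0.1 * spacing
        assert abs(mosaic.centers.mean()) < 0.05
        assert mosaic.centers.max() <= 2.5 + 0.05 + 1e-12
        assert np.all(np.abs(mosaic.sigmas / 0.25 - 1.0) <= 0.1 + 1e-12)

    def test_build_mosaic_deterministic(self):
        a = build_mosaic(seed=5)
        b = build_mosaic(seed=5)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_heterogeneous_raises_jitter(self):
        mosaic = build_mosaic(n_per_side=5, seed=1, heterogeneous=True)
        assert mosaic.jitter_frac == HETEROGENEOUS_JITTER
        # displacements from the perfect lattice exceed the default bound
        ref = build_mosaic(n_per_side=5, jitter_frac=0.0, seed=1)
        disp = np.abs(mosaic.centers - ref.centers).max()
        assert disp > 0.1 * 0.5


class TestOverlapTables:
    def test_rf_maps_unit_mass(self, toy_mosaic):
        maps = rf_maps(toy_mosaic, grid_extent=9, grid_spacing=1.0)
        np.testing.assert_allclose(maps.sum(axis=(1, 2)), 1.0, atol=1e-12)
        assert np.all(maps >= 0.0)

    def test_rf_maps_wrap_on_torus(self):
        """A cell placed at the grid edge has mass on both opposite edges."""
        mosaic = RGCMosaic(centers=np.array([[4.0, 0.0]]), sigmas=np.array([1.0]),
                           params=RGCParams())
        maps = rf_maps(mosaic, grid_extent=9, grid_spacing=1.0)
        assert maps[0, 0].sum() > 1e-4          # wrapped across x
        assert maps[0, -1].sum() > 1e-4

    def test_fft_table_matches_direct_sum(self, toy_mosaic):
        """Independent oracle: shift the canvas and take the inner product."""
        raster = render_E("up", 0.5, grid_spacing=1.0)
        G = 7
        table = overlap_table(toy_mosaic, raster, G)
        maps = rf_maps(toy_mosaic, G, raster.grid_spacing)
        canvas = _embed_raster(raster, G)
        c = G // 2
        for x, y in [(0, 0), (c, c), (2, 5), (6, 1)]:
            shifted = np.roll(canvas, (x - c, y - c), axis=(0, 1))
            for i in range(toy_mosaic.n_cells):
                expected = float((maps[i] * shifted).sum())
                assert table[i, x, y] == pytest.approx(expected, abs=1e-12)

    def test_translation_equivariance(self, toy_mosaic):
        raster = render_E("left", 0.5, grid_spacing=1.0)
        table = overlap_table(toy_mosaic, raster, 7)
        # moving the stimulus one grid unit shifts the table by one index
        c = 3
        np.testing.assert_allclose(
            table[:, (c + 1) % 7, c],
            [float((rf_maps(toy_mosaic, 7, 1.0)[i]
                    * np.roll(_embed_raster(raster, 7), (1, 0), axis=(0, 1))).sum())
             for i in range(toy_mosaic.n_cells)], atol=1e-12)

    def test_orientation_tables_shape_and_order(self, toy_mosaic, toy_overlaps):
        assert toy_overlaps.shape == (4, 3, 3, 3)
        direct = overlap_table(toy_mosaic, render_E("up", 0.25, 1.0), 3)
        np.testing.assert_allclose(toy_overlaps[0], direct, atol=1e-12)

    def test_oversized_stimulus_rejected(self, toy_mosaic):
        with pytest.raises(ValueError, match="exceeds the grid"):
            overlap_table(toy_mosaic, render_E("up", 2.0, 1.0), 3)


class TestRatesAndSpikes:
    def test_baseline_in_darkness(self, toy_params):
        assert firing_rate(toy_params, 0.0, 0.0) == 20.0

    def test_gain_and_transience(self, toy_params):
        # onset response: blank previous frame
        assert firing_rate(toy_params, 0.5, 0.0) == pytest.approx(20.0 + 120.0 * 0.5)
        # static stimulus: differencing leaves (1 - w) of the drive
        assert firing_rate(toy_params, 0.5, 0.5) == pytest.approx(
            20.0 + 120.0 * 0.5 * (1 - 0.8))

    def test_rectification(self, toy_params):
        # stimulus leaving the RF: negative drive clipped at zero
        assert firing_rate(toy_params, 0.0, 1.0) == 0.0

    def test_zero_w_responds_to_intensity(self):
        p = RGCParams(w=0.0)
        assert firing_rate(p, 1.0, 1.0) == pytest.approx(140.0)

    def test_poisson_statistics(self, toy_params):
        counts = sample_spikes(np.full(10**5, 40.0), toy_params, seed=0)
        mean = counts.mean() / toy_params.dt
        assert mean == pytest.approx(40.0, rel=0.02)
        # Fano factor ~ 1
        assert counts.var() / counts.mean() == pytest.approx(1.0, rel=0.05)

    def test_encode_first_bin_blank_and_transient_decay(self, toy_overlaps,
                                                        toy_params):
        """Static stimulus: mean count drops from onset to steady state."""
        rng = np.random.default_rng(3)
        positions = np.tile([1, 1], (2000, 1))
        train = encode(toy_overlaps[0], positions, toy_params, rng)
        O = toy_overlaps[0, :, 1, 1]
        onset = firing_rate(toy_params, O, 0.0) * toy_params.dt
        steady = firing_rate(toy_params, O, O) * toy_params.dt
        assert train.counts[0].sum() <= onset.sum() + 5 * np.sqrt(onset.sum())
        assert train.counts[1:].mean(axis=0) == pytest.approx(steady, abs=0.05)
        assert np.all(onset >= steady)

    def test_zero_contrast_is_baseline(self, toy_overlaps):
        p = RGCParams(contrast_scale=0.0)
        rng = np.random.default_rng(4)
        positions = np.tile([0, 0], (5000, 1))
        train = encode(toy_overlaps[2], positions, p, rng)
        assert train.mean_rate() == pytest.approx(20.0, rel=0.05)

    def test_spike_train_validation(self):
        with pytest.raises(ValueError, match="nonnegative"):
            SpikeTrain(counts=np.array([[-1, 0]]), dt=0.05)


class TestSimulateTrial:
    def test_rejects_wrong_dt(self):
        mosaic = build_mosaic(n_per_side=3, seed=0)
        raster = render_E("up", 0.5, 0.5)
        traj = Trajectory(times=np.arange(11) * 0.01, xs=np.zeros(11),
                          ys=np.zeros(11))
        with pytest.raises(ValueError, match="model dt"):
            simulate_trial(mosaic, raster, traj, 0.1)

    def test_rejects_short_trajectory(self):
        mosaic = build_mosaic(n_per_side=3, seed=0)
        raster = render_E("up", 0.5, 0.5)
        traj = generate_trajectory(DiffusionParams(D=10.0), 0.2, seed=0)
        with pytest.raises(ValueError, match="shorter"):
            simulate_trial(mosaic, raster, traj, 0.5)

    def test_matches_encode_on_static_trajectory(self):
        mosaic = build_mosaic(n_per_side=3, seed=0)
        raster = render_E("right", 0.5, 0.5)
        traj = Trajectory(times=np.arange(11) * 0.05, xs=np.zeros(11),
                          ys=np.zeros(11))
        a = simulate_trial(mosaic, raster, traj, 0.5, seed=7, grid_extent=15)
        O = overlap_table(mosaic, raster, 15)
        positions = np.tile([7, 7], (10, 1))
        b = encode(O, positions, mosaic.params, np.random.default_rng(7))
        np.testing.assert_array_equal(a.counts, b.counts)


class TestSpikeIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        train = SpikeTrain(counts=rng.poisson(1.0, (10, 9)), dt=0.05)
        path = tmp_path / "spikes.csv"
        write_spikes(train, path)
        back = read_spikes(path)
        np.testing.assert_array_equal(back.counts, train.counts)
        assert back.dt == train.dt

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "none.csv"
        path.write_text("cell,bin,count,n_bins,n_cells,dt_s\n")
        with pytest.raises(ValueError, match="empty"):
            read_spikes(path)
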