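import numpy as np
import pytest

from megfc.beamformer import (
    BeamformerConfig,
    CovarianceEstimate,
    SingularCovarianceError,
    WeightsVector,
    compute_weights,
    correlation_vs_distance,
    estimate_covariance,
    lead_field_correlation_map,
    noise_floor,
    optimal_orientation,
    project,
    pseudo_t_map,
    scan_grid,
    variance_map,
    volume_above,
    weights_correlation_map,
)
from megfc.core import FCVolumetricMap, SensorTimeSeries
from megfc.forward import DipoleSpec, lead_field, tangential_lead_fields
from megfc.significance import synth_sensor_noise
from megfc.spectral import DEFAULT_BANDS
from megfc.synthetic import make_grid

from _oracles import oracle_min_variance_weights, oracle_orientation_grid


def _random_spd(rng, m, scale=1.0):
    a = rng.standard_normal((m, m))
    return scale * (a @ a.T + m * np.eye(m))


class TestCovariance:
    def test_white_noise_near_identity(self):
        rng = np.random.default_rng(0)
        n = 40_000
        data = SensorTimeSeries(rng.standard_normal((6, n)), 100.0)
        cov = estimate_covariance(data)
        assert np.allclose(np.diag(cov.C), 1.0, atol=4.0 / np.sqrt(n) * 3)
        off = cov.C[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 4.0 / np.sqrt(n)

    def test_constant_channel_zeroed(self, rng):
        data = rng.standard_normal((4, 500))
        data[2] = 7.5
        cov = estimate_covariance(SensorTimeSeries(data, 100.0))
        assert np.allclose(cov.C[2], 0.0) and np.allclose(cov.C[:, 2], 0.0)

    def test_window_selects_samples(self, rng):
        data = SensorTimeSeries(rng.standard_normal((4, 1000)), 100.0)
        cov = estimate_covariance(data, (100, 600))
        seg = data.data[:, 100:600]
        seg = seg - seg.mean(axis=1, keepdims=True)
        assert np.allclose(cov.C, seg @ seg.T / 500)

    def test_empty_window_raises(self, rng):
        data = SensorTimeSeries(rng.standard_normal((4, 100)), 100.0)
        with pytest.raises(ValueError):
            estimate_covariance(data, (50, 50))

    def test_short_window_warns(self, rng):
        data = SensorTimeSeries(rng.standard_normal((30, 100)), 100.0)
        with pytest.warns(UserWarning, match="rank deficient"):
            estimate_covariance(data, (0, 10))


class TestNoiseFloor:
    def test_diag(self):
        cov = CovarianceEstimate(np.diag([1.0, 2.0, 3.0]), (0, 10), 10)
        assert noise_floor(cov) == pytest.approx(1.0)

    def test_scaled_identity(self):
        cov = CovarianceEstimate(4.2 * np.eye(5), (0, 10), 10)
        assert noise_floor(cov) == pytest.approx(4.2)

    def test_matches_eigensolve(self, rng):
        c = _random_spd(rng, 10)
        cov = CovarianceEstimate(c, (0, 100), 100)
        assert noise_floor(cov) == pytest.approx(np.linalg.eigvalsh(c)[0], abs=1e-10)


class TestComputeWeights:
    def test_unit_gain(self, rng):
        for _ in range(10):
            m = 12
            cov = CovarianceEstimate(_random_spd(rng, m), (0, 500), 500)
            L = rng.standard_normal(m)
            w = compute_weights(L, cov, BeamformerConfig())
            assert abs(np.dot(w.values, L) - 1.0) < 1e-10

    def test_isotropic_covariance_closed_form(self, rng):
        m = 8
        c = 3.0
        cov = CovarianceEstimate(c * np.eye(m), (0, 500), 500)
        L = rng.standard_normal(m)
        w = compute_weights(L, cov, BeamformerConfig(mu=4.0))
        assert np.allclose(w.values, L / np.dot(L, L), atol=1e-10)

    def test_matches_quadratic_program_oracle(self, rng):
        cfg = BeamformerConfig(mu=4.0)
        for _ in range(10):
            m = 8
            c = _random_spd(rng, m)
            cov = CovarianceEstimate(c, (0, 500), 500)
            sigma = noise_floor(cov)
            L = rng.standard_normal(m)
            w = compute_weights(L, cov, cfg)
            expected = oracle_min_variance_weights(L, c + cfg.mu * sigma * np.eye(m))
            assert np.allclose(w.values, expected, atol=1e-8 * np.abs(expected).max())

    def test_variance_optimality_against_random_unit_gain(self, rng):
        m = 10
        c = _random_spd(rng, m)
        cov = CovarianceEstimate(c, (0, 500), 500)
        cfg = BeamformerConfig()
        sigma = noise_floor(cov)
        c_reg = c + cfg.mu * sigma * np.eye(m)
        L = rng.standard_normal(m)
        w = compute_weights(L, cov, cfg).values
        var_w = w @ c_reg @ w
        for _ in range(50):
            v = rng.standard_normal(m)
            v = v / np.dot(v, L)  # unit gain
            assert var_w <= v @ c_reg @ v + 1e-12

    def test_singular_covariance_names_condition(self):
        c = np.diag([1.0, 1e-20, 1.0])
        cov = CovarianceEstimate(c, (0, 500), 500)
        with pytest.raises(SingularCovarianceError, match="condition number"):
            compute_weights(np.ones(3), cov, BeamformerConfig(mu=0.0), sigma=0.0)


class TestOptimalOrientation:
    def _setup(self, rng, m=16):
        L1 = rng.standard_normal(m)
        L2 = rng.standard_normal(m)
        c = _random_spd(rng, m)
        return L1, L2, CovarianceEstimate(c, (0, 500), 500)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        cfg = BeamformerConfig(mu=4.0)
        for _ in range(30):
            L1, L2, cov = self._setup(rng)
            sigma = noise_floor(cov)
            c_inv = np.linalg.inv(cov.C + cfg.mu * sigma * np.eye(cov.n_channels))

            def variance(d):
                L = np.cos(d) * L1 + np.sin(d) * L2
                ci_l = c_inv @ L
                w = ci_l / (L @ ci_l)
                return w @ cov.C @ w

            d_hat = optimal_orientation(np.zeros(3), cov, cfg, (L1, L2))
            d_grid = oracle_orientation_grid(variance, step_deg=0.1)
            diff = min(abs(d_hat - d_grid), np.pi - abs(d_hat - d_grid))
            assert diff <= np.deg2rad(0.11)

    def test_recovers_simulated_orientation(self, array32, conductor):
        rng = np.random.default_rng(1)
        loc = np.array([0.03, 0.01, 0.04])
        delta_true = 1.2
        L1, L2 = tangential_lead_fields(array32, conductor, loc)
        L = np.cos(delta_true) * L1 + np.sin(delta_true) * L2
        # strong source + small isotropic noise
        scale = np.linalg.norm(L)
        c = 1e4 * np.outer(L, L) / scale**2 + 1e-4 * np.eye(array32.n_channels)
        cov = CovarianceEstimate(c, (0, 1000), 1000)
        d_hat = optimal_orientation(loc, cov, BeamformerConfig(), (L1, L2))
        diff = min(abs(d_hat - delta_true), np.pi - abs(d_hat - delta_true))
        assert diff < np.deg2rad(2.0)

    def test_isotropic_covariance_warns_and_returns_min_norm(self, rng):
        m = 16
        L1 = rng.standard_normal(m)
        L2 = rng.standard_normal(m)
        cov = CovarianceEstimate(2.0 * np.eye(m), (0, 500), 500)
        with pytest.warns(UserWarning, match="no source structure"):
            d = optimal_orientation(np.zeros(3), cov, BeamformerConfig(), (L1, L2))
        # maximizer is the minimum-norm direction of the lead-field pair
        B = np.column_stack([L1, L2])
        evals, evecs = np.linalg.eigh(B.T @ B)
        d_min = np.arctan2(evecs[1, 0], evecs[0, 0]) % np.pi
        diff = min(abs(d - d_min), np.pi - abs(d - d_min))
        assert diff < 1e-6

    def test_zero_lead_fields_raise(self):
        cov = CovarianceEstimate(np.eye(4), (0, 10), 10)
        with pytest.raises(Exception, match="zero"):
            optimal_orientation(np.zeros(3), cov, BeamformerConfig(),
                                (np.zeros(4), np.zeros(4)))


class TestProject:
    def test_basis_vector_selects_channel(self, rng):
        data = SensorTimeSeries(rng.standard_normal((5, 200)), 100.0)
        w = WeightsVector(np.eye(5)[2], np.zeros(3), 0.0)
        out = project(w, data)
        assert np.array_equal(out.timecourse, data.data[2])

    def test_unit_gain_recovers_source(self, array32, conductor, rng):
        loc = np.array([0.02, -0.02, 0.05])
        L = lead_field(array32, conductor, DipoleSpec(loc, 0.4)).values
        s = rng.standard_normal(2000)
        data = SensorTimeSeries(np.outer(L, s), 100.0)
        cov = estimate_covariance(data)
        # noise-free: regularize lightly to invert the rank-1 covariance
        w = compute_weights(L, cov, BeamformerConfig(mu=1e-8),
                            sigma=np.trace(cov.C) / 32)
        out = project(w, data)
        assert np.allclose(out.timecourse, s, rtol=1e-6, atol=1e-8 * np.abs(s).max())

    def test_channel_mismatch_raises(self, rng):
        data = SensorTimeSeries(rng.standard_normal((5, 100)), 100.0)
        w = WeightsVector(np.ones(4), np.zeros(3), 0.0)
        with pytest.raises(ValueError):
            project(w, data)


@pytest.fixture(scope="module")
def single_source_scan(array64, conductor):
    """One strong simulated dipole at a grid point, modest noise."""
    rng_seed = 77
    fs = 200.0
    duration = 30.0
    grid = make_grid(20.0, conductor)
    loc = grid.positions[grid.nearest_voxel([0.03, 0.0, 0.04])]
    band = DEFAULT_BANDS["beta_low"]
    from megfc.significance import colored_noise_source

    s = colored_noise_source(band, (3e-8) ** 2, duration, fs, rng_seed)
    L = lead_field(array64, conductor, DipoleSpec(loc, 0.9)).values
    noise = synth_sensor_noise(array64, duration, fs, rng_seed + 1)
    data = SensorTimeSeries(np.outer(L, s) + noise.data, fs)
    cfg = BeamformerConfig(mu=4.0, band=band)
    gw = scan_grid(grid, data, cfg, array64, conductor)
    return grid, loc, data, gw


class TestScanGrid:
    def test_variance_peak_at_source(self, single_source_scan):
        grid, loc, _, gw = single_source_scan
        vmap = variance_map(gw)
        peak = int(np.argmax(vmap.values))
        assert np.linalg.norm(grid.positions[peak] - loc) <= grid.spacing_mm / 1000.0 * np.sqrt(3) + 1e-9

    def test_unit_gain_everywhere(self, single_source_scan):
        _, _, _, gw = single_source_scan
        gains = np.einsum("vm,vm->v", gw.weights, gw.lead_fields)
        assert np.abs(gains - 1.0).max() < 1e-10

    def test_deterministic(self, array64, conductor, single_source_scan):
        grid, _, data, gw = single_source_scan
        gw2 = scan_grid(grid, data, gw.config, array64, conductor)
        assert np.array_equal(gw.weights, gw2.weights)
        assert np.array_equal(gw.deltas, gw2.deltas)


class TestLeakageMaps:
    def test_weights_correlation_seed_is_one(self, single_source_scan):
        _, _, _, gw = single_source_scan
        m = weights_correlation_map(10, gw)
        assert m.values[10] == pytest.approx(1.0)
        assert np.all(m.values <= 1.0 + 1e-12)

    def test_neighbors_higher_than_distal(self, single_source_scan):
        grid, _, _, gw = single_source_scan
        seed = grid.nearest_voxel([0.0, 0.0, 0.02])
        m = weights_correlation_map(seed, gw)
        d = grid.distances_from(seed)
        near = m.values[(d > 0) & (d <= 25.0)].mean()
        far = m.values[d > 50.0].mean()
        assert near > far

    def test_lead_field_correlation_decays_slower(self, single_source_scan):
        grid, _, _, gw = single_source_scan
        seed = grid.nearest_voxel([0.0, 0.0, 0.02])
        wc = weights_correlation_map(seed, gw)
        lc = lead_field_correlation_map(seed, gw)
        assert lc.values[seed] == pytest.approx(1.0)
        d = grid.distances_from(seed)
        sel = d > 40.0
        assert lc.values[sel].mean() > wc.values[sel].mean()

    def test_correlation_vs_distance_table(self, single_source_scan):
        grid, _, _, gw = single_source_scan
        seed = 5
        m = weights_correlation_map(seed, gw)
        table = correlation_vs_distance(m, seed)
        assert table["distance_mm"].iloc[0] == 0.0
        assert table["value"].iloc[0] == pytest.approx(1.0)
        assert np.all(np.diff(table["distance_mm"].to_numpy()) >= 0)


class TestVolumeAbove:
    def test_zero_map(self, grid20):
        m = FCVolumetricMap(np.zeros(grid20.n_voxels), grid20)
        assert volume_above(m, 0.25) == 0.0

    def test_uniform_map(self, grid20):
        m = FCVolumetricMap(np.ones(grid20.n_voxels), grid20)
        assert volume_above(m, 0.25) == pytest.approx(grid20.n_voxels * (20.0 / 10.0) ** 3)

    def test_monotone_in_threshold(self, grid20, rng):
        m = FCVolumetricMap(rng.uniform(0, 1, grid20.n_voxels), grid20)
        vols = [volume_above(m, t) for t in np.linspace(0, 1, 11)]
        assert np.all(np.diff(vols) <= 0)


class TestPseudoT:
    def test_identical_windows_zero(self, array32, conductor, rng):
        fs = 200.0
        grid = make_grid(40.0, conductor)
        data = SensorTimeSeries(rng.standard_normal((32, 4000)), fs)
        m = pseudo_t_map(grid, data, (0, 2000), (0, 2000),
                         BeamformerConfig(band=DEFAULT_BANDS["beta_low"]),
                         array32, conductor)
        assert np.allclose(m.values, 0.0, atol=1e-12)

    def test_global_gain_invariance(self, array32, conductor, rng):
        fs = 200.0
        grid = make_grid(40.0, conductor)
        raw = rng.standard_normal((32, 4000))
        cfg = BeamformerConfig(band=DEFAULT_BANDS["beta_low"])
        m1 = pseudo_t_map(grid, SensorTimeSeries(raw, fs), (0, 2000), (2000, 4000),
                          cfg, array32, conductor)
        m2 = pseudo_t_map(grid, SensorTimeSeries(3.0 * raw, fs), (0, 2000),
                          (2000, 4000), cfg, array32, conductor)
        assert np.allclose(m1.values, m2.values, rtol=1e-8)

    def test_beta_power_decrease_minimum_at_source(self, array64, conductor):
        from megfc.significance import colored_noise_source

        fs = 200.0
        grid = make_grid(20.0, conductor)
        loc = grid.positions[grid.nearest_voxel([-0.03, 0.0, 0.04])]
        band = DEFAULT_BANDS["beta_low"]
        L = lead_field(array64, conductor, DipoleSpec(loc, 0.5)).values
        n = int(40 * fs)
        s = colored_noise_source(band, (4e-8) ** 2, 40.0, fs, 3)
        s[: n // 2] *= 0.3  # "active" half: beta power loss
        noise = synth_sensor_noise(array64, 40.0, fs, 4)
        data = SensorTimeSeries(np.outer(L, s) + noise.data, fs)
        m = pseudo_t_map(grid, data, (0, n // 2), (n // 2, n),
                         BeamformerConfig(band=band), array64, conductor)
        trough = int(np.argmin(m.values))
        dist = np.linalg.norm(grid.positions[trough] - loc)
        assert dist <= grid.spacing_mm / 1000.0 * np.sqrt(3) + 1e-9

    def test_empty_window_raises(self, array32, conductor, rng):
        grid = make_grid(40.0, conductor)
        data = SensorTimeSeries(rng.standard_normal((32, 1000)), 200.0)
        with pytest.raises(ValueError):
            pseudo_t_map(grid, data, (0, 0), (0, 500),
                         BeamformerConfig(band=DEFAULT_BANDS["beta_low"]),
                         array32, conductor)
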