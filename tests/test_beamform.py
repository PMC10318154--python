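"""Beamforming: CSD contracts, LCMV weights vs a constrained-optimizer
oracle, DICS localization on synthetic ground truth, surrogate calibration,
pooling and extraction."""

import numpy as np
import pytest
from scipy.optimize import minimize

from dicsnet import (SourceScenario, band_coherence, csd, extract_timeseries,
                     find_coherent_sources, generate_mvar_sources,
                     lcmv_weights, pool_source_signal, project_to_sensors,
                     source_map, surrogate_coherence_threshold,
                     surrogate_threshold)
from dicsnet.beamform import magnitude_squared_coherence, matched_filter
from dicsnet.preprocess import Recording, epoch
from dicsnet.spectral import get_band

ALPHA = get_band("alpha")


def noise_epochs(n_ch, seconds, srate=512.0, seed=0, positions=None):
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_ch, int(seconds * srate)))
    from dicsnet.simulate import fibonacci_sensors

    pos = positions if positions is not None else fibonacci_sensors(n_ch)
    rec = Recording(data=data, srate=srate,
                    channel_labels=[f"E{i+1}" for i in range(n_ch)],
                    sensor_positions=pos)
    return epoch(rec, 1.0)


def dipole_epochs(leadfield, positions, coeffs, profiles, snr_db, seed,
                  seconds=60.0, srate=1024.0):
    n = len(positions)
    sc = SourceScenario(
        positions=positions, orientations=np.tile([1.0, 0, 0], (n, 1)),
        mvar_coeffs=coeffs, innovation_cov=np.eye(n),
        band_profiles=profiles, snr_db=snr_db, seed=seed)
    x = generate_mvar_sources(sc, seconds, srate)
    rec = project_to_sensors(x, sc, leadfield, snr_db=snr_db, srate=srate)
    return epoch(rec, 1.0), x, sc


class TestCSD:
    def test_diagonal_equals_multitaper_band_power(self):
        eps = noise_epochs(4, 20.0, seed=1)
        cs = csd(eps, ALPHA)
        from dicsnet.spectral import epochs_tf

        tfr = epochs_tf(eps.data, eps.srate)
        bp = tfr.power[:, ALPHA.bin_mask(tfr.freqs), :].mean(axis=(0, 1))
        assert np.allclose(np.diag(cs.csd).real, bp, rtol=1e-9)
        assert np.all(np.diag(cs.csd).real >= 0)

    def test_duplicated_channel_has_unit_coherence(self):
        eps = noise_epochs(3, 20.0, seed=2)
        eps.data[:, 1, :] = eps.data[:, 0, :]
        cs = csd(eps, ALPHA)
        assert magnitude_squared_coherence(cs, 0, 1) == pytest.approx(
            1.0, abs=1e-9)

    def test_independent_channels_have_low_coherence(self):
        eps = noise_epochs(2, 60.0, seed=3)
        cs = csd(eps, ALPHA)
        assert magnitude_squared_coherence(cs, 0, 1) < 0.1

    def test_too_few_epochs_rejected(self):
        eps = noise_epochs(2, 5.0, seed=4)
        with pytest.raises(ValueError, match="epochs"):
            csd(eps, ALPHA)


class TestLCMVWeights:
    def test_identity_covariance_closed_form(self, leadfield32):
        l3 = leadfield32.voxel_columns(10)
        filt = lcmv_weights(l3, np.eye(32), reg=0.0)
        l = filt.leadfield
        assert np.allclose(filt.weights, l / (l @ l), atol=1e-10)

    def test_matches_constrained_optimizer_oracle(self, leadfield32):
        rng = np.random.default_rng(5)
        A = rng.standard_normal((32, 32))
        C = A @ A.T + 5.0 * np.eye(32)
        l3 = leadfield32.voxel_columns(40)
        filt = lcmv_weights(l3, C, reg=0.0)
        l = filt.leadfield

        def objective(w):
            return w @ C @ w

        cons = {"type": "eq", "fun": lambda w: w @ l - 1.0}
        res = minimize(objective, l / (l @ l), constraints=[cons],
                       method="SLSQP",
                       options={"maxiter": 2000, "ftol": 1e-14})
        assert res.success
        assert np.allclose(filt.weights, res.x, atol=1e-6)

    def test_unit_gain_constraint(self, leadfield32):
        rng = np.random.default_rng(6)
        A = rng.standard_normal((40, 32))
        C = A.T @ A / 40
        for v in (0, 17, 33):
            filt = lcmv_weights(leadfield32.voxel_columns(v), C, reg=0.05)
            assert np.real(filt.weights @ filt.leadfield) == pytest.approx(
                1.0, abs=1e-8)

    def test_singular_covariance_demands_regularization(self, leadfield32):
        C = np.zeros((32, 32))
        C[0, 0] = 1.0
        with pytest.raises(np.linalg.LinAlgError, match="regulari"):
            lcmv_weights(leadfield32.voxel_columns(0), C, reg=0.0)


class TestSourceMap:
    def test_single_dipole_localized_within_grid_spacing(self, leadfield32):
        true_pos = np.array([20.0, -40.0, 20.0])
        eps, _, _ = dipole_epochs(leadfield32, [true_pos],
                                  np.array([[[0.3]]]), [(10.0, 2.0)],
                                  snr_db=0.0, seed=7)
        cs = csd(eps, ALPHA)
        pmap = source_map(cs, leadfield32)
        best = leadfield32.grid.positions[int(np.argmax(pmap))]
        assert np.max(np.abs(best - true_pos)) <= leadfield32.grid.spacing
        assert np.linalg.norm(best - true_pos) <= 2 * leadfield32.grid.spacing

    def test_power_map_nonnegative_and_coherence_in_unit_interval(
            self, leadfield32):
        eps = noise_epochs(32, 20.0, seed=8,
                           positions=leadfield32.sensors)
        cs = csd(eps, ALPHA)
        pmap = source_map(cs, leadfield32)
        assert np.all(pmap >= 0)
        ref = eps.data[:, 0, :]  # any epoched signal as reference
        cmap = source_map(cs, leadfield32, reference=ref)
        assert np.all((cmap >= 0) & (cmap <= 1))


class TestSurrogates:
    def test_fixed_seed_reproducible_and_percentile_monotone(self):
        rng = np.random.default_rng(9)
        sig = rng.standard_normal((2, 30, 256))

        def stat(s):
            return float(np.corrcoef(s[0].ravel(), s[1].ravel())[0, 1])

        a = surrogate_threshold(sig, stat, n_perm=200, seed=42)
        b = surrogate_threshold(sig, stat, n_perm=200, seed=42)
        assert a == b
        t99 = surrogate_threshold(sig, stat, n_perm=200, percentile=99,
                                  seed=1)
        t95 = surrogate_threshold(sig, stat, n_perm=200, percentile=95,
                                  seed=1)
        assert t99 >= t95

    def test_constant_signal_rejected(self):
        sig = np.zeros((2, 30, 256))
        with pytest.raises(ValueError, match="constant"):
            surrogate_threshold(sig, lambda s: 0.0, n_perm=100)

    def test_fast_coherence_path_matches_generic(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((30, 512))
        y = rng.standard_normal((30, 512))
        fast = surrogate_coherence_threshold(x, y, 512.0, ALPHA, n_perm=300,
                                             seed=3)

        def stat(s):
            return band_coherence(s[0], s[1], 512.0, ALPHA)

        # generic path shuffles both signals; fast path permutes y only --
        # the thresholds agree statistically (same null), compare quantiles
        generic = surrogate_threshold(np.stack([x, y]), stat, n_perm=300,
                                      seed=3)
        assert fast == pytest.approx(generic, rel=0.25)

    def test_null_coherence_calibration_of_99pct_threshold(self):
        # the heart of the within-subject significance rule: ~99% of
        # independently drawn null coherences fall below the threshold
        rng = np.random.default_rng(11)
        M, L, srate = 30, 512, 512.0
        below = 0
        total = 0
        for rep in range(10):
            x = rng.standard_normal((M, L))
            y = rng.standard_normal((M, L))
            thr = surrogate_coherence_threshold(
                x, y, srate, ALPHA, n_perm=400, percentile=99,
                seed=100 + rep)
            for k in range(40):
                xx = rng.standard_normal((M, L))
                yy = rng.standard_normal((M, L))
                below += band_coherence(xx, yy, srate, ALPHA) < thr
                total += 1
        frac = below / total
        assert 0.95 <= frac <= 1.0


class TestPooling:
    def test_single_voxel_is_identity(self):
        sig = np.random.default_rng(12).standard_normal((1, 2048))
        pooled = pool_source_signal(sig, 512.0, ALPHA)
        np.testing.assert_array_equal(pooled.data, sig[0])
        assert pooled.weights.tolist() == [1.0]

    def test_identical_signals_pool_to_common_signal(self):
        s = np.random.default_rng(13).standard_normal(2048)
        pooled = pool_source_signal(np.tile(s, (4, 1)), 512.0, ALPHA)
        np.testing.assert_allclose(pooled.data, s, atol=1e-12)
        assert pooled.weights.sum() == pytest.approx(1.0)

    def test_power_proportional_weights(self):
        rng = np.random.default_rng(14)
        t = np.arange(4096) / 512.0
        base = np.sin(2 * np.pi * 10 * t)
        sig = np.stack([2.0 * base + 0.01 * rng.standard_normal(t.size),
                        1.0 * base + 0.01 * rng.standard_normal(t.size)])
        pooled = pool_source_signal(sig, 512.0, ALPHA)
        # 4x band power -> weight 0.8
        assert pooled.weights[0] == pytest.approx(0.8, abs=0.01)


class TestExtraction:
    def test_noiseless_source_recovered_at_own_voxel(self, leadfield32):
        true_pos = np.array([20.0, -40.0, 20.0])
        eps, x, sc = dipole_epochs(leadfield32, [true_pos],
                                   np.array([[[0.3]]]), [(10.0, 2.0)],
                                   snr_db=None, seed=15, seconds=10.0)
        cs = csd(eps, ALPHA)
        v, _ = leadfield32.grid.nearest(true_pos)
        filt = lcmv_weights(leadfield32.voxel_columns(v), cs.csd, reg=0.05)
        y = extract_timeseries(filt, eps)
        r = np.corrcoef(y, x[0, :y.size])[0, 1]
        assert abs(r) >= 0.99

    def test_zero_input_gives_zero_output_and_linearity(self, leadfield32):
        eps = noise_epochs(32, 12.0, seed=16, positions=leadfield32.sensors)
        cs = csd(eps, ALPHA)
        filt = lcmv_weights(leadfield32.voxel_columns(5), cs.csd, reg=0.05)
        zero = eps.copy_with(np.zeros_like(eps.data))
        assert np.all(extract_timeseries(filt, zero) == 0)
        eps2 = noise_epochs(32, 12.0, seed=17, positions=leadfield32.sensors)
        y12 = extract_timeseries(filt, eps.copy_with(eps.data + eps2.data))
        y1 = extract_timeseries(filt, eps)
        y2 = extract_timeseries(filt, eps2)
        assert np.allclose(y12, y1 + y2, atol=1e-10)


class TestIterativeSearch:
    def test_two_coupled_sources_recovered_in_order(self, leadfield32):
        pos = [[20.0, -40.0, 20.0], [-20.0, 30.0, 25.0]]
        coeffs = np.array([[[0.3, 0.0], [0.5, 0.3]]])
        eps, x, sc = dipole_epochs(leadfield32, pos, coeffs,
                                   [(10.0, 2.0), (10.0, 2.0)], snr_db=0.0,
                                   seed=4)
        sset = find_coherent_sources(eps, ALPHA, leadfield32, n_max=3,
                                     n_perm=150, seed=0)
        assert len(sset) == 2
        found = sset.positions()
        errs = [min(np.linalg.norm(found[i] - np.asarray(p))
                    for i in range(2)) for p in pos]
        assert max(errs) <= leadfield32.grid.spacing
        assert sset.sources[0].statistic == "power"
        assert sset.sources[1].statistic == "coherence"
        assert 0 < sset.sources[1].amplitude <= 1

    def test_nmax_one_is_power_map_argmax(self, leadfield32):
        eps, _, _ = dipole_epochs(leadfield32, [[20.0, -40.0, 20.0]],
                                  np.array([[[0.3]]]), [(10.0, 2.0)],
                                  snr_db=0.0, seed=18, seconds=30.0)
        cs = csd(eps, ALPHA)
        pmap = source_map(cs, leadfield32)
        sset = find_coherent_sources(eps, ALPHA, leadfield32, n_max=1,
                                     n_perm=150, seed=1)
        assert len(sset) == 1
        assert sset.sources[0].voxel == int(np.argmax(pmap))

    def test_pure_noise_yields_empty_set(self, leadfield32):
        eps = noise_epochs(32, 30.0, seed=19, positions=leadfield32.sensors)
        sset = find_coherent_sources(eps, ALPHA, leadfield32, n_max=3,
                                     n_perm=150, seed=2)
        assert len(sset) == 0

    def test_coherence_amplitude_grows_with_coupling(self, leadfield_coarse):
        # the property behind the between-group coherence contrast: stronger
        # source coupling -> larger recovered coherence amplitude
        pos = [[20.0, -40.0, 20.0], [-20.0, 30.0, 25.0]]
        amps = []
        for w in (0.15, 0.35, 0.55):
            coeffs = np.array([[[0.3, 0.0], [w, 0.3]]])
            eps, _, _ = dipole_epochs(leadfield_coarse, pos, coeffs,
                                      [(10.0, 2.0), (10.0, 2.0)],
                                      snr_db=3.0, seed=30, seconds=40.0)
            sset = find_coherent_sources(eps, ALPHA, leadfield_coarse,
                                         n_max=2, n_perm=120, seed=3)
            amps.append(sset.sources[1].amplitude if len(sset) > 1 else 0.0)
        assert amps[0] < amps[1] < amps[2]
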