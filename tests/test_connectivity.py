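"""Directed connectivity: MVAR fitting vs statsmodels, dual Kalman
filtering, TPDC identities and closed-form oracle, bootstrap and
time-reversal validation, graph assembly."""

import numpy as np
import pytest

from dicsnet import (DualEKFSettings, SourceScenario, bootstrap_significance,
                     build_graph, dual_ekf, fit_mvar, generate_mvar_sources,
                     pdc_from_coeffs, select_order, time_reversal_check,
                     tpdc)
from dicsnet.connectivity import band_tpdc
from dicsnet.spectral import BandDefinition, get_band

ALPHA = get_band("alpha")
SRATE = 256.0


def simulate(coeffs, seconds=60.0, seed=0, srate=SRATE, profiles=None):
    n = coeffs.shape[1]
    sc = SourceScenario(
        positions=[[0.0, 0.0, 30.0], [20.0, -30.0, 10.0],
                   [-25.0, 20.0, 15.0]][:n],
        orientations=np.tile([1.0, 0, 0], (n, 1)),
        mvar_coeffs=coeffs, innovation_cov=np.eye(n),
        band_profiles=profiles if profiles is not None else [None] * n,
        seed=seed)
    return generate_mvar_sources(sc, seconds, srate)


def biv_ar2(c10=0.5, c01=0.0):
    """Stable bivariate AR(2): channel0 drives channel1 with weight c10."""
    A = np.zeros((2, 2, 2))
    A[0, 0, 0] = 0.5
    A[0, 1, 1] = 0.5
    A[1, 0, 0] = -0.2
    A[1, 1, 1] = -0.2
    A[0, 1, 0] = c10
    A[0, 0, 1] = c01
    return A


class TestFitMVAR:
    def test_recovers_known_ar2_coefficients(self):
        A = biv_ar2()
        x = simulate(A, seconds=60.0, seed=1)
        coeffs, sigma, radius = fit_mvar(x, 2)
        assert np.sqrt(np.mean((coeffs - A) ** 2)) < 0.02
        assert radius < 1
        assert np.allclose(sigma, np.eye(2), atol=0.1)

    def test_agrees_with_statsmodels_var(self):
        from statsmodels.tsa.api import VAR

        x = simulate(biv_ar2(), seconds=30.0, seed=2)
        coeffs, _, _ = fit_mvar(x, 2)
        res = VAR(x.T).fit(2, trend="n")
        oracle = np.stack([res.coefs[r] for r in range(2)])
        assert np.max(np.abs(coeffs - oracle)) < 1e-10

    def test_white_noise_gives_near_zero_coefficients(self):
        x = simulate(np.zeros((1, 2, 2)).reshape(0, 2, 2) if False
                     else np.zeros((0, 2, 2)), seconds=60.0, seed=3)
        coeffs, _, _ = fit_mvar(x, 2)
        assert np.max(np.abs(coeffs)) < 0.05

    def test_order_scan_selects_true_order(self):
        A = np.zeros((5, 2, 2))
        A[0] = [[0.4, 0.0], [0.3, 0.4]]
        A[4] = [[-0.3, 0.0], [0.0, -0.3]]
        x = simulate(A, seconds=60.0, seed=4)
        p = select_order(x, p_max=10)
        assert abs(p - 5) <= 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            fit_mvar(np.zeros((3, 100)), 5)


class TestDualEKF:
    def test_stationary_limit_matches_static_fit(self):
        x = simulate(biv_ar2(), seconds=60.0, seed=5)
        model = dual_ekf(x, 2, SRATE)
        static, _, _ = fit_mvar(
            (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True), 2)
        rmse = np.sqrt(np.mean((model.mean_coeffs() - static) ** 2))
        assert rmse < 0.05

    def test_tracks_step_change_in_coupling(self):
        # coupling 0 -> 0.5 at t=30 s: the estimate crosses 0.25 within 5 s
        rng = np.random.default_rng(6)
        T = int(60 * SRATE)
        A0 = biv_ar2(c10=0.0)
        A1 = biv_ar2(c10=0.5)
        x = np.zeros((2, T))
        e = rng.standard_normal((2, T))
        for t in range(2, T):
            A = A0 if t < T // 2 else A1
            x[:, t] = (A[0] @ x[:, t - 1] + A[1] @ x[:, t - 2] + e[:, t])
        model = dual_ekf(x, 2, SRATE, DualEKFSettings(q=1e-3))
        track = model.coeffs[:, 0, 1, 0]  # lag-1 coefficient 0 -> 1
        # rescale to the standardized units the filter works in
        track = track * x[0].std() / x[1].std()
        crossed = np.flatnonzero(track > 0.25)
        crossed = crossed[crossed > T // 2]
        assert crossed.size > 0
        assert (crossed[0] - T // 2) / SRATE < 5.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            dual_ekf(np.zeros((2, 5000)), 2, SRATE)

    def test_coefficients_always_finite(self):
        x = simulate(biv_ar2(), seconds=20.0, seed=7)
        model = dual_ekf(x, 2, SRATE, DualEKFSettings(q=1e-3))
        assert np.all(np.isfinite(model.coeffs))


class TestTPDC:
    def test_diagonal_coefficients_give_zero_cross_tpdc(self):
        A = np.zeros((2, 2, 2))
        A[0] = np.diag([0.5, -0.4])
        A[1] = np.diag([-0.2, 0.1])
        pi = pdc_from_coeffs(A, np.arange(1.0, 100.0), SRATE * 2)
        assert np.max(pi[0, 1]) < 1e-12
        assert np.max(pi[1, 0]) < 1e-12

    def test_column_normalization_identity(self):
        rng = np.random.default_rng(8)
        A = rng.standard_normal((3, 3, 3)) * 0.15
        pi = pdc_from_coeffs(A, np.arange(1.0, 128.0), SRATE)
        colsums = (pi ** 2).sum(axis=0)
        assert np.allclose(colsums, 1.0, atol=1e-8)

    def test_matches_closed_form_two_channel_oracle(self):
        # x0 -> x1 with constant coefficients: pi from the explicit 2x2
        # A(f) evaluated by hand
        A = biv_ar2(c10=0.5)
        freqs = np.array([5.0, 10.0, 20.0])
        pi = pdc_from_coeffs(A, freqs, SRATE)
        for fi, f in enumerate(freqs):
            z1 = np.exp(-2j * np.pi * f * 1 / SRATE)
            z2 = np.exp(-2j * np.pi * f * 2 / SRATE)
            Abar = np.eye(2) - (A[0] * z1 + A[1] * z2)
            num = abs(Abar[1, 0])
            den = np.sqrt(abs(Abar[0, 0]) ** 2 + abs(Abar[1, 0]) ** 2)
            assert pi[1, 0, fi] == pytest.approx(num / den, abs=1e-9)
            assert pi[0, 1, fi] == pytest.approx(0.0, abs=1e-12)

    def test_time_varying_tpdc_in_unit_interval_and_normalized(self):
        x = simulate(biv_ar2(), seconds=30.0, seed=9)
        model = dual_ekf(x, 2, SRATE)
        res = tpdc(model, ALPHA)
        assert np.all((res.pi >= 0) & (res.pi <= 1))
        colsums = (res.pi ** 2).sum(axis=0)
        assert np.allclose(colsums, 1.0, atol=1e-8)

    def test_band_above_nyquist_rejected(self):
        x = simulate(biv_ar2(), seconds=20.0, seed=10)
        model = dual_ekf(x, 2, SRATE)
        with pytest.raises(ValueError, match="Nyquist"):
            tpdc(model, BandDefinition("hf", 200.0, 300.0))


class TestBootstrap:
    def test_fixed_seed_reproducible(self):
        x = simulate(biv_ar2(), seconds=30.0, seed=11)
        a = bootstrap_significance(x, 2, SRATE, ALPHA, n_boot=30, seed=5)
        b = bootstrap_significance(x, 2, SRATE, ALPHA, n_boot=30, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_strong_coupling_always_exceeds_threshold(self):
        hits = 0
        for seed in range(10):
            x = simulate(biv_ar2(c10=0.5), seconds=40.0, seed=20 + seed)
            thr = bootstrap_significance(x, 2, SRATE, ALPHA, n_boot=30,
                                         seed=seed, estimator="static",
                                         reduction="percentile")
            m = band_tpdc(x, 2, SRATE, ALPHA, estimator="static")
            hits += m[1, 0] > thr[1, 0]
        assert hits == 10

    def test_null_connections_rarely_exceed_percentile_threshold(self):
        # independent channels against the calibrated 99th-percentile rule
        exceed = 0
        for seed in range(10):
            x = simulate(np.zeros((0, 2, 2)), seconds=40.0, seed=40 + seed)
            thr = bootstrap_significance(x, 2, SRATE, ALPHA, n_boot=60,
                                         seed=seed, estimator="static",
                                         reduction="percentile")
            m = band_tpdc(x, 2, SRATE, ALPHA, estimator="static")
            exceed += (m[0, 1] > thr[0, 1]) + (m[1, 0] > thr[1, 0])
        assert exceed <= 5  # of 20 null connections

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="20 windows"):
            bootstrap_significance(np.random.default_rng(0).standard_normal(
                (2, int(5 * SRATE))), 2, SRATE, ALPHA, n_boot=10)


class TestTimeReversal:
    def test_unidirectional_coupling_passes(self):
        passes = 0
        for seed in range(5):
            x = simulate(biv_ar2(c10=0.5), seconds=40.0, seed=60 + seed)
            trt = time_reversal_check(x, 2, SRATE, ALPHA, estimator="static",
                                      seed=seed, n_boot_sd=30)
            passes += trt[1, 0]
        assert passes >= 4

    def test_instantaneous_mixing_fails(self):
        # one white-noise source mixed into both channels: volume-conduction
        # stand-in with no directed interaction
        rng = np.random.default_rng(12)
        s = rng.standard_normal(int(40 * SRATE))
        x = np.stack([s + 0.1 * rng.standard_normal(s.size),
                      0.8 * s + 0.1 * rng.standard_normal(s.size)])
        trt = time_reversal_check(x, 2, SRATE, ALPHA, estimator="static",
                                  seed=1, n_boot_sd=30)
        assert not trt[0, 1] and not trt[1, 0]

    def test_double_reversal_is_identity(self):
        x = simulate(biv_ar2(), seconds=30.0, seed=13)
        a = band_tpdc(x, 2, SRATE, ALPHA, estimator="static")
        b = band_tpdc(x[:, ::-1][:, ::-1], 2, SRATE, ALPHA,
                      estimator="static")
        assert np.allclose(a, b, atol=1e-9)


class TestGraph:
    def _analyze(self, x, seed=0):
        model = dual_ekf(x, 2, SRATE)
        res = tpdc(model, ALPHA)
        thr = bootstrap_significance(x, 2, SRATE, ALPHA, n_boot=40,
                                     seed=seed, estimator="ekf",
                                     reduction="percentile")
        trt = time_reversal_check(x, 2, SRATE, ALPHA, estimator="ekf",
                                  seed=seed, n_boot_sd=25)
        return build_graph(res, thr, trt)

    def test_no_exceedance_gives_empty_graph(self):
        x = simulate(np.zeros((0, 2, 2)), seconds=40.0, seed=14)
        model = dual_ekf(x, 2, SRATE)
        res = tpdc(model, ALPHA)
        thr = np.full((2, 2), np.inf)
        g = build_graph(res, thr)
        assert g.edges == []

    def test_unidirectional_coupling_gives_single_correct_edge(self):
        x = simulate(biv_ar2(c10=0.5), seconds=60.0, seed=15)
        g = self._analyze(x, seed=15)
        assert [(e.source, e.target) for e in g.edges] == [(0, 1)]
        assert not g.edges[0].bidirectional

    def test_mutual_coupling_sets_bidirectional_flag(self):
        A = biv_ar2(c10=0.5, c01=0.3)
        x = simulate(A, seconds=60.0, seed=16)
        g = self._analyze(x, seed=16)
        pairs = {(e.source, e.target) for e in g.edges}
        assert (0, 1) in pairs and (1, 0) in pairs
        assert all(e.bidirectional for e in g.edges)


def test_chain_partialization_keeps_indirect_link_weakest():
    """1 -> 2 -> 3: the spurious direct 1 -> 3 TPDC stays below both true
    links (the partialization property), across seeds."""
    A = np.zeros((1, 3, 3))
    A[0] = [[0.5, 0.0, 0.0],
            [0.5, 0.5, 0.0],
            [0.0, 0.5, 0.5]]
    for seed in range(5):
        x = simulate(A, seconds=40.0, seed=70 + seed)
        m = band_tpdc(x, 2, SRATE, ALPHA, estimator="static")
        assert m[2, 0] < m[1, 0]
        assert m[2, 0] < m[2, 1]
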