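"""Preprocessing chain: zero-phase filtering, epoching, ICA artifact
removal, cubic interpolation and average referencing."""

import numpy as np
import pytest

from dicsnet import (Recording, bandlimit, epoch, interpolate_bad_segments,
                     notch, remove_artifacts, rereference_average,
                     run_preprocessing)
from dicsnet.preprocess import detect_visible_artifacts
from dicsnet.simulate import _pink_noise, add_artifacts, fibonacci_sensors

SRATE = 512.0
POS16 = fibonacci_sensors(16)


def rec_of(data, srate=SRATE):
    n = data.shape[0]
    return Recording(data=data, srate=srate,
                     channel_labels=[f"E{i+1}" for i in range(n)],
                     sensor_positions=POS16[:n])


def sine_rec(freq, seconds=20.0, n_ch=4, srate=SRATE):
    t = np.arange(int(seconds * srate)) / srate
    return rec_of(np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1)), srate)


class TestBandlimit:
    def test_dc_removed_by_highpass(self):
        rec = rec_of(np.full((4, 8192), 5.0))
        out = bandlimit(rec, 0.5, 200.0)
        assert np.abs(out.data).mean() < 1e-6 * 5.0

    def test_passband_sine_preserved(self):
        out = bandlimit(sine_rec(10.0), 0.5, 200.0)
        mid = out.data[0, 2000:-2000]
        assert abs(np.abs(mid).max() - 1.0) < 0.01

    def test_stopband_attenuation_at_least_40db(self):
        rng = np.random.default_rng(0)
        rec = rec_of(rng.standard_normal((2, 60 * 1024)), srate=1024.0)
        out = bandlimit(rec, 0.5, 300.0)
        f = np.fft.rfftfreq(rec.n_samples, 1 / 1024.0)
        hi = f >= 450.0  # at least 1.5x the cutoff
        p_in = (np.abs(np.fft.rfft(rec.data[0])) ** 2)[hi].mean()
        p_out = (np.abs(np.fft.rfft(out.data[0])) ** 2)[hi].mean()
        assert 10 * np.log10(p_in / p_out) >= 40.0

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandlimit(sine_rec(10.0), 0.5, 300.0)  # srate 512


class TestNotch:
    def test_60hz_sine_suppressed(self):
        out = notch(sine_rec(60.0, seconds=10.0), [60.0])
        assert np.abs(out.data[0, 2000:-2000]).max() <= 0.03

    def test_neighboring_frequency_preserved_within_1db(self):
        out = notch(sine_rec(50.0, seconds=10.0), [60.0, 120.0, 180.0])
        amp = np.abs(out.data[0, 2000:-2000]).max()
        assert 20 * np.log10(1.0 / amp) < 1.0

    def test_empty_frequency_list_is_identity(self):
        rec = sine_rec(37.0)
        out = notch(rec, [])
        np.testing.assert_array_equal(out.data, rec.data)


class TestEpoch:
    def test_400s_recording_gives_400_epochs_of_1024(self):
        rng = np.random.default_rng(1)
        rec = Recording(data=rng.standard_normal((2, 400 * 1024)),
                        srate=1024.0, channel_labels=["A", "B"],
                        sensor_positions=POS16[:2])
        eps = epoch(rec, 1.0)
        assert eps.M == 400 and eps.L == 1024

    def test_mask_drops_intersecting_epochs(self):
        rec = rec_of(np.random.default_rng(2).standard_normal((2, 8 * 512)))
        mask = np.zeros(rec.n_samples, bool)
        mask[:2 * 512] = True
        eps = epoch(rec, 1.0, reject_mask=mask)
        assert list(eps.kept_epoch_indices) == [2, 3, 4, 5, 6, 7]

    def test_concatenation_round_trips(self):
        rec = rec_of(np.random.default_rng(3).standard_normal((3, 5 * 512)))
        eps = epoch(rec, 1.0)
        np.testing.assert_array_equal(eps.concatenated(),
                                      rec.data[:, :eps.M * eps.L])

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            epoch(rec_of(np.zeros((2, 100))), 1.0)

    def test_visible_artifact_detector_flags_amplitude_and_flatline(self):
        data = np.random.default_rng(4).standard_normal((2, 4 * 512)) * 10
        data[0, 600] = 900.0
        data[1, 1500:1700] = 3.14
        rec = rec_of(data)
        mask = detect_visible_artifacts(rec)
        assert mask[600]
        assert mask[1550]
        assert not mask[100]


@pytest.fixture(scope="module")
def alpha_recording():
    """Posterior alpha rhythm over pink background, 16 channels."""
    rng = np.random.default_rng(5)
    t = np.arange(int(20 * SRATE)) / SRATE
    alpha = np.sin(2 * np.pi * 10 * t) * (1 + 0.3 * np.sin(2 * np.pi * 0.2 * t))
    topo = np.clip(-POS16[:, 1], 0, None)
    topo /= topo.max()
    data = np.outer(topo, alpha) * 10 + 2 * _pink_noise((16, t.size), rng)
    return rec_of(data)


class TestICA:
    def test_clean_data_rejects_nothing_and_reconstructs(self, alpha_recording):
        eps = epoch(alpha_recording, 1.0)
        clean, res = remove_artifacts(eps, random_state=0)
        assert res.rejected.size == 0
        err = np.linalg.norm(clean.data - eps.data) / np.linalg.norm(eps.data)
        assert err < 1e-6
        # mixing o unmixing ~ identity on the retained subspace
        assert np.allclose(res.mixing @ res.unmixing, np.eye(16), atol=1e-6)

    def test_blink_component_found_and_removed(self, alpha_recording):
        recb = add_artifacts(alpha_recording, kinds=("blink",),
                             rng=np.random.default_rng(6), amplitude=80.0)
        eps = epoch(recb, 1.0)
        clean, res = remove_artifacts(eps, random_state=0)
        assert res.labels.count("eye") >= 1
        blink = (recb.data - alpha_recording.data)
        tpl = blink[int(np.argmax(np.abs(blink).max(axis=1)))]
        tpl = tpl[:eps.M * eps.L]
        beta_in = (eps.concatenated() @ tpl) / (tpl @ tpl)
        beta_out = (clean.concatenated() @ tpl) / (tpl @ tpl)
        var_in = (beta_in[:, None] * tpl).var()
        var_out = (beta_out[:, None] * tpl).var()
        assert var_out / var_in < 0.10  # >= 90% of blink variance removed

    def test_line_component_reduces_60hz_power_20db(self, alpha_recording):
        recl = add_artifacts(alpha_recording, kinds=("line",),
                             rng=np.random.default_rng(7), amplitude=80.0)
        eps = epoch(recl, 1.0)
        clean, res = remove_artifacts(eps, random_state=0)
        assert res.labels.count("line") >= 1
        f = np.fft.rfftfreq(eps.M * eps.L, 1 / SRATE)
        sel = np.abs(f - 60.0) < 0.5
        p_in = (np.abs(np.fft.rfft(eps.concatenated(), axis=1)) ** 2)[:, sel].sum()
        p_out = (np.abs(np.fft.rfft(clean.concatenated(), axis=1)) ** 2)[:, sel].sum()
        assert 10 * np.log10(p_in / p_out) >= 20.0

    def test_underdetermined_decomposition_rejected(self):
        rec = rec_of(np.random.default_rng(8).standard_normal((16, 2 * 512)))
        eps = epoch(rec, 1.0)
        # 2*512 samples < 20*16 channels * ... -> force the bound
        eps.data = eps.data[:, :, :150]
        eps.epoch_length = 150 / SRATE
        with pytest.raises(ValueError, match="M\\*L"):
            remove_artifacts(eps)


class TestInterpolation:
    def test_empty_mask_is_identity(self, alpha_recording):
        eps = epoch(alpha_recording, 1.0)
        out = interpolate_bad_segments(eps, np.zeros((eps.M, eps.L), bool))
        np.testing.assert_array_equal(out.data, eps.data)

    def test_cubic_polynomial_reconstructed_exactly(self):
        x = np.arange(512) / 512.0
        poly = 2 + x - 3 * x ** 2 + 0.5 * x ** 3
        rec = rec_of(np.tile(poly, (2, 1)))
        eps = epoch(rec, 1.0)
        mask = np.zeros((1, 512), bool)
        mask[0, 200:240] = True
        out = interpolate_bad_segments(eps, mask)
        assert np.max(np.abs(out.data - eps.data)) < 1e-9

    def test_sine_gap_reconstruction_error(self):
        # a cubic can track a 10-Hz sine across a 30-ms hole almost exactly,
        # but a 50-ms hole spans half a cycle and caps its accuracy near 25%
        # of the amplitude (values frozen from the standalone spline oracle)
        t = np.arange(512) / SRATE
        rec = rec_of(np.tile(np.sin(2 * np.pi * 10 * t), (1, 1)))
        eps = epoch(rec, 1.0)
        for gap_ms, bound in ((30, 0.05), (50, 0.25)):
            gap = int(gap_ms / 1000 * SRATE)
            mask = np.zeros((1, 512), bool)
            mask[0, 250:250 + gap] = True
            out = interpolate_bad_segments(eps, mask)
            assert np.max(np.abs(out.data - eps.data)) < bound

    def test_overlong_run_rejected(self):
        rec = rec_of(np.zeros((1, 512)))
        eps = epoch(rec, 1.0)
        mask = np.zeros((1, 512), bool)
        mask[0, :300] = True
        with pytest.raises(ValueError, match="half an epoch"):
            interpolate_bad_segments(eps, mask)

    def test_boundary_gap_falls_back_to_nearest_fill(self):
        rec = rec_of(np.tile(np.arange(512.0), (1, 1)))
        eps = epoch(rec, 1.0)
        mask = np.zeros((1, 512), bool)
        mask[0, :10] = True
        out = interpolate_bad_segments(eps, mask)
        assert np.all(out.data[0, 0, :10] == eps.data[0, 0, 10])


class TestRereference:
    def test_channel_mean_is_zero_at_every_sample(self, alpha_recording):
        eps = epoch(alpha_recording, 1.0)
        out = rereference_average(eps)
        assert np.max(np.abs(out.data.mean(axis=1))) < 1e-10

    def test_idempotent(self, alpha_recording):
        eps = epoch(alpha_recording, 1.0)
        once = rereference_average(eps)
        twice = rereference_average(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_single_channel_rejected(self):
        rec = rec_of(np.zeros((1, 1024)))
        eps = epoch(rec, 1.0)
        with pytest.raises(ValueError, match="2 channels"):
            rereference_average(eps)


class TestOrchestrator:
    def test_stage_order_and_report(self, alpha_recording):
        eps, ica, report = run_preprocessing(
            alpha_recording, notch_freqs=(60.0,), high_cut=200.0,
            random_state=0)
        d = report.to_dict()
        assert d["stages"] == ["bandlimit", "notch", "epoch", "ica",
                               "interpolate", "rereference"]
        assert d["n_epochs_kept"] <= d["n_epochs_total"]
        assert set(d["ica_components"]) == {"brain", "eye", "line", "muscle"}
        assert np.max(np.abs(eps.data.mean(axis=1))) < 1e-10

    def test_epoch_drops_are_monotone(self, alpha_recording):
        data = alpha_recording.data.copy()
        data[0, 3000] = 2000.0  # visible artifact in epoch 5
        rec = rec_of(data)
        eps, _, _ = run_preprocessing(rec, notch_freqs=(60.0,),
                                      high_cut=200.0, run_ica=False)
        ki = np.asarray(eps.kept_epoch_indices)
        assert np.all(np.diff(ki) > 0)
        assert 5 not in ki
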