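"""Spectral chain: CAR, trials, multitaper ASM, baseline log RSM, group test."""

import numpy as np
import pytest
from scipy.signal.windows import dpss

from neurolex.spectral import (
    ChannelInfo,
    Recording,
    SpectralConfig,
    baseline_correct,
    common_average_reference,
    compute_trial_spectra,
    extract_trials,
    multitaper_spectrogram,
    rsm_group_test,
)


def make_recording(data, fs=1024.0, status=None):
    n_ch = data.shape[0]
    status = status or ["good"] * n_ch
    return Recording(
        data=data,
        fs=fs,
        channels=[ChannelInfo(f"ch{i}", status=s) for i, s in enumerate(status)],
    )


class TestCommonAverageReference:
    def test_antisymmetric_pair_unchanged(self, rng):
        x = rng.standard_normal(1000)
        rec = make_recording(np.vstack([x, -x]))
        out = common_average_reference(rec)
        assert np.allclose(out.data, rec.data)

    def test_per_sample_mean_is_zero(self, rng):
        rec = make_recording(rng.standard_normal((8, 2000)))
        out = common_average_reference(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-12

    def test_bad_and_seizure_channels_dropped(self, rng):
        rec = make_recording(
            rng.standard_normal((4, 100)),
            status=["good", "seizure-onset", "good", "bad"],
        )
        out = common_average_reference(rec)
        assert out.channel_names() == ["ch0", "ch2"]

    def test_common_offset_invariance(self, rng):
        data = rng.standard_normal((5, 500))
        drift = rng.standard_normal(500)
        a = common_average_reference(make_recording(data))
        b = common_average_reference(make_recording(data + drift))
        assert np.allclose(a.data, b.data)

    def test_needs_two_good_channels(self, rng):
        rec = make_recording(rng.standard_normal((2, 100)), status=["good", "bad"])
        with pytest.raises(ValueError):
            common_average_reference(rec)


class TestTrialExtraction:
    def test_onset_too_close_to_start_dropped(self, rng):
        rec = make_recording(rng.standard_normal((2, 10 * 1024)))
        trials, kept = extract_trials(rec, [1.0, 5.0])
        assert kept.tolist() == [1]  # first onset lacks 2 s of history

    def test_shape_is_trials_by_channels_by_samples(self, rng):
        rec = make_recording(rng.standard_normal((3, 60 * 1024)))
        onsets = np.linspace(5, 50, 10)
        trials, kept = extract_trials(rec, onsets)
        assert trials.shape == (10, 3, 5120)

    def test_empty_onsets_give_empty_result(self, rng):
        rec = make_recording(rng.standard_normal((2, 10240)))
        trials, kept = extract_trials(rec, [])
        assert trials.shape[0] == 0


class TestMultitaperSpectrogram:
    def test_nominal_bin_spacing_is_about_5_hz(self):
        cfg = SpectralConfig()
        assert cfg.freq_resolution(1024.0) == pytest.approx(5.0, abs=0.1)

    def test_pure_tone_peaks_at_nearest_bin(self):
        fs = 1024.0
        t = np.arange(int(3 * fs)) / fs
        x = np.sin(2 * np.pi * 100.0 * t)[None, :]
        # single taper: the bell-shaped mainlobe peaks exactly at the tone
        asm1, freqs, _ = multitaper_spectrogram(x, fs, SpectralConfig(n_tapers=1))
        nearest = np.argmin(np.abs(freqs - 100.0))
        assert (asm1[0].argmax(axis=0) == nearest).all()
        # 5-taper average: flat-topped mainlobe, peak within one bin
        asm5, _, _ = multitaper_spectrogram(x, fs, SpectralConfig())
        assert (np.abs(asm5[0].argmax(axis=0) - nearest) <= 1).all()

    def test_matches_naive_single_window_oracle(self, rng):
        """Direct per-window tapered-FFT recomputation, both bin ranges."""
        fs = 1024.0
        x = rng.standard_normal(int(1.5 * fs))
        for f_max in (150.0, 300.0):  # exercises both computation paths
            cfg = SpectralConfig(f_max=f_max)
            asm, freqs, times = multitaper_spectrogram(x[None], fs, cfg)
            win, step = cfg.window_samples(fs), cfg.step_samples(fs)
            tapers = dpss(win, cfg.nw, cfg.n_tapers)
            for k in (0, 7, asm.shape[-1] - 1):
                seg = x[k * step : k * step + win]
                oracle = np.abs(np.fft.rfft(tapers * seg, axis=-1)).mean(axis=0)
                assert np.allclose(asm[0, :, k], oracle[: freqs.size], rtol=1e-4)

    def test_taper_averaging_reduces_variance(self, rng):
        fs = 1024.0
        cfg5 = SpectralConfig(window=0.2, step=0.15, f_max=300.0)
        cfg1 = SpectralConfig(window=0.2, step=0.15, f_max=300.0, n_tapers=1)
        multi, single = [], []
        for _ in range(100):
            x = rng.standard_normal(int(0.5 * fs))[None]
            multi.append(multitaper_spectrogram(x, fs, cfg5)[0])
            single.append(multitaper_spectrogram(x, fs, cfg1)[0])
        v5 = np.var(np.array(multi), axis=0)
        v1 = np.var(np.array(single), axis=0)
        assert v5.mean() < v1.mean()
        assert (v5 < v1).mean() > 0.9

    def test_energy_conservation_white_noise(self, rng):
        """Parseval check: total DFT power equals window energy on average."""
        fs = 1024.0
        cfg = SpectralConfig(f_max=fs / 2, magnitude=False)
        win = cfg.window_samples(fs)
        totals = []
        for _ in range(100):
            x = rng.standard_normal(win)[None]
            asm, freqs, _ = multitaper_spectrogram(x, fs, cfg)
            power = asm[0, :, 0]
            total = power[0] + 2 * power[1:].sum()  # odd window: no Nyquist bin
            totals.append(total)
        assert np.mean(totals) == pytest.approx(win, rel=0.10)

    def test_window_longer_than_trial_rejected(self):
        with pytest.raises(ValueError):
            multitaper_spectrogram(np.zeros((1, 100)), 1024.0, SpectralConfig())


class TestBaselineCorrection:
    def test_constant_asm_gives_zero_log_rsm(self):
        times = np.linspace(-1.95, 2.95, 246)
        asm = np.full((4, 2, 10, 246), 3.7)
        out = baseline_correct(asm, times)
        assert np.abs(out).max() < 1e-15

    def test_doubling_gives_log_two(self):
        times = np.linspace(-1.95, 2.95, 246)
        asm = np.ones((1, 1, 3, 246))
        asm[..., times > 0] = 2.0
        out = baseline_correct(asm, times)
        assert np.allclose(out[..., times > 0], np.log(2.0))
        assert np.allclose(out[..., times <= -1.81], 0.0)

    def test_baseline_mean_identity(self, rng):
        """Pre-log RSM averaged over the baseline bins is exactly 1."""
        times = np.linspace(-1.95, 2.95, 246)
        asm = np.exp(rng.standard_normal((5, 3, 8, 246)))
        out = baseline_correct(asm, times)
        base = (times >= -2) & (times <= -1.8)
        assert np.abs(np.exp(out)[..., base].mean(axis=-1) - 1).max() < 1e-12

    def test_zero_baseline_flagged_missing(self):
        times = np.linspace(-1.95, 2.95, 246)
        asm = np.ones((1, 1, 2, 246))
        asm[0, 0, 1, times <= -1.8] = 0.0
        out = baseline_correct(asm, times)
        assert np.isnan(out[0, 0, 1]).all() and np.isfinite(out[0, 0, 0]).all()


class TestRsmGroupTest:
    def test_extreme_bin_is_detected(self, rng):
        x = rng.standard_normal((40, 2, 6, 20)) * 0.05
        x[:, 1, 3, 10] += 1.0
        p, mask = rsm_group_test(x)
        assert mask[1, 3, 10]
        assert mask.mean() < 0.05

    def test_bh_mask_monotone_in_q(self, rng):
        x = rng.standard_normal((25, 2, 5, 12))
        x[:, 0] += 0.4
        _, strict = rsm_group_test(x, q=0.01)
        _, loose = rsm_group_test(x, q=0.05)
        assert not np.any(strict & ~loose)

    def test_sign_test_alternative(self, rng):
        x = rng.standard_normal((60, 1, 4, 10))
        x[:, 0, 0, 0] = np.abs(x[:, 0, 0, 0]) + 0.5
        p, mask = rsm_group_test(x, method="sign")
        assert mask[0, 0, 0]

    def test_needs_ten_trials(self, rng):
        with pytest.raises(ValueError):
            rsm_group_test(rng.standard_normal((5, 1, 2, 2)))


def test_compute_trial_spectra_coordinates(rng):
    rec = make_recording(rng.standard_normal((2, 40 * 1024)))
    sp = compute_trial_spectra(rec, [5.0, 10.0, 20.0], SpectralConfig(f_max=150.0))
    assert sp.log_rsm.shape == (3, 2, sp.freqs.size, sp.times.size)
    assert sp.freqs.max() <= 150.0
    assert np.allclose(np.diff(sp.times), 20 / 1024)
    assert sp.times[0] == pytest.approx(-2 + 102 / 1024)
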