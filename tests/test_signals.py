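"""Photometry/EMG preprocessing and event-locked analyses."""

import numpy as np
import pytest

from spindlelab import signals
from spindlelab import synthgen as sg

FS = 100.0


class TestComputeDff:
    def test_signal_equal_to_fitted_reference_gives_zero(self, rng):
        ref = 50 + rng.standard_normal(2000)
        f = 2.0 * ref + 5.0
        tr = signals.compute_dff(f, ref)
        assert np.allclose(tr.dff, 0.0, atol=1e-12)

    def test_pointwise_arithmetic(self, rng):
        ref = 50 + rng.standard_normal(2000)
        f = 2.0 * ref + 5.0
        f[100] = (2.0 * ref[100] + 5.0) * 1.1    # 10% above baseline there
        tr = signals.compute_dff(f, ref)
        assert tr.dff[100] == pytest.approx(0.1, abs=1e-3)

    def test_artifact_removed_by_regression(self):
        # shared artifact regressed out: dff ~ uncorrelated with artifact
        cors = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            t = np.arange(5000) / FS
            artifact = np.cumsum(r.standard_normal(5000)) * 0.01
            calcium = np.clip(r.standard_normal(5000), 0, None) * 0.5
            f = 100 + calcium + artifact
            ref = 50 + 0.8 * artifact
            tr = signals.compute_dff(f, ref)
            cors.append(np.corrcoef(tr.dff, artifact)[0, 1])
        assert abs(np.mean(cors)) < 0.05

    def test_invariant_to_affine_reference_rescaling(self, rng):
        ref = 50 + rng.standard_normal(2000)
        f = 100 + rng.standard_normal(2000)
        a = signals.compute_dff(f, ref).dff
        b = signals.compute_dff(f, 3.0 * ref - 20.0).dff
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            signals.compute_dff(np.ones(100), np.ones(100))


class TestMovementLabels:
    def test_stationary_noise_rarely_crosses(self):
        fractions = []
        for seed in range(10):
            emg = np.random.default_rng(seed).standard_normal(int(600 * FS))
            labels, _, flag = signals.movement_labels(emg, FS)
            fractions.append(labels.mean())
            assert not flag
        # median + 7*MAD of a smoothed-envelope series is far out in the
        # tail; epochs crossing it by chance stay rare
        assert np.mean(fractions) < 0.05

    def test_injected_burst_labels_its_epoch(self, rng):
        emg = rng.standard_normal(int(300 * FS))
        emg[int(155 * FS):int(156 * FS)] += 20.0
        labels, _, _ = signals.movement_labels(emg, FS)
        assert labels[15]

    def test_all_zero_emg_degenerate(self):
        with pytest.warns(UserWarning, match="MAD"):
            labels, _, flag = signals.movement_labels(np.zeros(int(100 * FS)),
                                                      FS)
        assert flag and not labels.any()


class TestRectifyLowpass:
    def test_nonnegative_slow_signal_passes(self):
        t = np.arange(int(30 * FS)) / FS
        x = 1.0 + 0.3 * np.sin(2 * np.pi * 0.2 * t)
        y = signals.rectify_lowpass(x, FS, cutoff=10.0)
        np.testing.assert_allclose(y[200:-200], x[200:-200], rtol=0.01)

    def test_pure_negative_input_near_zero(self):
        y = signals.rectify_lowpass(-np.ones(1000), FS, cutoff=5.0)
        assert np.allclose(y, 0.0, atol=1e-9)

    def test_halfwave_sine_mean(self):
        # closed form: mean of max(A sin, 0) = A / pi
        t = np.arange(int(100 * FS)) / FS
        y = signals.rectify_lowpass(2.0 * np.sin(2 * np.pi * 5 * t), FS, 1.0)
        assert np.mean(y[500:-500]) == pytest.approx(2.0 / np.pi, rel=0.02)

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            signals.rectify_lowpass(np.ones(100), FS, cutoff=60.0)


class TestRollingPearson:
    def test_identical_series_unity(self, rng):
        x = rng.standard_normal(int(60 * FS))
        r = signals.rolling_pearson(x, x, FS)
        assert np.all(r[int(5 * FS):-int(5 * FS)] > 0.999)

    def test_negated_series_minus_one(self, rng):
        x = rng.standard_normal(int(60 * FS))
        r = signals.rolling_pearson(x, -x, FS)
        assert np.all(r[int(5 * FS):-int(5 * FS)] < -0.999)

    def test_independent_noise_mean_near_zero(self):
        means = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = r.standard_normal(int(600 * FS))
            y = r.standard_normal(int(600 * FS))
            means.append(signals.rolling_pearson(x, y, FS).mean())
        assert abs(np.mean(means)) < 0.05


class TestRelativeBandPower:
    def test_sigma_tone_near_one(self):
        t = np.arange(int(20 * 500)) / 500
        _, vals = signals.relative_band_power_trace(
            np.sin(2 * np.pi * 12 * t), 500)
        assert vals.mean() > 0.95

    def test_delta_tone_near_zero(self):
        t = np.arange(int(20 * 500)) / 500
        _, vals = signals.relative_band_power_trace(
            np.sin(2 * np.pi * 3 * t), 500)
        assert vals.mean() < 0.05

    def test_bounded_unit_interval(self, rng):
        _, vals = signals.relative_band_power_trace(
            rng.standard_normal(int(30 * 500)), 500)
        assert np.all((vals >= 0) & (vals <= 1))

    def test_entrained_spindles_give_periodic_peaks(self):
        # spindle bursts at 1 Hz spacing: sigma-power peaks 1 s apart
        fs = 500.0
        x = 0.05 * np.random.default_rng(0).standard_normal(int(30 * fs))
        for k in range(2, 28):
            m = int(0.5 * fs)
            tt = np.arange(m) / fs
            x[int(k * fs):int(k * fs) + m] += \
                np.hanning(m) * np.sin(2 * np.pi * 12 * tt)
        times, vals = signals.relative_band_power_trace(x, fs)
        fs_series = 1.0 / np.median(np.diff(times))
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(vals, distance=int(0.5 * fs_series),
                              height=0.5)
        spacing = np.diff(times[peaks])
        assert np.median(spacing) == pytest.approx(1.0, abs=0.1)


class TestEventTriggered:
    def test_constructed_kernel_latency(self, rng):
        fs = 50.0
        n = int(300 * fs)
        x = 0.05 * rng.standard_normal(n)
        events = np.arange(2.0, 295.0, 3.0)
        kern = np.exp(-0.5 * ((np.arange(0, 1, 1 / fs) - 0.30) / 0.05) ** 2)
        for t0 in events:
            i0 = int(t0 * fs)
            x[i0:i0 + kern.size] += kern
        res = signals.event_triggered(x, fs, events, window=(0, 1))
        assert res.latency_to_peak == pytest.approx(0.30, abs=1.01 / fs)
        assert res.n_events == events.size

    def test_flat_signal_degenerate(self):
        res = signals.event_triggered(np.ones(1000), FS, [2.0, 4.0],
                                      window=(0, 1))
        assert res.degenerate and np.isnan(res.latency_to_peak)

    def test_no_usable_events_rejected(self):
        with pytest.raises(ValueError):
            signals.event_triggered(np.ones(100), FS, [50.0], window=(0, 1))

    @pytest.mark.parametrize("latency", [0.25, 0.35, 0.45])
    def test_generator_latency_recovered(self, latency):
        errs = []
        for seed in range(5):
            cfg = sg.SynthConfig(total_duration=150,
                                 state_dwell_means=(1e-9, np.inf, 1e-9),
                                 nrem_rebound_latency=latency, seed=seed)
            hyp = sg.generate_hypnogram(cfg, seed)
            onsets = np.arange(5.0, 145.0, 1.0)
            sig, ref = sg.generate_photometry(hyp, sg.PulseTrain(onsets),
                                              cfg, seed)
            tr = signals.compute_dff(sig, ref, cfg.photo_rate)
            t50 = np.arange(0, 150, 1 / 50.0)
            dff50 = np.interp(t50, np.arange(tr.dff.size) / cfg.photo_rate,
                              tr.dff)
            res = signals.event_triggered(dff50, 50.0, onsets, window=(0, 1))
            errs.append(abs(res.latency_to_peak - latency))
        assert np.mean(errs) <= 0.04


class TestCrossCorrelogram:
    def test_periodic_response_peaks_at_integer_lags(self):
        fs = 10.0
        t = np.arange(0, 300, 1 / fs)
        series = np.cos(2 * np.pi * 1.0 * t)       # 1 Hz response
        pulses = np.arange(1.0, 295.0, 1.0)
        lags, corr = signals.cross_correlogram(series, fs, pulses)
        n = signals.count_correlogram_peaks(lags, corr)
        assert n == 10

    def test_independent_series_small_correlation(self):
        fs = 10.0
        maxima, null_sds = [], []
        for seed in range(5):
            r = np.random.default_rng(seed)
            series = r.standard_normal(int(600 * fs))
            pulses = np.sort(r.uniform(0, 590, 200))
            lags, corr = signals.cross_correlogram(series, fs, pulses)
            maxima.append(np.abs(corr).max())
            # shuffled-pulse null
            null = []
            for _ in range(20):
                p2 = np.sort(r.uniform(0, 590, 200))
                _, c2 = signals.cross_correlogram(series, fs, p2)
                null.append(np.abs(c2).max())
            null_sds.append(np.mean(null) + 3 * np.std(null))
        assert np.mean(maxima) < np.mean(null_sds)

    def test_antiphase_response_minima_at_integer_lags(self):
        fs = 10.0
        t = np.arange(0, 300, 1 / fs)
        series = -np.cos(2 * np.pi * 1.0 * t)
        pulses = np.arange(1.0, 295.0, 1.0)
        lags, corr = signals.cross_correlogram(series, fs, pulses)
        at_integer = corr[np.isclose(lags % 1.0, 0) & (lags > 0.5)]
        assert np.all(at_integer < 0)

    def test_no_pulses_rejected(self):
        with pytest.raises(ValueError):
            signals.cross_correlogram(np.ones(100), 10.0, [])


class TestTwoPhoton:
    def test_pure_exponential_corrected_flat(self):
        fs = 20.0
        t = np.arange(0, 60, 1 / fs)
        trace = 200 * np.exp(-t / 30) + 50
        dff = signals.twophoton_dff(trace, fs, stim_onset=30.0)
        assert np.max(np.abs(dff)) < 0.02

    def test_boxcar_transient_recovered(self):
        fs = 20.0
        t = np.arange(0, 60, 1 / fs)
        bleach = 200 * np.exp(-t / 40) + 50
        transient = np.where((t >= 32) & (t < 40), 0.30, 0.0)
        trace = bleach * (1 + transient)
        dff = signals.twophoton_dff(trace, fs, stim_onset=30.0)
        plateau = dff[(t >= 34) & (t < 38)]
        assert np.mean(plateau) == pytest.approx(0.30, rel=0.05)

    def test_too_few_prestim_samples_rejected(self):
        with pytest.raises(ValueError, match="pre-stimulus"):
            signals.twophoton_dff(np.ones(100), 20.0, stim_onset=0.5)
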