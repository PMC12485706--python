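"""Synthetic session generator: determinism, containment, statistics."""

import numpy as np
import pytest

from spindlelab import signals
from spindlelab import synthgen as sg


class TestHypnogram:
    def test_infinite_wake_dwell_gives_all_wake(self):
        cfg = sg.SynthConfig(total_duration=1200,
                             state_dwell_means=(np.inf, 1e-9, 1e-9))
        hyp = sg.generate_hypnogram(cfg, 0)
        assert set(hyp.labels) == {sg.WAKE}

    def test_epoch_grid_arithmetic(self):
        cfg = sg.SynthConfig(total_duration=100.0)
        assert sg.generate_hypnogram(cfg, 0).n_epochs == 10

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            sg.generate_hypnogram(sg.SynthConfig(total_duration=50.0), 0)

    def test_rem_entered_only_from_nrem(self):
        cfg = sg.SynthConfig(total_duration=24 * 3600,
                             state_dwell_means=(60.0, 60.0, 30.0))
        hyp = sg.generate_hypnogram(cfg, 3)
        labels = hyp.labels
        for i in range(1, len(labels)):
            if labels[i] == sg.REM and labels[i - 1] != sg.REM:
                assert labels[i - 1] == sg.NREM

    def test_state_fractions_match_chain_enumeration_oracle(self):
        cfg = sg.SynthConfig(total_duration=24 * 3600)
        expected = sg.hypnogram_stationary_fractions(cfg)
        fracs = {s: [] for s in sg.STATES}
        for seed in range(25):
            hyp = sg.generate_hypnogram(cfg, seed)
            for s in sg.STATES:
                fracs[s].append(hyp.fraction(s))
        for s in sg.STATES:
            assert np.mean(fracs[s]) == pytest.approx(expected[s],
                                                      rel=0.20)

    def test_dwell_means_recovered(self):
        cfg = sg.SynthConfig(total_duration=8 * 3600,
                             state_dwell_means=(300.0, 180.0, 60.0))
        dwells = {s: [] for s in sg.STATES}
        for seed in range(10):
            hyp = sg.generate_hypnogram(cfg, seed)
            for s in sg.STATES:
                dwells[s].extend(e - a for a, e in hyp.runs(s))
        for s, mean in zip(sg.STATES, cfg.state_dwell_means):
            assert np.mean(dwells[s]) == pytest.approx(mean, rel=0.20)


class TestEEG:
    def test_zero_rate_no_spindles(self, nrem_hypnogram, nrem_config):
        cfg = sg.SynthConfig(**{**nrem_config.as_dict(),
                                "spindle_rate_nrem": 0.0})
        _, spn, _ = sg.generate_eeg(nrem_hypnogram, cfg, 0)
        assert spn == []

    def test_all_wake_no_spindles(self):
        cfg = sg.SynthConfig(total_duration=300,
                             state_dwell_means=(np.inf, 1e-9, 1e-9))
        hyp = sg.generate_hypnogram(cfg, 0)
        _, spn, _ = sg.generate_eeg(hyp, cfg, 0)
        assert spn == []

    def test_poisson_event_count(self):
        # 6 / min over ~10 min of NREM: mean count near 60 within
        # Monte-Carlo error of the Poisson mean
        counts = []
        for seed in range(30):
            cfg = sg.SynthConfig(total_duration=610,
                                 state_dwell_means=(1e-9, np.inf, 1e-9),
                                 spindle_rate_nrem=6.0, seed=seed)
            hyp = sg.generate_hypnogram(cfg, seed)
            nrem_minutes = 10 * hyp.fraction(sg.NREM) * 610 / 600
            _, spn, _ = sg.generate_eeg(hyp, cfg, seed)
            counts.append(len(spn) / nrem_minutes * 10)
        sem = np.sqrt(60) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 60) < 4 * sem + 1.0

    def test_spindles_contained_in_nrem(self):
        cfg = sg.SynthConfig(total_duration=1800,
                             state_dwell_means=(120.0, 120.0, 40.0), seed=2)
        hyp = sg.generate_hypnogram(cfg, 2)
        _, spn, _ = sg.generate_eeg(hyp, cfg, 2)
        assert spn
        for start, end in spn:
            assert end > start
            assert hyp.state_at(start) == sg.NREM
            assert hyp.state_at(end - 1e-6) == sg.NREM

    def test_nrem_sigma_fraction_exceeds_wake(self):
        # averaged periodograms: sigma band fraction higher in NREM
        ratios = []
        for seed in range(10):
            cfg = sg.SynthConfig(total_duration=600,
                                 state_dwell_means=(120.0, 120.0, 1e-9),
                                 rem_entry_prob=0.0, seed=seed)
            hyp = sg.generate_hypnogram(cfg, seed)
            eeg, _, _ = sg.generate_eeg(hyp, cfg, seed)
            fs = cfg.eeg_rate

            def band_fraction(state):
                runs = hyp.runs(state)
                vals = []
                for a, b in runs:
                    seg = eeg[int(a * fs):int(b * fs)]
                    if seg.size < fs:
                        continue
                    freqs = np.fft.rfftfreq(seg.size, 1 / fs)
                    spec = np.abs(np.fft.rfft(seg))**2
                    vals.append(spec[(freqs >= 9) & (freqs <= 16)].sum()
                                / spec[(freqs >= 1) & (freqs <= 30)].sum())
                return np.mean(vals)

            ratios.append(band_fraction(sg.NREM) - band_fraction(sg.WAKE))
        assert np.mean(ratios) > 0
        assert np.mean(np.array(ratios) > 0) >= 0.9


class TestEMG:
    def test_zero_burst_rate_no_movement(self, nrem_config):
        cfg = sg.SynthConfig(**{**nrem_config.as_dict(),
                                "emg_burst_rate_wake": 0.0})
        hyp = sg.generate_hypnogram(cfg, 0)
        _, mov = sg.generate_emg(hyp, cfg, 0)
        assert mov == []

    def test_nrem_only_no_movement(self, nrem_hypnogram, nrem_config):
        _, mov = sg.generate_emg(nrem_hypnogram, nrem_config, 0)
        # only the single leading wake epoch could host bursts
        assert all(e <= 10.0 for _, e in mov)

    def test_injected_burst_marks_its_epoch(self):
        cfg = sg.SynthConfig(total_duration=300,
                             state_dwell_means=(np.inf, 1e-9, 1e-9),
                             emg_burst_rate_wake=0.0, seed=1)
        hyp = sg.generate_hypnogram(cfg, 1)
        emg, _ = sg.generate_emg(hyp, cfg, 1)
        fs = cfg.emg_rate
        i0 = int(145.0 * fs)
        emg[i0:i0 + int(fs)] += 20 * sg.EMG_RMS   # burst in epoch 14
        labels, _, _ = signals.movement_labels(emg, fs)
        assert labels[14]


class TestPhotometry:
    def test_pulses_outside_recording_rejected(self, nrem_hypnogram,
                                               nrem_config):
        stim = sg.PulseTrain(onsets=np.array([400.0]))
        with pytest.raises(ValueError):
            sg.generate_photometry(nrem_hypnogram, stim, nrem_config, 0)

    def test_reference_explains_signal_without_events(self, nrem_config):
        cfg = sg.SynthConfig(**{**nrem_config.as_dict(),
                                "ca_event_rate": 1e-9})
        hyp = sg.generate_hypnogram(cfg, 0)
        sig, ref = sg.generate_photometry(hyp, None, cfg, 0)
        tr = signals.compute_dff(sig, ref, cfg.photo_rate)
        # residual dff noise well below the scale a calcium event adds
        assert np.nanstd(tr.dff) < 0.01

    def test_wake_pulses_suppress(self):
        cfg = sg.SynthConfig(total_duration=200,
                             state_dwell_means=(np.inf, 1e-9, 1e-9), seed=4)
        hyp = sg.generate_hypnogram(cfg, 4)
        onsets = np.arange(5.0, 195.0, 2.0)
        sig, ref = sg.generate_photometry(hyp, sg.PulseTrain(onsets), cfg, 4)
        tr = signals.compute_dff(sig, ref, cfg.photo_rate)
        res = signals.event_triggered(tr.dff, cfg.photo_rate, onsets,
                                      window=(0.0, 1.0))
        assert np.min(res.mean_response) < -abs(np.max(res.mean_response))


class TestSession:
    def test_bit_identical_per_seed(self):
        cfg = sg.SynthConfig(total_duration=120.0)
        a, _ = sg.generate_session(cfg, 9)
        b, _ = sg.generate_session(cfg, 9)
        for name in a.channels:
            assert np.array_equal(a.channels[name][0], b.channels[name][0])

    def test_seed_changes_output(self):
        cfg = sg.SynthConfig(total_duration=120.0)
        a, _ = sg.generate_session(cfg, 1)
        b, _ = sg.generate_session(cfg, 2)
        assert not np.array_equal(a.channels["eeg_R"][0],
                                  b.channels["eeg_R"][0])

    def test_epoch_count_and_channel_lengths(self):
        cfg = sg.SynthConfig(total_duration=600.0)
        rec, gt = sg.generate_session(cfg, 0)
        assert gt.hypnogram.n_epochs == 60
        for name, (x, fs, _) in rec.channels.items():
            assert abs(len(x) - 600.0 * fs) <= 1

    def test_movement_contained_in_wake(self):
        cfg = sg.SynthConfig(total_duration=1200,
                             state_dwell_means=(120.0, 120.0, 40.0))
        rec, gt = sg.generate_session(cfg, 5)
        for start, end in gt.movement_intervals:
            assert gt.hypnogram.state_at(start) == sg.WAKE
            assert gt.hypnogram.state_at(end - 1e-6) == sg.WAKE
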