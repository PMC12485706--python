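"""Closed-loop protocol simulation and condition contrasts."""

import numpy as np
import pandas as pd
import pytest

from spindlelab import closedloop as cl
from spindlelab import signals, spindles
from spindlelab import synthgen as sg


def make_session(duration, dwells, seed, **kw):
    cfg = sg.SynthConfig(total_duration=duration, state_dwell_means=dwells,
                         seed=seed, **kw)
    return cfg, *sg.generate_session(cfg, seed)


class TestSpectralStager:
    def test_recognizes_all_three_states(self):
        cfg, rec, gt = make_session(
            1800, (120.0, 120.0, 60.0), seed=11)
        eeg, fs_eeg = rec.get("eeg_R")
        emg, fs_emg = rec.get("emg_1")
        stager = cl.SpectralStager().calibrate(emg, fs_emg)
        correct = {s: [0, 0] for s in sg.STATES}
        for k in range(gt.hypnogram.n_epochs):
            t0 = k * sg.EPOCH_LEN
            truth = str(gt.hypnogram.labels[k])
            guess = stager.stage(
                eeg[int(t0 * fs_eeg):int((t0 + 10) * fs_eeg)],
                emg[int(t0 * fs_emg):int((t0 + 10) * fs_emg)],
                fs_eeg, fs_emg)
            correct[truth][0] += guess == truth
            correct[truth][1] += 1
        for state, (hit, tot) in correct.items():
            if tot:
                assert hit / tot > 0.6, (state, hit, tot)

    def test_uncalibrated_rejected(self):
        with pytest.raises(ValueError, match="calibrat"):
            cl.SpectralStager().stage(np.ones(100), np.ones(100), 10.0, 10.0)


class TestRunProtocol:
    @pytest.mark.parametrize("rate, n_expected", [(0.5, 5), (1.0, 10),
                                                  (1.5, 15)])
    def test_pulses_per_block(self, rate, n_expected, nrem_config,
                              nrem_hypnogram):
        rec, gt = sg.generate_session(nrem_config, 0)
        protocol = cl.StimProtocol(
            schedule=[cl.ScheduleWindow(0.0, 300.0, sg.NREM)],
            pulse_rate=rate)
        log = cl.run_protocol(rec, protocol, cl.TruthStager(gt.hypnogram))
        assert len(log.blocks) > 0
        starts = log.blocks["start"].to_numpy()
        block_of = np.searchsorted(starts, log.pulses["onset"].to_numpy(),
                                   side="right") - 1
        for _, grp in log.pulses.groupby(block_of):
            assert len(grp) == n_expected

    def test_never_triggering_state_empty_log(self, nrem_config):
        rec, gt = sg.generate_session(nrem_config, 0)
        protocol = cl.StimProtocol(
            schedule=[cl.ScheduleWindow(0.0, 300.0, sg.REM)])
        log = cl.run_protocol(rec, protocol, cl.TruthStager(gt.hypnogram))
        assert log.pulses.empty and log.blocks.empty

    def test_causality_no_pulse_before_trigger(self, nrem_config):
        rec, gt = sg.generate_session(nrem_config, 0)
        protocol = cl.StimProtocol(
            schedule=[cl.ScheduleWindow(0.0, 300.0, sg.NREM)])
        log = cl.run_protocol(rec, protocol, cl.TruthStager(gt.hypnogram))
        trig = log.triggers.set_index("time")["detected_state"]
        for _, p in log.pulses.iterrows():
            prior = trig[trig.index <= p.onset]
            assert (prior == sg.NREM).any()
            assert p.onset > prior.index[-1] - 10.0

    def test_halves_protocol_concurrent_channels(self):
        cfg, rec, gt = make_session(600, (1e-9, np.inf, 1e-9), seed=5)
        protocol = cl.halves_protocol(600.0)
        log = cl.run_protocol(rec, protocol, cl.TruthStager(gt.hypnogram))
        first = log.pulses[log.pulses.onset < 300]
        second = log.pulses[log.pulses.onset >= 300]
        assert set(first.channel) == {"stim"}
        assert set(second.channel) == {"stim", "inhibit"}
        inh = second[second.channel == "inhibit"]
        assert np.allclose(inh.width, 10.0, atol=0.5)   # continuous light

    def test_no_overlapping_pulses_within_channel(self, nrem_config):
        rec, gt = sg.generate_session(nrem_config, 0)
        protocol = cl.StimProtocol(
            schedule=[cl.ScheduleWindow(0.0, 300.0, sg.NREM)],
            pulse_rate=1.5)
        log = cl.run_protocol(rec, protocol, cl.TruthStager(gt.hypnogram))
        for _, grp in log.pulses.groupby("channel"):
            onsets = grp.onset.to_numpy()
            widths = grp.width.to_numpy()
            assert np.all(onsets[1:] >= onsets[:-1] + widths[:-1] - 1e-9)

    def test_invalid_duty_cycle_rejected(self):
        with pytest.raises(ValueError):
            cl.StimProtocol(schedule=[], pulse_rate=10.0,
                            pulse_width=0.2).validate()

    def test_entrainment_end_to_end(self):
        # protocol pulses drive entrained spindles; the sigma-power
        # cross-correlogram locks to the 1 Hz pulse period
        cfg, rec, gt = make_session(400, (1e-9, np.inf, 1e-9), seed=6)
        protocol = cl.StimProtocol(
            schedule=[cl.ScheduleWindow(0.0, 400.0, sg.NREM)],
            pulse_rate=1.0)
        log = cl.run_protocol(rec, protocol, cl.TruthStager(gt.hypnogram))
        train = log.pulse_train()
        eeg, _, _ = sg.generate_eeg(gt.hypnogram, cfg, 6, entrain_stim=train)
        times, rp = signals.relative_band_power_trace(eeg, cfg.eeg_rate)
        fs_series = 1.0 / np.median(np.diff(times))
        usable = train.onsets[train.onsets < times[-1]]
        lags, corr = signals.cross_correlogram(rp, fs_series,
                                               usable - times[0])
        assert signals.count_correlogram_peaks(lags, corr) == 10


class TestCompareConditions:
    def _detect_subjects(self, seeds, dur_range, rate):
        events, windows = {}, {}
        for s in seeds:
            cfg = sg.SynthConfig(total_duration=240,
                                 state_dwell_means=(1e-9, np.inf, 1e-9),
                                 spindle_dur_range=dur_range,
                                 spindle_rate_nrem=rate, seed=s)
            hyp = sg.generate_hypnogram(cfg, s)
            eeg, _, _ = sg.generate_eeg(hyp, cfg, s)
            events[s] = spindles.detect(eeg, cfg.eeg_rate)
            windows[s] = 24
        return events, windows

    def test_identical_conditions_zero_differences(self):
        ev, win = self._detect_subjects(range(4), (0.6, 1.5), 4.0)
        table, tests = cl.compare_conditions(ev, ev, win, win)
        assert np.allclose(table["diff"].fillna(0.0), 0.0)
        assert tests == {}

    def test_shifted_duration_detected_others_null(self):
        ev, win = self._detect_subjects(range(5), (0.6, 1.5), 4.0)
        ev_b = {s: df.assign(Duration=df.Duration + 0.2)
                for s, df in ev.items()}
        table, tests = cl.compare_conditions(ev, ev_b, win, win, sided="one")
        assert tests["Duration"].p == pytest.approx(0.5**5)
        assert "Frequency" not in tests or tests["Frequency"].p > 0.2

    def test_injected_inhibition_effect_recovered(self):
        # "inhibition" condition: longer and more frequent spindles
        ev_a, win_a = self._detect_subjects(range(6), (0.6, 1.2), 3.0)
        ev_b, win_b = self._detect_subjects(range(100, 106), (1.0, 1.8), 6.0)
        ev_b = {s - 100: df for s, df in ev_b.items()}
        win_b = {s - 100: w for s, w in win_b.items()}
        table, tests = cl.compare_conditions(ev_a, ev_b, win_a, win_b,
                                             sided="one")
        dur = table[table.characteristic == "Duration"]["diff"]
        cnt = table[table.characteristic == "spindles_per_10s"]["diff"]
        assert dur.mean() > 0 and cnt.mean() > 0
        assert tests["Duration"].p < 0.05
        assert tests["spindles_per_10s"].p < 0.05

    def test_unmatched_subjects_rejected(self):
        ev, win = self._detect_subjects(range(2), (0.6, 1.5), 4.0)
        with pytest.raises(ValueError, match="subject"):
            cl.compare_conditions(ev, {99: list(ev.values())[0]}, win,
                                  {99: 24})

    def test_amplitude_exclusion_drops_only_violators(self, rng):
        fs = 500.0
        eeg = 1e-4 * rng.standard_normal(int(100 * fs))
        eeg[int(35 * fs)] = 400e-5          # constructed outlier in window 3
        windows = [(10.0 * k, 10.0 * (k + 1)) for k in range(10)]
        kept = cl.exclude_windows(eeg, fs, windows, amplitude_cap=300e-5)
        assert (30.0, 40.0) not in kept
        assert len(kept) == 9
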