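"""Closed-loop, state-triggered stimulation protocol simulation.

Mirrors the in vivo closed-loop designs: a recording is walked in 10 s
epochs; when the stager's state call matches the active schedule
window's trigger state, a 10 s block of light pulses (0.2 s on, at
0.5/1/1.5 Hz) -- or continuous light on an inhibition channel -- is
emitted starting at the next sample.  Typical schedules split a day
into thirds (REM/wake/NREM triggers) or halves (stimulation vs
stimulation+inhibition).

The original real-time sleep stager was a trained neural network; here
staging is pluggable: a rule-based spectral stager is provided, and the
ground-truth hypnogram can be passed directly to isolate protocol logic
from staging errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import synthgen
from .exactstats import ExactTestResult, wilcoxon_exact
from .synthgen import EPOCH_LEN, NREM, REM, WAKE, Hypnogram, Recording

__all__ = ["ScheduleWindow", "StimProtocol", "StimLog", "SpectralStager",
           "TruthStager", "spectral_stage", "run_protocol",
           "thirds_protocol", "halves_protocol", "compare_conditions"]


@dataclass(frozen=True)
class ScheduleWindow:
    start: float                  # s
    end: float                    # s
    trigger_state: str            # wake | nrem | rem
    channels: tuple[str, ...] = ("stim",)


@dataclass
class StimProtocol:
    """Schedule plus pulse shape; windows must partition the session."""

    schedule: list[ScheduleWindow]
    pulse_rate: float = 1.0       # Hz, in {0.5, 1, 1.5}
    pulse_width: float = 0.2      # s
    block_len: float = 10.0       # s of stimulation per trigger
    continuous_channels: tuple[str, ...] = ()   # emitted as solid light

    def validate(self, duration: float | None = None) -> None:
        if self.pulse_width * self.pulse_rate > 1.0:
            raise ValueError("pulse_width * pulse_rate must be <= 1")
        sched = sorted(self.schedule, key=lambda w: w.start)
        for a, b in zip(sched, sched[1:]):
            if a.end > b.start:
                raise ValueError("schedule windows overlap")
        if duration is not None and sched and sched[-1].end > duration + 1e-9:
            raise ValueError("schedule extends past the recording")

    def window_at(self, t: float) -> ScheduleWindow | None:
        for w in self.schedule:
            if w.start <= t < w.end:
                return w
        return None


@dataclass
class StimLog:
    pulses: pd.DataFrame          # onset, width, channel, condition
    triggers: pd.DataFrame        # time, detected_state
    blocks: pd.DataFrame          # start, end, condition

    def pulse_train(self, channel: str = "stim") -> synthgen.PulseTrain:
        sel = self.pulses[self.pulses["channel"] == channel]
        width = float(sel["width"].iloc[0]) if len(sel) else 0.2
        return synthgen.PulseTrain(onsets=sel["onset"].to_numpy(),
                                   width=width)


def thirds_protocol(duration: float, pulse_rate: float = 1.0,
                    order: tuple[str, str, str] = (REM, WAKE, NREM)
                    ) -> StimProtocol:
    """Day split into thirds; each third triggers on one state."""
    third = duration / 3.0
    schedule = [ScheduleWindow(i * third, (i + 1) * third, st)
                for i, st in enumerate(order)]
    return StimProtocol(schedule=schedule, pulse_rate=pulse_rate)


def halves_protocol(duration: float, pulse_rate: float = 1.0,
                    trigger_state: str = NREM,
                    inhibit_second_half: bool = True) -> StimProtocol:
    """NREM-triggered stimulation; one half adds a continuous-inhibition
    channel (order reversible for the counterbalanced day)."""
    half = duration / 2.0
    first = ScheduleWindow(0.0, half, trigger_state,
                           ("stim",) if inhibit_second_half
                           else ("stim", "inhibit"))
    second = ScheduleWindow(half, duration, trigger_state,
                            ("stim", "inhibit") if inhibit_second_half
                            else ("stim",))
    return StimProtocol(schedule=[first, second],
                        continuous_channels=("inhibit",))


class TruthStager:
    """Stager that reads the ground-truth hypnogram (no staging error)."""

    def __init__(self, hypnogram: Hypnogram):
        self.hypnogram = hypnogram

    def stage(self, eeg_epoch, emg_epoch, fs_eeg, fs_emg, t_start):
        return self.hypnogram.state_at(t_start)


class SpectralStager:
    """Rule-based stand-in for the real-time sleep stager.

    A sustained, elevated EMG envelope marks wake; otherwise the delta
    (1-4 Hz) to theta (5-9 Hz) EEG power ratio separates NREM
    (delta-dominant) from REM (theta-dominant).  The EMG threshold is
    calibrated per recording as the session mean of the smoothed
    rectified EMG, mimicking the per-animal normalization of the
    original classifier: wake muscle tone sits above the mixed-state
    mean, sleep tone below it.
    """

    def __init__(self, emg_threshold: float | None = None,
                 delta_theta_ratio: float = 1.0,
                 smooth_window: float = 0.5):
        self.emg_threshold = emg_threshold
        self.delta_theta_ratio = delta_theta_ratio
        self.smooth_window = smooth_window

    def calibrate(self, emg: np.ndarray, fs_emg: float) -> "SpectralStager":
        from .signals import _moving_average

        env = _moving_average(np.abs(np.asarray(emg, dtype=float)),
                              int(round(self.smooth_window * fs_emg)))
        self.emg_threshold = float(env.mean())
        return self

    def stage(self, eeg_epoch, emg_epoch, fs_eeg, fs_emg, t_start=0.0):
        from .signals import _moving_average

        if eeg_epoch is None or emg_epoch is None:
            raise ValueError("stager needs both EEG and EMG epochs")
        if self.emg_threshold is None:
            raise ValueError("stager not calibrated: no EMG threshold")
        env = _moving_average(np.abs(np.asarray(emg_epoch, dtype=float)),
                              int(round(self.smooth_window * fs_emg)))
        if env.mean() > self.emg_threshold:
            return WAKE
        freqs = np.fft.rfftfreq(len(eeg_epoch), d=1.0 / fs_eeg)
        spec = np.abs(np.fft.rfft(np.asarray(eeg_epoch, dtype=float))) ** 2
        delta = spec[(freqs >= 1) & (freqs <= 4)].sum()
        theta = spec[(freqs >= 5) & (freqs <= 9)].sum()
        ratio = delta / theta if theta > 0 else np.inf
        return NREM if ratio > self.delta_theta_ratio else REM


def spectral_stage(eeg_epoch, emg_epoch, fs_eeg: float, fs_emg: float,
                   emg_threshold: float,
                   delta_theta_ratio: float = 1.0) -> str:
    """One-shot staging of a single 10 s epoch (see SpectralStager)."""
    stager = SpectralStager(emg_threshold, delta_theta_ratio)
    return stager.stage(eeg_epoch, emg_epoch, fs_eeg, fs_emg)


def run_protocol(recording: Recording, protocol: StimProtocol, stager,
                 seed: int = 0,
                 eeg_channel: str = "eeg_R",
                 emg_channel: str = "emg_1") -> StimLog:
    """Simulate the closed loop over a recording, epoch by epoch.

    The state is evaluated at every 10 s epoch boundary from the
    rolling buffer just ended; on a trigger match a stimulation block
    starts at the next sample (1/fs after detection).  Consecutive
    trigger-state epochs re-trigger seamlessly, so sustained NREM
    yields back-to-back blocks.  Pulses per block = floor(block_len *
    pulse_rate); continuous channels log one solid interval per block.
    """
    eeg, fs_eeg = recording.get(eeg_channel)
    emg, fs_emg = recording.get(emg_channel)
    duration = recording.duration
    protocol.validate(duration)

    pulses, triggers, blocks = [], [], []
    n_epochs = int(duration // EPOCH_LEN)
    n_per_block = int(np.floor(protocol.block_len * protocol.pulse_rate))

    for k in range(n_epochs):
        t0, t1 = k * EPOCH_LEN, (k + 1) * EPOCH_LEN
        eeg_ep = eeg[int(t0 * fs_eeg):int(t1 * fs_eeg)]
        emg_ep = emg[int(t0 * fs_emg):int(t1 * fs_emg)]
        state = stager.stage(eeg_ep, emg_ep, fs_eeg, fs_emg, t0)
        triggers.append({"time": t1, "detected_state": state})
        window = protocol.window_at(t0)
        if window is None or state != window.trigger_state:
            continue
        start = t1 + 1.0 / fs_eeg          # next sample after detection
        if start >= duration:
            continue                        # recording over before onset
        if blocks and start < blocks[-1]["end"]:
            continue                        # previous block still running
        end = min(start + protocol.block_len, duration)
        condition = "+".join(window.channels)
        blocks.append({"start": start, "end": end, "condition": condition})
        for ch in window.channels:
            if ch in protocol.continuous_channels:
                pulses.append({"onset": start, "width": end - start,
                               "channel": ch, "condition": condition})
            else:
                for j in range(n_per_block):
                    onset = start + j / protocol.pulse_rate
                    if onset + protocol.pulse_width > end:
                        break
                    pulses.append({"onset": onset,
                                   "width": protocol.pulse_width,
                                   "channel": ch, "condition": condition})
        block_end_until = end

    return StimLog(
        pulses=pd.DataFrame(pulses,
                            columns=["onset", "width", "channel",
                                     "condition"]),
        triggers=pd.DataFrame(triggers, columns=["time", "detected_state"]),
        blocks=pd.DataFrame(blocks, columns=["start", "end", "condition"]),
    )


# ---------------------------------------------------------------------------
# condition contrasts

CHARACTERISTICS = ["spindles_per_10s", "Duration", "Oscillations",
                   "Amplitude", "RMS", "AbsPower", "RelPower", "Frequency",
                   "Symmetry"]


def _subject_summary(events: pd.DataFrame, n_windows_10s: int) -> dict:
    out = {"spindles_per_10s": len(events) / max(n_windows_10s, 1)}
    for col in CHARACTERISTICS[1:]:
        out[col] = float(events[col].mean()) if len(events) else np.nan
    return out


def compare_conditions(events_by_subject_a: dict[object, pd.DataFrame],
                       events_by_subject_b: dict[object, pd.DataFrame],
                       n_windows_a: dict[object, int],
                       n_windows_b: dict[object, int],
                       sided: str = "two"
                       ) -> tuple[pd.DataFrame, dict[str, ExactTestResult]]:
    """Paired per-subject spindle-characteristic comparison A vs B.

    Event tables must carry the feature columns of the detector output;
    ``n_windows_*`` give the number of analyzed 10 s windows per
    subject (after any amplitude exclusions).  Returns the per-subject
    summary table and a paired exact Wilcoxon result per characteristic.
    """
    subjects = sorted(events_by_subject_a)
    if sorted(events_by_subject_b) != subjects:
        raise ValueError("subject sets differ between conditions")

    rows = []
    for s in subjects:
        sa = _subject_summary(events_by_subject_a[s], n_windows_a[s])
        sb = _subject_summary(events_by_subject_b[s], n_windows_b[s])
        for char in CHARACTERISTICS:
            rows.append({"subject": s, "characteristic": char,
                         "A": sa[char], "B": sb[char],
                         "diff": sb[char] - sa[char]})
    table = pd.DataFrame(rows)

    tests: dict[str, ExactTestResult] = {}
    for char in CHARACTERISTICS:
        d = table.loc[table["characteristic"] == char, "diff"].to_numpy()
        d = d[np.isfinite(d)]
        if d.size == 0 or np.all(d == 0):
            continue
        tests[char] = wilcoxon_exact(d, sided=sided)
    return table, tests


def exclude_windows(eeg: np.ndarray, fs: float, windows: list[tuple[float, float]],
                    amplitude_cap: float = 300e-5) -> list[tuple[float, float]]:
    """Drop analysis windows containing any sample above the cap (V)."""
    kept = []
    for start, end in windows:
        seg = eeg[int(start * fs):int(end * fs)]
        if seg.size and np.max(np.abs(seg)) <= amplitude_cap:
            kept.append((start, end))
    return kept
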