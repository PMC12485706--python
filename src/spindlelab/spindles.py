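"""Sigma-band spindle detection and per-event featurization.

Single-channel detector for transient 9-16 Hz (sleep spindle) or
8-12 Hz (mu) oscillatory events.  Three decision signals are computed
on sliding windows -- relative sigma power from a short-time Fourier
transform, the moving Pearson correlation between broadband- and
sigma-filtered traces, and the moving RMS of the sigma-filtered trace
-- thresholded, summed into a per-sample decision vector, smoothed
("soft threshold"), and segmented: samples where at least two of the
three criteria hold become candidate events.  Candidates closer than
the merge gap are merged and events outside the 0.5-2 s duration
bounds are dropped.

Eight features are then measured per event: duration, sigma-band RMS,
median log10 absolute sigma power (Hilbert envelope), median relative
sigma power, peak-to-peak amplitude, median instantaneous frequency,
oscillation count (peaks at >= 60 ms spacing) and symmetry (relative
position of the most prominent peak).

Filters are zero-phase 4th-order Butterworth band-passes applied
forward-backward, so event timing is not skewed by filter delay.
Decision series are step-interpolated onto the sample grid; threshold
comparisons are strict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = ["SpindleParams", "SpindleEvent", "decision_signals",
           "detect_events", "merge_and_filter", "event_features", "detect",
           "events_to_frame"]


@dataclass(frozen=True)
class SpindleParams:
    broad_band: tuple[float, float] = (1.0, 30.0)
    event_band: tuple[float, float] = (9.0, 16.0)
    relpow_window: float = 2.0      # s, STFT frame
    relpow_step: float = 0.2        # s
    relpow_thresh: float = 0.2      # sigma / broadband power ratio
    corr_window: float = 0.3        # s
    corr_step: float = 0.1          # s
    corr_thresh: float = 0.65
    rms_window: float = 0.3         # s
    rms_step: float = 0.1           # s
    rms_sd_mult: float = 1.5        # threshold = mean + mult * sd
    soft_window: float = 0.1        # s, decision-vector smoothing
    min_votes: float = 2.0          # of the 3 criteria, after smoothing
    merge_gap: float = 0.1          # s
    min_dur: float = 0.5            # s
    max_dur: float = 2.0            # s
    peak_min_interval: float = 0.060  # s between counted peaks

    def validate(self) -> None:
        if not 0 < self.min_dur < self.max_dur:
            raise ValueError("need 0 < min_dur < max_dur")
        for name in ("relpow_window", "relpow_step", "corr_window",
                     "corr_step", "rms_window", "rms_step", "soft_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.relpow_thresh <= 1.0:
            raise ValueError("relpow_thresh must be in [0, 1]")
        if not -1.0 <= self.corr_thresh <= 1.0:
            raise ValueError("corr_thresh must be in [-1, 1]")


MU_BAND = (8.0, 12.0)


@dataclass
class SpindleEvent:
    start: float            # s, half-open interval [start, end)
    end: float
    duration: float         # s
    rms_amp: float          # uV-scale units of the input trace
    abs_power: float        # log10 power of the sigma-filtered signal
    rel_power: float        # fraction of broadband power in the sigma band
    p2p_amplitude: float    # max - min of the broadband event waveform
    frequency: float        # Hz, median instantaneous frequency
    oscillations: int
    symmetry: float         # in [0, 1]


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float],
              order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    lo, hi = band
    hi = min(hi, nyq * 0.99)
    sos = sps.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x)


def _frame_times(n: int, fs: float, window: float, step: float) -> np.ndarray:
    """Frame start samples for a sliding window that fits inside the trace."""
    win = int(round(window * fs))
    hop = max(int(round(step * fs)), 1)
    if n < win:
        raise ValueError("trace shorter than analysis window")
    return np.arange(0, n - win + 1, hop), win


def _step_interp(frame_starts: np.ndarray, values: np.ndarray, n: int,
                 win: int) -> np.ndarray:
    """Hold each frame's value over the samples it covers (step interp).

    Frames are indexed by their centers; each sample takes the value of
    the nearest preceding frame center (the first frame backfills).
    """
    centers = frame_starts + win // 2
    idx = np.searchsorted(centers, np.arange(n), side="right") - 1
    idx = np.clip(idx, 0, len(values) - 1)
    return values[idx]


def decision_signals(eeg, fs: float, params: SpindleParams | None = None):
    """The three sliding-window decision series on the sample grid.

    Returns ``(relpow, corr, rms, rms_threshold)`` where the three
    series are step-interpolated to one value per input sample and
    ``rms_threshold = mean(rms) + rms_sd_mult * sd(rms)`` over the
    analyzed trace (restrict the input to NREM to reproduce sleep
    scoring practice).
    """
    params = params or SpindleParams()
    params.validate()
    x = np.asarray(eeg, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite values")
    n = x.size
    if n < int(params.relpow_window * fs):
        raise ValueError("trace shorter than the relative-power window")

    broad = _bandpass(x, fs, params.broad_band)
    sigma = _bandpass(x, fs, params.event_band)

    degenerate = np.ptp(x) == 0.0

    # --- relative sigma power via STFT -------------------------------------
    starts, win = _frame_times(n, fs, params.relpow_window, params.relpow_step)
    hann = np.hanning(win)
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    band_lo, band_hi = params.event_band
    broad_lo, broad_hi = params.broad_band
    in_band = (freqs >= band_lo) & (freqs <= band_hi)
    in_broad = (freqs >= broad_lo) & (freqs <= broad_hi)
    # framed on the raw trace so that a flat input spectrum yields the
    # bandwidth ratio (sigma width / broad width) exactly
    frames = x[starts[:, None] + np.arange(win)[None, :]] * hann
    spec = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    tot = spec[:, in_broad].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        relpow_f = np.where(tot > 0, spec[:, in_band].sum(axis=1) / tot, 0.0)
    relpow = _step_interp(starts, relpow_f, n, win)

    # --- moving Pearson correlation (broadband vs sigma) -------------------
    starts_c, win_c = _frame_times(n, fs, params.corr_window, params.corr_step)
    corr_f = np.empty(starts_c.size)
    if degenerate:
        corr_f[:] = 0.0
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            for i, s0 in enumerate(starts_c):
                b = broad[s0:s0 + win_c]
                s = sigma[s0:s0 + win_c]
                sb, ss = b.std(), s.std()
                corr_f[i] = (np.mean((b - b.mean()) * (s - s.mean()))
                             / (sb * ss) if sb > 0 and ss > 0 else 0.0)
    corr = _step_interp(starts_c, corr_f, n, win_c)

    # --- moving RMS of the sigma-filtered trace ----------------------------
    starts_r, win_r = _frame_times(n, fs, params.rms_window, params.rms_step)
    rms_f = np.sqrt(np.array([np.mean(sigma[s0:s0 + win_r] ** 2)
                              for s0 in starts_r]))
    rms = _step_interp(starts_r, rms_f, n, win_r)
    rms_threshold = float(rms_f.mean() + params.rms_sd_mult * rms_f.std())

    if degenerate:
        warnings.warn("all-constant trace: correlation undefined, emitting 0",
                      stacklevel=2)
    return relpow, corr, rms, rms_threshold


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [i0, i1) index runs where mask is True."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts, ends))


def detect_events(eeg, fs: float,
                  params: SpindleParams | None = None) -> list[tuple[float, float]]:
    """Segment the decision vector into candidate event intervals.

    Votes are strict exceedances of the three thresholds, summed per
    sample, smoothed with the soft window; runs with smoothed votes
    >= ``min_votes`` become candidates, neighbours with gaps shorter
    than ``merge_gap`` are merged, and candidates outside the duration
    bounds are dropped.  Intervals are half-open [start, end) seconds.
    """
    params = params or SpindleParams()
    relpow, corr, rms, rms_thr = decision_signals(eeg, fs, params)
    votes = ((relpow > params.relpow_thresh).astype(float)
             + (corr > params.corr_thresh).astype(float)
             + (rms > rms_thr).astype(float))

    smooth_n = max(int(round(params.soft_window * fs)), 1)
    kernel = np.ones(smooth_n) / smooth_n
    soft = np.convolve(votes, kernel, mode="same")

    candidates = [(i0 / fs, i1 / fs)
                  for i0, i1 in _runs_above(soft >= params.min_votes)]
    return merge_and_filter(candidates, params)


def merge_and_filter(candidates: list[tuple[float, float]],
                     params: SpindleParams | None = None
                     ) -> list[tuple[float, float]]:
    """Merge candidates closer than the gap, then apply duration bounds.

    Exposed separately so the segmentation rules can be exercised on
    constructed candidate lists independent of the decision signals.
    """
    params = params or SpindleParams()
    merged: list[tuple[float, float]] = []
    for start, end in sorted(candidates):
        if merged and start - merged[-1][1] < params.merge_gap:
            merged[-1] = (merged[-1][0], max(end, merged[-1][1]))
        else:
            merged.append((start, end))

    return [(s, e) for s, e in merged
            if params.min_dur <= e - s <= params.max_dur]


def event_features(eeg, fs: float, event_interval: tuple[float, float],
                   params: SpindleParams | None = None) -> SpindleEvent:
    """Measure the eight per-event characteristics over one interval."""
    params = params or SpindleParams()
    x = np.asarray(eeg, dtype=float)
    broad = _bandpass(x, fs, params.broad_band)
    sigma = _bandpass(x, fs, params.event_band)
    relpow, _, _, _ = decision_signals(x, fs, params)
    return _features_precomputed(broad, sigma, relpow, fs,
                                 event_interval, params)


def _features_precomputed(broad, sigma, relpow, fs, event_interval,
                          params) -> SpindleEvent:
    start, end = event_interval
    i0, i1 = int(round(start * fs)), int(round(end * fs))
    if i0 < 0 or i1 > broad.size or i1 <= i0:
        raise ValueError("event interval outside trace")

    seg_broad = broad[i0:i1]
    seg_sigma = sigma[i0:i1]
    if np.ptp(seg_broad) == 0.0:
        raise ValueError("degenerate (constant) event segment")

    analytic = sps.hilbert(seg_sigma)
    envelope = np.abs(analytic)
    inst_power = envelope ** 2
    with np.errstate(divide="ignore"):
        abs_power = float(np.median(np.log10(inst_power[inst_power > 0])))

    phase = np.unwrap(np.angle(analytic))
    inst_freq = np.diff(phase) / (2 * np.pi) * fs
    frequency = float(np.median(inst_freq))

    distance = max(int(round(params.peak_min_interval * fs)), 1)
    peaks, props = sps.find_peaks(seg_sigma, distance=distance,
                                  prominence=1e-12)
    if peaks.size:
        best = peaks[np.argmax(props["prominences"])]
        symmetry = float(best / max(len(seg_sigma) - 1, 1))
    else:
        symmetry = float("nan")

    return SpindleEvent(
        start=float(start),
        end=float(end),
        duration=float(end - start),
        rms_amp=float(np.sqrt(np.mean(seg_sigma ** 2))),
        abs_power=abs_power,
        rel_power=float(np.median(relpow[i0:i1])),
        p2p_amplitude=float(np.ptp(seg_broad)),
        frequency=frequency,
        oscillations=int(peaks.size),
        symmetry=symmetry,
    )


def detect(eeg, fs: float, params: SpindleParams | None = None,
           band: str = "spindle") -> pd.DataFrame:
    """Full detection: events plus features, as a tidy event table."""
    params = params or SpindleParams()
    if band == "spindle":
        pass
    elif band == "mu":
        params = replace(params, event_band=MU_BAND)
    else:
        raise ValueError(f"unknown band {band!r}; use 'spindle' or 'mu'")

    x = np.asarray(eeg, dtype=float)
    intervals = detect_events(x, fs, params)
    broad = _bandpass(x, fs, params.broad_band)
    sigma = _bandpass(x, fs, params.event_band)
    relpow, _, _, _ = decision_signals(x, fs, params)
    events = [_features_precomputed(broad, sigma, relpow, fs, iv, params)
              for iv in intervals]
    return events_to_frame(events)


def events_to_frame(events: list[SpindleEvent]) -> pd.DataFrame:
    cols = ["Start", "End", "Duration", "Amplitude", "RMS", "AbsPower",
            "RelPower", "Frequency", "Oscillations", "Symmetry"]
    rows = [[e.start, e.end, e.duration, e.p2p_amplitude, e.rms_amp,
             e.abs_power, e.rel_power, e.frequency, e.oscillations,
             e.symmetry] for e in events]
    return pd.DataFrame(rows, columns=cols)
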