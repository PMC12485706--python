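"""Photometry and EMG preprocessing plus event-locked / spectral analyses.

Includes the isosbestic-style dF/F computation (reference channel
affine-fitted to the signal channel), robust EMG movement labelling
(median + 7*MAD of the smoothed rectified envelope), rolling Pearson
correlation, frame-wise relative band power, event-triggered averaging
with latency-to-peak, cross-correlograms against pulse trains, and the
slice two-photon dF/F pipeline (background subtraction, single
exponential photobleach correction, 5-point running mean, pre-stimulus
baseline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import signal as sps

__all__ = [
    "PhotometryTrace", "EventTriggeredResult", "compute_dff",
    "movement_labels", "rectify_lowpass", "rolling_pearson",
    "relative_band_power_trace", "event_triggered", "cross_correlogram",
    "twophoton_dff", "mad",
]

#: set True to scale MAD by the 1.4826 normal-consistency factor
MAD_CONSISTENCY = False


def mad(x: np.ndarray, consistency: bool = MAD_CONSISTENCY) -> float:
    """Median absolute deviation (raw by default; see MAD_CONSISTENCY)."""
    m = float(np.median(np.abs(x - np.median(x))))
    return 1.4826 * m if consistency else m


@dataclass
class PhotometryTrace:
    t: np.ndarray         # s
    f: np.ndarray         # signal-channel fluorescence
    f_ref: np.ndarray     # reference-channel fluorescence
    f0: np.ndarray        # fitted baseline (reference mapped onto signal)
    dff: np.ndarray       # (f - f0) / f0


@dataclass
class EventTriggeredResult:
    lags: np.ndarray           # s relative to event onset
    mean_response: np.ndarray
    sem: np.ndarray
    latency_to_peak: float     # s; NaN when flat/degenerate
    n_events: int
    degenerate: bool = False


def compute_dff(f, f_ref, fs: float = 1.0) -> PhotometryTrace:
    """dF/F with the baseline taken from the fitted reference channel.

    f0 is the least-squares affine map of the reference onto the signal
    (f0 = a*f_ref + b), so motion/bleaching components common to both
    channels cancel up to the fit error.  Invariant to affine rescaling
    of the reference.
    """
    f = np.asarray(f, dtype=float)
    f_ref = np.asarray(f_ref, dtype=float)
    if f.shape != f_ref.shape:
        raise ValueError("signal and reference must have equal length")
    if f_ref.std() == 0:
        raise ValueError("reference channel has zero variance; fit degenerate")
    a, b = np.polyfit(f_ref, f, 1)
    f0 = a * f_ref + b
    if np.any(f0 <= 0):
        warnings.warn("fitted baseline non-positive somewhere; dff set to NaN "
                      "there", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = np.where(f0 > 0, (f - f0) / f0, np.nan)
    t = np.arange(f.size) / fs
    return PhotometryTrace(t=t, f=f, f_ref=f_ref, f0=f0, dff=dff)


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    n = max(int(n), 1)
    pad = n // 2
    padded = np.pad(x, (pad, n - 1 - pad), mode="edge")
    return np.convolve(padded, np.ones(n) / n, mode="valid")


def movement_labels(emg, fs: float, epoch_len: float = 10.0,
                    smooth_window: float = 0.5,
                    mad_mult: float = 7.0):
    """Robust per-epoch movement labels from the EMG envelope.

    Envelope = |EMG| smoothed with a 0.5 s moving average; threshold =
    median + ``mad_mult`` * MAD of the envelope; an epoch counts as
    movement when *any* envelope sample within it exceeds the threshold.
    Returns ``(labels, threshold, degenerate_flag)``.
    """
    x = np.asarray(emg, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("EMG contains non-finite values")
    envelope = _moving_average(np.abs(x), int(round(smooth_window * fs)))
    med = np.median(envelope)
    spread = mad(envelope)
    degenerate = spread == 0.0
    if degenerate:
        warnings.warn("constant EMG envelope: MAD is zero, threshold "
                      "degenerate", stacklevel=2)
    threshold = med + mad_mult * spread

    n_epochs = int(x.size / fs // epoch_len)
    labels = np.zeros(n_epochs, dtype=bool)
    per_epoch = int(round(epoch_len * fs))
    for k in range(n_epochs):
        seg = envelope[k * per_epoch:(k + 1) * per_epoch]
        labels[k] = bool(np.any(seg > threshold))
    if degenerate:
        labels[:] = False
    return labels, float(threshold), degenerate


def rectify_lowpass(x, fs: float, cutoff: float) -> np.ndarray:
    """Half-wave rectification followed by a zero-phase low-pass."""
    if not 0 < cutoff < fs / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    rectified = np.maximum(np.asarray(x, dtype=float), 0.0)
    sos = sps.butter(4, cutoff / (fs / 2), btype="low", output="sos")
    return sps.sosfiltfilt(sos, rectified)


def rolling_pearson(x, y, fs: float, window: float = 5.0) -> np.ndarray:
    """Centered moving-window Pearson r; zero-variance windows emit 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    win = int(round(window * fs))
    if x.size < win:
        raise ValueError("trace shorter than the correlation window")
    kernel = np.ones(win) / win
    mx = np.convolve(x, kernel, mode="same")
    my = np.convolve(y, kernel, mode="same")
    mxy = np.convolve(x * y, kernel, mode="same")
    mxx = np.convolve(x * x, kernel, mode="same")
    myy = np.convolve(y * y, kernel, mode="same")
    cov = mxy - mx * my
    vx = np.maximum(mxx - mx**2, 0.0)
    vy = np.maximum(myy - my**2, 0.0)
    denom = np.sqrt(vx * vy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


def relative_band_power_trace(eeg, fs: float,
                              band: tuple[float, float] = (9.0, 16.0),
                              broad: tuple[float, float] = (1.0, 30.0),
                              window: float = 0.5, step: float = 0.1):
    """Frame-wise band power over broadband power, in [0, 1].

    Returns ``(times, values)`` with times at frame centers.  The 0.5 s
    window / 0.1 s step pairing is the convention used for sigma-power
    traces outside spindle detection proper.
    """
    x = np.asarray(eeg, dtype=float)
    win = int(round(window * fs))
    hop = max(int(round(step * fs)), 1)
    if x.size < win:
        raise ValueError("trace shorter than the analysis window")
    starts = np.arange(0, x.size - win + 1, hop)
    hann = np.hanning(win)
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    in_broad = (freqs >= broad[0]) & (freqs <= broad[1])
    frames = x[starts[:, None] + np.arange(win)[None, :]] * hann
    spec = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    tot = spec[:, in_broad].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(tot > 0, spec[:, in_band].sum(axis=1) / tot, 0.0)
    times = (starts + win / 2) / fs
    return times, np.clip(vals, 0.0, 1.0)


def event_triggered(signal, fs: float, event_times,
                    window: tuple[float, float] = (0.0, 1.0)
                    ) -> EventTriggeredResult:
    """Average the signal around events; latency to the mean-curve peak.

    Only events whose full window lies inside the trace are used; the
    SEM is across events.  A flat mean response yields NaN latency with
    the degenerate flag set.
    """
    x = np.asarray(signal, dtype=float)
    events = np.asarray(event_times, dtype=float)
    i_lo = int(round(window[0] * fs))
    i_hi = int(round(window[1] * fs))
    snippets = []
    for t0 in events:
        i0 = int(round(t0 * fs))
        if i0 + i_lo < 0 or i0 + i_hi > x.size:
            continue
        snippets.append(x[i0 + i_lo:i0 + i_hi])
    if not snippets:
        raise ValueError("no events with a full analysis window inside trace")
    snips = np.asarray(snippets)
    mean = snips.mean(axis=0)
    sem = snips.std(axis=0, ddof=1) / np.sqrt(snips.shape[0]) \
        if snips.shape[0] > 1 else np.zeros_like(mean)
    lags = (np.arange(i_lo, i_hi)) / fs
    degenerate = np.ptp(mean) == 0.0
    latency = float("nan") if degenerate else float(lags[np.argmax(mean)])
    return EventTriggeredResult(lags=lags, mean_response=mean, sem=sem,
                                latency_to_peak=latency,
                                n_events=snips.shape[0],
                                degenerate=degenerate)


def cross_correlogram(series, series_fs: float, pulse_times,
                      max_lag: float = 10.0):
    """Normalized cross-correlation of a series with a pulse train.

    The pulse onsets are binned onto the series' sample grid as an
    indicator train; both inputs are z-scored and correlated over lags
    in [-max_lag, +max_lag].  Positive lag means the series follows the
    pulses.  Returns ``(lags, corr)``.
    """
    x = np.asarray(series, dtype=float)
    pulses = np.asarray(pulse_times, dtype=float)
    if pulses.size == 0:
        raise ValueError("no pulses supplied")
    n = x.size
    duration = n / series_fs
    if pulses.min() < 0 or pulses.max() > duration:
        raise ValueError("pulses outside the series span")
    indicator = np.zeros(n)
    idx = np.minimum((pulses * series_fs).astype(int), n - 1)
    indicator[idx] = 1.0

    xs = (x - x.mean()) / (x.std() + 1e-30)
    ps = (indicator - indicator.mean()) / (indicator.std() + 1e-30)
    max_k = int(round(max_lag * series_fs))
    full = sps.correlate(xs, ps, mode="full") / n
    mid = n - 1
    lags = np.arange(-max_k, max_k + 1) / series_fs
    return lags, full[mid - max_k: mid + max_k + 1]


def count_correlogram_peaks(lags, corr, min_separation: float = 0.5,
                            span: tuple[float, float] = (0.0, 10.0)) -> int:
    """Count local maxima of a correlogram within a half-open lag span.

    Peak finding runs on a span padded by one separation so maxima at
    the span edges are not missed; peaks are then counted over
    [span[0], span[1]).
    """
    lags = np.asarray(lags)
    fs = 1.0 / float(np.median(np.diff(lags)))
    sel = (lags >= span[0] - min_separation) & (lags <= span[1]
                                                + min_separation)
    distance = max(int(round(min_separation * fs)), 1)
    peaks, _ = sps.find_peaks(corr[sel], distance=distance,
                              prominence=np.std(corr[sel]) * 0.1)
    peak_lags = lags[sel][peaks]
    return int(np.sum((peak_lags >= span[0]) & (peak_lags < span[1])))


def twophoton_dff(trace, fs: float, stim_onset: float,
                  background: float = 0.0,
                  running_mean: int = 5) -> np.ndarray:
    """Slice-imaging dF/F pipeline for a mean-fluorescence trace.

    Steps: subtract the background level, correct photobleaching by
    fitting and dividing a single exponential (fit on the pre-stimulus
    portion, where no evoked transient distorts it), apply a 5-point
    running mean, and normalize to the pre-stimulus mean.
    """
    x = np.asarray(trace, dtype=float) - background
    n_pre = int(round(stim_onset * fs))
    if n_pre < 20:
        raise ValueError("need at least 20 pre-stimulus samples")
    t = np.arange(x.size) / fs

    def model(t, a, tau, c):
        return a * np.exp(-t / tau) + c

    pre_t, pre_x = t[:n_pre], x[:n_pre]
    a0 = max(pre_x[0] - pre_x[-1], 1e-6)
    try:
        popt, _ = optimize.curve_fit(
            model, pre_t, pre_x, p0=(a0, max(t[-1] / 2, 1e-3), pre_x[-1]),
            maxfev=10000)
    except RuntimeError as err:
        resid = float(np.std(pre_x - pre_x.mean()))
        raise RuntimeError(
            f"photobleach exponential fit failed (residual SD {resid:.3g})"
        ) from err
    bleach = model(t, *popt)
    if np.any(bleach <= 0):
        raise ValueError("fitted photobleach baseline non-positive")
    corrected = x / bleach
    smoothed = _moving_average(corrected, running_mean)
    f0 = smoothed[:n_pre].mean()
    if f0 <= 0:
        raise ValueError("pre-stimulus baseline non-positive")
    return (smoothed - f0) / f0
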