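"""Figure-level analysis pipelines over synthetic sessions.

Random-segment sampling with the exclusion rules used throughout the
in vivo analyses (z-score and absolute-amplitude caps), aligned-vs-
shuffled paired comparisons, spindle-locked power spectral contrasts,
and a fully seeded miniature end-to-end run (simulate -> detect ->
decode -> closed loop -> exact stats) whose JSON output is
byte-reproducible per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import closedloop, decode, exactstats, signals, spindles, synthgen
from .synthgen import Hypnogram, Recording

__all__ = ["SamplingSpec", "sample_segments", "aligned_vs_shuffled",
           "spindle_psd_contrast", "run_miniature"]


@dataclass
class SamplingSpec:
    n_samples: int = 100
    segment_len: float = 2.0          # s
    state_constraint: str | None = synthgen.NREM
    n_iterations: int = 100
    zscore_exclusion: float | None = 5.0
    amplitude_exclusion: float | None = None    # V, any-sample cap
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.segment_len <= 0:
            raise ValueError("segment_len must be positive")
        for name in ("zscore_exclusion", "amplitude_exclusion"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")


def _eligible_anchor_times(hyp: Hypnogram, spec: SamplingSpec, anchor: str,
                           event_intervals=None, stim_onsets=None,
                           rng=None) -> np.ndarray:
    half = spec.segment_len / 2.0
    if anchor == "spindle_center":
        if not event_intervals:
            raise ValueError("no detected events to anchor on")
        centers = np.array([(s + e) / 2.0 for s, e in event_intervals])
        return centers
    if anchor == "stim_onset":
        if stim_onsets is None or len(stim_onsets) == 0:
            raise ValueError("no stimulation onsets to anchor on")
        return np.asarray(stim_onsets, dtype=float)
    if anchor == "random":
        runs = (hyp.runs(spec.state_constraint) if spec.state_constraint
                else [(0.0, hyp.duration)])
        runs = [(a + half, b - half) for a, b in runs if b - a > spec.segment_len]
        if not runs:
            raise ValueError("no state runs long enough for the segment")
        spans = np.array([b - a for a, b in runs])
        # oversample; distinct draws stand in for without-replacement
        n_draw = spec.n_samples * 4
        choices = rng.choice(len(runs), size=n_draw, p=spans / spans.sum())
        return np.array([rng.uniform(*runs[c]) for c in choices])
    raise ValueError(f"unknown anchor {anchor!r}")


def sample_segments(recording: Recording, hyp: Hypnogram,
                    spec: SamplingSpec, anchor: str = "random",
                    channel: str = "eeg_R", event_intervals=None,
                    stim_onsets=None):
    """Repeatedly sample fixed-length segments around anchors.

    Per iteration: draw ``n_samples`` anchors without replacement,
    apply the z-score exclusion (segment mean against the whole-
    recording mean/SD of the channel) and the any-sample amplitude
    cap, and keep the surviving segments.  Returns a list of 2D arrays
    (one per iteration, segments x samples) plus the segment onset
    times used, and the mean trace averaged over everything.
    """
    spec.validate()
    x, fs = recording.get(channel)
    rng = np.random.default_rng(spec.seed)
    half = spec.segment_len / 2.0
    seg_n = int(round(spec.segment_len * fs))
    mu, sd = float(x.mean()), float(x.std())

    anchors = _eligible_anchor_times(hyp, spec, anchor, event_intervals,
                                     stim_onsets, rng)
    anchors = anchors[(anchors - half >= 0)
                      & (anchors + half <= recording.duration)]
    if anchors.size == 0:
        raise ValueError("no eligible anchors inside the recording")

    iterations, onsets_used = [], []
    for _ in range(spec.n_iterations):
        take = min(spec.n_samples, anchors.size)
        picked = rng.choice(anchors, size=take, replace=False)
        segs, onsets = [], []
        for c in picked:
            i0 = int(round((c - half) * fs))
            seg = x[i0:i0 + seg_n]
            if seg.size < seg_n:
                continue
            if spec.zscore_exclusion is not None and sd > 0:
                if abs((seg.mean() - mu) / sd) > spec.zscore_exclusion:
                    continue
            if spec.amplitude_exclusion is not None:
                if np.max(np.abs(seg)) > spec.amplitude_exclusion:
                    continue
            segs.append(seg)
            onsets.append(c - half)
        if segs:
            iterations.append(np.asarray(segs))
            onsets_used.append(np.asarray(onsets))
    if not iterations:
        raise ValueError("all sampled segments excluded")
    grand_mean = np.mean([it.mean(axis=0) for it in iterations], axis=0)
    return iterations, onsets_used, grand_mean


def aligned_vs_shuffled(metric_fn, aligned_by_subject: dict,
                        shuffled_by_subject: dict, sided: str = "one"):
    """Per-subject metric means for two conditions plus a paired test.

    ``metric_fn`` maps one sampled segment (whatever object the caller
    stored) to a scalar.  Differences aligned - shuffled are tested
    with the exact one-sided Wilcoxon signed-rank; an all-zero
    difference vector is reported as degenerate with p = 1.
    """
    subjects = sorted(aligned_by_subject)
    if sorted(shuffled_by_subject) != subjects:
        raise ValueError("subject sets differ between conditions")
    rows = []
    for s in subjects:
        a = float(np.mean([metric_fn(seg) for seg in aligned_by_subject[s]]))
        b = float(np.mean([metric_fn(seg) for seg in shuffled_by_subject[s]]))
        rows.append({"subject": s, "aligned": a, "shuffled": b,
                     "diff": a - b})
    table = pd.DataFrame(rows)
    diffs = table["diff"].to_numpy()
    if np.all(diffs == 0):
        result = exactstats.ExactTestResult(
            statistic=0.0, p=1.0, sided=sided, n_config=(len(diffs),),
            method="degenerate", warnings=["all paired differences zero"])
    else:
        result = exactstats.wilcoxon_exact(diffs, sided=sided)
    return table, result


def spindle_psd_contrast(det_segments: np.ndarray,
                         shuf_segments: np.ndarray, fs: float,
                         band: tuple[float, float] = (9.0, 16.0)):
    """Averaged, total-power-normalized periodograms in decibels.

    Returns ``(freqs, db_det, db_shuf, summary)`` where the summary
    holds the peak in-band dB elevation of detected over shuffled.
    """
    det = np.atleast_2d(np.asarray(det_segments, dtype=float))
    shuf = np.atleast_2d(np.asarray(shuf_segments, dtype=float))
    if det.shape[1] != shuf.shape[1]:
        raise ValueError("segment lengths differ between conditions")

    def norm_db(segs):
        freqs, pxx = sps.periodogram(segs, fs=fs, axis=1)
        mean_pxx = pxx.mean(axis=0)
        mean_pxx = mean_pxx / mean_pxx.sum()
        return freqs, 10.0 * np.log10(mean_pxx + 1e-30)

    freqs, db_det = norm_db(det)
    _, db_shuf = norm_db(shuf)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    elevation = db_det[in_band] - db_shuf[in_band]
    summary = {
        "band": band,
        "peak_elevation_db": float(elevation.max()),
        "peak_freq": float(freqs[in_band][np.argmax(elevation)]),
    }
    return freqs, db_det, db_shuf, summary


# ---------------------------------------------------------------------------
# miniature end-to-end run

def run_miniature(seed: int = 0, duration: float = 600.0) -> dict:
    """Seeded simulate -> detect -> closed-loop -> stats miniature.

    Deterministic: identical seeds give byte-identical JSON (via
    ``json.dumps`` of the result) across runs.
    """
    cfg = synthgen.SynthConfig(total_duration=duration, seed=seed)
    rec, gt = synthgen.generate_session(cfg, seed)
    eeg, fs = rec.get("eeg_R")

    events = spindles.detect_events(eeg, fs)
    det_df = spindles.detect(eeg, fs)

    # closed-loop NREM-triggered stimulation against the truth stager
    protocol = closedloop.StimProtocol(
        schedule=[closedloop.ScheduleWindow(0.0, duration, synthgen.NREM)],
        pulse_rate=1.0)
    log = closedloop.run_protocol(rec, protocol,
                                  closedloop.TruthStager(gt.hypnogram))

    # movement labelling + spindle labels on the epoch grid
    emg, fs_emg = rec.get("emg_1")
    mov, thr, _ = signals.movement_labels(emg, fs_emg)
    n_epochs = gt.hypnogram.n_epochs
    spn_labels = decode.label_epochs(n_epochs, gt.spindle_intervals)

    out = {
        "seed": seed,
        "n_epochs": n_epochs,
        "nrem_fraction": round(gt.hypnogram.fraction(synthgen.NREM), 6),
        "n_true_spindles": len(gt.spindle_intervals),
        "n_detected_events": len(events),
        "mean_detected_duration": round(float(det_df["Duration"].mean()), 6)
        if len(det_df) else None,
        "n_movement_epochs": int(mov.sum()),
        "movement_threshold": round(float(thr), 10),
        "n_spindle_epochs": int(spn_labels.sum()),
        "n_stim_pulses": int(len(log.pulses)),
        "n_stim_blocks": int(len(log.blocks)),
    }
    # paired exact test demo on deterministic per-epoch split
    if len(events) >= 6:
        durs = np.array([e - s for s, e in events])
        half = len(durs) // 2
        res = exactstats.wilcoxon_exact(durs[:half] - durs[half:2 * half],
                                        sided="two")
        out["duration_split_p"] = round(res.p, 10)
    return json.loads(json.dumps(out))
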