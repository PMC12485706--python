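"""Plain-text readers and writers for sessions, events and results.

Synthetic sessions are written as delimited tables (CSV) plus JSON
ground truth and a key=value config file; real EEG/EMG in EDF can be
read through MNE when it is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthgen import (GroundTruth, Hypnogram, PulseTrain, Recording,
                       SynthConfig)

__all__ = ["write_session", "read_session", "write_events",
           "read_edf_channels"]


def write_session(out_dir, recording: Recording, gt: GroundTruth,
                  config: SynthConfig | None = None) -> None:
    """Write a session as CSV traces + JSON ground truth (+ config)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # EEG/EMG share one table when rates agree, else one file per channel
    ephys = {k: v for k, v in recording.channels.items()
             if k.startswith(("eeg", "emg"))}
    rates = {v[1] for v in ephys.values()}
    if len(rates) == 1:
        fs = rates.pop()
        n = min(len(v[0]) for v in ephys.values())
        df = pd.DataFrame({"time_s": np.arange(n) / fs})
        for k, (x, _, _) in ephys.items():
            df[k] = x[:n]
        df.to_csv(out / "ephys.csv", index=False)
    else:
        for k, (x, fs, _) in ephys.items():
            pd.DataFrame({"time_s": np.arange(len(x)) / fs, k: x}
                         ).to_csv(out / f"{k}.csv", index=False)

    if "photo_signal" in recording.channels:
        sig, fs_p = recording.get("photo_signal")
        ref, _ = recording.get("photo_reference")
        pd.DataFrame({"time_s": np.arange(len(sig)) / fs_p,
                      "signal": sig, "reference": ref}
                     ).to_csv(out / "photometry.csv", index=False)

    gt_json = {
        "hypnogram": list(map(str, gt.hypnogram.labels)),
        "epoch_len": gt.hypnogram.epoch_len,
        "spindle_intervals": [list(iv) for iv in gt.spindle_intervals],
        "movement_intervals": [list(iv) for iv in gt.movement_intervals],
        "mu_intervals": [list(iv) for iv in gt.mu_intervals],
        "stim_pulses": None if gt.stim_pulses is None else {
            "onsets": gt.stim_pulses.onsets.tolist(),
            "width": gt.stim_pulses.width},
        "latent_response_latency": gt.latent_response_latency,
    }
    (out / "ground_truth.json").write_text(json.dumps(gt_json, indent=1))

    if config is not None:
        lines = [f"{k}={v}" for k, v in config.as_dict().items()]
        (out / "config.txt").write_text("\n".join(lines) + "\n")

    meta = {k: {"rate": v[1], "units": v[2]}
            for k, v in recording.channels.items()}
    (out / "channels.json").write_text(json.dumps(meta, indent=1))


def read_session(session_dir) -> tuple[Recording, GroundTruth]:
    """Read a session written by :func:`write_session`."""
    d = Path(session_dir)
    meta = json.loads((d / "channels.json").read_text())
    channels: dict[str, tuple[np.ndarray, float, str]] = {}

    ephys_path = d / "ephys.csv"
    if ephys_path.exists():
        df = pd.read_csv(ephys_path)
        for col in df.columns:
            if col == "time_s":
                continue
            channels[col] = (df[col].to_numpy(), meta[col]["rate"],
                             meta[col]["units"])
    photo_path = d / "photometry.csv"
    if photo_path.exists():
        df = pd.read_csv(photo_path)
        channels["photo_signal"] = (df["signal"].to_numpy(),
                                    meta["photo_signal"]["rate"], "au")
        channels["photo_reference"] = (df["reference"].to_numpy(),
                                       meta["photo_reference"]["rate"], "au")

    gtj = json.loads((d / "ground_truth.json").read_text())
    hyp = Hypnogram(np.array(gtj["hypnogram"], dtype=object),
                    epoch_len=gtj["epoch_len"])
    stim = None
    if gtj.get("stim_pulses"):
        stim = PulseTrain(onsets=np.array(gtj["stim_pulses"]["onsets"]),
                          width=gtj["stim_pulses"]["width"])
    gt = GroundTruth(
        hypnogram=hyp,
        spindle_intervals=[tuple(iv) for iv in gtj["spindle_intervals"]],
        movement_intervals=[tuple(iv) for iv in gtj["movement_intervals"]],
        stim_pulses=stim,
        latent_response_latency=gtj.get("latent_response_latency"),
        mu_intervals=[tuple(iv) for iv in gtj.get("mu_intervals", [])],
    )
    return Recording(channels=channels), gt


def write_events(path, events_frame: pd.DataFrame) -> None:
    events_frame.to_csv(path, index=False)


def read_edf_channels(path, channel_names) -> dict[str, tuple[np.ndarray, float]]:
    """Read selected channels from an EDF file via MNE (optional dep)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), include=list(channel_names),
                              preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    return {name: (raw.get_data(picks=name)[0], fs)
            for name in channel_names}
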