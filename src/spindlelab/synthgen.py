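"""Seeded synthetic polysomnography + fiber-photometry sessions.

Generates the kind of data the downstream analyses assume: a three-state
(wake/NREM/REM) hypnogram on a 10 s epoch grid, EEG with a 1/f
background carrying delta activity and waxing-and-waning sigma-band
spindle bursts during NREM, EMG with movement bursts during wake, and a
two-channel photometry stream (calcium-sensitive signal + reference)
whose stimulus-locked responses are state dependent: a delayed rebound
peak after each light pulse in NREM, suppression in wake and REM.

Everything is driven by one integer seed; independent sub-streams are
split deterministically per component so that, e.g., changing the
spindle rate does not reshuffle the EMG noise.

Amplitudes are in volts for EEG/EMG (background RMS ~1e-4 V, i.e.
100 uV, typical of mouse epidural screw recordings) and arbitrary
fluorescence units for photometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "SynthConfig",
    "Hypnogram",
    "PulseTrain",
    "Recording",
    "GroundTruth",
    "generate_hypnogram",
    "generate_eeg",
    "generate_emg",
    "generate_photometry",
    "generate_session",
    "pink_noise",
]

WAKE, NREM, REM = "wake", "nrem", "rem"
STATES = (WAKE, NREM, REM)

EPOCH_LEN = 10.0  # s, the staging grid used throughout

# deterministic sub-stream split by component name
_STREAMS = {"hypnogram": 0, "eeg": 1, "emg": 2, "photometry": 3}

#: background RMS amplitudes (V); photometry baselines (arb. units)
EEG_RMS = 1.0e-4
EMG_RMS = 2.0e-5
PHOTO_F0_SIGNAL = 100.0
PHOTO_F0_REFERENCE = 50.0


def _rng(seed: int, component: str) -> np.random.Generator:
    ss = np.random.SeedSequence([int(seed), _STREAMS[component]])
    return np.random.default_rng(ss)


@dataclass
class SynthConfig:
    """Session-level generator settings.

    Dwell means are the expected bout lengths of the semi-Markov state
    chain; spindle parameters set Poisson rate, frequency, duration and
    amplitude (relative to the EEG background RMS) of the embedded
    sigma bursts; the calcium kernel and rebound latency shape the
    photometry responses.
    """

    total_duration: float = 3600.0          # s
    eeg_rate: float = 500.0                 # Hz
    emg_rate: float = 500.0                 # Hz
    photo_rate: float = 1000.0              # Hz
    state_dwell_means: tuple[float, float, float] = (300.0, 180.0, 60.0)
    rem_entry_prob: float = 0.35            # P(NREM -> REM) at bout end
    spindle_rate_nrem: float = 4.0          # events / minute of NREM
    spindle_freq_range: tuple[float, float] = (9.0, 16.0)
    spindle_dur_range: tuple[float, float] = (0.6, 1.5)
    spindle_amp_snr: float = 4.0            # envelope peak / background RMS
    noise_exponent: float = 1.0             # 1/f^a slope of EEG background
    delta_gain: float = 0.6                 # NREM 1-4 Hz amplitude vs background
    theta_gain_rem: float = 0.6             # REM 5-9 Hz amplitude vs background
    emg_burst_rate_wake: float = 4.0        # bursts / minute of wake
    emg_burst_gain: float = 10.0            # burst envelope vs baseline RMS
    emg_tone: tuple[float, float, float] = (1.5, 1.0, 0.4)
    # baseline muscle tone per state (wake, NREM, REM atonia)
    ca_kernel: tuple[float, float] = (0.1, 0.8)   # rise, decay (s)
    ca_event_rate: float = 10.0             # latent transients / minute
    ca_movement_gain: float = 3.0           # transient amp per movement bout
    ca_spindle_gain: float = 3.0            # transient amp per spindle
    nrem_rebound_latency: float = 0.45      # s, peak after pulse onset
    rebound_amp: float = 3.0                # fluorescence units
    wake_rem_suppression_gain: float = 1.0  # depth of wake/REM dip
    mu_rate_rem: float = 0.0                # optional 8-12 Hz REM events/min
    mu_freq_range: tuple[float, float] = (8.0, 12.0)
    seed: int = 0

    def validate(self) -> None:
        if self.total_duration < 10 * EPOCH_LEN:
            raise ValueError("total_duration must cover at least 10 epochs")
        for name in ("eeg_rate", "emg_rate", "photo_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.eeg_rate < 100:
            raise ValueError("eeg_rate must be >= 100 Hz")
        if self.emg_rate < 100:
            raise ValueError("emg_rate must be >= 100 Hz")
        if self.photo_rate < 20:
            raise ValueError("photo_rate must be >= 20 Hz")
        lo, hi = self.spindle_dur_range
        if not (0.3 <= lo < hi <= 3.0):
            raise ValueError("spindle_dur_range must lie within [0.3, 3] s")
        flo, fhi = self.spindle_freq_range
        if not (1.0 <= flo < fhi < self.eeg_rate / 2):
            raise ValueError("spindle_freq_range must lie in [1, Nyquist)")
        if not 0.0 <= self.rem_entry_prob <= 1.0:
            raise ValueError("rem_entry_prob must be in [0, 1]")
        if any(r < 0 for r in (self.spindle_rate_nrem,
                               self.emg_burst_rate_wake, self.mu_rate_rem)):
            raise ValueError("event rates must be non-negative")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class Hypnogram:
    """Per-epoch state labels on a fixed epoch grid."""

    labels: np.ndarray                      # array of state strings
    epoch_len: float = EPOCH_LEN

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)

    @property
    def n_epochs(self) -> int:
        return int(self.labels.size)

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_len

    def state_at(self, t: float) -> str:
        i = min(int(t // self.epoch_len), self.n_epochs - 1)
        return str(self.labels[i])

    def sample_mask(self, state: str, rate: float, n: int) -> np.ndarray:
        """Boolean per-sample mask for one state at a given sample rate."""
        idx = np.minimum((np.arange(n) / rate // self.epoch_len).astype(int),
                         self.n_epochs - 1)
        return np.asarray(self.labels[idx] == state)

    def runs(self, state: str) -> list[tuple[float, float]]:
        """Contiguous (start, end) second intervals labelled ``state``."""
        out, start = [], None
        for i, lab in enumerate(self.labels):
            if lab == state and start is None:
                start = i * self.epoch_len
            elif lab != state and start is not None:
                out.append((start, i * self.epoch_len))
                start = None
        if start is not None:
            out.append((start, self.duration))
        return out

    def fraction(self, state: str) -> float:
        return float(np.mean(self.labels == state))


@dataclass
class PulseTrain:
    """Light-pulse schedule: onset times (s) and a common pulse width."""

    onsets: np.ndarray
    width: float = 0.2

    def __post_init__(self):
        self.onsets = np.sort(np.asarray(self.onsets, dtype=float))


@dataclass
class Recording:
    """Named multichannel traces with per-channel sample rate and units."""

    channels: dict[str, tuple[np.ndarray, float, str]]
    t0: float = 0.0

    def get(self, name: str) -> tuple[np.ndarray, float]:
        x, fs, _units = self.channels[name]
        return x, fs

    @property
    def duration(self) -> float:
        name = next(iter(self.channels))
        x, fs, _ = self.channels[name]
        return len(x) / fs


@dataclass
class GroundTruth:
    hypnogram: Hypnogram
    spindle_intervals: list[tuple[float, float]]
    movement_intervals: list[tuple[float, float]]
    stim_pulses: PulseTrain | None = None
    latent_response_latency: float | None = None
    mu_intervals: list[tuple[float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# hypnogram

def generate_hypnogram(config: SynthConfig, seed: int | None = None) -> Hypnogram:
    """Semi-Markov wake/NREM/REM chain on the 10 s epoch grid.

    Bout lengths are geometric in epochs with the configured means; the
    cycle is wake -> NREM -> (REM with ``rem_entry_prob`` else wake) ->
    wake, so REM is entered only from NREM.
    """
    config.validate()
    rng = _rng(config.seed if seed is None else seed, "hypnogram")
    n_epochs = int(config.total_duration // EPOCH_LEN)
    means = dict(zip(STATES, config.state_dwell_means))

    labels: list[str] = []
    state = WAKE
    while len(labels) < n_epochs:
        m = means[state]
        if math.isinf(m):
            dwell = n_epochs - len(labels)
        else:
            mean_epochs = max(m / EPOCH_LEN, 1.0)
            dwell = int(rng.geometric(1.0 / mean_epochs))
        labels.extend([state] * min(dwell, n_epochs - len(labels)))
        if state == WAKE:
            state = NREM
        elif state == NREM:
            state = REM if rng.random() < config.rem_entry_prob else WAKE
        else:
            state = WAKE
    return Hypnogram(np.array(labels[:n_epochs], dtype=object))


def hypnogram_stationary_fractions(config: SynthConfig) -> dict[str, float]:
    """Long-run state fractions of the chain, by renewal-reward enumeration.

    Per wake->NREM->(REM?) cycle the expected occupancies are the dwell
    means weighted by visit counts (wake 1, NREM 1, REM ``rem_entry_prob``).
    Used as the independent oracle for the generator's dwell statistics.
    """
    dw, dn, dr = config.state_dwell_means
    w = {WAKE: dw, NREM: dn, REM: config.rem_entry_prob * dr}
    total = sum(w.values())
    return {s: v / total for s, v in w.items()}


# ---------------------------------------------------------------------------
# EEG

def pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    return x / x.std()


def _bandlimited_noise(n: int, fs: float, lo: float, hi: float,
                       rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _place_bursts(runs, rate_per_min, dur_range, rng):
    """Poisson-place non-overlapping (start, end) intervals inside runs."""
    intervals: list[tuple[float, float]] = []
    for r_start, r_end in runs:
        run_dur = r_end - r_start
        lam = rate_per_min * run_dur / 60.0
        n_ev = rng.poisson(lam)
        for _ in range(n_ev):
            dur = rng.uniform(*dur_range)
            if dur >= run_dur:
                continue
            for _attempt in range(20):
                start = rng.uniform(r_start, r_end - dur)
                if all(start + dur <= s or start >= e
                       for s, e in intervals):
                    intervals.append((start, start + dur))
                    break
    return sorted(intervals)


def _add_oscillatory_bursts(trace, fs, intervals, freq_range, amp, rng):
    t_check = []
    for start, end in intervals:
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        n = i1 - i0
        if n < 2:
            continue
        f = rng.uniform(*freq_range)
        phase = rng.uniform(0, 2 * np.pi)
        tt = np.arange(n) / fs
        envelope = np.hanning(n)
        trace[i0:i1] += amp * envelope * np.sin(2 * np.pi * f * tt + phase)
        t_check.append(f)
    return t_check


def _entrained_intervals(stim: "PulseTrain", hyp: Hypnogram,
                         config: SynthConfig, rng) -> list[tuple[float, float]]:
    """One spindle in the light-off phase of each NREM pulse cycle.

    The burst starts just after light-off (small jittered latency) and
    is clipped so it ends before the next pulse; cycles too fast to fit
    a minimal burst are skipped (fast trains clip spindles).
    """
    onsets = stim.onsets
    intervals = []
    for i, onset in enumerate(onsets):
        if hyp.state_at(onset) != NREM:
            continue
        next_on = onsets[i + 1] if i + 1 < onsets.size else hyp.duration
        start = onset + stim.width + rng.uniform(0.0, 0.1)
        max_dur = next_on - start - 0.02
        dur = min(rng.uniform(*config.spindle_dur_range), max_dur)
        if dur < 0.3:
            continue
        intervals.append((start, start + dur))
    return intervals


def generate_eeg(hyp: Hypnogram, config: SynthConfig,
                 seed: int | None = None,
                 entrain_stim: "PulseTrain | None" = None):
    """EEG trace: 1/f background + NREM delta + Poisson spindle bursts.

    Returns ``(trace, spindle_intervals, mu_intervals)``; a second call
    with the same seed is bit-identical.  Spindles are Hann-enveloped
    sinusoids with a per-event frequency drawn uniformly from
    ``spindle_freq_range`` and envelope peak ``spindle_amp_snr`` times
    the background RMS, placed only inside NREM runs (mu events, if
    enabled, inside REM).  When ``entrain_stim`` is given, spindles are
    instead locked to the light-off phase of each NREM pulse cycle.
    """
    config.validate()
    rng = _rng(config.seed if seed is None else seed, "eeg")
    fs = config.eeg_rate
    n = int(round(hyp.duration * fs))

    trace = EEG_RMS * pink_noise(n, config.noise_exponent, rng)

    # NREM slow-wave activity: band-limited 1-4 Hz noise gated by state
    nrem_mask = hyp.sample_mask(NREM, fs, n)
    if nrem_mask.any():
        delta = _bandlimited_noise(n, fs, 1.0, 4.0, rng)
        trace[nrem_mask] += config.delta_gain * EEG_RMS * delta[nrem_mask]

    # REM theta rhythm: band-limited 5-9 Hz noise gated by state
    rem_mask = hyp.sample_mask(REM, fs, n)
    if rem_mask.any():
        theta = _bandlimited_noise(n, fs, 5.0, 9.0, rng)
        trace[rem_mask] += config.theta_gain_rem * EEG_RMS * theta[rem_mask]

    spindle_amp = config.spindle_amp_snr * EEG_RMS
    if entrain_stim is not None:
        spindles = _entrained_intervals(entrain_stim, hyp, config, rng)
    else:
        spindles = _place_bursts(hyp.runs(NREM), config.spindle_rate_nrem,
                                 config.spindle_dur_range, rng)
    _add_oscillatory_bursts(trace, fs, spindles,
                            config.spindle_freq_range, spindle_amp, rng)

    mu_intervals = []
    if config.mu_rate_rem > 0:
        mu_intervals = _place_bursts(hyp.runs(REM), config.mu_rate_rem,
                                     config.spindle_dur_range, rng)
        _add_oscillatory_bursts(trace, fs, mu_intervals,
                                config.mu_freq_range, spindle_amp, rng)

    return trace, spindles, mu_intervals


def generate_emg(hyp: Hypnogram, config: SynthConfig,
                 seed: int | None = None):
    """EMG: state-dependent muscle tone plus Hann-enveloped wake bursts.

    Baseline tone is scaled per state (highest in wake, lowest in REM,
    emulating atonia); movement bursts occur only in wake.
    """
    config.validate()
    rng = _rng(config.seed if seed is None else seed, "emg")
    fs = config.emg_rate
    n = int(round(hyp.duration * fs))

    trace = EMG_RMS * rng.standard_normal(n)
    tone = dict(zip(STATES, config.emg_tone))
    for state, gain in tone.items():
        if gain != 1.0:
            mask = hyp.sample_mask(state, fs, n)
            trace[mask] *= gain
    bursts = _place_bursts(hyp.runs(WAKE), config.emg_burst_rate_wake,
                           (0.3, 1.5), rng)
    for start, end in bursts:
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        m = i1 - i0
        if m < 2:
            continue
        envelope = np.hanning(m)
        trace[i0:i1] += (config.emg_burst_gain * EMG_RMS * envelope
                         * rng.standard_normal(m))
    return trace, bursts


# ---------------------------------------------------------------------------
# photometry

def _ca_kernel(fs: float, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials calcium impulse response, peak 1."""
    t = np.arange(0, 5 * decay, 1.0 / fs)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    return k / k.max()


def _rebound_bump(fs: float, latency: float, decay: float = 0.3) -> np.ndarray:
    """Stimulus-locked response with its maximum exactly at ``latency``.

    Half-cosine rise to the peak followed by an exponential tail; the
    analytic peak position makes latency-recovery tests exact.
    """
    t = np.arange(0, latency + 5 * decay, 1.0 / fs)
    bump = np.where(
        t < latency,
        0.5 * (1 - np.cos(np.pi * t / max(latency, 1.0 / fs))),
        np.exp(-(t - latency) / decay),
    )
    return bump


def _suppression_bump(fs: float, dur: float = 0.6) -> np.ndarray:
    t = np.arange(0, dur, 1.0 / fs)
    return 0.5 * (1 - np.cos(2 * np.pi * t / dur))


def generate_photometry(hyp: Hypnogram, stim: PulseTrain | None,
                        config: SynthConfig, seed: int | None = None,
                        movement_intervals=None, spindle_intervals=None):
    """Two-channel photometry: calcium signal + artifact-only reference.

    The signal carries a latent Poisson transient train convolved with
    the calcium kernel, plus state-dependent stimulus-locked responses
    (NREM: rebound peaking ``nrem_rebound_latency`` after pulse onset;
    wake/REM: suppression dip), plus a slow motion artifact shared -- up
    to an affine map -- with the reference channel.  When movement or
    spindle ground-truth intervals are supplied, calcium transients are
    additionally locked to them (population activity rises with
    movement and around spindles), making the epoch labels decodable
    from calcium features alone.
    """
    config.validate()
    rng = _rng(config.seed if seed is None else seed, "photometry")
    fs = config.photo_rate
    n = int(round(hyp.duration * fs))

    if stim is not None and stim.onsets.size:
        if stim.onsets.min() < 0 or stim.onsets.max() + stim.width > hyp.duration:
            raise ValueError("stim pulses fall outside the recording")

    # latent calcium transients
    rate_per_sample = config.ca_event_rate / 60.0 / fs
    events = rng.random(n) < rate_per_sample
    amps = np.zeros(n)
    amps[events] = rng.exponential(1.0, events.sum())

    # behaviour-locked transients
    for intervals, gain in ((movement_intervals, config.ca_movement_gain),
                            (spindle_intervals, config.ca_spindle_gain)):
        if not intervals or gain == 0.0:
            continue
        for start, end in intervals:
            i0 = min(int(round(start * fs)), n - 1)
            amps[i0] += gain * (1.0 + 0.3 * rng.standard_normal())
            # sustained bouts keep firing through their duration
            extra = rng.random(max(int((end - start) * fs), 1)) \
                < 5.0 * rate_per_sample
            j0 = i0 + np.flatnonzero(extra)
            j0 = j0[j0 < n]
            amps[j0] += gain * rng.exponential(0.5, j0.size)
    kernel = _ca_kernel(fs, *config.ca_kernel)
    calcium = 2.0 * np.convolve(amps, kernel)[:n]

    # stimulus-locked responses
    if stim is not None:
        rebound = config.rebound_amp * _rebound_bump(
            fs, config.nrem_rebound_latency)
        dip = (config.rebound_amp * config.wake_rem_suppression_gain
               * _suppression_bump(fs))
        for onset in stim.onsets:
            i0 = int(round(onset * fs))
            state = hyp.state_at(onset)
            shape = rebound if state == NREM else -dip
            i1 = min(n, i0 + shape.size)
            calcium[i0:i1] += shape[: i1 - i0]

    # shared slow motion artifact
    artifact = 1.5 * _bandlimited_noise(n, fs, 0.0, 0.1, rng)

    signal = (PHOTO_F0_SIGNAL + calcium + artifact
              + 0.3 * rng.standard_normal(n))
    reference = (PHOTO_F0_REFERENCE + 0.8 * artifact
                 + 0.2 * rng.standard_normal(n))
    return signal, reference


# ---------------------------------------------------------------------------
# session bundle

def generate_session(config: SynthConfig, seed: int | None = None,
                     stim: PulseTrain | None = None):
    """All generators on one time base; returns (Recording, GroundTruth)."""
    config.validate()
    seed = config.seed if seed is None else seed
    hyp = generate_hypnogram(config, seed)
    eeg, spindles, mu = generate_eeg(hyp, config, seed)
    emg, movement = generate_emg(hyp, config, seed)
    photo_sig, photo_ref = generate_photometry(
        hyp, stim, config, seed,
        movement_intervals=movement, spindle_intervals=spindles)

    # left-hemisphere EEG / second EMG: same generative statistics,
    # independent noise stream (sub-seeded off the session seed)
    alt = SynthConfig(**{**config.as_dict(), "seed": seed})
    eeg_l, _, _ = generate_eeg(hyp, alt, seed + 2**20)
    emg_2, _ = generate_emg(hyp, alt, seed + 2**20)

    rec = Recording(channels={
        "eeg_R": (eeg, config.eeg_rate, "V"),
        "eeg_L": (eeg_l, config.eeg_rate, "V"),
        "emg_1": (emg, config.emg_rate, "V"),
        "emg_2": (emg_2, config.emg_rate, "V"),
        "photo_signal": (photo_sig, config.photo_rate, "au"),
        "photo_reference": (photo_ref, config.photo_rate, "au"),
    })
    gt = GroundTruth(
        hypnogram=hyp,
        spindle_intervals=spindles,
        movement_intervals=movement,
        stim_pulses=stim,
        latent_response_latency=config.nrem_rebound_latency,
        mu_intervals=mu,
    )
    return rec, gt
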