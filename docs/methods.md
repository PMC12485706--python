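# Methods

This note documents the models, parameters, and numerical choices
behind `spindlelab`, and what the synthetic-data tests do and do not
establish about real recordings.

## Synthetic sessions

The generator emulates the statistical structure the downstream
analyses rely on, not thalamocortical biophysics.

**Hypnogram.** A semi-Markov chain over {wake, NREM, REM} on a 10 s
epoch grid. Bout lengths are geometric in epochs with configurable
means (defaults 300/180/60 s — typical mouse bout scales); the cycle
is wake → NREM → (REM with probability 0.35, else wake) → wake, so REM
is entered only from NREM. The long-run state fractions have a closed
form (dwell means weighted by per-cycle visit counts), used as the
oracle for the generator's dwell statistics.

**EEG** (500 Hz, volts). A 1/f background (spectral shaping of white
noise, exponent 1, RMS 100 µV — epidural screw scale), plus
band-limited 1–4 Hz noise in NREM (amplitude 0.6 × background RMS) and
5–9 Hz noise in REM (0.6×). Spindles are Hann-enveloped sinusoids:
Poisson-placed within NREM runs at 4/min, frequency uniform in
9–16 Hz, duration uniform in 0.6–1.5 s, envelope peak 4 × background
RMS (the SNR at which detector recovery is validated). The NREM delta
gain is deliberately modest: adding 1–4 Hz power dilutes the
*relative* sigma fraction, and above ≈ 1.4× the NREM sigma fraction
would fall below wake despite the spindles, inverting the contrast the
analyses assume. Real NREM slow-wave activity is stronger than this —
a stated limitation, traded for a generator whose NREM/wake sigma
contrast behaves like scored sleep data.

**EMG** (500 Hz). Gaussian baseline with state-dependent tone (wake
1.5×, NREM 1×, REM 0.4× — atonia), plus Hann-enveloped movement bursts
in wake (4/min, gain 10× baseline RMS).

**Photometry** (modelled at 1 kHz; signal + reference channel). The
signal is a latent Poisson transient train (10/min, exponential
amplitudes) convolved with a difference-of-exponentials calcium kernel
(rise 0.1 s, decay 0.8 s, GCaMP8-scale), plus transients locked to
movement bouts and spindle events (gains 3.0 each) so that epoch
labels are decodable from calcium features alone, plus a slow shared
motion artifact that enters the reference channel through an affine
map, plus white noise. Stimulus pulses add state-dependent responses:
in NREM a rebound whose maximum sits exactly at the configured latency
(half-cosine rise, exponential tail — the analytic peak makes latency
recovery testable to the sample); in wake/REM a suppression dip.
Responses are additive and linear with no refractoriness; this
suffices for latency- and entrainment-recovery tests but does not
model response adaptation or T-type channel dynamics.

An entrainment mode locks one spindle to the light-off phase of each
NREM pulse cycle (onset jittered 0–0.1 s after light-off, duration
clipped to the cycle), emulating rebound-driven spindle induction;
cycles too short for a ≥ 0.3 s burst are skipped, which reproduces the
clipping seen at fast stimulation rates.

Determinism: one integer seed; sub-streams are split per component
(hypnogram/EEG/EMG/photometry) so changing one component's parameters
leaves the others' noise untouched. Identical (config, seed) gives
bit-identical traces.

## Spindle detection

Zero-phase 4th-order Butterworth band-passes (applied
forward-backward) for the 1–30 Hz broadband and the event band
(9–16 Hz; 8–12 Hz for mu events). The three decision series use the
stated window/step sizes; the relative-power STFT runs on the raw
trace so that a flat input spectrum yields the bandwidth ratio
(7/29 ≈ 0.24) exactly — running it on the pre-filtered trace would
inflate the ratio through band-edge attenuation. Series are
step-interpolated onto the sample grid (frame centers, previous-value
hold): the windows provide no sub-frame information and step
interpolation fabricates none. Threshold comparisons are strict
(`>`); the RMS threshold (mean + 1.5 SD) is computed over whatever
segment is passed in, so callers restrict to NREM to reproduce
sleep-scored practice. Detection is invariant to positive rescaling
of the input (all three criteria are either ratios or
signal-calibrated), which the suite asserts.

Feature conventions: absolute sigma power is the median log10
instantaneous power of the Hilbert envelope; frequency is the median
instantaneous frequency from the analytic phase; oscillations are
`find_peaks` counts at ≥ 60 ms spacing; symmetry is the relative
position of the most prominent peak (prominence, not height — the
natural reading of "most prominent"). Filter family/order and the
prominence rule are fixed here because the algorithm description
names only bands and windows.

One behavioural caveat documented rather than hidden: with 2 s
relative-power frames and 0.3 s correlation/RMS frames, a strong but
very brief (≲ 0.3 s) sigma transient can smear into a decision run
that passes the 0.5 s minimum. The merge-gap and duration rules are
therefore verified exactly at the segmentation stage
(`merge_and_filter` on constructed candidate runs), and detector
recovery is validated event-wise (F1 against ground truth at ≥ 50 %
overlap) rather than by the literal "short burst in, nothing out"
construction.

## Photometry and EMG analyses

ΔF/F uses f0 = a·reference + b fitted by ordinary least squares over
the whole session — the standard isosbestic correction; it is
invariant to affine rescaling of the reference and removes shared
artifacts up to fit error. The EMG movement threshold is
median + 7 × MAD of the 0.5 s-smoothed rectified envelope; MAD is used
raw (no 1.4826 consistency factor) with a module flag to enable the
factor; an epoch is "movement" if any envelope sample exceeds the
threshold (any-sample rather than epoch-mean exceedance — the stricter
and more sensitive reading). The 0.5 s smoothing constant is a choice;
nothing in the analyses is sensitive to it at the tested scales.

Event-triggered averages search 0–1 s after pulse onset (pulse width
0.2 s, 1 Hz trains); latency-to-peak is the argmax of the mean
response. Cross-correlograms z-score the series and the pulse
indicator train and normalize by length; peaks are counted over a
half-open 10 s lag span (padded during peak finding so span-edge peaks
are neither dropped nor double-counted) with ≥ 0.5 s separation.

The slice two-photon pipeline fits the photobleach exponential on the
pre-stimulus portion only (an evoked transient would bias a whole-trace
fit), divides, applies a 5-point running mean (edge-padded), and
normalizes to the pre-stimulus mean.

## Decoding

Calcium traces are zero-phase low-passed at 1 Hz and brought to 50 Hz;
each 10 s epoch yields std, MAD, IQR, RMS of successive differences,
and 0.2–0.5 Hz power over 0.05–3 Hz power (per-epoch periodogram).
The classifier is a standardized elastic-net logistic regression
(l1_ratio 0.5, C = 1.0, saga, seeded) under leave-one-mouse-out
cross-validation; the scaler is fit on training folds only (asserted
by an injected test-set outlier leaving the fold model unchanged).
ROC curves are vertically averaged on a 101-point FPR grid; the mean
AUC is the mean of per-fold AUCs. The chance baseline permutes labels
within each mouse (preserving per-mouse class counts). Folds with a
single-class held-out set are skipped with a warning. Penalty
strength/mixing are fixed defaults — the decoding claims validated
here are directional (real vs shuffled), not sensitive to tuning.

## Closed-loop simulation

The original real-time sleep stager was a trained neural network;
here staging is pluggable. The provided rule-based spectral stager
uses the smoothed rectified EMG (wake when the epoch envelope mean
exceeds the session mean — wake muscle tone sits above, sleep below)
and the delta(1–4)/theta(5–9) power ratio (NREM above 1, REM below).
It reaches ≳ 60 % per-state accuracy on synthetic sessions; the
ground-truth stager isolates protocol logic from staging error and is
used wherever staging accuracy is not itself under test. State is
evaluated at 10 s epoch boundaries from the buffer just ended;
stimulation starts one sample after detection (hardware latency is
not modelled), runs for a 10 s block — floor(block_len × pulse_rate)
pulses, or solid light on inhibition channels — and consecutive
trigger-state epochs re-trigger back-to-back. Blocks never precede
their trigger and never overlap within a channel.

## Behavior

Outcomes follow the response window (licks in 2.0–3.0 s from trial
start); early/late licks are logged but unscored. Rates of exactly 0
or 1 are nudged by 1/(2N) of the relevant trial count before the
normal-quantile transform (flagged in the output) — the standard
correction; the resulting d′ floor/ceiling depends on trial counts,
which the outputs carry. Disengagement truncates at the first run of
10 consecutive unanswered go trials with no licks on the no-go trials
strictly between the run's first and tenth go. Training-half deltas
split four sessions from the end, so the "second half" is always the
final four sessions.

## Exact statistics

Mann-Whitney and Wilcoxon null distributions are computed by
dynamic-programming enumeration — arithmetically identical to walking
all C(n1+n2, n1) rank subsets or 2^n sign patterns — and fall back to
the midrank normal approximation only above 10^7 outcomes (Mann-
Whitney also under cross-group ties, where the rank null is no longer
distribution-free). The signed-rank test stays exact under tied
|differences| by enumerating sign flips conditionally on the observed
|differences| (midranks, doubled to stay integral). Zero differences
are dropped before ranking, so the one-sided floor with n informative
pairs is exactly 1/2^n. One-sided p-values report the tail in the
direction of the observed effect (`greater`/`less` pin a direction
explicitly); two-sided doubles the smaller tail. Dunn's z tests carry
the usual tie correction and are reported unadjusted, with an optional
step-down (Holm) flag — no multiplicity correction is applied by
default because the analyses report per-characteristic tests
individually.

## Problem sizes and what passing shows

Tests and the acceptance script run on deliberately small problems:
sessions of 2–30 minutes, cohorts of 4–8 synthetic mice, 20-seed
Monte-Carlo loops, 100 stimulation blocks for the entrainment count.
These sizes give stable statistics for every claim tested (Poisson
counts within Monte-Carlo error, AUC null within ±0.05, latencies
within ±0.04 s) while keeping the full suite around a minute.

Passing on synthetic data establishes that the *pipelines* are
correct: the detector recovers constructed events, the decoder finds
only information that is present, latencies and entrainment
periodicity are recovered, and the exact tests match enumeration.
It does not establish detector performance on real EEG (no artifacts,
no non-stationary background, no inter-animal variability in the
generator), nor that real calcium signals are decodable — only that
the analysis would find it if they were.
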