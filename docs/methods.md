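# Methods

This note documents the models, defaults and numerical choices behind
`murisleep`, and what the synthetic-data tests do and do not establish
about real recordings.

## Signal model and conditioning

Recordings are two channels in microvolts: cortical EEG and nuchal EMG,
sampled at a common rate (default 300 Hz; 60 Hz is the floor needed to
resolve the 0.5–30 Hz EEG analysis range and the EMG envelope).
Conditioning band-passes the EEG at 0.1–30 Hz and the EMG at 10–100 Hz
with 4th-order Butterworth filters applied forward-backward
(zero-phase), so filtering never shifts epoch boundaries. When the
sampling rate cannot support the 100-Hz EMG corner it is capped at
0.45·fs with a logged warning.

## Per-epoch features

The scoring epoch is 10 s, short enough to resolve the start and end of
REM bouts that last about a minute. Band power is the integral of the
one-sided Hann-windowed periodogram over the closed band — delta
0.5–4.0 Hz, theta 6.0–9.0 Hz, sigma 10.0–14.0 Hz — using density
scaling, so the total over all bins equals the epoch's mean square
(Parseval) and a unit-amplitude in-band tone reads 0.5 µV². A single
window per epoch (0.1-Hz resolution) was chosen over Welch averaging as
the minimal estimator consistent with per-epoch Fourier analysis; the
window is configurable. EMG amplitude is the epoch mean of a 1-s moving
average of the rectified signal; 1 s is the conventional smoothing for
nuchal tone and is likewise configurable. Powers are not
log-transformed at this stage; skew is handled where it matters, in
calibration.

## Staging

Two rules, applied in fixed precedence:

1. **Sleep/wake line.** Epochs are points (x, y) = (log₁₀ EMG
   amplitude, log₁₀ σ·θ power). A line y = m·x + b splits the plane;
   the high-EMG side is wake. The wake rule is decided first and never
   consults delta/theta.
2. **δ/θ ratio.** Sleep-side epochs are NREM when δ/θ ≥ r, REM below.

The original method sets m, b and r per 24-h record without a stated
procedure; that gap is isolated in `fit_thresholds`. The automatic
calibration fits 2-component k-means to the (x, y) cloud (log axes,
because band powers are strongly right-skewed) and uses the
perpendicular bisector of the centres as the line — equivalently,
nearest-centre classification — then places r at the antimode (deepest
kernel-density minimum between the two tallest modes) of log(δ/θ) over
sleep-side epochs. Gaussian KDE uses Scott's bandwidth on a 512-point
grid. Any threshold can be pinned manually, and degenerate inputs
(near-zero variance, inseparable clusters, unimodal δ/θ) raise a
calibration error rather than guessing.

Tie-breaks close boundaries toward the majority state: a point exactly
on the line scores sleep, a ratio exactly at r scores NREM. Labels are
not smoothed after classification — the bout rules below are themselves
the temporal smoother. Calibration is gain-equivariant: rescaling the
EEG (or EMG) and refitting reproduces the same labels.

## Bout, arousal and latency rules

All rules are run-length conditions on the hypnogram, implemented as a
single left-to-right scan over run-length-encoded labels:

* NREM bout: opens on ≥3 consecutive NREM epochs; closes immediately
  before the first run of ≥3 wake epochs or ≥2 REM epochs.
* REM bout: opens on ≥2 consecutive REM epochs; closes immediately
  before the first stretch of ≥3 consecutive non-REM epochs. Pooling
  wake and NREM here mirrors the wake-bout rule's "any combination"
  reading; a per-state reading was rejected as asymmetric.
* Wake bout: opens on ≥3 consecutive wake epochs; closes on ≥3
  consecutive sleep epochs of any NREM/REM mix.
* Arousal: the first epoch of any maximal wake run immediately preceded
  by ≥3 consecutive sleep epochs ("periods" read as epochs, pooled
  across NREM/REM). One arousal per wake run; arousals and wake-bout
  onsets are deliberately not mutually exclusive.
* Time to resume sleep: from the onset of a ≥3-epoch wake run to the
  first epoch of the next ≥3-epoch sleep stretch; unresolved onsets are
  excluded from the mean.

Consequences worth noting. While a bout is open no other bout can
open, so bouts never overlap; intrusions too short to terminate (one or
two wake epochs inside an NREM bout, say) fall inside the bout's span.
Bout duration is therefore span duration, and `n_state_epochs`
separately counts the bout's own-state epochs, so both tallies are
available. Runs truncated by the record boundary qualify if their
observed length meets the minimum, and a bout whose terminator never
arrives closes at the last epoch of its own state — this avoids
discarding up to three epochs at each boundary. The whole rule set is
verified exhaustively against an independently written brute-force
evaluator on every hypnogram up to length 12 (3¹² sequences).

## Summaries and statistics

State percentages are epoch-count fractions per window (24 h, 12-h
light, 12-h dark; epochs take the phase of their start, so a phase
transition affects at most two epochs per day). Because the 24-h count
is the sum of the two phase counts, the 24-h percentage of each state
is exactly the epoch-weighted mean of the phase percentages — the
arithmetic mean when the phases are equal length. Bouts and events
belong to the phase of their onset. Arousal frequency is arousals per
hour of sleep in the window; mean resume latency is the unweighted mean
over events. Metrics without supporting events are NaN and excluded
from group statistics with a warning.

Group comparison is the unpaired two-tailed Student's t test with
pooled variance and df = n₁ + n₂ − 2, reported as mean ± SEM
(SD/√n). ("Two-way" in some descriptions of this design is read as
"two-tailed".) Identical groups return t = 0, p = 1. No
multiple-testing correction is applied by default, matching common
practice in these studies; the comparison table exposes raw p values so
a correction can be layered on. The implementation is checked against
scipy's reference t test to 1e-10 and its type-I error is calibrated by
simulation.

## Synthetic-data generator

**Architecture layer.** States follow a semi-Markov chain at epoch
resolution. Bout lengths are geometric (memoryless within state) with
means: NREM 4.5 min, REM 1.1 min, WAKE 3.8 min in the light, ×1.5 in
the dark. Transitions: WAKE→NREM always; NREM→REM with probability
0.5, else WAKE; REM→WAKE with probability 0.5, else NREM; direct
WAKE→REM never occurs, the standard rodent ordering. The NREM and REM
means sit at the scale reported for healthy mice; the wake mean and the
dark multiplier were chosen once so that the stationary fractions (57%
NREM / 7% REM light, 48% / 6% dark, computed analytically from visit
rates × mean durations and verified by Monte Carlo) reproduce a
realistic murine light/dark profile. The recording starts at lights-on
in WAKE.

**Signal layer.** EEG is a sum of three band-limited unit-variance
Gaussian tracks (white noise filtered by a zero-phase spectral mask per
band, so the expected in-band power is exact) scaled per state by the
square root of the band-power target, plus a flat broadband floor
(0.05 µV²/Hz). Defaults (δ, θ, σ in µV²): WAKE (30, 30, 15), NREM
(200, 50, 40), REM (30, 90, 15) — NREM delta-dominant, REM
theta-dominant, WAKE low-amplitude mixed. EMG is 10–100 Hz Gaussian
noise scaled so its rectified mean hits the per-state target (25 / 8 /
3 µV for WAKE / NREM / REM; a Gaussian's rectified mean is σ√(2/π)).
State changes are crossfaded by smoothing the gain over 1 s, keeping
the signals continuous across epoch boundaries at the cost of ~5%
feature mixing in transition epochs. Absolute microvolt scales are
arbitrary (none are published for this preparation) and configurable;
staging is scale-free once calibrated. All randomness derives from the
config seed via named substreams, and cohorts derive per-animal seeds
from one master seed.

A `separated_config` preset (wider target separation, lower floor)
realises the near-zero-overlap regime in which staging accuracy should
approach 100%.

**What the generator does not emulate.** Spindles, phasic REM events,
movement artifacts, electrode drift, 50/60-Hz interference, and any
within-state nonstationarity; bout lengths are geometric, so their
dispersion is tied to the mean (a negative-binomial extension is left
open). In particular, the geometric wake-bout law cannot reproduce both
realistic bout counts and the high arousal rates (~20/h of sleep) seen
in mice, which arise from a separate population of very brief
awakenings; the default conditions yield ~8 arousals/h. Passing the
recovery tests therefore shows that the pipeline inverts its own
generative assumptions at realistic SNR — it does not certify staging
accuracy on real, artifact-laden recordings, where manual threshold
review remains advisable.

## Problem sizes and tolerances

Staging/metric recovery runs ten 24-h recordings at 300 Hz (86 400
epochs pooled) plus one separated-regime recording; recovery is asserted
at ≥90% accuracy, ≥80% REM recall (≥99% separated) and ≤15% relative
metric error. The t-test calibration uses 1000 null cohorts of 6 vs 6
truth hypnograms and checks the rejection rate against the 95% binomial
interval around 0.05. Bout-rule agreement is exhaustive at length 12 in
the test suite and length 10 in the acceptance script. Spectral checks
allow 1e-6 relative error on tones and 5% Monte-Carlo tolerance on
flat-spectrum band ratios (closed-interval bin counts 36:31:41 at
0.1-Hz resolution). The 16-bit EDF writer is accurate to one part in
32 767 of the channel's peak amplitude.
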