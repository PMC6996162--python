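# Methods

This note documents the models, estimators and numerical choices behind
`abrkit`, and what the synthetic-data validation does and does not show
about real recordings.

## Data model and units

An archive holds averaged evoked-potential traces (µV) over a 20 ms
window, one per (mouse, stimulus), at a default 9.75 kHz sampling rate
(195 samples). Stimulus levels are dB SPL; sensation level (dB SL, level
above an individual's threshold) is always derived from an estimated
threshold and never stored. Serialisation uses `repr` for floats, so
archives round-trip exactly and repeated writes are byte-identical.

## Synthetic cochlea

Each trace is a sum of five stereotyped biphasic wave components plus
Gaussian noise on the average (`noise_floor_sd_uV / sqrt(n_sweeps)`; the
default 1.6 µV per sweep over 256 sweeps gives a 0.1 µV residual floor,
typical of averaged mouse ABRs). Only wave 1 carries the manipulated
physiology; waves 2–5 are fixed fractions (0.8, 0.6, 0.45, 0.35) of the
wave-1 amplitude at 1.0 ms spacing. Each component is a positive Gaussian
lobe (σ = 0.10 ms) followed 0.5 ms later by an equal negative lobe, and
lobe centres are snapped to the sample grid so that the sampled
peak-to-peak amplitude equals the model amplitude to well under 1 %; the
residual comes from overlap with the neighbouring wave. At 0.8 ms spacing
the wave-2 lobe would contaminate the wave-1 trough by ≈5 %, which is why
the spacing is 1.0 ms.

For sensation level `L_SL = level − true threshold` (per stimulus family):

* wave-1 amplitude `A = amp_max / (1 + exp(−(L_SL − level50)/slope))` for
  `L_SL > 0`, else exactly 0 (defaults: amp_max 6 µV, level50 15 dB SL,
  slope 5 dB);
* P1 latency `latency_min + 1.5·exp(−L_SL/20)` ms (+ half the onset ramp
  for tones);
* presentation rate multiplies the response by
  `max(0, 1 − rate_coeff·log2(rate/10.65))` and an onset ramp ρ by
  `max(0, 1 − ramp_coeff·(ρ − 0.25))`;
* a forward masker multiplies by
  `1 − S0·depth·exp(−gap/τ)` where the zero-gap suppression `S0` is
  logistic in the masker's effective level — `masker level − T(f)` for
  tonal maskers, with `T(f)` a V-shaped filter (tip 30 dB SPL at the probe
  frequency, 25 dB/octave below, 50 dB/octave above), and
  `masker level − probe level + 10` for broadband maskers (the standard
  recovery paradigm fixes the masker 10 dB below the click, so `S0 = 0.5`
  there). Masking, rate and ramp factors scale the whole five-wave
  response: reduced auditory-nerve drive propagates downstream.

Wildtype baseline thresholds are 20 dB SPL for clicks and
45/30/15/15/20/35/50/60 dB SPL at 3–42 kHz (best sensitivity 12–24 kHz).
Between-mouse variation: thresholds normal with 5 dB SD (clipped to the
tested 0–95 dB range, chosen so the 95 % reference band spans ≈15–20 dB),
amp_max SD 0.8 µV, recovery τ SD 2 ms around 20 ms, tuning tip SD 3 dB.
Genotype effects add threshold shifts and scale amplitude and τ; the
identity effect reproduces the wildtype law exactly.

Noise exposure applies a per-family shift
`PTS(f) + TTS(f)·exp(−t/τ_rec)` (defaults: TTS 5/25/40 dB and PTS 0/5/10 dB
below/inside/above the 8–16 kHz band, τ_rec 3 days) — a single exponential
per frequency; mutant effects add permanent shift and scale the recovery
rate. qPCR simulation draws triplicate Cts, Normal with SD 0.15 cycles,
around `μ_ref` (reference gene) and `μ_ref + offset − log2(relative
expression)` (target).

What the simulator does **not** emulate: single-sweep statistics and
artefact rejection, filter ringing and electrode drift, wave-component
latency jitter between waves, level-dependent waveform morphology beyond
latency/amplitude, and masker-evoked responses inside the analysis window.
Passing parameter-recovery tests therefore shows the estimators are
correct for this signal family at realistic SNR, not that they reproduce
human scoring of noisy clinical traces.

## Wave-1 extraction and thresholds

P1 is the maximum sample in a search window (0.8–2.8 ms after onset for
clicks, shifted by half the ramp for tones), N1 the minimum within 1.5 ms
after P1; a flat trace yields amplitude 0 at the window start. The
extractor equals an exhaustive scan oracle by construction.

Threshold is the lowest level of the terminal run of levels whose response
passes a detection criterion ("sustained response": the level itself and
every higher level respond) — an automated stand-in for visual judgement,
deliberately not a reimplementation of it. Two criteria are provided:

* **template correlation** (default): the mean of the three highest-level
  traces over 0.8–6.5 ms serves as template (leave-one-out for its own
  members, otherwise shared noise fakes detections); a level responds when
  its maximum Pearson correlation with the template over 0–1.6 ms latency
  lags exceeds 0.5 and the wave-1 amplitude clears a 0.1 µV floor. The
  0.5 criterion sits well above the null maximum correlation (≈0.35 for
  56-sample segments over 17 lags).
* **amplitude criterion**: wave-1 amplitude above
  `max(4σ̂, 0.1 µV)`, σ̂ the SD of the pre-response window (0–0.7 ms)
  pooled over the three lowest levels.

Template correlation is the default because a peak-to-peak statistic on
pure noise already averages ≈3.3σ, so the 4σ rule admits runs of false
positives that drag estimates tens of dB below threshold, while raising
the multiple inflates the median error beyond the 5 dB grid; the matched
template gives median |error| ≈ 4 dB with no underestimates > 5 dB at the
default noise floor. Censored estimates are recorded as "> 95 dB SPL",
excluded from dB-SL-dependent paradigms, and imputed one grid step above
the ceiling (100 dB) for rank-based group comparison — censored thresholds
rank above all finite ones, which is the only property rank statistics
use.

## Tuning curves

Masked thresholds use the 50 % amplitude-reduction criterion. (The
descriptive "3 dB" label sometimes attached to a 50 % reduction is
internally inconsistent — 50 % amplitude is −6 dB in the 20·log10
convention — so the implemented criterion is the fraction, configurable.)
Normalised amplitudes are smoothed by non-increasing isotonic regression
before the first downward crossing is linearly interpolated between the
10 dB masker grid points; smoothing-then-crossing is more stable than the
raw first crossing on noisy points. Censoring is exhaustive: finite,
"> 90 dB", "< 0 dB", or unusable (unmasked probe below the noise
criterion). Probe level is the mouse's own threshold + 20 dB.

## Recovery fits

The recovery curve normalises the probe-click wave-1 amplitude to the
reference click (150 ms after masker onset; values may exceed 1). Fits of
`y = y0 + a(1 − e^(−bx))` use unweighted trust-region least squares,
initialised at `y0 = first point`, `a = last − first`, `b = 1/20 ms⁻¹`,
with `b` bounded to (1e−4, 10) and tolerances 1e−12; a grid-search oracle
in the tests guards against local minima. Negative `y0` is allowed. Flat
input returns a degenerate fit (`a ≈ 0`, τ meaningless and flagged). The
primary analysis fits the group-mean curve; per-mouse fits remain
available for dispersion. Group-mean-then-fit carries a small (~5 %)
downward τ bias when mice differ in τ, since a mixture of exponentials
decays slightly faster than the exponential at the mean rate.

## Group statistics

Kruskal–Wallis H uses mid-ranks and the tie correction
`1 − Σ(t³−t)/(N³−N)`; all-tied input returns H = 0, p = 1. p-values come
from the χ² approximation with k−1 degrees of freedom — the convention of
the field's analysis software. At very small samples (N ≤ 12) this
approximation deviates from the exact permutation null by up to ≈0.07 for
continuous data and far more under heavy ties; the test suite checks H and
Q against brute-force rank oracles exactly and the p-value against a
sampled permutation null within that documented band. Dunn's Q versus
control uses the pooled-rank variance with tie correction; the two-sided
normal p is scaled by the comparison family and capped at 1 (which
produces the p = 1 entries typical of such tables). The per-test
significance level is `family α / m` (0.05/12 displayed as 0.00417;
0.05/4 as 0.0125; display rounds to 3 significant figures only).

Endpoint comparison supports two units of observation: `pooled` (default;
each mouse contributes its mean across conditions, one Q per group per
endpoint, mirroring one-row-per-endpoint summary tables) and
`per_condition`. Neither is claimed to be "the" historical computation —
the pooling rule behind single-Q summaries is not standardised.
Shapiro–Wilk normality checks are computed for logging only; the
nonparametric path is always taken for battery endpoints.

Reference ranges are 2.5–97.5 percentiles by inclusive linear
interpolation (reproducible bit-for-bit). Note the interpolated bounds lie
just inside the sample extremes, and at n = 37 the band's expected fresh-
draw coverage is ≈90 %, the usual small-n undercoverage of empirical
percentile bands.

## qPCR

ΔCt aggregates triplicates by arithmetic mean of Ct (the scale on which
the ΔΔCt method is defined); fold changes are exponentiated per mouse and
then averaged within genotype, with SD over per-mouse folds.
Amplification efficiency is fixed at 2.0; no standard-curve correction.

## Noise exposure

Shifts are `threshold(t) − threshold(pre)` per frequency; families with a
censored pre-exposure baseline are excluded, and censored post-exposure
thresholds become lower-bound records ("≥ ceiling − pre") that are
summarised separately and never averaged as exact. Trajectories are
reported per (group, timepoint, band position) with the exposure band
fixed at 8–16 kHz inclusive. The 6-week archive doubles as a standard full
battery; the noise comparison block runs the endpoint harness twice (vs
sham and vs exposed wildtype) with a Bonferroni family of 4.

## Problem sizes used in validation

The test suite and acceptance script validate at sizes chosen to give
stable Monte-Carlo estimates while staying quick on one CPU: 20-mouse
cohorts for threshold accuracy (180 level series), 6-mouse cohorts for
tuning and recovery (the screen's minimum group size), 200 replicates for
recovery-τ and qPCR recovery, 6 null and 10 power cohorts (12 test groups
of 6 vs a pooled-37 control, the screen's control size) for error control,
and 300–500 random instances for the oracle-equivalence checks.
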