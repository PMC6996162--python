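"""Wave-1 feature extraction, threshold estimation and growth functions.

Wave 1 is measured as the first positive peak (P1) and the following
trough (N1) within a configurable search window; peak-to-peak amplitude is
``sample(P1) - sample(N1)``.  The default search window is 0.8-2.8 ms after
stimulus onset for clicks, shifted by half the onset ramp for tones.

Threshold is defined operationally, standing in for visual inspection of
stacked level series: the lowest level whose wave-1 amplitude, and that of
every higher tested level, exceeds ``max(4 * noise-floor SD, 0.1 µV)``.
The noise-floor SD is estimated from the pre-response window (0-0.7 ms)
pooled over the three lowest levels.  A series in which no level sustains
the criterion yields a censored estimate ("> max tested level").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from abrkit.abr_io import AveragedWaveform, ContractError

__all__ = [
    "Wave1Measurement",
    "ThresholdEstimate",
    "GrowthFunction",
    "detect_wave1",
    "estimate_threshold",
    "growth_function",
    "sensation_level",
    "default_search_window",
]

#: default P1 search window for clicks, ms after stimulus onset
DEFAULT_WINDOW_MS = (0.8, 2.8)
#: N1 searched within this span after P1, ms
N1_SPAN_MS = 1.5
#: pre-response window used for the noise-floor estimate, ms
NOISE_WINDOW_MS = (0.0, 0.7)
#: absolute amplitude floor of the threshold criterion, µV
AMPLITUDE_FLOOR_UV = 0.1
#: noise-floor multiple of the threshold criterion
SIGMA_MULTIPLE = 4.0
#: a trace whose total excursion is below this is treated as flat, µV
FLAT_TOLERANCE_UV = 1e-12


@dataclass(frozen=True)
class Wave1Measurement:
    p1_latency_ms: float
    n1_latency_ms: float
    p1n1_amplitude_uV: float


@dataclass(frozen=True)
class ThresholdEstimate:
    """Estimated threshold for one stimulus family.

    ``censored`` means no tested level sustained the response criterion;
    the true threshold then exceeds ``ceiling_dB_SPL`` (the maximum tested
    level) and ``threshold_dB_SPL`` is None.
    """

    stimulus_family: str
    threshold_dB_SPL: float | None
    ceiling_dB_SPL: float
    method: str = "amplitude_criterion"

    @property
    def censored(self) -> bool:
        return self.threshold_dB_SPL is None

    def value_or(self, default: float) -> float:
        return default if self.censored else self.threshold_dB_SPL

    def __str__(self) -> str:
        if self.censored:
            return f"> {self.ceiling_dB_SPL:g} dB SPL"
        return f"{self.threshold_dB_SPL:g} dB SPL"


@dataclass(frozen=True)
class GrowthFunction:
    """Wave-1 amplitude vs level for one stimulus family and condition."""

    stimulus_family: str
    condition: str
    points: tuple[tuple[float, float], ...]  # (level dB SPL, amplitude µV)

    @property
    def levels(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


def default_search_window(stimulus) -> tuple[float, float]:
    """P1 search window for a stimulus: click default shifted by ramp/2."""
    shift = stimulus.ramp_ms / 2.0
    return (DEFAULT_WINDOW_MS[0] + shift, DEFAULT_WINDOW_MS[1] + shift)


def detect_wave1(
    waveform: AveragedWaveform,
    search_window_ms: tuple[float, float] | None = None,
) -> Wave1Measurement:
    """Extract P1/N1 latencies and peak-to-peak wave-1 amplitude.

    P1 is the maximum sample within the search window; N1 the minimum in
    the 1.5 ms after P1.  A flat trace yields amplitude 0 with both
    latencies at the window start.
    """
    if search_window_ms is None:
        search_window_ms = default_search_window(waveform.stimulus)
    lo, hi = search_window_ms
    if lo < 0 or hi > waveform.window_ms or lo >= hi:
        raise ContractError(
            f"search window {search_window_ms} outside recording window "
            f"[0, {waveform.window_ms:g}] ms"
        )
    t = waveform.times_ms
    samples = waveform.samples
    in_window = (t >= lo) & (t <= hi)
    if not np.any(in_window):
        raise ContractError("search window contains no samples")
    if samples.max() - samples.min() < FLAT_TOLERANCE_UV:
        return Wave1Measurement(lo, lo, 0.0)
    window_idx = np.flatnonzero(in_window)
    p1_idx = window_idx[np.argmax(samples[window_idx])]
    p1_t = t[p1_idx]
    after = np.flatnonzero((t > p1_t) & (t <= p1_t + N1_SPAN_MS))
    if after.size == 0:
        return Wave1Measurement(p1_t, p1_t, 0.0)
    n1_idx = after[np.argmin(samples[after])]
    amplitude = samples[p1_idx] - samples[n1_idx]
    return Wave1Measurement(p1_t, t[n1_idx], max(0.0, float(amplitude)))


def _check_series(series: Sequence[AveragedWaveform]) -> None:
    if len(series) < 4:
        raise ContractError("threshold estimation needs >= 4 levels")
    families = {w.stimulus.family for w in series}
    if len(families) != 1:
        raise ContractError(f"mixed stimulus families in level series: {families}")
    levels = [w.stimulus.level_dB_SPL for w in series]
    if levels != sorted(levels):
        raise ContractError("level series must be sorted ascending")
    if len(set(levels)) != len(levels):
        raise ContractError("duplicate levels in series")


#: template-correlation detection: response-window extent (ms), maximum
#: latency lag searched (ms), and the correlation criterion
TEMPLATE_WINDOW_MS = (0.8, 6.5)
TEMPLATE_MAX_LAG_MS = 1.6
TEMPLATE_R_CRITERION = 0.5


def _noise_sigma(series: Sequence[AveragedWaveform]) -> float:
    """Noise-floor SD: pre-response samples pooled over the 3 lowest levels."""
    pooled = []
    for w in series[:3]:
        t = w.times_ms
        pooled.append(w.samples[(t >= NOISE_WINDOW_MS[0]) & (t <= NOISE_WINDOW_MS[1])])
    return float(np.std(np.concatenate(pooled), ddof=1))


def _template_detects(
    series: Sequence[AveragedWaveform], amplitude_floor_uV: float
) -> list[bool]:
    """Per-level response detection by lag-tolerant template correlation.

    The template is the mean of the three highest-level traces over the
    response window.  A level counts as responding when the maximum
    Pearson correlation with the template, over latency lags up to
    ``TEMPLATE_MAX_LAG_MS`` (responses shift later near threshold),
    exceeds ``TEMPLATE_R_CRITERION`` and the wave-1 amplitude clears the
    absolute floor.
    """
    dt = 1.0 / series[0].sample_rate_kHz
    i0 = int(round(TEMPLATE_WINDOW_MS[0] / dt))
    i1 = int(round(TEMPLATE_WINDOW_MS[1] / dt))
    max_lag = int(round(TEMPLATE_MAX_LAG_MS / dt))
    top = series[-3:]

    def _template_excluding(waveform):
        # leave-one-out for the template's own members, else noise in a
        # template trace correlates with itself and fakes a detection
        members = [w for w in top if w is not waveform] or top
        template = np.mean([w.samples[i0:i1] for w in members], axis=0)
        return template - template.mean()

    detections = []
    for w in series:
        amp = detect_wave1(w).p1n1_amplitude_uV
        template = _template_excluding(w)
        t_norm = float(np.linalg.norm(template))
        if amp <= amplitude_floor_uV or t_norm == 0.0:
            detections.append(False)
            continue
        best = 0.0
        for lag in range(max_lag + 1):
            seg = w.samples[i0 + lag : i1 + lag]
            seg = seg - seg.mean()
            denom = t_norm * float(np.linalg.norm(seg))
            if denom > 0:
                best = max(best, float(np.dot(template, seg)) / denom)
        detections.append(best > TEMPLATE_R_CRITERION)
    return detections


def estimate_threshold(
    series: Sequence[AveragedWaveform],
    *,
    method: str = "template_correlation",
    sigma_multiple: float = SIGMA_MULTIPLE,
    amplitude_floor_uV: float = AMPLITUDE_FLOOR_UV,
) -> ThresholdEstimate:
    """Estimate threshold from an ascending level series of one family.

    Threshold is the lowest level at which the response criterion holds at
    that level and every higher tested level (a sustained response,
    standing in for the visual rule that features be consistent with their
    trends at higher levels); censored if no level qualifies.

    Two criteria are available.  ``template_correlation`` (default)
    detects a response when the trace correlates with the high-level
    template (see :func:`_template_detects`); it tracks the response shape
    down into the noise floor and is robust against the upward bias of a
    peak-to-peak statistic on pure noise.  ``amplitude_criterion`` uses
    the simpler rule wave-1 amplitude > ``max(sigma_multiple * noise-floor
    SD, amplitude_floor_uV)`` with the noise floor estimated from the
    pre-response window of the 3 lowest levels.
    """
    _check_series(series)
    family = series[0].stimulus.family
    ceiling = series[-1].stimulus.level_dB_SPL

    if method == "template_correlation":
        detections = _template_detects(series, amplitude_floor_uV)
    elif method == "amplitude_criterion":
        criterion = max(sigma_multiple * _noise_sigma(series), amplitude_floor_uV)
        detections = [
            detect_wave1(w).p1n1_amplitude_uV > criterion for w in series
        ]
    else:
        raise ContractError(f"unknown threshold method {method!r}")

    threshold = None
    # scan from the top: the lowest level of the terminal detected run
    for w, detected in zip(reversed(series), reversed(detections)):
        if detected:
            threshold = w.stimulus.level_dB_SPL
        else:
            break
    return ThresholdEstimate(
        stimulus_family=family,
        threshold_dB_SPL=threshold,
        ceiling_dB_SPL=ceiling,
        method=method,
    )


def growth_function(
    series: Sequence[AveragedWaveform], condition: str = ""
) -> GrowthFunction:
    """Wave-1 amplitude growth function over a level series.

    Accepts any presentation order (series are recorded in randomised
    order) and returns points sorted by ascending level.
    """
    if not series:
        raise ContractError("empty level series")
    families = {w.stimulus.family for w in series}
    if len(families) != 1:
        raise ContractError(f"mixed stimulus families in level series: {families}")
    ordered = sorted(series, key=lambda w: w.stimulus.level_dB_SPL)
    levels = [w.stimulus.level_dB_SPL for w in ordered]
    if len(set(levels)) != len(levels):
        raise ContractError("duplicate level in growth-function series")
    points = tuple(
        (w.stimulus.level_dB_SPL, detect_wave1(w).p1n1_amplitude_uV) for w in ordered
    )
    return GrowthFunction(
        stimulus_family=families.pop(), condition=condition, points=points
    )


def sensation_level(level_dB_SPL: float, threshold: ThresholdEstimate) -> float:
    """Convert dB SPL to dB SL (level above the individual threshold)."""
    if threshold.censored:
        raise ContractError(
            f"sensation level undefined for censored threshold ({threshold})"
        )
    return level_dB_SPL - threshold.threshold_dB_SPL
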