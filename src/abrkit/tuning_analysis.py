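"""Forward-masked frequency tuning curves.

A fixed probe tone (12, 18 or 24 kHz, presented 20 dB above the mouse's
own threshold) follows a variable-frequency masker tone after a 4 ms gap.
For each masker frequency (probe x 0.5 ... 1.6) the probe's wave-1
amplitude, normalised to the unmasked probe response, is measured across
masker levels 0-90 dB SPL in 10 dB steps.  The masked threshold is the
masker level producing a criterion 50 % amplitude reduction; plotted
against masker frequency these thresholds form the tuning curve, whose tip
marks the frequency of greatest masking effectiveness.

Normalised amplitudes are first smoothed by non-increasing isotonic
regression; the masked threshold is the linearly interpolated first
downward crossing of the criterion.  Censoring is exhaustive: every
masking function yields a finite threshold, "> 90 dB" (never reaches the
criterion), "< 0 dB" (already below it at 0 dB), or is unusable (unmasked
amplitude below the noise criterion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import isotonic_regression

from abrkit.abr_io import (
    AveragedWaveform,
    ContractError,
    SessionArchive,
    StimulusSpec,
)
from abrkit.waveform_metrics import (
    AMPLITUDE_FLOOR_UV,
    SIGMA_MULTIPLE,
    ThresholdEstimate,
    detect_wave1,
    estimate_threshold,
)

__all__ = [
    "MaskingFunction",
    "MaskedThreshold",
    "TuningCurve",
    "masking_function",
    "masked_threshold",
    "build_tuning_curve",
    "mean_tuning_curve",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MaskingFunction:
    """Normalised probe amplitude vs masker level for one masker frequency."""

    probe: StimulusSpec
    masker_frequency_kHz: float
    points: tuple[tuple[float, float], ...]  # (masker level dB SPL, amp ratio)
    usable: bool = True

    @property
    def levels(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def normalized_amplitudes(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass(frozen=True)
class MaskedThreshold:
    """Masker level at criterion reduction, or a censoring marker.

    ``censor`` is None for a finite threshold, ``"above"`` when the
    criterion is never reached by the highest tested level, ``"below"``
    when the function is already past criterion at the lowest level, and
    ``"unusable"`` when the unmasked reference response was itself below
    the noise criterion.
    """

    value: float | None
    censor: str | None = None

    @property
    def finite(self) -> bool:
        return self.censor is None

    def __str__(self) -> str:
        if self.censor == "above":
            return "> 90 dB SPL"
        if self.censor == "below":
            return "< 0 dB SPL"
        if self.censor == "unusable":
            return "unusable"
        return f"{self.value:g} dB SPL"


@dataclass(frozen=True)
class TuningCurve:
    probe_frequency_kHz: float
    probe_level_dB_SPL: float
    points: tuple[tuple[float, MaskedThreshold], ...]  # (masker freq, threshold)

    @property
    def tip(self) -> tuple[float, float]:
        """(masker frequency, masked threshold) at the curve minimum."""
        finite = [(f, t.value) for f, t in self.points if t.finite]
        if not finite:
            raise ContractError("tuning curve has no finite masked thresholds")
        return min(finite, key=lambda p: p[1])


def masking_function(
    masked: Sequence[AveragedWaveform],
    unmasked: AveragedWaveform,
    *,
    noise_criterion_uV: float | None = None,
) -> MaskingFunction:
    """Build the normalised masking function for one masker frequency.

    ``noise_criterion_uV`` defaults to ``max(4 * SD of the unmasked
    pre-response window, 0.1 µV)``, the same criterion used for threshold
    estimation; an unmasked amplitude at or below it marks the function
    unusable rather than raising.
    """
    if not masked:
        raise ContractError("no masked waveforms supplied")
    probe = unmasked.stimulus
    freqs = {w.stimulus.masker.frequency_kHz for w in masked if w.stimulus.masker}
    if len(freqs) != 1:
        raise ContractError(f"masked waveforms mix masker frequencies: {freqs}")
    for w in masked:
        if (
            w.stimulus.kind != probe.kind
            or w.stimulus.frequency_kHz != probe.frequency_kHz
            or w.stimulus.level_dB_SPL != probe.level_dB_SPL
        ):
            raise ContractError("masked and unmasked probes differ")
    masker_freq = freqs.pop()

    if noise_criterion_uV is None:
        t = unmasked.times_ms
        pre = unmasked.samples[(t >= 0.0) & (t <= 0.7)]
        sigma = float(np.std(pre, ddof=1))
        noise_criterion_uV = max(SIGMA_MULTIPLE * sigma, AMPLITUDE_FLOOR_UV)

    reference = detect_wave1(unmasked).p1n1_amplitude_uV
    ordered = sorted(masked, key=lambda w: w.stimulus.masker.level_dB_SPL)
    if reference <= noise_criterion_uV:
        points = tuple((w.stimulus.masker.level_dB_SPL, 0.0) for w in ordered)
        return MaskingFunction(probe, masker_freq, points, usable=False)
    points = tuple(
        (
            w.stimulus.masker.level_dB_SPL,
            detect_wave1(w).p1n1_amplitude_uV / reference,
        )
        for w in ordered
    )
    return MaskingFunction(probe, masker_freq, points, usable=True)


def masked_threshold(fn: MaskingFunction, criterion: float = 0.5) -> MaskedThreshold:
    """Masker level at the criterion amplitude reduction.

    Applies non-increasing isotonic regression to the normalised
    amplitudes, then linearly interpolates the first downward crossing of
    ``criterion`` (a criterion of 0.5 is the 50 % amplitude reduction).
    """
    if not 0.0 < criterion < 1.0:
        raise ContractError(f"criterion must lie in (0, 1), got {criterion}")
    if not fn.usable:
        return MaskedThreshold(None, "unusable")
    levels = fn.levels
    fitted = isotonic_regression(fn.normalized_amplitudes, increasing=False).x
    if fitted[0] < criterion:
        return MaskedThreshold(None, "below")
    below = np.flatnonzero(fitted < criterion)
    if below.size == 0:
        return MaskedThreshold(None, "above")
    i = int(below[0])
    y0, y1 = fitted[i - 1], fitted[i]
    x0, x1 = levels[i - 1], levels[i]
    crossing = x0 + (y0 - criterion) / (y0 - y1) * (x1 - x0)
    return MaskedThreshold(float(crossing))


def _probe_threshold(
    archive: SessionArchive, mouse_id: str, probe_frequency_kHz: float
) -> ThresholdEstimate:
    series = archive.waveforms_for(
        mouse_id,
        lambda s: (
            s.kind == "tone"
            and s.frequency_kHz == probe_frequency_kHz
            and s.masker is None
            and s.duration_ms == 5.0
        ),
    )
    series.sort(key=lambda w: w.stimulus.level_dB_SPL)
    return estimate_threshold(series)


def build_tuning_curve(
    archive: SessionArchive,
    mouse_id: str,
    probe_frequency_kHz: float,
    criterion: float = 0.5,
) -> TuningCurve | None:
    """Tuning curve for one mouse and probe frequency, or None if skipped.

    The mouse is skipped (with a logged reason) when its probe-frequency
    threshold is censored, since the probe is placed relative to it.
    """
    probe_thr = _probe_threshold(archive, mouse_id, probe_frequency_kHz)
    if probe_thr.censored:
        logger.info(
            "skipping mouse %s at %g kHz: censored probe threshold (%s)",
            mouse_id,
            probe_frequency_kHz,
            probe_thr,
        )
        return None

    masked = archive.waveforms_for(
        mouse_id,
        lambda s: (
            s.kind == "tone"
            and s.frequency_kHz == probe_frequency_kHz
            and s.masker is not None
            and s.masker.kind == "tone"
        ),
    )
    if not masked:
        raise ContractError(
            f"mouse {mouse_id}: no masked probe waveforms at "
            f"{probe_frequency_kHz:g} kHz"
        )
    probe_level = masked[0].stimulus.level_dB_SPL
    unmasked_candidates = archive.waveforms_for(
        mouse_id,
        lambda s: (
            s.kind == "tone"
            and s.frequency_kHz == probe_frequency_kHz
            and s.masker is None
            and s.level_dB_SPL == probe_level
        ),
    )
    if not unmasked_candidates:
        raise ContractError(
            f"mouse {mouse_id}: no unmasked probe reference at "
            f"{probe_level:g} dB SPL"
        )
    unmasked = unmasked_candidates[0]

    by_masker_freq: dict[float, list[AveragedWaveform]] = {}
    for w in masked:
        by_masker_freq.setdefault(w.stimulus.masker.frequency_kHz, []).append(w)

    points = []
    for freq in sorted(by_masker_freq):
        fn = masking_function(by_masker_freq[freq], unmasked)
        points.append((freq, masked_threshold(fn, criterion)))
    return TuningCurve(
        probe_frequency_kHz=probe_frequency_kHz,
        probe_level_dB_SPL=probe_level,
        points=tuple(points),
    )


def mean_tuning_curve(curves: Sequence[TuningCurve]) -> TuningCurve:
    """Pointwise group-mean curve over finite masked thresholds.

    Masker frequencies are matched by their ratio to the probe frequency;
    a ratio whose thresholds are censored in every mouse stays censored.
    """
    if not curves:
        raise ContractError("no tuning curves to average")
    probe_freq = curves[0].probe_frequency_kHz
    if any(c.probe_frequency_kHz != probe_freq for c in curves):
        raise ContractError("tuning curves mix probe frequencies")
    by_ratio: dict[float, list[float]] = {}
    for curve in curves:
        for freq, thr in curve.points:
            ratio = round(freq / probe_freq, 6)
            if thr.finite:
                by_ratio.setdefault(ratio, []).append(thr.value)
    points = []
    for ratio in sorted(set(round(f / probe_freq, 6) for c in curves for f, _ in c.points)):
        values = by_ratio.get(ratio, [])
        thr = (
            MaskedThreshold(float(np.mean(values)))
            if values
            else MaskedThreshold(None, "above")
        )
        points.append((ratio * probe_freq, thr))
    return TuningCurve(
        probe_frequency_kHz=probe_freq,
        probe_level_dB_SPL=float(np.mean([c.probe_level_dB_SPL for c in curves])),
        points=tuple(points),
    )
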