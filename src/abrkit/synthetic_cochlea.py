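"""Seeded synthetic cochlea: ground-truth generative model for ABR batteries.

The simulator produces :class:`~abrkit.abr_io.SessionArchive` objects for the
full stimulus battery (click/tone level series, forward-masked tuning
paradigm, forward-masking recovery, rate and ramp series, noise-exposure
timelines) plus qPCR Ct tables, with every generated quantity a pure
function of the phenotype parameters and the seed.

Generative model
----------------
Each averaged trace is a sum of five stereotyped biphasic (positive then
negative) wave components at fixed inter-wave spacing, plus Gaussian noise
of standard deviation ``noise_floor_sd_uV / sqrt(n_sweeps)`` (additive noise
on the average; single sweeps are never synthesised).  Only wave 1 carries
the manipulated physiology; waves 2-5 are fixed fractions of the wave-1
amplitude.  For a stimulus at sensation level ``L_SL = level - true
threshold`` (dB):

* wave-1 peak-to-peak amplitude ``A(L_SL) = amp_max / (1 + exp(-(L_SL -
  level50) / growth_slope))`` for ``L_SL > 0``, else exactly zero;
* P1 latency ``latency_min + 1.5 * exp(-L_SL / latency_decay)`` ms, plus
  half the onset ramp for tones;
* a forward masker multiplies the response by a recovery factor
  ``1 - S0 * adaptation_depth * exp(-gap / recovery_tau_ms)`` where ``S0``
  is the zero-gap suppression (logistic in the masker's effective level);
* presentation rate ``r`` multiplies by ``max(0, 1 - rate_coeff *
  log2(r / 10.65))``; an onset ramp ``rho`` (tones) multiplies by
  ``max(0, 1 - ramp_coeff * (rho - 0.25))``.

Wave component centres are snapped to the sample grid so that the sampled
peak equals the continuous peak; peak-to-peak amplitude of the sampled
trace then matches ``A(L_SL)`` to well under 1 % (the residual comes from
overlap with the neighbouring wave).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from abrkit.abr_io import (
    CLICK_RATES_PER_S,
    DEFAULT_RATE_PER_S,
    LEVEL_GRID_DB,
    MaskerSpec,
    MouseRecord,
    RAMP_TIMES_MS,
    RECOVERY_GAPS_MS,
    REFERENCE_GAP_MS,
    ContractError,
    SessionArchive,
    StimulusSpec,
    THRESHOLD_TONE_KHZ,
    TUNING_RATIOS,
    AveragedWaveform,
)
from abrkit.expression_qpcr import CtRecord

__all__ = [
    "MousePhenotypeParams",
    "GenotypeEffect",
    "ExposureModel",
    "simulate_waveform",
    "simulate_masking",
    "simulate_cohort",
    "simulate_exposure_timeline",
    "simulate_exposure_cohort",
    "simulate_qpcr",
    "draw_mouse_params",
    "tuning_filter_db",
    "wave1_amplitude",
    "PRE_EXPOSURE",
]

SAMPLE_RATE_KHZ = 9.75  # 195 samples over the 20 ms window
WINDOW_MS = 20.0
N_SWEEPS = 256

# five-wave morphology: amplitude fractions relative to wave 1 and
# inter-wave spacing; lobe width sigma and P-to-N lobe separation in ms
WAVE_AMPLITUDE_FRACTIONS = (1.0, 0.8, 0.6, 0.45, 0.35)
WAVE_SPACING_MS = 1.0
LOBE_SIGMA_MS = 0.10
PN_SEPARATION_MS = 0.5
LATENCY_RANGE_MS = 1.5  # latency prolongation from high level down to threshold

# zero-gap suppression logistic: midpoint (dB above the tuning filter for
# tonal maskers) and slope constant
MASK_E50_DB = 10.0
MASK_K_DB = 2.5

#: sentinel day offset marking the pre-exposure measurement
PRE_EXPOSURE = -1.0

#: baseline wildtype thresholds (dB SPL); best sensitivity at 12-24 kHz
BASE_THRESHOLDS_DB: dict[str, float] = {
    "click": 20.0,
    "3kHz": 45.0,
    "6kHz": 30.0,
    "12kHz": 15.0,
    "18kHz": 15.0,
    "24kHz": 20.0,
    "30kHz": 35.0,
    "36kHz": 50.0,
    "42kHz": 60.0,
}


@dataclass
class MousePhenotypeParams:
    """Ground-truth physiological parameters of one simulated mouse."""

    true_threshold_dB: dict[str, float] = field(
        default_factory=lambda: dict(BASE_THRESHOLDS_DB)
    )
    amp_max_uV: float = 6.0
    growth_slope_dB: float = 5.0
    level50_dB_SL: float = 15.0
    latency_min_ms: float = 1.1
    latency_decay_dB: float = 20.0
    recovery_tau_ms: float = 20.0
    adaptation_depth: float = 0.9
    rate_coeff: float = 0.05
    ramp_coeff: float = 0.08
    tuning_tip_dB: float = 30.0
    tuning_slope_low_dB_per_oct: float = 25.0
    tuning_slope_high_dB_per_oct: float = 50.0
    noise_floor_sd_uV: float = 1.6

    def __post_init__(self) -> None:
        positive = [
            ("amp_max_uV", self.amp_max_uV),
            ("growth_slope_dB", self.growth_slope_dB),
            ("latency_min_ms", self.latency_min_ms),
            ("latency_decay_dB", self.latency_decay_dB),
            ("recovery_tau_ms", self.recovery_tau_ms),
            ("tuning_slope_low_dB_per_oct", self.tuning_slope_low_dB_per_oct),
            ("tuning_slope_high_dB_per_oct", self.tuning_slope_high_dB_per_oct),
        ]
        for name, value in positive:
            if value <= 0:
                raise ContractError(f"{name} must be positive, got {value}")
        if not 0.0 <= self.adaptation_depth <= 1.0:
            raise ContractError("adaptation_depth must lie in [0, 1]")
        if self.rate_coeff < 0 or self.ramp_coeff < 0:
            raise ContractError("rate_coeff and ramp_coeff must be >= 0")
        if self.noise_floor_sd_uV < 0:
            raise ContractError("noise_floor_sd_uV must be >= 0")


@dataclass(frozen=True)
class GenotypeEffect:
    """Multiplicative/additive deviation of a genotype from wildtype.

    The identity effect (all shifts 0, all scales 1) reproduces the
    wildtype distribution exactly.
    """

    threshold_shift_dB: Mapping[str, float] = field(default_factory=dict)
    amp_scale: float = 1.0
    tau_scale: float = 1.0
    pts_extra_dB: Mapping[str, float] = field(default_factory=dict)
    recovery_rate_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.amp_scale <= 0 or self.tau_scale <= 0:
            raise ContractError("amp_scale and tau_scale must be positive")
        if self.recovery_rate_scale <= 0:
            raise ContractError("recovery_rate_scale must be positive")

    def shift_for(self, family: str) -> float:
        return float(self.threshold_shift_dB.get(family, 0.0))

    def pts_extra_for(self, family: str) -> float:
        return float(self.pts_extra_dB.get(family, 0.0))


IDENTITY_EFFECT = GenotypeEffect()


@dataclass(frozen=True)
class ExposureModel:
    """Noise-exposure damage profile (octave-band 8-16 kHz exposure).

    Temporary threshold shift (TTS) recovers exponentially with time
    constant ``tau_rec_days``; permanent shift (PTS) remains.  Damage is
    larger inside the exposure band than below it, and largest above the
    band, mirroring the basalward spread of noise damage.
    """

    tts_below_band_dB: float = 5.0
    tts_in_band_dB: float = 25.0
    tts_above_band_dB: float = 40.0
    pts_below_band_dB: float = 0.0
    pts_in_band_dB: float = 5.0
    pts_above_band_dB: float = 10.0
    tau_rec_days: float = 3.0
    band_kHz: tuple[float, float] = (8.0, 16.0)

    @classmethod
    def sham(cls) -> "ExposureModel":
        return cls(
            tts_below_band_dB=0.0,
            tts_in_band_dB=0.0,
            tts_above_band_dB=0.0,
            pts_below_band_dB=0.0,
            pts_in_band_dB=0.0,
            pts_above_band_dB=0.0,
        )

    def _band_value(self, family: str, below: float, inside: float, above: float) -> float:
        if family == "click":
            # broadband click reflects the whole cochlea; use the in-band value
            return inside
        f = float(family.removesuffix("kHz"))
        lo, hi = self.band_kHz
        if f < lo:
            return below
        if f <= hi:
            return inside
        return above

    def tts_dB(self, family: str) -> float:
        return self._band_value(
            family, self.tts_below_band_dB, self.tts_in_band_dB, self.tts_above_band_dB
        )

    def pts_dB(self, family: str) -> float:
        return self._band_value(
            family, self.pts_below_band_dB, self.pts_in_band_dB, self.pts_above_band_dB
        )

    def shift_dB(self, family: str, day: float, effect: GenotypeEffect = IDENTITY_EFFECT) -> float:
        """Threshold shift at ``day`` after exposure (``PRE_EXPOSURE`` -> 0)."""
        if day == PRE_EXPOSURE:
            return 0.0
        if day < 0:
            raise ContractError(
                f"timepoint {day} is negative and not the pre-exposure marker"
            )
        pts = self.pts_dB(family) + effect.pts_extra_for(family)
        rate = effect.recovery_rate_scale / self.tau_rec_days
        return pts + self.tts_dB(family) * math.exp(-day * rate)


# ---------------------------------------------------------------------------
# waveform synthesis


def wave1_amplitude(params: MousePhenotypeParams, family: str, level_dB_SPL: float) -> float:
    """Noise-free wave-1 peak-to-peak amplitude (µV) before masking/rate/ramp."""
    threshold = params.true_threshold_dB[family]
    l_sl = level_dB_SPL - threshold
    if l_sl <= 0:
        return 0.0
    return params.amp_max_uV / (
        1.0 + math.exp(-(l_sl - params.level50_dB_SL) / params.growth_slope_dB)
    )


def p1_latency_ms(params: MousePhenotypeParams, family: str, level_dB_SPL: float) -> float:
    l_sl = max(0.0, level_dB_SPL - params.true_threshold_dB[family])
    return params.latency_min_ms + LATENCY_RANGE_MS * math.exp(
        -l_sl / params.latency_decay_dB
    )


def tuning_filter_db(
    params: MousePhenotypeParams, masker_frequency_kHz: float, probe_frequency_kHz: float
) -> float:
    """Masker level (dB SPL) at the edge of effectiveness, a V-shaped filter.

    Minimum (``tuning_tip_dB``) at the probe frequency, rising with octave
    distance at the configured low-side/high-side slopes.
    """
    octaves = math.log2(masker_frequency_kHz / probe_frequency_kHz)
    if octaves < 0:
        return params.tuning_tip_dB - octaves * params.tuning_slope_low_dB_per_oct
    return params.tuning_tip_dB + octaves * params.tuning_slope_high_dB_per_oct


def _suppression_zero_gap(
    params: MousePhenotypeParams, probe: StimulusSpec, masker: MaskerSpec
) -> float:
    if masker.kind == "tone":
        effective = masker.level_dB_SPL - tuning_filter_db(
            params, masker.frequency_kHz, probe.frequency_kHz
        )
        return 1.0 / (1.0 + math.exp(-(effective - MASK_E50_DB) / MASK_K_DB))
    # broadband: the standard paradigm presents the masker 10 dB below the click
    return 1.0 / (
        1.0 + math.exp(-(masker.level_dB_SPL - probe.level_dB_SPL + 10.0) / MASK_K_DB)
    )


def simulate_masking(
    params: MousePhenotypeParams, probe: StimulusSpec, masker: MaskerSpec | None = None
) -> float:
    """Suppression factor in [0, 1] applied to the probe response.

    ``factor = 1 - S0 * adaptation_depth * exp(-gap / recovery_tau_ms)``
    where ``S0`` is the zero-gap suppression.  Complete recovery (factor
    -> 1) as the gap grows; at 150 ms the factor exceeds 0.999 for the
    default time constant.
    """
    if masker is None:
        masker = probe.masker
    if masker is None:
        raise ContractError("simulate_masking requires a masker")
    s0 = _suppression_zero_gap(params, probe, masker)
    factor = 1.0 - s0 * params.adaptation_depth * math.exp(
        -masker.gap_ms / params.recovery_tau_ms
    )
    return max(0.0, factor)


def _response_scale(params: MousePhenotypeParams, stimulus: StimulusSpec) -> float:
    """Combined masking * rate * ramp multiplier for the whole response."""
    scale = 1.0
    if stimulus.masker is not None:
        scale *= simulate_masking(params, stimulus)
    scale *= max(0.0, 1.0 - params.rate_coeff * math.log2(stimulus.rate_per_s / 10.65))
    if stimulus.ramp_ms > 0:
        scale *= max(0.0, 1.0 - params.ramp_coeff * (stimulus.ramp_ms - 0.25))
    return scale


def simulate_waveform(
    params: MousePhenotypeParams,
    stimulus: StimulusSpec,
    rng: np.random.Generator | None = None,
    *,
    mouse_id: str = "m0",
    sample_rate_kHz: float = SAMPLE_RATE_KHZ,
    window_ms: float = WINDOW_MS,
    n_sweeps: int = N_SWEEPS,
) -> AveragedWaveform:
    """Synthesise one averaged trace for ``stimulus``.

    Deterministic given ``(params, stimulus)`` and the state of ``rng``;
    pass ``rng=None`` for a noise-free trace regardless of the phenotype's
    noise floor.
    """
    n = round(sample_rate_kHz * window_ms)
    dt = 1.0 / sample_rate_kHz
    t = np.arange(n) * dt
    if rng is not None and params.noise_floor_sd_uV > 0:
        trace = rng.normal(0.0, params.noise_floor_sd_uV / math.sqrt(n_sweeps), n)
    else:
        trace = np.zeros(n)

    amp1 = wave1_amplitude(params, stimulus.family, stimulus.level_dB_SPL)
    if amp1 > 0:
        amp1 *= _response_scale(params, stimulus)
        latency = p1_latency_ms(params, stimulus.family, stimulus.level_dB_SPL)
        latency += stimulus.ramp_ms / 2.0  # effective onset of ramped tones
        pn_offset = round(PN_SEPARATION_MS / dt) * dt
        two_sigma_sq = 2.0 * LOBE_SIGMA_MS**2
        for i, fraction in enumerate(WAVE_AMPLITUDE_FRACTIONS):
            peak_t = round((latency + i * WAVE_SPACING_MS) / dt) * dt
            lobe = 0.5 * amp1 * fraction
            trace += lobe * np.exp(-((t - peak_t) ** 2) / two_sigma_sq)
            trace -= lobe * np.exp(-((t - peak_t - pn_offset) ** 2) / two_sigma_sq)

    return AveragedWaveform(
        mouse_id=mouse_id,
        stimulus=stimulus,
        samples=trace,
        sample_rate_kHz=sample_rate_kHz,
        window_ms=window_ms,
        n_sweeps=n_sweeps,
    )


# ---------------------------------------------------------------------------
# per-mouse parameter draws

THRESHOLD_BETWEEN_MOUSE_SD_DB = 5.0


def draw_mouse_params(
    rng: np.random.Generator,
    effect: GenotypeEffect = IDENTITY_EFFECT,
    base: MousePhenotypeParams | None = None,
) -> MousePhenotypeParams:
    """Draw one mouse's phenotype from the between-mouse distributions.

    Thresholds are normal around the (effect-shifted) baseline with a 5 dB
    between-mouse SD, clipped to the tested 0-95 dB range.
    """
    if base is None:
        base = MousePhenotypeParams()
    thresholds = {}
    for family in sorted(base.true_threshold_dB):
        mean = base.true_threshold_dB[family] + effect.shift_for(family)
        thresholds[family] = float(
            np.clip(rng.normal(mean, THRESHOLD_BETWEEN_MOUSE_SD_DB), 0.0, 95.0)
        )
    return MousePhenotypeParams(
        true_threshold_dB=thresholds,
        amp_max_uV=max(1.0, rng.normal(base.amp_max_uV, 0.8)) * effect.amp_scale,
        growth_slope_dB=base.growth_slope_dB,
        level50_dB_SL=rng.normal(base.level50_dB_SL, 2.0),
        latency_min_ms=max(0.8, rng.normal(base.latency_min_ms, 0.05)),
        latency_decay_dB=base.latency_decay_dB,
        recovery_tau_ms=max(5.0, rng.normal(base.recovery_tau_ms, 2.0))
        * effect.tau_scale,
        adaptation_depth=base.adaptation_depth,
        rate_coeff=base.rate_coeff,
        ramp_coeff=base.ramp_coeff,
        tuning_tip_dB=rng.normal(base.tuning_tip_dB, 3.0),
        tuning_slope_low_dB_per_oct=base.tuning_slope_low_dB_per_oct,
        tuning_slope_high_dB_per_oct=base.tuning_slope_high_dB_per_oct,
        noise_floor_sd_uV=base.noise_floor_sd_uV,
    )


# ---------------------------------------------------------------------------
# stimulus battery enumeration

BATTERIES = ("thresholds_only", "full", "tuning", "recovery", "rate", "ramp")


def _click(level: float, rate: float = DEFAULT_RATE_PER_S, masker: MaskerSpec | None = None) -> StimulusSpec:
    return StimulusSpec(kind="click", level_dB_SPL=level, rate_per_s=rate, masker=masker)


def _tone(freq: float, level: float, duration: float = 5.0, ramp: float = 1.0,
          masker: MaskerSpec | None = None) -> StimulusSpec:
    return StimulusSpec(
        kind="tone",
        frequency_kHz=freq,
        level_dB_SPL=level,
        duration_ms=duration,
        ramp_ms=ramp,
        masker=masker,
    )


def _threshold_stimuli() -> list[StimulusSpec]:
    out = [_click(level) for level in LEVEL_GRID_DB]
    for freq in THRESHOLD_TONE_KHZ:
        out.extend(_tone(freq, level) for level in LEVEL_GRID_DB)
    return out


def _tuning_stimuli(params: MousePhenotypeParams) -> list[StimulusSpec]:
    out: list[StimulusSpec] = []
    for probe_freq in (12.0, 18.0, 24.0):
        probe_level = params.true_threshold_dB[f"{probe_freq:g}kHz"] + 20.0
        out.append(_tone(probe_freq, probe_level))  # unmasked reference
        for ratio in TUNING_RATIOS:
            for masker_level in np.arange(0.0, 100.0, 10.0):
                masker = MaskerSpec(
                    kind="tone",
                    frequency_kHz=probe_freq * ratio,
                    level_dB_SPL=float(masker_level),
                    duration_ms=10.0,
                    gap_ms=4.0,
                )
                out.append(_tone(probe_freq, probe_level, masker=masker))
    return out


def _recovery_stimuli(params: MousePhenotypeParams) -> list[StimulusSpec]:
    out: list[StimulusSpec] = []
    for sl in (20.0, 50.0):
        click_level = params.true_threshold_dB["click"] + sl
        for gap in (*RECOVERY_GAPS_MS, REFERENCE_GAP_MS):
            masker = MaskerSpec(
                kind="broadband",
                level_dB_SPL=click_level - 10.0,
                duration_ms=10.0,
                gap_ms=gap,
            )
            out.append(_click(click_level, masker=masker))
    return out


def _rate_stimuli() -> list[StimulusSpec]:
    return [
        _click(level, rate=rate)
        for rate in CLICK_RATES_PER_S
        for level in LEVEL_GRID_DB
    ]


def _ramp_stimuli() -> list[StimulusSpec]:
    return [
        _tone(18.0, level, duration=8.0, ramp=ramp)
        for ramp in RAMP_TIMES_MS
        for level in LEVEL_GRID_DB
    ]


def _battery_stimuli(battery: str, params: MousePhenotypeParams) -> list[StimulusSpec]:
    if battery not in BATTERIES:
        raise ContractError(f"unknown battery {battery!r}; choose from {BATTERIES}")
    stimuli: dict[StimulusSpec, None] = {}  # insertion-ordered de-duplication
    for s in _threshold_stimuli():
        stimuli[s] = None
    if battery in ("tuning", "full"):
        for s in _tuning_stimuli(params):
            stimuli[s] = None
    if battery in ("recovery", "full"):
        for s in _recovery_stimuli(params):
            stimuli[s] = None
    if battery in ("rate", "full"):
        for s in _rate_stimuli():
            stimuli[s] = None
    if battery in ("ramp", "full"):
        for s in _ramp_stimuli():
            stimuli[s] = None
    return list(stimuli)


def _simulate_mouse(
    mouse_id: str,
    params: MousePhenotypeParams,
    stimuli: Sequence[StimulusSpec],
    rng: np.random.Generator,
) -> list[AveragedWaveform]:
    return [
        simulate_waveform(params, stim, rng, mouse_id=mouse_id) for stim in stimuli
    ]


def simulate_cohort(
    n_per_group: int,
    effects: Mapping[str, GenotypeEffect],
    battery: str = "thresholds_only",
    seed: int = 0,
    *,
    base: MousePhenotypeParams | None = None,
    return_truth: bool = False,
):
    """Simulate a cohort archive: ``n_per_group`` mice per genotype group.

    Group labels become genotype tags; mouse ids are ``<group>_<index>``.
    With ``return_truth=True`` also returns ``{mouse_id: params}`` for
    parameter-recovery tests.
    """
    if n_per_group < 1:
        raise ContractError("n_per_group must be >= 1")
    root = np.random.SeedSequence(seed)
    mice: list[MouseRecord] = []
    waveforms: list[AveragedWaveform] = []
    truth: dict[str, MousePhenotypeParams] = {}
    labels = sorted(effects)
    children = root.spawn(len(labels) * n_per_group)
    k = 0
    for label in labels:
        effect = effects[label]
        for i in range(n_per_group):
            rng = np.random.default_rng(children[k])
            k += 1
            mouse_id = f"{label}_{i:02d}"
            params = draw_mouse_params(rng, effect, base)
            truth[mouse_id] = params
            mice.append(MouseRecord(mouse_id=mouse_id, genotype=label, age_weeks=14.0))
            waveforms.extend(
                _simulate_mouse(mouse_id, params, _battery_stimuli(battery, params), rng)
            )
    archive = SessionArchive(
        mice=mice,
        waveforms=waveforms,
        provenance=f"synthetic cohort; battery={battery}; seed={seed}",
    )
    if return_truth:
        return archive, truth
    return archive


# ---------------------------------------------------------------------------
# noise-exposure timelines


def simulate_exposure_timeline(
    params: MousePhenotypeParams,
    effect: GenotypeEffect,
    timepoints: Sequence[float],
    seed: int,
    *,
    exposure: ExposureModel | None = None,
    mouse_id: str = "m0",
    genotype: str = "exposed",
) -> dict[float, SessionArchive]:
    """Threshold batteries for one mouse across exposure timepoints.

    ``timepoints`` are day offsets sorted ascending; :data:`PRE_EXPOSURE`
    marks the pre-exposure baseline.  The threshold shift applied at day
    ``t`` and frequency family ``f`` is ``PTS(f) + TTS(f) * exp(-t /
    tau_rec)``, with the genotype effect adding permanent shift and scaling
    the recovery rate.
    """
    if list(timepoints) != sorted(timepoints):
        raise ContractError("timepoints must be sorted ascending")
    if exposure is None:
        exposure = ExposureModel()
    root = np.random.SeedSequence(seed)
    archives: dict[float, SessionArchive] = {}
    for child, day in zip(root.spawn(len(timepoints)), timepoints):
        rng = np.random.default_rng(child)
        shifted = replace(
            params,
            true_threshold_dB={
                fam: min(thr + exposure.shift_dB(fam, day, effect), 200.0)
                for fam, thr in params.true_threshold_dB.items()
            },
        )
        waveforms = _simulate_mouse(
            mouse_id, shifted, _threshold_stimuli(), rng
        )
        archives[day] = SessionArchive(
            mice=[MouseRecord(mouse_id=mouse_id, genotype=genotype)],
            waveforms=waveforms,
            provenance=f"synthetic exposure timeline; day={day}; seed={seed}",
        )
    return archives


def simulate_exposure_cohort(
    n_per_group: Mapping[str, int],
    effects: Mapping[str, GenotypeEffect],
    exposures: Mapping[str, ExposureModel],
    timepoints: Sequence[float],
    seed: int,
    *,
    base: MousePhenotypeParams | None = None,
) -> dict[float, SessionArchive]:
    """Multi-group exposure study: merged archive per timepoint.

    ``effects`` and ``exposures`` are keyed by group label (e.g. ``sham``
    with :meth:`ExposureModel.sham`, ``wildtype_exposed``,
    ``mutant_exposed``).
    """
    labels = sorted(effects)
    if set(labels) != set(exposures):
        raise ContractError("effects and exposures must share group labels")
    root = np.random.SeedSequence(seed)
    per_tp: dict[float, tuple[list[MouseRecord], list[AveragedWaveform]]] = {
        day: ([], []) for day in timepoints
    }
    children = iter(root.spawn(sum(n_per_group[g] for g in labels) * 2))
    for label in labels:
        for i in range(n_per_group[label]):
            draw_rng = np.random.default_rng(next(children))
            params = draw_mouse_params(draw_rng, effects[label], base)
            mouse_id = f"{label}_{i:02d}"
            timeline = simulate_exposure_timeline(
                params,
                effects[label],
                timepoints,
                int(next(children).generate_state(1)[0] % (2**31)),
                exposure=exposures[label],
                mouse_id=mouse_id,
                genotype=label,
            )
            for day, arch in timeline.items():
                per_tp[day][0].extend(arch.mice)
                per_tp[day][1].extend(arch.waveforms)
    return {
        day: SessionArchive(
            mice=mice,
            waveforms=wfs,
            provenance=f"synthetic exposure cohort; day={day}; seed={seed}",
        )
        for day, (mice, wfs) in per_tp.items()
    }


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    true_rel_expression: Mapping[str, float],
    n_mice: Mapping[str, int],
    seed: int,
    *,
    sigma_ct: float = 0.15,
    mu_ref: float = 20.0,
    offset: float = 5.0,
) -> list[CtRecord]:
    """Simulate triplicate Ct tables for target and reference genes.

    Per mouse, reference Cts are Normal(``mu_ref``, ``sigma_ct``) and target
    Cts are Normal(``mu_ref + offset - log2(relative expression)``,
    ``sigma_ct``).  Wildtype must be present with relative expression 1.
    """
    if "wildtype" not in true_rel_expression:
        raise ContractError("wildtype must be present in true_rel_expression")
    for genotype, expr in true_rel_expression.items():
        if expr <= 0:
            raise ContractError(
                f"relative expression must be positive ({genotype}: {expr})"
            )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records: list[CtRecord] = []
    for genotype in sorted(true_rel_expression):
        mu_target = mu_ref + offset - math.log2(true_rel_expression[genotype])
        for i in range(n_mice[genotype]):
            mouse_id = f"{genotype}_{i:02d}"
            ref = mu_ref + rng.normal(0.0, sigma_ct, 3) if sigma_ct > 0 else np.full(3, mu_ref)
            tgt = (
                mu_target + rng.normal(0.0, sigma_ct, 3)
                if sigma_ct > 0
                else np.full(3, mu_target)
            )
            records.append(
                CtRecord(mouse_id=mouse_id, genotype=genotype, gene="reference",
                         ct_values=tuple(float(v) for v in ref))
            )
            records.append(
                CtRecord(mouse_id=mouse_id, genotype=genotype, gene="target",
                         ct_values=tuple(float(v) for v in tgt))
            )
    return records
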