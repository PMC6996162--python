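"""Forward-masking recovery fits and rate/ramp growth batteries.

Recovery from forward masking is measured with a probe click at 4, 8, 16,
32 or 64 ms after a 10 ms broadband masker (masker 10 dB below the click),
normalised to a reference click 150 ms after masker onset.  The recovery
curve is fitted with an exponential growth-to-maximum function

    y = y0 + a * (1 - exp(-b * x))

where ``y0`` is the predicted amplitude at zero gap, ``a`` the maximum
rise, and ``tau = 1/b`` the recovery time constant (ms).  The fit is
unweighted nonlinear least squares; the primary analysis fits the
group-mean curve, with per-mouse fits available for dispersion.

The rate battery collects click growth functions at 10.65, 21.3, 42.6 and
85.2 clicks/s; the ramp battery collects 18 kHz tone growth functions at
0.25-4 ms onset ramps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from abrkit.abr_io import (
    AveragedWaveform,
    CLICK_RATES_PER_S,
    ContractError,
    RAMP_TIMES_MS,
    RECOVERY_GAPS_MS,
    REFERENCE_GAP_MS,
    SessionArchive,
)
from abrkit.waveform_metrics import (
    AMPLITUDE_FLOOR_UV,
    SIGMA_MULTIPLE,
    GrowthFunction,
    detect_wave1,
    growth_function,
)

__all__ = [
    "RecoveryCurve",
    "RecoveryFit",
    "RateBattery",
    "RampBattery",
    "recovery_curve",
    "mean_recovery_curve",
    "fit_recovery",
    "recovery_model",
    "rate_battery",
    "ramp_battery",
]

logger = logging.getLogger(__name__)

B_BOUNDS = (1e-4, 10.0)  # 1/ms; tau between 0.1 ms and 10 s
_FLAT_A_TOLERANCE = 1e-9


@dataclass(frozen=True)
class RecoveryCurve:
    """Normalised probe amplitude vs masker-probe gap for one click level."""

    mouse_id: str
    click_level_dB_SL: float
    points: tuple[tuple[float, float], ...]  # (gap ms, normalised amplitude)
    reference_amplitude_uV: float = float("nan")

    @property
    def gaps_ms(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def normalized_amplitudes(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass(frozen=True)
class RecoveryFit:
    """Parameters of y = y0 + a(1 - e^(-bx)); tau_ms = 1/b exactly."""

    y0: float
    a: float
    b: float
    r_squared: float
    degenerate: bool = False

    @property
    def tau_ms(self) -> float:
        return 1.0 / self.b

    def predict(self, gap_ms):
        return recovery_model(np.asarray(gap_ms, dtype=float), self.y0, self.a, self.b)


@dataclass(frozen=True)
class RateBattery:
    mouse_id: str
    functions: dict[float, GrowthFunction]  # keyed by clicks/s


@dataclass(frozen=True)
class RampBattery:
    mouse_id: str
    functions: dict[float, GrowthFunction]  # keyed by ramp ms


def recovery_model(x, y0, a, b):
    return y0 + a * (1.0 - np.exp(-b * x))


def _noise_criterion(waveform: AveragedWaveform) -> float:
    t = waveform.times_ms
    pre = waveform.samples[(t >= 0.0) & (t <= 0.7)]
    return max(SIGMA_MULTIPLE * float(np.std(pre, ddof=1)), AMPLITUDE_FLOOR_UV)


def recovery_curve(
    archive: SessionArchive, mouse_id: str, click_level_dB_SL: float
) -> RecoveryCurve | None:
    """Extract one mouse's recovery curve at the 20 or 50 dB SL click level.

    The two click levels present in the archive are identified by rank
    (the lower is the 20 dB SL condition).  Returns None, with a logged
    reason, when the reference-click amplitude is below the noise
    criterion.
    """
    if click_level_dB_SL not in (20.0, 50.0):
        raise ContractError("click_level_dB_SL must be 20 or 50")
    masked_clicks = archive.waveforms_for(
        mouse_id,
        lambda s: s.kind == "click" and s.masker is not None,
    )
    if not masked_clicks:
        raise ContractError(f"mouse {mouse_id}: no forward-masked click waveforms")
    levels = sorted({w.stimulus.level_dB_SPL for w in masked_clicks})
    if len(levels) != 2:
        raise ContractError(
            f"mouse {mouse_id}: expected 2 click levels, found {levels}"
        )
    level = levels[0] if click_level_dB_SL == 20.0 else levels[1]
    at_level = [w for w in masked_clicks if w.stimulus.level_dB_SPL == level]

    by_gap = {w.stimulus.masker.gap_ms: w for w in at_level}
    if REFERENCE_GAP_MS not in by_gap:
        raise ContractError(f"mouse {mouse_id}: reference click (150 ms) missing")
    missing = [g for g in RECOVERY_GAPS_MS if g not in by_gap]
    if missing:
        raise ContractError(f"mouse {mouse_id}: missing probe gaps {missing}")

    reference_wf = by_gap[REFERENCE_GAP_MS]
    reference = detect_wave1(reference_wf).p1n1_amplitude_uV
    if reference <= _noise_criterion(reference_wf):
        logger.info(
            "skipping mouse %s at %g dB SL: reference amplitude %.3g µV "
            "below noise criterion",
            mouse_id,
            click_level_dB_SL,
            reference,
        )
        return None
    points = tuple(
        (gap, detect_wave1(by_gap[gap]).p1n1_amplitude_uV / reference)
        for gap in RECOVERY_GAPS_MS
    )
    return RecoveryCurve(
        mouse_id=mouse_id,
        click_level_dB_SL=click_level_dB_SL,
        points=points,
        reference_amplitude_uV=reference,
    )


def mean_recovery_curve(curves: Sequence[RecoveryCurve]) -> RecoveryCurve:
    """Pointwise mean curve across mice (the primary fit target)."""
    if not curves:
        raise ContractError("no recovery curves to average")
    sl = {c.click_level_dB_SL for c in curves}
    if len(sl) != 1:
        raise ContractError("recovery curves mix click levels")
    gaps = curves[0].gaps_ms
    stacked = np.vstack([c.normalized_amplitudes for c in curves])
    return RecoveryCurve(
        mouse_id="group-mean",
        click_level_dB_SL=sl.pop(),
        points=tuple(zip(gaps.tolist(), stacked.mean(axis=0).tolist())),
    )


def fit_recovery(
    curve: RecoveryCurve | Sequence[tuple[float, float]]
) -> RecoveryFit:
    """Nonlinear least-squares fit of the exponential recovery function.

    Initialisation: y0 = first observed point, a = last - first, b = 1/20
    per ms; b is bounded to (1e-4, 10).  A flat input returns a degenerate
    fit with a ~ 0 (tau is then meaningless and flagged).
    """
    if isinstance(curve, RecoveryCurve):
        x, y = curve.gaps_ms, curve.normalized_amplitudes
    else:
        pts = sorted(curve)
        x = np.array([p[0] for p in pts], dtype=float)
        y = np.array([p[1] for p in pts], dtype=float)
    if len(set(x.tolist())) < 4:
        raise ContractError("recovery fit needs >= 4 distinct gaps")

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot < _FLAT_A_TOLERANCE:
        return RecoveryFit(y0=float(y.mean()), a=0.0, b=1.0 / 20.0, r_squared=1.0,
                           degenerate=True)

    p0 = (float(y[0]), float(y[-1] - y[0]), 1.0 / 20.0)
    try:
        popt, _ = curve_fit(
            recovery_model,
            x,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, B_BOUNDS[0]], [np.inf, np.inf, B_BOUNDS[1]]),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            maxfev=1000 * 4,
        )
    except RuntimeError as exc:
        raise ContractError(f"recovery fit did not converge: {exc}") from exc
    y0, a, b = (float(v) for v in popt)
    residual = y - recovery_model(x, y0, a, b)
    r_squared = 1.0 - float(np.sum(residual**2)) / ss_tot
    return RecoveryFit(y0=y0, a=a, b=b, r_squared=r_squared,
                       degenerate=abs(a) < _FLAT_A_TOLERANCE)


def _battery(
    archive: SessionArchive,
    mouse_id: str,
    keys: Sequence[float],
    selector,
    label: str,
) -> dict[float, GrowthFunction]:
    functions: dict[float, GrowthFunction] = {}
    for key in keys:
        series = archive.waveforms_for(mouse_id, lambda s, k=key: selector(s, k))
        if not series:
            raise ContractError(f"mouse {mouse_id}: missing {label} condition {key:g}")
        functions[key] = growth_function(series, condition=f"{label}={key:g}")
    return functions


def rate_battery(archive: SessionArchive, mouse_id: str) -> RateBattery:
    """Click growth functions at the four standard presentation rates."""
    functions = _battery(
        archive,
        mouse_id,
        CLICK_RATES_PER_S,
        lambda s, rate: s.kind == "click" and s.masker is None and s.rate_per_s == rate,
        "rate_per_s",
    )
    return RateBattery(mouse_id=mouse_id, functions=functions)


def ramp_battery(archive: SessionArchive, mouse_id: str) -> RampBattery:
    """18 kHz tone growth functions at the five standard onset ramps."""
    functions = _battery(
        archive,
        mouse_id,
        RAMP_TIMES_MS,
        lambda s, ramp: (
            s.kind == "tone"
            and s.masker is None
            and s.frequency_kHz == 18.0
            and s.duration_ms == 8.0
            and s.ramp_ms == ramp
        ),
        "ramp_ms",
    )
    return RampBattery(mouse_id=mouse_id, functions=functions)
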