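"""Longitudinal threshold-shift analysis after octave-band noise exposure.

Mice are tested before exposure and at 1 day, 3 days, 1 week, 2 weeks and
6 weeks afterwards.  The threshold shift at each frequency and timepoint
is ``threshold(t) - threshold(pre)``.  When the post-exposure threshold is
censored at the ceiling the shift is carried as a lower bound (">= ceiling
- pre"), never averaged as if exact.  Trajectories are summarised per
group and timepoint, split by position relative to the 8-16 kHz exposure
band (damage is typically largest above the band).  The 6-week archive
doubles as a standard full battery and feeds the same endpoint-comparison
harness, with sham-exposed and wildtype-exposed groups as controls and a
Bonferroni family of 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from abrkit.abr_io import ContractError, SessionArchive
from abrkit.group_statistics import (
    GroupComparison,
    compare_endpoints,
    threshold_endpoint_table,
)
from abrkit.waveform_metrics import ThresholdEstimate, estimate_threshold

__all__ = [
    "ExposureTimeline",
    "ShiftRecord",
    "build_timelines",
    "threshold_shift",
    "recovery_summary",
    "endpoint_comparison_noise",
    "band_position",
]

#: canonical follow-up schedule, days (PRE is -1)
SCHEDULE_DAYS = (-1.0, 1.0, 3.0, 7.0, 14.0, 42.0)
PRE_DAY = -1.0


@dataclass(frozen=True)
class ExposureTimeline:
    """Per-frequency threshold estimates across timepoints for one mouse."""

    mouse_id: str
    group: str
    thresholds: Mapping[float, Mapping[str, ThresholdEstimate]]  # day -> family

    def __post_init__(self) -> None:
        if PRE_DAY not in self.thresholds:
            raise ContractError(
                f"mouse {self.mouse_id}: pre-exposure timepoint missing"
            )


@dataclass(frozen=True)
class ShiftRecord:
    """Threshold shift for one (mouse, family, timepoint).

    ``kind`` is "exact", or "lower_bound" when the post threshold was
    censored (the true shift is at least ``shift_dB``).
    """

    mouse_id: str
    group: str
    family: str
    day: float
    shift_dB: float
    kind: str = "exact"


def band_position(family: str, band_kHz: tuple[float, float] = (8.0, 16.0)) -> str:
    """Classify a stimulus family relative to the exposure band."""
    if family == "click":
        return "click"
    f = float(family.removesuffix("kHz"))
    lo, hi = band_kHz
    if f < lo:
        return "below"
    if f <= hi:
        return "inside"
    return "above"


def build_timelines(
    archives: Mapping[float, SessionArchive]
) -> list[ExposureTimeline]:
    """Estimate per-mouse, per-family thresholds for each timepoint archive."""
    if PRE_DAY not in archives:
        raise ContractError("pre-exposure archive (day -1) missing")
    days = sorted(archives)
    mouse_ids = archives[PRE_DAY].mouse_ids()
    timelines = []
    for mouse_id in mouse_ids:
        per_day: dict[float, dict[str, ThresholdEstimate]] = {}
        for day in days:
            archive = archives[day]
            if mouse_id not in archive.mouse_ids():
                continue
            families: dict[str, list] = {}
            for w in archive.waveforms_for(
                mouse_id,
                lambda s: s.masker is None
                and (
                    s.kind == "click"
                    or (s.kind == "tone" and s.duration_ms == 5.0)
                ),
            ):
                families.setdefault(w.stimulus.family, []).append(w)
            per_day[day] = {}
            for family, series in sorted(families.items()):
                series.sort(key=lambda w: w.stimulus.level_dB_SPL)
                if len(series) >= 4:
                    per_day[day][family] = estimate_threshold(series)
        timelines.append(
            ExposureTimeline(
                mouse_id=mouse_id,
                group=archives[PRE_DAY].genotype_of(mouse_id),
                thresholds=per_day,
            )
        )
    return timelines


def threshold_shift(timeline: ExposureTimeline) -> list[ShiftRecord]:
    """Shift table for one mouse: threshold(t) - threshold(pre) per family.

    Families whose pre-exposure threshold is censored are excluded (no
    finite baseline).  A censored post-exposure threshold produces a
    lower-bound record ``>= ceiling - pre``.
    """
    pre = timeline.thresholds[PRE_DAY]
    records = []
    for day in sorted(timeline.thresholds):
        for family, est in sorted(timeline.thresholds[day].items()):
            baseline = pre.get(family)
            if baseline is None or baseline.censored:
                continue
            if est.censored:
                records.append(
                    ShiftRecord(
                        mouse_id=timeline.mouse_id,
                        group=timeline.group,
                        family=family,
                        day=day,
                        shift_dB=est.ceiling_dB_SPL - baseline.threshold_dB_SPL,
                        kind="lower_bound",
                    )
                )
            else:
                records.append(
                    ShiftRecord(
                        mouse_id=timeline.mouse_id,
                        group=timeline.group,
                        family=family,
                        day=day,
                        shift_dB=est.threshold_dB_SPL - baseline.threshold_dB_SPL,
                        kind="exact",
                    )
                )
    return records


def recovery_summary(
    shifts: Sequence[ShiftRecord],
    band_kHz: tuple[float, float] = (8.0, 16.0),
) -> pd.DataFrame:
    """Mean +/- SD shift per (group, timepoint, band position).

    Lower-bound records are counted separately (``n_lower_bound``) and
    never averaged as exact values.
    """
    if not shifts:
        raise ContractError("empty shift table")
    rows = [
        {
            "group": s.group,
            "day": s.day,
            "band": band_position(s.family, band_kHz),
            "shift_dB": s.shift_dB,
            "kind": s.kind,
        }
        for s in shifts
    ]
    df = pd.DataFrame(rows)
    if df.loc[df["band"].isin(["below", "inside", "above"])].empty:
        raise ContractError("no tone families fall in or around the band")
    out = []
    for (group, day, band), sub in df.groupby(["group", "day", "band"], sort=True):
        exact = sub.loc[sub["kind"] == "exact", "shift_dB"]
        out.append(
            {
                "group": group,
                "day": day,
                "band": band,
                "mean_shift_dB": float(exact.mean()) if len(exact) else float("nan"),
                "sd_shift_dB": float(exact.std(ddof=1)) if len(exact) > 1 else 0.0,
                "n": int(len(exact)),
                "n_lower_bound": int((sub["kind"] == "lower_bound").sum()),
                "min_lower_bound_dB": (
                    float(sub.loc[sub["kind"] == "lower_bound", "shift_dB"].min())
                    if (sub["kind"] == "lower_bound").any()
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(out)


def endpoint_comparison_noise(
    archive: SessionArchive,
    *,
    sham_group: str = "sham",
    wildtype_group: str = "wildtype_exposed",
    family_alpha: float = 0.05,
    family_size: int = 4,
    mode: str = "pooled",
) -> dict[str, list[GroupComparison]]:
    """Noise-block comparison table on the 6-week archive.

    Runs the endpoint harness twice: once with the sham-exposed group as
    control ("vs SHAM" rows) and once with the wildtype-exposed group
    ("vs WT" rows), Bonferroni family of 4.
    """
    table = threshold_endpoint_table(archive)
    groups = set(table["group"])
    out: dict[str, list[GroupComparison]] = {}
    for label, control in (("vs_sham", sham_group), ("vs_wildtype", wildtype_group)):
        if control not in groups:
            out[label] = []
            continue
        out[label] = compare_endpoints(
            table,
            control,
            family_alpha=family_alpha,
            family_size=family_size,
            mode=mode,
        )
    return out
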