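"""Domain types, TSV archive formats and configuration.

An ABR session archive is a directory holding three plain-text files:

``mice.tsv``
    one row per animal: ``mouse_id``, ``genotype``, ``age_weeks``, ``line``.
``waveforms.tsv``
    one row per averaged waveform: the stimulus descriptor columns, the
    acquisition parameters, and the sampled trace (microvolts) as a single
    comma-joined field.  One row per waveform keeps the (mouse, stimulus)
    key atomic and the files compact.
``provenance.txt``
    free-text provenance; simulated archives record the generator seed.

``read_archive`` also accepts a bare ``waveforms.tsv`` file, in which case
mouse records are synthesised with unknown genotype.

Units are fixed throughout the package: microvolts for trace amplitude,
milliseconds for time, dB SPL for stimulus level.  Sensation level (dB SL,
level above an individual threshold) is always derived, never stored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "StimulusSpec",
    "MaskerSpec",
    "MouseRecord",
    "AveragedWaveform",
    "SessionArchive",
    "ArchiveFormatError",
    "ArchiveValidationError",
    "ContractError",
    "read_archive",
    "write_archive",
    "load_config",
    "DEFAULT_CONFIG",
]

#: tone frequencies (kHz) of the standard threshold battery
THRESHOLD_TONE_KHZ = (3.0, 6.0, 12.0, 18.0, 24.0, 30.0, 36.0, 42.0)
#: stimulus levels of the standard level series, dB SPL
LEVEL_GRID_DB = tuple(float(v) for v in range(0, 100, 5))
#: masker/probe frequency ratios of the tuning-curve paradigm
TUNING_RATIOS = (0.5, 0.7, 0.9, 0.95, 1.0, 1.05, 1.1, 1.3, 1.6)
#: masker-probe gaps (ms) of the forward-masking recovery paradigm
RECOVERY_GAPS_MS = (4.0, 8.0, 16.0, 32.0, 64.0)
#: gap (ms) encoding the reference click, 150 ms after onset of the 10 ms masker
REFERENCE_GAP_MS = 140.0
#: click presentation rates of the rate-adaptation battery, per second
CLICK_RATES_PER_S = (10.65, 21.3, 42.6, 85.2)
#: onset/offset ramp times of the desynchronisation battery, ms
RAMP_TIMES_MS = (0.25, 0.5, 1.0, 2.0, 4.0)
#: standard presentation rate of the threshold battery, per second
DEFAULT_RATE_PER_S = 42.6


class ArchiveFormatError(ValueError):
    """A required column or file is missing or malformed."""


class ArchiveValidationError(ValueError):
    """Archive content violates a structural invariant."""


class ContractError(ValueError):
    """An operation was called outside its contract."""


@dataclass(frozen=True)
class MaskerSpec:
    """Forward masker preceding a probe stimulus.

    ``gap_ms`` is measured from masker offset to probe onset.
    """

    kind: str  # "tone" | "broadband"
    level_dB_SPL: float
    duration_ms: float = 10.0
    gap_ms: float = 4.0
    frequency_kHz: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("tone", "broadband"):
            raise ContractError(f"unknown masker kind {self.kind!r}")
        if self.kind == "tone" and (
            self.frequency_kHz is None or self.frequency_kHz <= 0
        ):
            raise ContractError("tone masker requires a positive frequency_kHz")
        if self.duration_ms <= 0:
            raise ContractError("masker duration must be positive")
        if self.gap_ms < 0:
            raise ContractError("masker gap must be non-negative")

    def sort_key(self) -> tuple:
        return (
            self.kind,
            -1.0 if self.frequency_kHz is None else self.frequency_kHz,
            self.level_dB_SPL,
            self.duration_ms,
            self.gap_ms,
        )


@dataclass(frozen=True)
class StimulusSpec:
    """One acoustic stimulus of the battery.

    Clicks are 10 microseconds long by convention and carry no frequency;
    tone pips carry a frequency in kHz and an onset/offset ramp.
    """

    kind: str  # "click" | "tone" | "noise_burst"
    level_dB_SPL: float
    frequency_kHz: float | None = None
    duration_ms: float = 0.01
    ramp_ms: float = 0.0
    rate_per_s: float = DEFAULT_RATE_PER_S
    masker: MaskerSpec | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("click", "tone", "noise_burst"):
            raise ContractError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "tone":
            if self.frequency_kHz is None or self.frequency_kHz <= 0:
                raise ContractError("tone requires a positive frequency_kHz")
        elif self.frequency_kHz is not None:
            raise ContractError(f"{self.kind} stimulus must not carry a frequency")
        if self.duration_ms <= 0:
            raise ContractError("duration must be positive")
        if self.ramp_ms < 0:
            raise ContractError("ramp must be non-negative")
        # <= admits fully ramped tones (e.g. the 8 ms stimulus with 4 ms
        # onset and offset ramps of the desynchronisation battery)
        if self.ramp_ms > self.duration_ms / 2:
            raise ContractError("ramp_ms must be <= duration_ms / 2")
        if self.rate_per_s <= 0:
            raise ContractError("rate must be positive")

    @property
    def family(self) -> str:
        """Stimulus family key: ``"click"`` or the tone frequency in kHz."""
        if self.kind == "click":
            return "click"
        if self.kind == "tone":
            return f"{self.frequency_kHz:g}kHz"
        return "noise_burst"

    def sort_key(self) -> tuple:
        """Total order over stimulus descriptors (deterministic archives)."""
        kind_rank = {"click": 0, "tone": 1, "noise_burst": 2}[self.kind]
        masker_key = ("",) if self.masker is None else self.masker.sort_key()
        return (
            kind_rank,
            -1.0 if self.frequency_kHz is None else self.frequency_kHz,
            self.rate_per_s,
            self.ramp_ms,
            self.duration_ms,
            masker_key,
            self.level_dB_SPL,
        )


@dataclass(frozen=True)
class MouseRecord:
    mouse_id: str
    genotype: str = "unknown"
    age_weeks: float = float("nan")
    line: str = ""


@dataclass
class AveragedWaveform:
    """One stimulus-locked averaged evoked-potential trace (microvolts)."""

    mouse_id: str
    stimulus: StimulusSpec
    samples: np.ndarray
    sample_rate_kHz: float = 9.75
    window_ms: float = 20.0
    n_sweeps: int = 256

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        expected = round(self.sample_rate_kHz * self.window_ms)
        if self.samples.size != expected:
            raise ArchiveValidationError(
                f"waveform ({self.mouse_id}, {self.stimulus.family}, "
                f"{self.stimulus.level_dB_SPL:g} dB): {self.samples.size} samples, "
                f"expected {expected} for {self.sample_rate_kHz:g} kHz x "
                f"{self.window_ms:g} ms"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ArchiveValidationError(
                f"waveform ({self.mouse_id}, {self.stimulus.family}) has "
                "non-finite samples"
            )

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate_kHz

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AveragedWaveform):
            return NotImplemented
        return (
            self.mouse_id == other.mouse_id
            and self.stimulus == other.stimulus
            and self.sample_rate_kHz == other.sample_rate_kHz
            and self.window_ms == other.window_ms
            and self.n_sweeps == other.n_sweeps
            and np.array_equal(self.samples, other.samples)
        )


@dataclass
class SessionArchive:
    """A set of mice with their averaged waveforms."""

    mice: list[MouseRecord] = field(default_factory=list)
    waveforms: list[AveragedWaveform] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()
        self.sort()

    def validate(self) -> None:
        ids = {m.mouse_id for m in self.mice}
        if len(ids) != len(self.mice):
            raise ArchiveValidationError("duplicate mouse_id in mouse table")
        seen: set[tuple] = set()
        for w in self.waveforms:
            if w.mouse_id not in ids:
                raise ArchiveValidationError(
                    f"waveform references unknown mouse {w.mouse_id!r}"
                )
            key = (w.mouse_id, w.stimulus)
            if key in seen:
                raise ArchiveValidationError(
                    f"duplicate (mouse, stimulus) key: {w.mouse_id}, {w.stimulus}"
                )
            seen.add(key)

    def sort(self) -> None:
        self.mice.sort(key=lambda m: m.mouse_id)
        self.waveforms.sort(key=lambda w: (w.mouse_id, w.stimulus.sort_key()))

    def genotype_of(self, mouse_id: str) -> str:
        for m in self.mice:
            if m.mouse_id == mouse_id:
                return m.genotype
        raise KeyError(mouse_id)

    def mouse_ids(self) -> list[str]:
        return [m.mouse_id for m in self.mice]

    def waveforms_for(
        self, mouse_id: str, predicate=None
    ) -> list[AveragedWaveform]:
        out = [w for w in self.waveforms if w.mouse_id == mouse_id]
        if predicate is not None:
            out = [w for w in out if predicate(w.stimulus)]
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SessionArchive):
            return NotImplemented
        return (
            self.mice == other.mice
            and self.provenance == other.provenance
            and len(self.waveforms) == len(other.waveforms)
            and all(a == b for a, b in zip(self.waveforms, other.waveforms))
        )


# ---------------------------------------------------------------------------
# serialisation

_MICE_COLUMNS = ["mouse_id", "genotype", "age_weeks", "line"]
_WAVEFORM_COLUMNS = [
    "mouse_id",
    "kind",
    "frequency_kHz",
    "level_dB_SPL",
    "duration_ms",
    "ramp_ms",
    "rate_per_s",
    "masker_kind",
    "masker_frequency_kHz",
    "masker_level_dB_SPL",
    "masker_duration_ms",
    "masker_gap_ms",
    "sample_rate_kHz",
    "window_ms",
    "n_sweeps",
    "samples",
]


def _fmt(value: float | None) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and math.isnan(value):
        return "nan"
    # repr round-trips floats exactly (>= 9 significant digits)
    return repr(float(value))


def _parse_float(text: str) -> float | None:
    text = text.strip()
    if not text:
        return None
    return float(text)


def write_archive(archive: SessionArchive, path: str | Path) -> None:
    """Write ``archive`` to directory ``path`` (created if absent).

    Two writes of the same archive produce byte-identical files; floats are
    serialised with full round-trip precision.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "mice.tsv", "w") as fh:
        fh.write("\t".join(_MICE_COLUMNS) + "\n")
        for m in archive.mice:
            fh.write(
                f"{m.mouse_id}\t{m.genotype}\t{_fmt(m.age_weeks)}\t{m.line}\n"
            )
    with open(path / "waveforms.tsv", "w") as fh:
        fh.write("\t".join(_WAVEFORM_COLUMNS) + "\n")
        for w in archive.waveforms:
            s = w.stimulus
            mk = s.masker
            row = [
                w.mouse_id,
                s.kind,
                _fmt(s.frequency_kHz),
                _fmt(s.level_dB_SPL),
                _fmt(s.duration_ms),
                _fmt(s.ramp_ms),
                _fmt(s.rate_per_s),
                mk.kind if mk else "",
                _fmt(mk.frequency_kHz if mk else None),
                _fmt(mk.level_dB_SPL if mk else None),
                _fmt(mk.duration_ms if mk else None),
                _fmt(mk.gap_ms if mk else None),
                _fmt(w.sample_rate_kHz),
                _fmt(w.window_ms),
                str(w.n_sweeps),
                ",".join(repr(float(v)) for v in w.samples),
            ]
            fh.write("\t".join(row) + "\n")
    with open(path / "provenance.txt", "w") as fh:
        fh.write(archive.provenance)


def _read_tsv_rows(path: Path, required: Sequence[str]) -> list[dict[str, str]]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ArchiveFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    for col in required:
        if col not in header:
            raise ArchiveFormatError(f"{path}: missing required column {col!r}")
    rows = []
    for line in lines[1:]:
        if not line.strip():
            continue
        values = line.split("\t")
        if len(values) != len(header):
            raise ArchiveFormatError(
                f"{path}: row has {len(values)} fields, header has {len(header)}"
            )
        rows.append(dict(zip(header, values)))
    return rows


def _waveform_from_row(row: Mapping[str, str]) -> AveragedWaveform:
    masker = None
    if row["masker_kind"].strip():
        masker = MaskerSpec(
            kind=row["masker_kind"],
            frequency_kHz=_parse_float(row["masker_frequency_kHz"]),
            level_dB_SPL=_parse_float(row["masker_level_dB_SPL"]),
            duration_ms=_parse_float(row["masker_duration_ms"]),
            gap_ms=_parse_float(row["masker_gap_ms"]),
        )
    stimulus = StimulusSpec(
        kind=row["kind"],
        frequency_kHz=_parse_float(row["frequency_kHz"]),
        level_dB_SPL=_parse_float(row["level_dB_SPL"]),
        duration_ms=_parse_float(row["duration_ms"]),
        ramp_ms=_parse_float(row["ramp_ms"]) or 0.0,
        rate_per_s=_parse_float(row["rate_per_s"]),
        masker=masker,
    )
    samples_field = row["samples"].strip()
    samples = (
        np.array([float(v) for v in samples_field.split(",")])
        if samples_field
        else np.array([])
    )
    return AveragedWaveform(
        mouse_id=row["mouse_id"],
        stimulus=stimulus,
        samples=samples,
        sample_rate_kHz=_parse_float(row["sample_rate_kHz"]),
        window_ms=_parse_float(row["window_ms"]),
        n_sweeps=int(row["n_sweeps"]),
    )


def read_archive(path: str | Path) -> SessionArchive:
    """Read a session archive from a directory or a bare waveform TSV."""
    path = Path(path)
    if path.is_dir():
        mice_rows = _read_tsv_rows(path / "mice.tsv", _MICE_COLUMNS)
        mice = [
            MouseRecord(
                mouse_id=r["mouse_id"],
                genotype=r["genotype"],
                age_weeks=(
                    _parse_float(r["age_weeks"])
                    if r["age_weeks"].strip()
                    else float("nan")
                ),
                line=r["line"],
            )
            for r in mice_rows
        ]
        wf_rows = _read_tsv_rows(path / "waveforms.tsv", _WAVEFORM_COLUMNS)
        provenance_file = path / "provenance.txt"
        provenance = (
            provenance_file.read_text() if provenance_file.exists() else ""
        )
    elif path.is_file():
        wf_rows = _read_tsv_rows(path, _WAVEFORM_COLUMNS)
        mice = [
            MouseRecord(mouse_id=mid)
            for mid in sorted({r["mouse_id"] for r in wf_rows})
        ]
        provenance = ""
    else:
        raise ArchiveFormatError(f"no such archive: {path}")
    waveforms = [_waveform_from_row(r) for r in wf_rows]
    return SessionArchive(mice=mice, waveforms=waveforms, provenance=provenance)


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict = {
    "control_genotype": "wildtype",
    "family_alpha": 0.05,
    "bonferroni_family_main": 12,
    "bonferroni_family_noise": 4,
    "masked_threshold_criterion": 0.5,
    "threshold_sigma_multiple": 4.0,
    "threshold_amplitude_floor_uV": 0.1,
    "probe_sensation_level_dB": 20.0,
    "exposure_band_kHz": [8.0, 16.0],
}


def load_config(path: str | Path | None = None) -> dict:
    """Return the analysis configuration, merging a YAML file over defaults."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ArchiveFormatError(f"{path}: config must be a mapping")
        config.update(user)
    return config
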