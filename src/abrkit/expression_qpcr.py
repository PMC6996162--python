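"""Relative gene expression by the 2^-ddCt method.

Each mouse contributes triplicate cycle-threshold (Ct) values for the
target gene and for a housekeeping reference gene (Hprt in the standard
assay).  Per mouse, dCt = mean(Ct_target) - mean(Ct_reference); ddCt
subtracts the mean dCt of the calibrator genotype (wildtype), and the fold
change is 2^-ddCt.  The calibrator's mean fold change is 1 by construction.
Amplification efficiency is fixed at 2.0, the method's assumption; no
standard-curve efficiency correction is applied.

Per-mouse fold changes are exponentiated first and then averaged within
genotype; the genotype SD is taken over per-mouse fold changes.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Sequence

from abrkit.abr_io import ContractError

__all__ = ["CtRecord", "FoldChangeResult", "delta_delta_ct", "read_ct_table", "write_fold_changes"]


@dataclass(frozen=True)
class CtRecord:
    """Triplicate Ct values for one (mouse, gene)."""

    mouse_id: str
    genotype: str
    gene: str  # "target" | "reference"
    ct_values: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.gene not in ("target", "reference"):
            raise ContractError(f"gene must be 'target' or 'reference', got {self.gene!r}")
        if len(self.ct_values) != 3:
            raise ContractError(
                f"mouse {self.mouse_id}: expected exactly 3 Ct replicates, "
                f"got {len(self.ct_values)}"
            )
        for ct in self.ct_values:
            if not 0.0 < ct < 45.0:
                raise ContractError(
                    f"mouse {self.mouse_id}: Ct value {ct} outside (0, 45)"
                )

    @property
    def mean_ct(self) -> float:
        return sum(self.ct_values) / 3.0


@dataclass(frozen=True)
class FoldChangeResult:
    genotype: str
    mean_fold_change: float
    sd_fold_change: float
    n_mice: int


def delta_delta_ct(
    records: Sequence[CtRecord], calibrator_genotype: str = "wildtype"
) -> list[FoldChangeResult]:
    """Per-genotype mean and SD of 2^-ddCt fold changes.

    Raises :class:`~abrkit.abr_io.ContractError` if any mouse lacks a
    target or reference triplicate, or if the calibrator genotype is
    absent.
    """
    by_mouse: dict[str, dict[str, CtRecord]] = {}
    genotype_of: dict[str, str] = {}
    for rec in records:
        slot = by_mouse.setdefault(rec.mouse_id, {})
        if rec.gene in slot:
            raise ContractError(
                f"mouse {rec.mouse_id}: duplicate {rec.gene} triplicate"
            )
        slot[rec.gene] = rec
        genotype_of[rec.mouse_id] = rec.genotype

    delta_ct: dict[str, float] = {}
    for mouse_id, slot in by_mouse.items():
        for gene in ("target", "reference"):
            if gene not in slot:
                raise ContractError(f"mouse {mouse_id}: missing {gene} triplicate")
        delta_ct[mouse_id] = slot["target"].mean_ct - slot["reference"].mean_ct

    calibrators = [
        dct for mid, dct in delta_ct.items() if genotype_of[mid] == calibrator_genotype
    ]
    if not calibrators:
        raise ContractError(f"no mice of calibrator genotype {calibrator_genotype!r}")
    calibrator_mean = sum(calibrators) / len(calibrators)

    folds: dict[str, list[float]] = {}
    for mouse_id, dct in delta_ct.items():
        folds.setdefault(genotype_of[mouse_id], []).append(
            2.0 ** -(dct - calibrator_mean)
        )

    results = []
    for genotype in sorted(folds):
        values = folds[genotype]
        results.append(
            FoldChangeResult(
                genotype=genotype,
                mean_fold_change=sum(values) / len(values),
                sd_fold_change=statistics.stdev(values) if len(values) > 1 else 0.0,
                n_mice=len(values),
            )
        )
    return results


# ---------------------------------------------------------------------------
# TSV plumbing for the CLI

_CT_COLUMNS = ["mouse_id", "genotype", "gene", "ct1", "ct2", "ct3"]


def read_ct_table(path) -> list[CtRecord]:
    """Read CtRecords from a TSV with columns mouse_id, genotype, gene, ct1-3."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    header = lines[0].split("\t")
    for col in _CT_COLUMNS:
        if col not in header:
            raise ContractError(f"{path}: missing required column {col!r}")
    records = []
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        records.append(
            CtRecord(
                mouse_id=row["mouse_id"],
                genotype=row["genotype"],
                gene=row["gene"],
                ct_values=(float(row["ct1"]), float(row["ct2"]), float(row["ct3"])),
            )
        )
    return records


def write_fold_changes(results: Sequence[FoldChangeResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("genotype\tmean_fold_change\tsd_fold_change\tn_mice\n")
        for r in results:
            fh.write(
                f"{r.genotype}\t{r.mean_fold_change:.6g}\t{r.sd_fold_change:.6g}\t{r.n_mice}\n"
            )
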