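"""Reference ranges and nonparametric group comparison versus control.

Mutant groups are judged against a pooled wildtype control dataset.  For
each endpoint a Kruskal-Wallis one-way ANOVA on ranks is followed by
Dunn's method of multiple comparisons versus the control group; the
significance level is Bonferroni-corrected for the number of test groups
(0.05/12 for the main battery, 0.05/4 for noise-exposure groups).

Rank statistics are computed with mid-ranks and the standard tie
correction:

    H = [12/(N(N+1)) * sum n_i R_i^2 - 3(N+1)] / (1 - sum(t^3 - t)/(N^3 - N))

    Q_i = |R_i - R_c| / sqrt[(N(N+1)/12 - sum(t^3 - t)/(12(N-1)))
                             * (1/n_i + 1/n_c)]

with the Dunn p-value adjusted two-sidedly, ``min(1, m * 2 * (1 -
Phi(Q)))`` for ``m`` comparisons (this Bonferroni-style scaling produces
the capped p = 1 entries typical of such tables).

Wildtype reference ranges span the 2.5th to 97.5th percentile of pooled
control values, computed by inclusive linear interpolation of order
statistics so that the band is reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from abrkit.abr_io import ContractError, SessionArchive
from abrkit.waveform_metrics import estimate_threshold

__all__ = [
    "ReferenceRange",
    "DunnComparison",
    "GroupComparison",
    "reference_range",
    "kruskal_wallis",
    "dunns_vs_control",
    "bonferroni_alpha",
    "format_alpha",
    "check_normality",
    "compare_endpoints",
    "threshold_endpoint_table",
]


@dataclass(frozen=True)
class ReferenceRange:
    stimulus_family: str
    lo: float
    hi: float
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class DunnComparison:
    group: str
    q: float
    p_adjusted: float
    significant: bool
    n: int


@dataclass(frozen=True)
class GroupComparison:
    """One endpoint's omnibus test plus per-group Dunn comparisons."""

    endpoint: str
    condition: str
    h: float
    df: int
    p_omnibus: float
    comparisons: tuple[DunnComparison, ...]
    alpha: float  # Bonferroni-corrected per-test significance level
    control: str


def reference_range(
    values: Sequence[float],
    lo_pct: float = 2.5,
    hi_pct: float = 97.5,
    stimulus_family: str = "",
) -> ReferenceRange:
    """2.5-97.5 percentile reference band with mean and SD.

    Percentiles use inclusive linear interpolation of order statistics
    (for values 1..100 the 2.5th percentile is 3.475).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ContractError("reference range needs n >= 2")
    lo, hi = np.percentile(values, [lo_pct, hi_pct], method="linear")
    return ReferenceRange(
        stimulus_family=stimulus_family,
        lo=float(lo),
        hi=float(hi),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        n=int(values.size),
    )


def _pooled_ranks(groups: Sequence[Sequence[float]]):
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    return split, pooled.size, tie_term


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal-Wallis H, degrees of freedom and chi-square p-value.

    Uses mid-ranks and the tie correction; a sample in which every value
    is identical returns H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ContractError("kruskal_wallis needs >= 2 groups")
    if any(len(g) < 1 for g in groups):
        raise ContractError("every group needs n >= 1")
    split, n_total, tie_term = _pooled_ranks(groups)
    if n_total < 3:
        raise ContractError("kruskal_wallis needs total N >= 3")
    df = len(groups) - 1
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    if correction <= 0:  # all values tied
        return 0.0, df, 1.0
    h_uncorrected = (
        12.0 / (n_total * (n_total + 1))
        * sum(len(r) * r.mean() ** 2 for r in split)
        - 3.0 * (n_total + 1)
    )
    h = h_uncorrected / correction
    p = float(sps.chi2.sf(h, df))
    return float(h), df, p


def dunns_vs_control(
    groups: Sequence[Sequence[float]],
    control_index: int = 0,
    n_comparisons: int | None = None,
) -> list[tuple[float, float]]:
    """Dunn's (Q, adjusted p) for each non-control group versus control.

    ``n_comparisons`` defaults to the number of non-control groups; the
    two-sided p is scaled by it and capped at 1.
    """
    if any(len(g) < 1 for g in groups):
        raise ContractError("every group needs n >= 1")
    if not 0 <= control_index < len(groups):
        raise ContractError("control_index out of range")
    if n_comparisons is None:
        n_comparisons = len(groups) - 1
    split, n_total, tie_term = _pooled_ranks(groups)
    variance = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        variance -= tie_term / (12.0 * (n_total - 1))
    control_rank = split[control_index].mean()
    n_control = len(split[control_index])
    out = []
    for i, ranks in enumerate(split):
        if i == control_index:
            continue
        se = math.sqrt(variance * (1.0 / len(ranks) + 1.0 / n_control))
        q = abs(ranks.mean() - control_rank) / se if se > 0 else 0.0
        p = min(1.0, n_comparisons * 2.0 * float(sps.norm.sf(q)))
        out.append((float(q), p))
    return out


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-test significance level ``family_alpha / m``."""
    if not 0.0 < family_alpha < 1.0:
        raise ContractError("family_alpha must lie in (0, 1)")
    if m < 1:
        raise ContractError("m must be a positive integer")
    return family_alpha / m


def format_alpha(alpha: float) -> str:
    """Display form of a significance level, 3 significant figures."""
    return f"{alpha:.3g}"


def check_normality(values: Sequence[float]) -> float:
    """Shapiro-Wilk p-value (3 <= n <= 5000).

    Logged for the parametric/nonparametric routing decision only; the
    nonparametric path is always taken for battery endpoints.
    """
    values = np.asarray(values, dtype=float)
    if not 3 <= values.size <= 5000:
        raise ContractError("Shapiro-Wilk requires 3 <= n <= 5000")
    return float(sps.shapiro(values).pvalue)


# ---------------------------------------------------------------------------
# endpoint harness

#: censored thresholds are imputed one grid step above the ceiling for
#: group comparison, so absent responses rank above every measurable one
CENSORED_IMPUTE_OFFSET_DB = 5.0


def threshold_endpoint_table(archive: SessionArchive) -> pd.DataFrame:
    """Tidy threshold endpoint table: one row per (mouse, family).

    Columns: endpoint, condition, group, mouse_id, value, censored.
    Censored thresholds are imputed at ceiling + 5 dB (they rank above all
    finite thresholds; the flag is retained).
    """
    rows = []
    for mouse_id in archive.mouse_ids():
        genotype = archive.genotype_of(mouse_id)
        families: dict[str, list] = {}
        for w in archive.waveforms_for(
            mouse_id,
            lambda s: s.masker is None
            and (
                (s.kind == "click" and s.rate_per_s == 42.6)
                or (s.kind == "tone" and s.duration_ms == 5.0)
            ),
        ):
            families.setdefault(w.stimulus.family, []).append(w)
        for family, series in sorted(families.items()):
            series.sort(key=lambda w: w.stimulus.level_dB_SPL)
            if len(series) < 4:
                continue
            est = estimate_threshold(series)
            rows.append(
                {
                    "endpoint": "abr_threshold",
                    "condition": family,
                    "group": genotype,
                    "mouse_id": mouse_id,
                    "value": est.value_or(
                        est.ceiling_dB_SPL + CENSORED_IMPUTE_OFFSET_DB
                    ),
                    "censored": est.censored,
                }
            )
    return pd.DataFrame(rows)


def compare_endpoints(
    table: pd.DataFrame,
    control: str,
    *,
    family_alpha: float = 0.05,
    family_size: int | None = None,
    mode: str = "pooled",
) -> list[GroupComparison]:
    """Table-style comparison report over a tidy endpoint table.

    ``table`` columns: endpoint, condition, group, mouse_id, value.  In
    ``pooled`` mode each mouse contributes its mean value across
    conditions, yielding one comparison per endpoint (one Q per group per
    endpoint); ``per_condition`` mode emits one comparison per (endpoint,
    condition).  ``family_size`` defaults to the number of test groups.
    Groups missing an endpoint are reported with an NaN Q rather than
    silently dropped.
    """
    if mode not in ("pooled", "per_condition"):
        raise ContractError(f"unknown mode {mode!r}")
    required = {"endpoint", "condition", "group", "mouse_id", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ContractError(f"endpoint table missing columns {sorted(missing)}")
    if control not in set(table["group"]):
        raise ContractError(f"control group {control!r} absent from table")

    all_groups = sorted(set(table["group"]) - {control})
    if family_size is None:
        family_size = max(1, len(all_groups))
    alpha = bonferroni_alpha(family_alpha, family_size)

    results = []
    for endpoint, ep_table in table.groupby("endpoint", sort=True):
        if mode == "pooled":
            pooled = (
                ep_table.groupby(["group", "mouse_id"], sort=True)["value"]
                .mean()
                .reset_index()
            )
            units = [("all", pooled)]
        else:
            units = [
                (str(cond), sub)
                for cond, sub in ep_table.groupby("condition", sort=True)
            ]
        for condition, sub in units:
            present = [
                g for g in all_groups if (sub["group"] == g).any()
            ]
            samples = [sub.loc[sub["group"] == control, "value"].to_numpy()] + [
                sub.loc[sub["group"] == g, "value"].to_numpy() for g in present
            ]
            if samples[0].size == 0:
                continue
            if len(samples) < 2:
                h, df, p_omnibus, dunn = float("nan"), 0, float("nan"), []
            else:
                h, df, p_omnibus = kruskal_wallis(samples)
                dunn = dunns_vs_control(samples, 0, n_comparisons=family_size)
            comparisons = []
            for g, (q, p) in zip(present, dunn):
                comparisons.append(
                    DunnComparison(
                        group=g,
                        q=q,
                        p_adjusted=p,
                        significant=p < alpha,
                        n=int((sub["group"] == g).sum()),
                    )
                )
            for g in all_groups:
                if g not in present:
                    comparisons.append(
                        DunnComparison(
                            group=g,
                            q=float("nan"),
                            p_adjusted=float("nan"),
                            significant=False,
                            n=0,
                        )
                    )
            results.append(
                GroupComparison(
                    endpoint=str(endpoint),
                    condition=condition,
                    h=h,
                    df=df,
                    p_omnibus=p_omnibus,
                    comparisons=tuple(comparisons),
                    alpha=alpha,
                    control=control,
                )
            )
    return results
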