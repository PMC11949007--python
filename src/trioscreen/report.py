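"""Cohort-level summaries: diagnostic yield, suture distribution, MPV carriers.

All percentages are recomputed from integer counts at call time and
rounded half-up to one decimal, so a count -> percent -> report round
trip can never drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SINGLE_SUTURES",
    "CohortSummary",
    "percent",
    "diagnostic_yield",
    "suture_distribution",
    "detect_mpv",
]

SINGLE_SUTURES = ("sagittal", "coronal", "lambdoid", "metopic")


def percent(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-up to one decimal."""
    if denominator == 0:
        raise ValueError("denominator must be positive")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """Counts over probands; percentages are always derived, never stored."""

    n_probands: int
    n_trios: int
    n_singletons: int
    n_with_plp: int  # probands carrying >= 1 P/LP variant
    n_denovo_plp_probands: int  # trio probands with a de novo P/LP variant
    suture_counts: dict[str, int] = field(default_factory=dict)  # single sutures + "multiple"
    mpv_probands: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = [self.n_probands, self.n_trios, self.n_singletons, self.n_with_plp, self.n_denovo_plp_probands]
        if any(c < 0 for c in counts) or any(c < 0 for c in self.suture_counts.values()):
            raise ValueError("counts must be non-negative")
        if self.suture_counts:
            total = sum(self.suture_counts.get(s, 0) for s in SINGLE_SUTURES) + self.suture_counts.get("multiple", 0)
            if total != self.n_probands:
                raise ValueError(
                    f"suture counts sum to {total}, expected n_probands={self.n_probands}"
                )


def diagnostic_yield(summary: CohortSummary) -> dict[str, float]:
    """Molecular diagnostic yield as percentages.

    overall_pct: probands with >= 1 P/LP variant over all probands;
    trio_denovo_pct: trio probands with a de novo P/LP variant over trios.
    """
    if summary.n_probands == 0:
        raise ValueError("empty cohort")
    out = {"overall_pct": percent(summary.n_with_plp, summary.n_probands)}
    if summary.n_trios > 0:
        out["trio_denovo_pct"] = percent(summary.n_denovo_plp_probands, summary.n_trios)
    return out


def suture_distribution(summary: CohortSummary) -> dict[str, float]:
    """Percent of probands per affected suture category, plus the
    single-suture total."""
    if summary.n_probands == 0:
        raise ValueError("empty cohort")
    out = {s: percent(summary.suture_counts.get(s, 0), summary.n_probands) for s in SINGLE_SUTURES}
    out["multiple"] = percent(summary.suture_counts.get("multiple", 0), summary.n_probands)
    n_single = sum(summary.suture_counts.get(s, 0) for s in SINGLE_SUTURES)
    out["single_suture_pct"] = percent(n_single, summary.n_probands)
    return out


def detect_mpv(plp_calls: pd.DataFrame | Iterable[tuple[str, str]]) -> list[str]:
    """Probands with multilocus pathogenic variation.

    Input is (proband, gene) records for P/LP variants (a DataFrame with
    ``proband``/``gene`` columns, optionally a ``label`` column restricted
    to P/LP, or an iterable of tuples).  A proband is flagged when it
    carries P/LP variants in two or more distinct genes; duplicate records
    and multiple variants in one gene do not count twice.
    """
    if isinstance(plp_calls, pd.DataFrame):
        df = plp_calls
        if "label" in df.columns:
            df = df[df["label"].isin(["P", "LP"])]
        records = list(zip(df["proband"], df["gene"]))
    else:
        records = list(plp_calls)
    genes_by_proband: dict[str, set[str]] = {}
    for proband, gene in records:
        genes_by_proband.setdefault(str(proband), set()).add(str(gene).strip().upper())
    return sorted(p for p, genes in genes_by_proband.items() if len(genes) >= 2)
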