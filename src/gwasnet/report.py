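"""Reporting helpers: rounded percentages and the study summary table."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["percent", "fraction_report", "study_summary"]


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded half-up to ``decimals`` places (as tables print it)."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    value = Decimal(100 * numerator) / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def fraction_report(counts: Mapping[str, tuple[int, int]], decimals: int = 1
                    ) -> dict[str, float]:
    """Map of label -> rounded percentage for (numerator, denominator) pairs."""
    return {k: percent(n, d, decimals) for k, (n, d) in counts.items()}


def study_summary(cohort_rows: Sequence[Mapping], merged_row: Mapping | None = None
                  ) -> pd.DataFrame:
    """Assemble the per-cohort summary table of the analysis.

    Each cohort row should provide: cohort, genes_in_ppi, genes_p05,
    initial_modules, discovery_pass, selected_modules, module_genes,
    module_genes_p05.  Percentages are derived columns.
    """
    rows = []
    for r in cohort_rows:
        row = dict(r)
        if r.get("genes_in_ppi"):
            row["genes_p05_pct"] = percent(r["genes_p05"], r["genes_in_ppi"])
        if r.get("module_genes"):
            row["module_genes_p05_pct"] = percent(
                r["module_genes_p05"], r["module_genes"])
        rows.append(row)
    df = pd.DataFrame(rows)
    if merged_row is not None:
        row = dict(merged_row)
        row["cohort"] = "merged"
        if row.get("module_genes"):
            row["module_genes_p05_pct"] = percent(
                row["module_genes_p05"], row["module_genes"])
        df = pd.concat([df, pd.DataFrame([row])], ignore_index=True)
    return df
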