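"""Gene-set enrichment of module genes and crosstalk between term groups.

Enrichment is a hypergeometric upper-tail test of the overlap between
the input gene list and each term, against the background from which the
module genes arose (the weighted-PPI background, not the whole genome).
An optional EASE variant decrements the hit count by one before taking
the tail, as a conservative correction.  Terms are retained when the
Benjamini-Hochberg adjusted P is below 0.05 and the term has fewer than
350 background genes.

Crosstalk groups the retained terms (a user-supplied mapping, since
grouping by function is a judgement call) and reports the genes shared
between group unions and the within-group term-membership count of each
gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genetest import bh_adjust

__all__ = ["read_gmt", "enrich", "CrosstalkReport", "crosstalk"]


def read_gmt(path: str | Path) -> dict[str, set]:
    """Parse a GMT file into term -> gene set (duplicates collapsed)."""
    terms: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {lineno}: expected >= 3 tab-separated "
                                 f"fields, got {len(parts)}")
            terms[parts[0]] = set(parts[2:])
    return terms


def enrich(input_genes: Sequence[str], terms: Mapping[str, set],
           background_genes: Sequence[str], ease: bool = False,
           fdr_max: float = 0.05, max_term_size: int = 350) -> pd.DataFrame:
    """Hypergeometric enrichment of the input list in each term.

    Returns one row per term with background overlap: term, N (term size
    in background), X (input hits), p, fdr, retained.  ``retained``
    requires FDR < ``fdr_max`` and N < ``max_term_size``.
    """
    background = set(background_genes)
    input_set = set(input_genes)
    if not input_set <= background:
        extra = sorted(input_set - background)[:5]
        raise ValueError(f"input genes not in background: {extra}")
    M, n_draw = len(background), len(input_set)

    rows = []
    for term, genes in terms.items():
        term_bg = genes & background
        N = len(term_bg)
        if N == 0:
            continue
        X = len(term_bg & input_set)
        hits = max(X - 1, 0) if ease else X
        p = 1.0 if hits == 0 else float(hypergeom.sf(hits - 1, M, N, n_draw))
        rows.append((term, N, X, p))
    df = pd.DataFrame(rows, columns=["term", "N", "X", "p"])
    if df.empty:
        df["fdr"] = df["retained"] = []
        return df
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    df["retained"] = (df["fdr"] < fdr_max) & (df["N"] < max_term_size)
    return df.sort_values(["p", "term"]).reset_index(drop=True)


@dataclass
class CrosstalkReport:
    group_genes: dict                 # group -> sorted union of hit genes
    shared: dict                      # (group_a, group_b) -> sorted shared genes
    gene_term_counts: dict            # group -> {gene: n terms containing it}


def crosstalk(retained: pd.DataFrame, groups: Mapping[str, str],
              input_genes: Sequence[str],
              terms: Mapping[str, set]) -> CrosstalkReport:
    """Shared genes between groups of retained enriched terms.

    ``groups`` maps term -> group label; unassigned terms go to "other".
    Only genes from the input list count.  ``gene_term_counts`` flags
    the genes shared by most terms of a group.
    """
    input_set = set(input_genes)
    group_terms: dict[str, list[str]] = {}
    for term in retained.loc[retained["retained"], "term"]:
        group_terms.setdefault(groups.get(term, "other"), []).append(term)

    group_genes: dict[str, set] = {}
    counts: dict[str, dict] = {}
    for grp, term_list in group_terms.items():
        union: set = set()
        cnt: dict[str, int] = {}
        for term in term_list:
            hit = terms[term] & input_set
            union |= hit
            for g in hit:
                cnt[g] = cnt.get(g, 0) + 1
        group_genes[grp] = union
        counts[grp] = dict(sorted(cnt.items()))

    shared = {
        (a, b): sorted(group_genes[a] & group_genes[b])
        for a, b in combinations(sorted(group_genes), 2)
    }
    return CrosstalkReport(
        group_genes={g: sorted(s) for g, s in sorted(group_genes.items())},
        shared=shared,
        gene_term_counts=counts,
    )
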