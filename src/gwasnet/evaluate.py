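"""Module significance, cross-cohort evaluation, selection and merging.

Raw module scores from a greedy search are not comparable to a standard
normal, so they are standardized against an empirical null: scores are
median-centred, the null mean delta and SD sigma are fitted to the
central bulk (central matching: a Gaussian fitted to the histogram of
the central 50% of the centred scores), and each score becomes
Z_s = ((Z_m - median) - delta) / sigma with P = 1 - Phi(Z_s).

Cross evaluation re-scores each discovery module with an independent
cohort's gene weights and standardizes those evaluation scores the same
way, demanding module-level replication.  Modules pass when the
discovery P and at least one evaluation P are both below 0.05; the
selected modules from all cohorts merge into one resultant subnetwork
with per-edge repeat counts and per-gene cohort provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "NullFit", "fit_empirical_null", "module_p", "score_modules",
    "CrossEvalResult", "cross_evaluate", "SelectionCriteria",
    "select_modules", "MergedSubnetwork", "merge_modules",
]


@dataclass
class NullFit:
    """Empirical-null mean and SD on the median-centred score scale."""

    delta: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


def fit_empirical_null(scores: Sequence[float], n_bins: int = 25) -> NullFit:
    """Fit the empirical null to the central bulk of module scores.

    Scores are centred at their median and the null N(delta, sigma) is
    fitted by central matching: Poisson maximum likelihood of the
    histogram counts on the interquartile range against a quadratic in
    the bin centres (a Gaussian log-density is a quadratic, whose
    curvature gives sigma and whose tilt gives delta).  Fitting the
    central *density* rather than only the central observations keeps
    sigma identified, and the central window makes the fit insensitive
    to the enriched right tail that genuine disease modules produce.
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise ValueError("need at least 4 finite scores")
    centred = x - np.median(x)
    a, b = np.percentile(centred, [25, 75])
    if not b > a:
        raise ValueError("zero spread in module scores")
    delta, sigma = _central_matching(centred, a, b, n_bins)
    return NullFit(delta=delta, sigma=sigma)


def _central_matching(centred: np.ndarray, a: float, b: float,
                      n_bins: int) -> tuple[float, float]:
    """Gaussian log-density (quadratic) fitted to central histogram counts.

    The fit window is asymmetric around the bulk centre — wide on the
    left, shorter on the right — because score enrichment from genuine
    modules contaminates only the upper tail.
    """
    import statsmodels.api as sm

    s0 = (b - a) / 1.349                  # normal-consistent initial scale
    m0 = 0.5 * (a + b)
    lo, hi = m0 - 2.5 * s0, m0 + 1.5 * s0
    counts, edges = np.histogram(centred, bins=n_bins, range=(lo, hi))
    mid = 0.5 * (edges[:-1] + edges[1:])
    X = np.column_stack([np.ones_like(mid), mid, mid * mid])
    b2 = 0.0
    try:
        fit = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
        b1, b2 = fit.params[1], fit.params[2]
    except Exception:
        pass
    if b2 < -1e-12:
        sigma = math.sqrt(-1.0 / (2.0 * b2))
        delta = b1 * sigma * sigma
        # a fitted centre far outside the bulk means the quadratic chased
        # tail structure; fall back to moments
        if lo <= delta <= hi:
            return float(delta), float(sigma)
    return float(m0), float(s0)


def module_p(score, fit: NullFit, median: float):
    """P(Z_m) = 1 - Phi(((Z_m - median) - delta) / sigma)."""
    score = np.asarray(score, dtype=float)
    zs = ((score - median) - fit.delta) / fit.sigma
    out = norm.sf(zs)
    return float(out) if out.ndim == 0 else out


def score_modules(scores: Sequence[float]) -> tuple[np.ndarray, NullFit, float]:
    """Standardize a score list against its own empirical null."""
    scores = np.asarray(scores, dtype=float)
    fit = fit_empirical_null(scores)
    median = float(np.nanmedian(scores))
    return module_p(scores, fit, median), fit, median


@dataclass
class CrossEvalResult:
    scores: np.ndarray                # evaluation-cohort Z_m per module (NaN if none)
    ps: np.ndarray                    # standardized P(Z_m(eval)); NaN = not evaluable
    coverage: np.ndarray              # fraction of members present in eval background
    low_coverage: np.ndarray = None   # flagged: under half the members evaluable
    fit: NullFit | None = None
    median: float = float("nan")


def cross_evaluate(modules: Sequence, eval_stats: pd.DataFrame,
                   min_coverage_flag: float = 0.5) -> CrossEvalResult:
    """Re-score discovery modules with an evaluation cohort's gene weights.

    Member genes absent from the evaluation background are dropped and k
    reduced accordingly; a module with no evaluable gene gets a missing P
    and fails evaluation in that cohort.  The evaluation scores of the
    same module list form their own empirical null for standardization.
    """
    zmap = dict(zip(eval_stats["gene"], eval_stats["z"]))
    scores = np.full(len(modules), np.nan)
    coverage = np.zeros(len(modules))
    for i, mod in enumerate(modules):
        members = [g for g in mod.members if g in zmap]
        coverage[i] = len(members) / len(mod.members)
        if members:
            scores[i] = sum(zmap[g] for g in members) / math.sqrt(len(members))
    low = coverage < min_coverage_flag
    finite = np.isfinite(scores)
    if finite.sum() < 4:
        return CrossEvalResult(scores=scores, ps=np.full_like(scores, np.nan),
                               coverage=coverage, low_coverage=low)
    fit = fit_empirical_null(scores[finite])
    median = float(np.median(scores[finite]))
    ps = np.full_like(scores, np.nan)
    ps[finite] = module_p(scores[finite], fit, median)
    return CrossEvalResult(scores=scores, ps=ps, coverage=coverage,
                           low_coverage=low, fit=fit, median=median)


@dataclass
class SelectionCriteria:
    """Dual criteria: discovery P and replication in >= 1 evaluation cohort."""

    discovery_p_max: float = 0.05
    eval_p_max: float = 0.05
    min_datasets_passing_eval: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.discovery_p_max < 1 and 0 < self.eval_p_max < 1):
            raise ValueError("thresholds must be in (0,1)")


def select_modules(modules: Sequence, discovery_ps: np.ndarray,
                   eval_ps_by_cohort: Sequence[np.ndarray],
                   crit: SelectionCriteria | None = None
                   ) -> tuple[list[int], dict]:
    """Indices of modules passing the dual criteria, plus per-step counts."""
    crit = crit or SelectionCriteria()
    discovery_ps = np.asarray(discovery_ps, dtype=float)
    disc_pass = discovery_ps < crit.discovery_p_max
    counts = {"discovery_pass": int(disc_pass.sum())}
    n_eval_pass = np.zeros(len(modules), dtype=int)
    for j, eval_ps in enumerate(eval_ps_by_cohort):
        eval_ps = np.asarray(eval_ps, dtype=float)
        ok = np.where(np.isfinite(eval_ps), eval_ps < crit.eval_p_max, False)
        counts[f"eval_pass_{j}"] = int((disc_pass & ok).sum())
        n_eval_pass += ok.astype(int)
    selected = disc_pass & (n_eval_pass >= crit.min_datasets_passing_eval)
    counts["selected"] = int(selected.sum())
    return list(np.where(selected)[0]), counts


@dataclass
class MergedSubnetwork:
    """Union of selected modules across cohorts."""

    genes: dict                       # gene -> sorted list of source cohorts
    edges: pd.DataFrame               # gene1, gene2, repeats, cohorts
    n_modules_by_cohort: dict
    n_modules_pre_dedup: dict
    shared_genes: dict                # (cohort_a, cohort_b) -> sorted shared genes

    @property
    def n_modules_total(self) -> int:
        return sum(self.n_modules_by_cohort.values())

    @property
    def gene_set(self) -> set:
        return set(self.genes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def merge_modules(selected: Mapping[str, Sequence],
                  ppi: Sequence[tuple[str, str]] | None = None
                  ) -> MergedSubnetwork:
    """Merge selected modules from all cohorts into one subnetwork.

    Within a cohort, duplicate member sets (identical gene sets grown
    from different seeds) collapse to the earliest seed in input order.
    Edges are the PPI pairs co-occurring in at least one selected module,
    annotated with how many modules repeat them and which cohorts they
    come from.
    """
    deduped: dict[str, list] = {}
    pre_counts: dict[str, int] = {}
    for cohort, mods in selected.items():
        pre_counts[cohort] = len(mods)
        seen: set[frozenset] = set()
        kept = []
        for mod in mods:
            key = frozenset(mod.members)
            if key not in seen:
                seen.add(key)
                kept.append(mod)
        deduped[cohort] = kept

    genes: dict[str, set] = {}
    for cohort, mods in deduped.items():
        for mod in mods:
            for g in mod.members:
                genes.setdefault(g, set()).add(cohort)

    edge_rows: dict[tuple[str, str], dict] = {}
    if ppi is not None:
        edge_set = {tuple(sorted(e)) for e in ppi}
        for cohort, mods in deduped.items():
            for mod in mods:
                members = sorted(mod.members)
                for i in range(len(members)):
                    for j in range(i + 1, len(members)):
                        e = (members[i], members[j])
                        if e in edge_set:
                            row = edge_rows.setdefault(
                                e, {"repeats": 0, "cohorts": set()})
                            row["repeats"] += 1
                            row["cohorts"].add(cohort)
    edges = pd.DataFrame(
        [{"gene1": e[0], "gene2": e[1], "repeats": row["repeats"],
          "cohorts": ";".join(sorted(row["cohorts"]))}
         for e, row in sorted(edge_rows.items())],
        columns=["gene1", "gene2", "repeats", "cohorts"])

    cohorts = sorted(deduped)
    shared = {}
    for i in range(len(cohorts)):
        for j in range(i + 1, len(cohorts)):
            a, b = cohorts[i], cohorts[j]
            ga = {g for g, cs in genes.items() if a in cs}
            gb = {g for g, cs in genes.items() if b in cs}
            shared[(a, b)] = sorted(ga & gb)

    return MergedSubnetwork(
        genes={g: sorted(cs) for g, cs in genes.items()},
        edges=edges,
        n_modules_by_cohort={c: len(m) for c, m in deduped.items()},
        n_modules_pre_dedup=pre_counts,
        shared_genes=shared,
    )
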