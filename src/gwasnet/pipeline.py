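"""End-to-end driver: synthetic study -> QC -> gene tests -> modules.

Runs every stage in sequence for each cohort, cross-evaluates modules
between cohorts, applies the dual selection criteria and merges the
survivors, returning all intermediate products plus recovery metrics
against the planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import dms, evaluate, genetest, qc, report
from .simulate import SimulationConfig, SyntheticStudy, simulate_study

__all__ = ["CohortResult", "StudyResult", "run_study"]


@dataclass
class CohortResult:
    name: str
    qc: qc.QCResult
    gene_stats: pd.DataFrame
    net: dms.WeightedNetwork
    modules: list[dms.Module]
    discovery_ps: np.ndarray
    eval_ps: dict = field(default_factory=dict)   # other cohort -> P array


@dataclass
class StudyResult:
    study: SyntheticStudy
    cohorts: list[CohortResult]
    selected: dict                     # cohort -> list of selected Modules
    selection_counts: dict             # cohort -> per-step counts
    merged: evaluate.MergedSubnetwork
    metrics: dict

    def summary(self) -> pd.DataFrame:
        rows = []
        for cr in self.cohorts:
            member_genes = {g for m in self.selected[cr.name] for g in m.members}
            p05 = {g for g in member_genes if cr.net.p.get(g, 1.0) < 0.05}
            rows.append({
                "cohort": cr.name,
                "genes_in_ppi": cr.net.background_size,
                "genes_p05": cr.net.n_significant,
                "initial_modules": len(cr.modules),
                "discovery_pass": int(np.sum(cr.discovery_ps < 0.05)),
                "selected_modules": len(self.selected[cr.name]),
                "module_genes": len(member_genes),
                "module_genes_p05": len(p05),
            })
        merged_p05 = set()
        for cr in self.cohorts:
            merged_p05 |= {g for g in self.merged.gene_set
                           if cr.net.p.get(g, 1.0) < 0.05}
        merged_row = {
            "selected_modules": self.merged.n_modules_total,
            "module_genes": self.merged.n_genes,
            "module_genes_p05": len(merged_p05),
        }
        return report.study_summary(rows, merged_row)


def run_study(config: SimulationConfig | None = None,
              study: SyntheticStudy | None = None,
              thresholds: qc.QCThresholds | None = None,
              gene_test: str = "vegas",
              vegas_schedule: Sequence[int] = genetest.VEGAS_SCHEDULE,
              r: float = 0.1, d: int = 2,
              criteria: evaluate.SelectionCriteria | None = None,
              seed: int | None = None) -> StudyResult:
    """Run the complete pipeline on a synthetic study.

    Either pass a ``config`` (a study is simulated from it) or a
    pre-built ``study``.  ``seed`` defaults to the study config seed and
    drives the gene-test simulations.
    """
    if study is None:
        if config is None:
            config = SimulationConfig()
        study = simulate_study(config)
    config = study.config
    seed = config.seed if seed is None else seed
    thresholds = thresholds or qc.QCThresholds()
    criteria = criteria or evaluate.SelectionCriteria()

    cohorts: list[CohortResult] = []
    for i, data in enumerate(study.cohorts):
        name = config.cohort_name(i)
        qcr = qc.run_qc(data, thresholds)
        gmap = genetest.map_snps_to_genes(qcr.data.snp_table, study.genes,
                                          config.flank_bp)
        gstats = genetest.gene_stats(qcr.assoc, gmap, qcr.data,
                                     method=gene_test, seed=seed * 1000 + i,
                                     vegas_schedule=vegas_schedule)
        net = dms.weight_network(study.ppi, gstats)
        modules = dms.search_all_seeds(net, r=r, d=d)
        disc_ps, _, _ = evaluate.score_modules([m.score for m in modules])
        cohorts.append(CohortResult(name=name, qc=qcr, gene_stats=gstats,
                                    net=net, modules=modules,
                                    discovery_ps=disc_ps))

    for cr in cohorts:
        for other in cohorts:
            if other.name == cr.name:
                continue
            res = evaluate.cross_evaluate(cr.modules, other.gene_stats)
            cr.eval_ps[other.name] = res.ps

    selected: dict[str, list] = {}
    counts: dict[str, dict] = {}
    for cr in cohorts:
        eval_lists = [cr.eval_ps[o.name] for o in cohorts if o.name != cr.name]
        idx, c = evaluate.select_modules(cr.modules, cr.discovery_ps,
                                         eval_lists, criteria)
        selected[cr.name] = [cr.modules[i] for i in idx]
        counts[cr.name] = c

    merged = evaluate.merge_modules(selected, study.ppi)

    planted = study.planted_genes
    union = merged.gene_set
    background = {g for cr in cohorts for g in cr.net.background}
    n_bg_nonplanted = len(background - planted)
    metrics = {
        "planted_genes": len(planted),
        "planted_covered": len(union & planted),
        "planted_coverage": (len(union & planted) / len(planted)) if planted else np.nan,
        "background_selected": len(union - planted),
        "background_fraction": (len(union - planted) / n_bg_nonplanted
                                if n_bg_nonplanted else np.nan),
        "selected_modules_total": merged.n_modules_total,
        "merged_genes": merged.n_genes,
        "merged_edges": merged.n_edges,
        "discovery_pass_total": int(sum(c["discovery_pass"] for c in counts.values())),
    }
    return StudyResult(study=study, cohorts=cohorts, selected=selected,
                       selection_counts=counts, merged=merged, metrics=metrics)
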