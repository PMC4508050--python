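"""Synthetic GWAS study generator.

Emulates a multi-cohort case-control GWAS resource: several independent
cohorts of differing sample size and SNP density genotyped on a shared SNP
panel, a scale-free protein-interaction network, and a handful of "planted"
disease modules — connected subgraphs whose member genes carry genuine
risk alleles in every cohort.  Downstream stages (QC, gene-based tests,
dense module search, cross-cohort evaluation) can therefore be exercised
end to end with known ground truth and no external data.

Model
-----
* LD: SNPs are grouped into blocks; haplotypes within a block come from a
  latent Gaussian with exchangeable correlation ``ld_rho`` thresholded at
  the Phi^{-1}(MAF) quantile, so the marginal allele frequency is exact and
  a single parameter controls within-block r^2.
* Risk: additive on the log-odds scale.  Each planted gene contributes one
  causal SNP (its central SNP); case status is drawn from a logistic model
  whose linear predictor is log(planted_or) per risk allele plus a
  per-cohort batch intercept with SD ``batch_effect_sd``.
* Genes are laid out non-overlapping on one synthetic chromosome with a
  fixed number of SNPs per gene, making the SNP-to-gene map deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .data import MISSING, GenotypeDataset

__all__ = [
    "SimulationConfig",
    "simulate_ppi",
    "plant_modules",
    "simulate_cohort",
    "simulate_study",
    "gene_table",
    "snp_table",
    "causal_snp_indices",
    "random_gene_sets",
]


def _per_cohort(value, i: int, n: int):
    if np.isscalar(value) or isinstance(value, str):
        return value
    seq = list(value)
    if len(seq) != n:
        raise ValueError(f"per-cohort value must have length {n}, got {len(seq)}")
    return seq[i]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic multi-cohort GWAS.

    Scalar fields apply to every cohort; sequences give per-cohort values.
    Defaults emulate three cohorts of unequal size and SNP density sharing
    one SNP panel, one PPI network and one set of planted disease modules.
    """

    n_cohorts: int = 3
    n_cases: int | Sequence[int] = (1000, 700, 400)
    n_controls: int | Sequence[int] = (1000, 900, 1300)
    n_snps: int = 10_000
    snp_keep_fraction: float | Sequence[float] = (1.0, 0.9, 0.4)
    ld_block_size: int = 20
    ld_rho: float = 0.7
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_genes: int = 1000
    gene_span_bp: int = 10_000
    flank_bp: int = 20_000
    gene_gap_bp: int = 50_000
    n_planted_modules: int = 3
    planted_module_size: int = 8
    planted_or: float = 1.6
    batch_effect_sd: float = 0.2
    missing_rate: float = 0.02
    case_missing_rate: float | None = None
    ppi_attachment: int = 3
    n_random_terms: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [self.n_cohorts, self.n_snps, self.n_genes, self.ld_block_size,
                  self.gene_span_bp, self.flank_bp, self.gene_gap_bp,
                  self.n_planted_modules, self.planted_module_size]
        if any(int(c) <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.planted_or < 1.0:
            raise ValueError("planted_or must be >= 1 (risk-allele odds ratio)")
        if self.planted_module_size < 2:
            raise ValueError("planted_module_size must be >= 2")
        if self.n_snps < self.n_genes:
            raise ValueError("need at least one SNP per gene")
        for i in range(self.n_cohorts):
            if self.cases(i) <= 0 or self.controls(i) <= 0:
                raise ValueError("per-cohort case/control counts must be positive")

    def cases(self, i: int) -> int:
        return int(_per_cohort(self.n_cases, i, self.n_cohorts))

    def controls(self, i: int) -> int:
        return int(_per_cohort(self.n_controls, i, self.n_cohorts))

    def keep_fraction(self, i: int) -> float:
        f = float(_per_cohort(self.snp_keep_fraction, i, self.n_cohorts))
        if not (0.0 < f <= 1.0):
            raise ValueError("snp_keep_fraction must be in (0, 1]")
        return f

    @property
    def snps_per_gene(self) -> int:
        return self.n_snps // self.n_genes

    def cohort_name(self, i: int) -> str:
        return f"study{i + 1}"


# ---------------------------------------------------------------------------
# deterministic coordinate layout
# ---------------------------------------------------------------------------

def gene_table(config: SimulationConfig) -> pd.DataFrame:
    """BED-like gene table (chrom, 0-based start, end, gene_id), non-overlapping."""
    width = len(str(config.n_genes))
    pitch = config.gene_span_bp + config.gene_gap_bp
    starts = np.arange(config.n_genes, dtype=np.int64) * pitch
    return pd.DataFrame(
        {
            "chrom": "1",
            "start": starts,
            "end": starts + config.gene_span_bp,
            "gene": [f"G{i + 1:0{width}d}" for i in range(config.n_genes)],
        }
    )


def snp_table(config: SimulationConfig) -> pd.DataFrame:
    """Master SNP panel: a fixed number of SNPs evenly spaced inside each gene.

    SNPs left over when ``n_snps`` does not divide ``n_genes`` are placed
    beyond the last gene (intergenic).
    """
    s = config.snps_per_gene
    pitch = config.gene_span_bp + config.gene_gap_bp
    genes = gene_table(config)
    pos = []
    for g in range(config.n_genes):
        start = genes["start"].iat[g]
        # 1-based positions strictly inside the gene span
        offs = (np.arange(1, s + 1) * config.gene_span_bp) // (s + 1)
        pos.extend(int(start + o) + 1 for o in offs)
    n_extra = config.n_snps - s * config.n_genes
    tail = config.n_genes * pitch
    for j in range(n_extra):
        pos.append(tail + (j + 1) * 1000)
    width = len(str(config.n_snps))
    return pd.DataFrame(
        {
            "snp": [f"rs{i + 1:0{width}d}" for i in range(config.n_snps)],
            "chrom": "1",
            "pos": np.asarray(pos, dtype=np.int64),
            "a1": "A",
            "a2": "B",
        }
    )


def causal_snp_indices(config: SimulationConfig, planted_genes: Sequence[str]) -> np.ndarray:
    """One causal SNP per planted gene: the central SNP of the gene."""
    genes = gene_table(config)
    lookup = {g: i for i, g in enumerate(genes["gene"])}
    s = config.snps_per_gene
    idx = []
    for g in planted_genes:
        gi = lookup[g]
        idx.append(gi * s + s // 2)
    return np.asarray(sorted(idx), dtype=np.int64)


# ---------------------------------------------------------------------------
# network and planted modules
# ---------------------------------------------------------------------------

def simulate_ppi(n_genes: int, attachment: int = 3, seed: int = 0,
                 gene_ids: Sequence[str] | None = None) -> list[tuple[str, str]]:
    """Scale-free PPI edge list via preferential attachment.

    The result is a connected, undirected, simple graph with no self-loops.
    """
    if not (n_genes > attachment >= 1):
        raise ValueError("need n_genes > attachment >= 1")
    g = nx.barabasi_albert_graph(n_genes, attachment, seed=int(seed))
    if gene_ids is None:
        width = len(str(n_genes))
        gene_ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    edges = []
    for u, v in g.edges():
        a, b = gene_ids[u], gene_ids[v]
        edges.append((a, b) if a <= b else (b, a))
    return sorted(edges)


def plant_modules(ppi: Sequence[tuple[str, str]], config: SimulationConfig,
                  seed: int | None = None, max_tries: int = 1000) -> list[tuple[str, ...]]:
    """Grow pairwise-disjoint connected gene sets to serve as ground truth.

    Each module starts at a random seed node and accretes random neighbours
    (breadth-first frontier) until it reaches ``planted_module_size``.
    """
    rng = np.random.default_rng([config.seed if seed is None else seed, 103])
    graph = nx.Graph(list(ppi))
    nodes = sorted(graph.nodes)
    for _ in range(max_tries):
        used: set[str] = set()
        modules: list[tuple[str, ...]] = []
        ok = True
        for _m in range(config.n_planted_modules):
            grown = _grow_one(graph, nodes, used, config.planted_module_size, rng)
            if grown is None:
                ok = False
                break
            modules.append(tuple(sorted(grown)))
            used.update(grown)
        if ok:
            return modules
    raise RuntimeError("could not plant disjoint connected modules; "
                       "network too small or fragmented")


def _grow_one(graph, nodes, used, size, rng, attempts: int = 50):
    avail = [n for n in nodes if n not in used]
    if not avail:
        return None
    for _ in range(attempts):
        start = avail[int(rng.integers(len(avail)))]
        members = {start}
        while len(members) < size:
            frontier = sorted(
                {nb for m in members for nb in graph.neighbors(m)} - members - used
            )
            if not frontier:
                break
            members.add(frontier[int(rng.integers(len(frontier)))])
        if len(members) == size:
            return members
    return None


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _shared_maf(config: SimulationConfig) -> np.ndarray:
    rng = np.random.default_rng([config.seed, 101])
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.n_snps)


def _block_slices(n_snps: int, block: int) -> list[slice]:
    # block size not dividing n_snps is handled by a final short block
    return [slice(i, min(i + block, n_snps)) for i in range(0, n_snps, block)]


def _simulate_haplotypes(config: SimulationConfig, rng: np.random.Generator,
                         n_hap: int, thresholds: np.ndarray) -> np.ndarray:
    """Haplotypes (n_hap x n_snps, bool) with block-exchangeable LD."""
    h = np.empty((n_hap, config.n_snps), dtype=bool)
    rho = config.ld_rho
    sr, se = math.sqrt(rho), math.sqrt(1.0 - rho)
    for sl in _block_slices(config.n_snps, config.ld_block_size):
        width = sl.stop - sl.start
        shared = rng.standard_normal((n_hap, 1), dtype=np.float32)
        eps = rng.standard_normal((n_hap, width), dtype=np.float32)
        latent = sr * shared + se * eps
        h[:, sl] = latent < thresholds[sl].astype(np.float32)
    return h


def simulate_cohort(config: SimulationConfig, cohort_index: int,
                    planted_genes: Sequence[str] | None = None) -> GenotypeDataset:
    """Simulate one case-control cohort on the shared SNP panel.

    ``planted_genes`` defaults to the union of the planted modules derived
    deterministically from ``config.seed`` (so every cohort shares the same
    disease genes).  Case status follows a logistic model over the causal
    risk-allele counts; sampling continues until the case and control
    quotas are filled.
    """
    if not (0 <= cohort_index < config.n_cohorts):
        raise ValueError("cohort_index out of range")
    if planted_genes is None:
        ppi = simulate_ppi(config.n_genes, config.ppi_attachment, seed=config.seed)
        planted_genes = [g for mod in plant_modules(ppi, config) for g in mod]

    maf = _shared_maf(config)
    thresholds = ndtri(maf)
    causal = causal_snp_indices(config, planted_genes)
    beta = math.log(config.planted_or)

    rng = np.random.default_rng([config.seed, 11, cohort_index])
    b0 = float(rng.normal(0.0, config.batch_effect_sd)) if config.batch_effect_sd > 0 else 0.0
    # centre the linear predictor so both quotas fill at a reasonable rate
    centre = beta * 2.0 * maf[causal].sum()

    need_cases, need_controls = config.cases(cohort_index), config.controls(cohort_index)
    case_rows, control_rows = [], []
    got_cases = got_controls = 0
    guard = 0
    while got_cases < need_cases or got_controls < need_controls:
        guard += 1
        if guard > 200:
            raise RuntimeError("case/control sampling failed to fill quotas")
        batch = max(256, int(1.3 * ((need_cases - got_cases) + (need_controls - got_controls))))
        hap = _simulate_haplotypes(config, rng, 2 * batch, thresholds)
        geno = hap[0::2].astype(np.int8) + hap[1::2].astype(np.int8)
        eta = b0 + beta * geno[:, causal].sum(axis=1) - centre
        is_case = rng.random(batch) < expit(eta)
        if got_cases < need_cases:
            take = geno[is_case][: need_cases - got_cases]
            case_rows.append(take)
            got_cases += len(take)
        if got_controls < need_controls:
            take = geno[~is_case][: need_controls - got_controls]
            control_rows.append(take)
            got_controls += len(take)

    geno = np.vstack([np.vstack(case_rows), np.vstack(control_rows)])
    phenotype = np.concatenate([np.ones(need_cases, dtype=np.int64),
                                np.zeros(need_controls, dtype=np.int64)])

    # per-cohort SNP panel (platform density); causal SNPs always genotyped
    snps = snp_table(config)
    frac = config.keep_fraction(cohort_index)
    if frac < 1.0:
        sub_rng = np.random.default_rng([config.seed, 12, cohort_index])
        n_keep = max(1, int(round(frac * config.n_snps)))
        keep = sub_rng.choice(config.n_snps, size=n_keep, replace=False)
        keep = np.unique(np.concatenate([keep, causal]))
        geno = geno[:, keep]
        snps = snps.iloc[keep].reset_index(drop=True)

    # missingness (MCAR by default; optionally case-biased)
    if config.missing_rate > 0 or config.case_missing_rate is not None:
        rate = np.full(len(phenotype), config.missing_rate)
        if config.case_missing_rate is not None:
            rate[phenotype == 1] = config.case_missing_rate
        mask = rng.random(geno.shape) < rate[:, None]
        geno[mask] = MISSING

    name = config.cohort_name(cohort_index)
    n = len(phenotype)
    sample_ids = np.array([f"{name}_S{i + 1:05d}" for i in range(n)])
    return GenotypeDataset(
        genotypes=geno,
        phenotype=phenotype,
        study_indicator=np.array([name] * n),
        snp_table=snps,
        sample_ids=sample_ids,
    )


def random_gene_sets(config: SimulationConfig, gene_ids: Sequence[str],
                     n_terms: int | None = None,
                     size_range: tuple[int, int] = (10, 50)) -> dict[str, list[str]]:
    """Random gene-set terms for the GMT fixture."""
    rng = np.random.default_rng([config.seed, 104])
    n_terms = config.n_random_terms if n_terms is None else n_terms
    gene_ids = list(gene_ids)
    lo, hi = size_range
    hi = min(hi, len(gene_ids))
    terms = {}
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(gene_ids), size=size, replace=False)
        terms[f"RANDOM_TERM_{t + 1}"] = sorted(gene_ids[i] for i in members)
    return terms


@dataclass
class SyntheticStudy:
    """A complete synthetic multi-cohort study with ground truth."""

    config: SimulationConfig
    cohorts: list[GenotypeDataset]
    ppi: list[tuple[str, str]]
    genes: pd.DataFrame
    planted_modules: list[tuple[str, ...]]
    gmt: dict[str, list[str]] = field(default_factory=dict)

    @property
    def planted_genes(self) -> set[str]:
        return {g for mod in self.planted_modules for g in mod}


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate cohorts, PPI network, coordinates, planted truth and gene sets."""
    ppi = simulate_ppi(config.n_genes, config.ppi_attachment, seed=config.seed)
    planted = plant_modules(ppi, config)
    planted_genes = [g for mod in planted for g in mod]
    cohorts = [simulate_cohort(config, i, planted_genes) for i in range(config.n_cohorts)]
    genes = gene_table(config)
    gmt = {f"PLANTED_MODULE_{i + 1}": list(mod) for i, mod in enumerate(planted)}
    gmt.update(random_gene_sets(config, genes["gene"]))
    return SyntheticStudy(config=config, cohorts=cohorts, ppi=ppi, genes=genes,
                          planted_modules=planted, gmt=gmt)
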