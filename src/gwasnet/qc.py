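"""Genotype quality control and SNP association testing.

The pipeline applies, in order: (i) SNP missingness, (ii) sample
missingness and heterozygosity outliers, (iii) LD pruning followed by
identity-by-descent relatedness removal, (iv) differential missingness,
minor allele frequency and Hardy-Weinberg filters.  Principal components
are computed on the pruned SNP set, screened one at a time by genomic
inflation, and the best five join the study indicators as covariates in
the logistic Wald scan that yields per-SNP P-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from sklearn.utils.extmath import randomized_svd

from .data import GenotypeDataset
from .glm import genomic_lambda, logistic_scan

__all__ = [
    "QCThresholds", "filter_snp_missingness", "filter_samples", "ld_prune",
    "pi_hat_matrix", "ibd_estimate", "differential_missingness_test",
    "hwe_exact_test", "hwe_filter", "maf_filter", "pca_covariates",
    "select_pcs_by_lambda", "run_qc", "QCResult",
]


@dataclass
class QCThresholds:
    """Filter thresholds; the defaults are standard GWAS practice."""

    snp_missing_max: float = 0.05
    sample_missing_max: float = 0.05
    het_sd: float = 3.0
    prune_r2: float = 0.2
    prune_window: int = 50
    prune_step: int = 5
    ibd_max: float = 0.185
    diff_miss_p: float = 1e-5
    maf_min: float = 0.05
    hwe_p: float = 1e-6
    hwe_controls_only: bool = False
    n_pcs_screened: int = 20
    n_pcs_used: int = 5

    def __post_init__(self) -> None:
        for name in ("snp_missing_max", "sample_missing_max", "prune_r2",
                     "ibd_max", "diff_miss_p", "maf_min", "hwe_p"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {v}")


# ---------------------------------------------------------------------------
# (i) / (ii): missingness and heterozygosity filters
# ---------------------------------------------------------------------------

def filter_snp_missingness(data: GenotypeDataset, thr: QCThresholds
                           ) -> tuple[GenotypeDataset, list[str]]:
    """Drop SNPs whose missing fraction exceeds the threshold.

    Applied before any sample removal.
    """
    if data.n_snps == 0 or data.n_samples == 0:
        raise ValueError("empty dataset")
    rate = data.snp_missing_rate()
    keep = rate <= thr.snp_missing_max
    if not keep.any():
        raise ValueError("all SNPs removed by missingness filter")
    removed = list(data.snp_ids[~keep])
    return data.subset_snps(np.where(keep)[0]), removed


def filter_samples(data: GenotypeDataset, thr: QCThresholds
                   ) -> tuple[GenotypeDataset, list[str], dict]:
    """Drop samples by missing rate and heterozygosity-rate outliers.

    The heterozygosity band is mean +/- ``het_sd`` standard deviations,
    computed over all samples before any removal.  Zero heterozygosity
    variance disables the het rule (degenerate, e.g. identical samples).
    """
    if data.n_samples < 3:
        raise ValueError("need at least 3 samples")
    miss = data.sample_missing_rate()
    het = data.heterozygosity_rate()
    mu, sd = float(np.nanmean(het)), float(np.nanstd(het))
    bad_miss = miss > thr.sample_missing_max
    if sd > 0:
        bad_het = np.abs(het - mu) > thr.het_sd * sd
    else:
        bad_het = np.zeros(data.n_samples, dtype=bool)
    bad = bad_miss | bad_het
    removed = list(data.sample_ids[bad])
    stats = {"het_mean": mu, "het_sd": sd,
             "n_missing_removed": int(bad_miss.sum()),
             "n_het_removed": int((bad_het & ~bad_miss).sum())}
    return data.subset_samples(np.where(~bad)[0]), removed, stats


# ---------------------------------------------------------------------------
# (iii): LD pruning and IBD relatedness
# ---------------------------------------------------------------------------

def _banded_r2(X: np.ndarray, band: int) -> np.ndarray:
    """r^2 between SNP pairs at column offsets 1..band-1.

    Returns array (band-1, m); entry [o-1, i] is r^2(snp_i, snp_{i+o}).
    """
    n, m = X.shape
    Xs = (X - X.mean(axis=0)).astype(np.float32)
    norm = np.sqrt((Xs ** 2).sum(axis=0))
    norm[norm == 0] = np.inf
    Xs /= norm
    out = np.zeros((band - 1, m), dtype=np.float32)
    for o in range(1, min(band, m)):
        out[o - 1, : m - o] = np.einsum("ij,ij->j", Xs[:, : m - o], Xs[:, o:])
    return out ** 2


def ld_prune(data: GenotypeDataset, r2_max: float = 0.2,
             window: int = 50, step: int = 5) -> list[str]:
    """Greedy windowed LD pruning on genotype correlations.

    Within each sliding window of ``window`` SNPs (advanced by ``step``),
    any retained pair with r^2 above the threshold loses its
    later-positioned member.  Missing genotypes are mean-imputed for the
    correlation only.  Returns retained SNP ids in positional order.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    m = data.n_snps
    r2 = _banded_r2(data.dosage(impute=True), window)
    keep = np.ones(m, dtype=bool)
    for start in range(0, m, step):
        idx = np.where(keep[start:min(start + window, m)])[0] + start
        for a in range(len(idx)):
            i = idx[a]
            if not keep[i]:
                continue
            later = idx[a + 1:]
            later = later[keep[later]]
            hot = later[r2[later - i - 1, i] > r2_max]
            keep[hot] = False
        if start + window >= m:
            break
    return list(data.snp_ids[keep])


def pi_hat_matrix(data: GenotypeDataset, snp_ids: list[str] | None = None
                  ) -> np.ndarray:
    """Pairwise PI_HAT by method-of-moments on identity-by-state counts.

    P(IBD=0,1,2) are solved from observed versus expected IBS counts
    given allele frequencies; PI_HAT = P(IBD=2) + 0.5 P(IBD=1), clamped
    to [0, 1].  Monomorphic SNPs are skipped.  A sample against itself
    gives exactly 1.
    """
    idx = np.arange(data.n_snps) if snp_ids is None else data.snp_index(snp_ids)
    sub = data.genotypes[:, idx]
    p = data.allele_freq()[idx]
    poly = (p > 0) & (p < 1)
    sub, p = sub[:, poly], p[poly]
    q = 1.0 - p
    m = sub.shape[1]
    if m == 0:
        raise ValueError("no polymorphic SNPs for IBD estimation")

    I0 = (sub == 0).astype(np.float32)
    I1 = (sub == 1).astype(np.float32)
    I2 = (sub == 2).astype(np.float32)
    V = (sub >= 0).astype(np.float32)

    ibs2 = I0 @ I0.T + I1 @ I1.T + I2 @ I2.T
    ibs0 = I0 @ I2.T + I2 @ I0.T
    nvalid = V @ V.T
    ibs1 = nvalid - ibs2 - ibs0

    # expected IBS class probabilities summed over SNPs, unrelated pair
    e0 = float(np.sum(2 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e1_ibd1 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e2_ibd0 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e2_ibd1 = float(np.sum(p**3 + q**3 + p * q))

    frac = nvalid / m
    frac[frac == 0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = ibs0 / (e0 * frac)
        p1 = (ibs1 - p0 * e1_ibd0 * frac) / (e1_ibd1 * frac)
        p2 = (ibs2 - p0 * e2_ibd0 * frac - p1 * e2_ibd1 * frac) / (m * frac)
    pi = p2 + 0.5 * p1
    pi = np.clip(np.nan_to_num(pi, nan=0.0), 0.0, 1.0)
    np.fill_diagonal(pi, 1.0)
    return pi


def ibd_estimate(data: GenotypeDataset, pruned: list[str],
                 thr: QCThresholds) -> tuple[pd.DataFrame, list[str]]:
    """Flag related pairs (PI_HAT above threshold) and pick removals.

    From each flagged pair still intact, the member with the lower call
    rate is marked for removal.
    """
    pi = pi_hat_matrix(data, pruned)
    n = data.n_samples
    iu = np.triu_indices(n, k=1)
    flagged = pi[iu] > thr.ibd_max
    pairs = pd.DataFrame({
        "sample1": data.sample_ids[iu[0][flagged]],
        "sample2": data.sample_ids[iu[1][flagged]],
        "pi_hat": pi[iu][flagged],
    }).sort_values("pi_hat", ascending=False).reset_index(drop=True)

    call = dict(zip(data.sample_ids, data.sample_call_rate()))
    removed: list[str] = []
    gone: set[str] = set()
    for s1, s2 in zip(pairs["sample1"], pairs["sample2"]):
        if s1 in gone or s2 in gone:
            continue
        drop = s1 if call[s1] <= call[s2] else s2
        gone.add(drop)
        removed.append(drop)
    return pairs, removed


# ---------------------------------------------------------------------------
# (iv): differential missingness, MAF, HWE
# ---------------------------------------------------------------------------

def differential_missingness_test(data: GenotypeDataset) -> np.ndarray:
    """Per-SNP 2x2 chi-square of missing/non-missing by case/control."""
    case = data.phenotype == 1
    if not case.any() or case.all():
        raise ValueError("both phenotype classes required")
    miss = data.missing_mask()
    a = miss[case].sum(axis=0).astype(float)        # missing in cases
    b = (~miss[case]).sum(axis=0).astype(float)
    c = miss[~case].sum(axis=0).astype(float)       # missing in controls
    d = (~miss[~case]).sum(axis=0).astype(float)
    n = a + b + c + d
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = n * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
    stat = np.where(col1 == 0, 0.0, stat)  # no missing calls at all -> P=1
    return chi2.sf(stat, 1)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Sums the probabilities of all heterozygote counts, conditional on the
    allele counts, that are no more probable than the observed one.
    Monomorphic input returns 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total count must be positive")
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = _hwe_log_probs(n, rare, hets)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_Aa)]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def _hwe_log_probs(n: int, rare: int, hets: np.ndarray) -> np.ndarray:
    common = 2 * n - rare
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    return (hets * np.log(2.0)
            + gammaln(n + 1) - gammaln(hom_r + 1) - gammaln(hets + 1)
            - gammaln(hom_c + 1)
            + gammaln(rare + 1) + gammaln(common + 1) - gammaln(2 * n + 1))


def hwe_filter(data: GenotypeDataset, thr: QCThresholds) -> np.ndarray:
    """Per-SNP HWE exact P (controls-only if configured)."""
    if thr.hwe_controls_only:
        sub = data.subset_samples(np.where(data.phenotype == 0)[0])
    else:
        sub = data
    g = sub.genotypes
    n_aa = (g == 2).sum(axis=0)
    n_Aa = (g == 1).sum(axis=0)
    n_AA = (g == 0).sum(axis=0)
    return np.array([hwe_exact_test(int(a), int(h), int(b))
                     for a, h, b in zip(n_AA, n_Aa, n_aa)])


def maf_filter(data: GenotypeDataset, thr: QCThresholds) -> np.ndarray:
    """Boolean keep mask: MAF >= threshold on non-missing genotypes."""
    return data.minor_allele_freq() >= thr.maf_min


# ---------------------------------------------------------------------------
# PCA covariates and lambda screening
# ---------------------------------------------------------------------------

def pca_covariates(data: GenotypeDataset, pruned: list[str],
                   n_pcs: int = 20, random_state: int = 0) -> np.ndarray:
    """Sample scores on the top principal components of normalized genotypes.

    Missing calls are mean-imputed; each SNP is centred and scaled by
    sqrt(p(1-p)).  Returns an (n_samples, n_pcs) orthonormal score matrix
    (fewer columns, with a warning, if the matrix has lower rank).
    """
    idx = data.snp_index(pruned)
    X = data.dosage(impute=True)[:, idx]
    p = X.mean(axis=0) / 2.0
    scale = np.sqrt(np.clip(p * (1 - p), 1e-12, None))
    X = (X - 2 * p) / scale
    rank_cap = min(X.shape) - 1
    k = min(n_pcs, rank_cap)
    if k < n_pcs:
        warnings.warn(f"only {k} PCs available (rank limit)", stacklevel=2)
    U, S, _ = randomized_svd(X, n_components=k, random_state=random_state)
    return U


def select_pcs_by_lambda(data: GenotypeDataset, pcs: np.ndarray,
                         n_select: int = 5, method: str = "score"
                         ) -> tuple[list[int], np.ndarray]:
    """Rank PCs by the genomic inflation of a single-covariate scan.

    Each PC in turn is used as the sole covariate of an association scan;
    the ``n_select`` PCs with the smallest lambda win, ties broken by PC
    index.  The default scan statistic is the Rao score test (one shared
    null fit per PC, no per-SNP iteration); ``method="wald"`` runs the
    full logistic scan.
    """
    y = data.phenotype
    lambdas = np.empty(pcs.shape[1])
    if method == "score":
        G = data.dosage(impute=True).astype(np.float32)
        G2 = G * G
        yf = y.astype(np.float64)
        from .glm import _design, _null_fit
        for j in range(pcs.shape[1]):
            Z = _design(len(y), pcs[:, [j]])
            mu = _null_fit(Z, yf)
            w = (mu * (1 - mu)).astype(np.float32)
            r = (yf - mu).astype(np.float32)
            U = G.T @ r
            B = np.stack([(w * Z[:, c].astype(np.float32)) @ G
                          for c in range(Z.shape[1])])
            M = Z.T @ (w[:, None].astype(np.float64) * Z)
            V = w @ G2 - (B * np.linalg.solve(M, B.astype(np.float64))).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                chisq = np.where(V > 1e-8, U.astype(np.float64) ** 2 / V, np.nan)
            lambdas[j] = genomic_lambda(chisq)
    else:
        G = data.dosage(impute=False)
        for j in range(pcs.shape[1]):
            res = logistic_scan(G, y, covariates=pcs[:, [j]])
            lambdas[j] = genomic_lambda(res["chisq"])
    order = np.lexsort((np.arange(len(lambdas)), lambdas))
    chosen = sorted(order[:n_select].tolist())
    return chosen, lambdas


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class QCResult:
    data: GenotypeDataset
    assoc: pd.DataFrame
    lam: float
    report: dict = field(default_factory=dict)
    pruned_snps: list[str] = field(default_factory=list)
    pcs: np.ndarray | None = None
    chosen_pcs: list[int] = field(default_factory=list)
    pc_lambdas: np.ndarray | None = None


def _study_dummies(study: np.ndarray) -> np.ndarray | None:
    levels = sorted(set(study))
    if len(levels) < 2:
        return None
    return np.column_stack([(study == s).astype(float) for s in levels[1:]])


def run_qc(data: GenotypeDataset, thr: QCThresholds | None = None,
           screen_method: str = "score") -> QCResult:
    """Run the full QC + association pipeline in the canonical order."""
    thr = thr or QCThresholds()
    report: dict = {"n_samples_in": data.n_samples, "n_snps_in": data.n_snps}

    data, removed_snps = filter_snp_missingness(data, thr)
    report["snps_removed_missingness"] = len(removed_snps)

    data, removed_samples, het_stats = filter_samples(data, thr)
    report["samples_removed"] = len(removed_samples)
    report.update(het_stats)

    pruned = ld_prune(data, thr.prune_r2, thr.prune_window, thr.prune_step)
    report["n_pruned_snps"] = len(pruned)
    pairs, ibd_removed = ibd_estimate(data, pruned, thr)
    report["ibd_flagged_pairs"] = len(pairs)
    report["samples_removed_ibd"] = len(ibd_removed)
    if ibd_removed:
        keep = ~np.isin(data.sample_ids, ibd_removed)
        data = data.subset_samples(np.where(keep)[0])
    data_post_ibd = data

    diff_p = differential_missingness_test(data)
    keep = diff_p >= thr.diff_miss_p
    report["snps_removed_diff_missingness"] = int((~keep).sum())
    data = data.subset_snps(np.where(keep)[0])

    keep = maf_filter(data, thr)
    report["snps_removed_maf"] = int((~keep).sum())
    data = data.subset_snps(np.where(keep)[0])

    hwe_p = hwe_filter(data, thr)
    keep = hwe_p >= thr.hwe_p
    report["snps_removed_hwe"] = int((~keep).sum())
    data = data.subset_snps(np.where(keep)[0])
    report["n_samples_out"] = data.n_samples
    report["n_snps_out"] = data.n_snps

    # PCs on the pruned collection (same SNPs as the IBD step)
    pcs = pca_covariates(data_post_ibd, pruned, thr.n_pcs_screened)
    chosen, lambdas = select_pcs_by_lambda(data_post_ibd, pcs,
                                           thr.n_pcs_used, screen_method)
    covs = [pcs[:, chosen]]
    dummies = _study_dummies(data.study_indicator)
    if dummies is not None:
        covs.append(dummies)
    covariates = np.column_stack(covs)

    scan = logistic_scan(data.dosage(impute=False), data.phenotype, covariates)
    report["n_nonconverged"] = int((~scan["converged"]).sum())
    lam = genomic_lambda(scan["chisq"])
    assoc = pd.DataFrame({
        "snp": data.snp_ids,
        "chrom": data.snp_table["chrom"].to_numpy(),
        "pos": data.snp_table["pos"].to_numpy(),
        "beta": scan["beta"],
        "se": scan["se"],
        "p": scan["p"],
    })
    return QCResult(data=data, assoc=assoc, lam=lam, report=report,
                    pruned_snps=pruned, pcs=pcs, chosen_pcs=chosen,
                    pc_lambdas=lambdas)
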