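"""Core container for case-control genotype data.

Genotypes are stored as an int8 samples x SNPs matrix of minor-allele counts
{0, 1, 2} with ``-1`` marking a missing call.  Phenotype is binary
(1 = case, 0 = control); every sample carries a study label so that merged
collections can be modelled with study-indicator covariates downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = np.int8(-1)


@dataclass
class GenotypeDataset:
    """Samples x SNPs allele-count matrix with phenotype and metadata.

    Attributes
    ----------
    genotypes : ndarray of int8, shape (n_samples, n_snps)
        Minor-allele counts in {0, 1, 2}; -1 encodes a missing call.
    phenotype : ndarray of int, shape (n_samples,)
        1 for cases, 0 for controls.
    study_indicator : ndarray of str, shape (n_samples,)
        Study/collection label per sample.
    snp_table : DataFrame with columns snp, chrom, pos, a1, a2
        ``pos`` is 1-based and strictly increasing within chromosome.
    sample_ids : ndarray of str, shape (n_samples,)
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    study_indicator: np.ndarray
    snp_table: pd.DataFrame
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype)
        self.study_indicator = np.asarray(self.study_indicator)
        self.sample_ids = np.asarray(self.sample_ids)
        n, m = self.genotypes.shape
        if len(self.phenotype) != n or len(self.sample_ids) != n:
            raise ValueError("sample metadata length does not match genotypes")
        if len(self.snp_table) != m:
            raise ValueError("snp_table length does not match genotype columns")
        vals = np.unique(self.genotypes)
        if not np.all(np.isin(vals, [-1, 0, 1, 2])):
            raise ValueError("genotype entries must be in {0,1,2} or -1 (missing)")
        if not np.all(np.isin(self.phenotype, [0, 1])):
            raise ValueError("phenotype must be binary 0/1")
        for _, grp in self.snp_table.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
                raise ValueError("positions must be strictly increasing within chromosome")

    # -- basic shapes -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_table["snp"].to_numpy()

    # -- masks and summaries ---------------------------------------------
    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def snp_missing_rate(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - self.sample_missing_rate()

    def heterozygosity_rate(self) -> np.ndarray:
        """Per sample: heterozygous genotypes / non-missing genotypes."""
        het = (self.genotypes == 1).sum(axis=1)
        nonmiss = (~self.missing_mask()).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), np.nan)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted (a2) allele from non-missing genotypes."""
        g = self.genotypes.astype(np.float64)
        g[self.missing_mask()] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(g, axis=0) / 2.0

    def minor_allele_freq(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def dosage(self, impute: bool = True) -> np.ndarray:
        """Float genotype matrix; missing calls NaN or mean-imputed per SNP."""
        g = self.genotypes.astype(np.float64)
        g[self.missing_mask()] = np.nan
        if impute:
            col_mean = np.nanmean(np.where(np.isnan(g), np.nan, g), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(g))
            g[idx] = col_mean[idx[1]]
        return g

    # -- subsetting -------------------------------------------------------
    def subset_samples(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return replace(
            self,
            genotypes=self.genotypes[index],
            phenotype=self.phenotype[index],
            study_indicator=self.study_indicator[index],
            sample_ids=self.sample_ids[index],
        )

    def subset_snps(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return replace(
            self,
            genotypes=self.genotypes[:, index],
            snp_table=self.snp_table.iloc[index].reset_index(drop=True),
        )

    def snp_index(self, snp_ids) -> np.ndarray:
        """Positional indices of the given SNP ids, in the given order."""
        lookup = pd.Series(np.arange(self.n_snps), index=self.snp_table["snp"])
        missing = [s for s in snp_ids if s not in lookup.index]
        if missing:
            raise KeyError(f"unknown SNP ids: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        return lookup.loc[list(snp_ids)].to_numpy()
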