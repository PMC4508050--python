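"""Readers and writers for the plain-text interchange formats.

Genotypes travel as PLINK-style .ped/.map text (space separated, alleles
A/B, ``0 0`` for a missing call, phenotype coded 1=control/2=case, family
id reused as the study label).  Gene coordinates are BED-like TSV
(chrom, 0-based start, end, gene_id), the PPI network is a two-column TSV
of gene-symbol pairs, and gene sets use the GMT dialect
(term, description, tab-separated genes).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeDataset

_PED_CODES = {0: "A A", 1: "A B", 2: "B B", -1: "0 0"}
_PED_DECODE = {"AA": 0, "AB": 1, "BA": 1, "BB": 2, "00": -1}


# ---------------------------------------------------------------------------
# PLINK-style text genotypes
# ---------------------------------------------------------------------------

def write_ped_map(data: GenotypeDataset, prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ped_path, map_path = prefix.with_suffix(".ped"), prefix.with_suffix(".map")

    snp = data.snp_table
    with open(map_path, "w") as fh:
        for chrom, snp_id, pos in zip(snp["chrom"], snp["snp"], snp["pos"]):
            fh.write(f"{chrom} {snp_id} 0 {pos}\n")

    lut = np.array([_PED_CODES[0], _PED_CODES[1], _PED_CODES[2], _PED_CODES[-1]])
    codes = lut[np.where(data.genotypes == MISSING, 3, data.genotypes)]
    with open(ped_path, "w") as fh:
        for i in range(data.n_samples):
            pheno = 2 if data.phenotype[i] == 1 else 1
            head = f"{data.study_indicator[i]} {data.sample_ids[i]} 0 0 0 {pheno}"
            fh.write(head + " " + " ".join(codes[i]) + "\n")
    return ped_path, map_path


def read_ped_map(prefix: str | Path) -> GenotypeDataset:
    prefix = Path(prefix)
    ped_path, map_path = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    snp = pd.read_csv(map_path, sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos"], dtype={"chrom": str})
    snp = snp[["snp", "chrom", "pos"]].copy()
    snp["a1"], snp["a2"] = "A", "B"
    m = len(snp)

    studies, sample_ids, phenos, rows = [], [], [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"ped line has {len(parts)} fields, expected {6 + 2 * m}")
            studies.append(parts[0])
            sample_ids.append(parts[1])
            phenos.append(1 if parts[5] == "2" else 0)
            alleles = parts[6:]
            row = np.empty(m, dtype=np.int8)
            for j in range(m):
                row[j] = _PED_DECODE[alleles[2 * j] + alleles[2 * j + 1]]
            rows.append(row)
    return GenotypeDataset(
        genotypes=np.vstack(rows),
        phenotype=np.asarray(phenos),
        study_indicator=np.asarray(studies),
        snp_table=snp,
        sample_ids=np.asarray(sample_ids),
    )


# ---------------------------------------------------------------------------
# gene table / PPI / GMT
# ---------------------------------------------------------------------------

def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    genes[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", header=False, index=False)
    return path


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "gene"], dtype={"chrom": str})


def write_ppi(edges: Sequence[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")
    return path


def read_ppi(path: str | Path) -> list[tuple[str, str]]:
    edges = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            edges.append((parts[0], parts[1]))
    return edges


def write_gmt(terms: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for term, genes in terms.items():
            desc = (descriptions or {}).get(term, "na")
            fh.write(term + "\t" + desc + "\t" + "\t".join(genes) + "\n")
    return path


# ---------------------------------------------------------------------------
# per-stage result tables
# ---------------------------------------------------------------------------

def write_assoc(assoc: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    assoc.to_csv(path, sep="\t", index=False)
    return path


def read_assoc(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_gene_stats(stats: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    stats.to_csv(path, sep="\t", index=False)
    return path


def read_gene_stats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_modules(modules, path: str | Path) -> Path:
    """Module table: seed, members (semicolon-joined), k, score."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("seed\tmembers\tk\tscore\n")
        for mod in modules:
            members = ";".join(sorted(mod.members))
            fh.write(f"{mod.seed}\t{members}\t{len(mod.members)}\t{mod.score:.10g}\n")
    return path


def read_modules(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["members"] = df["members"].map(lambda s: tuple(s.split(";")))
    return df


# ---------------------------------------------------------------------------
# complete fixture bundle
# ---------------------------------------------------------------------------

def write_fixtures(datasets: Sequence[GenotypeDataset],
                   ppi: Sequence[tuple[str, str]],
                   gene_table: pd.DataFrame,
                   gmt_terms: Mapping[str, Sequence[str]],
                   out_dir: str | Path) -> dict[str, Path]:
    """Write every fixture a downstream run needs; checks id consistency."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gene_ids = set(gene_table["gene"])

    ppi_genes = {g for e in ppi for g in e}
    if not ppi_genes <= gene_ids:
        bad = sorted(ppi_genes - gene_ids)[:5]
        raise ValueError(f"PPI references genes absent from gene table: {bad}")
    for term, genes in gmt_terms.items():
        if not set(genes) <= gene_ids:
            bad = sorted(set(genes) - gene_ids)[:5]
            raise ValueError(f"GMT term {term!r} references unknown genes: {bad}")

    paths: dict[str, Path] = {}
    for data in datasets:
        study = str(data.study_indicator[0])
        ped, _ = write_ped_map(data, out_dir / study)
        paths[study] = ped
    paths["genes"] = write_gene_bed(gene_table, out_dir / "genes.bed")
    paths["ppi"] = write_ppi(ppi, out_dir / "ppi.tsv")
    paths["gmt"] = write_gmt(gmt_terms, out_dir / "sets.gmt")
    return paths
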