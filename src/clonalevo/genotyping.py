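"""Per-cell genotype calling from read counts, sample QC, and file I/O.

The calling rule reproduces the standard amplicon-panel filter: a call needs
total depth >= 10x and at least 3 alternate reads, with an additional variant
allele fraction gate of 15% in the 20-99x depth band and 10% at >= 100x.
Entries failing the depth gate are missing; alternate evidence below the VAF
gate is called wild type by default (the gates exist to suppress the ~1%
sequencing-error false positives), with a config switch to call it missing
instead.

Allele dropout (ADO) is estimated from loci known to be heterozygous in the
germline: the fraction of non-missing calls at those loci that look
homozygous (either direction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, ReadCountMatrix, WT, HET, HOM, MISSING

MIN_DEPTH = 10
MIN_ALT = 3
VAF_MID_BAND = 0.15  # 20x <= DP <= 99x
VAF_HIGH_BAND = 0.10  # DP >= 100x
HOM_VAF = 0.9  # optional zygosity-aware calling


@dataclass
class SampleQc:
    """Sample-level quality summary."""

    ado_rate: float
    missing_fraction: np.ndarray  # per locus
    mean_depth: np.ndarray  # per locus
    n_cells: int

    def __post_init__(self) -> None:
        if not 0 <= self.ado_rate <= 1:
            raise ValueError("ado_rate must lie in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "ado_rate": self.ado_rate,
            "missing_fraction": np.asarray(self.missing_fraction).tolist(),
            "mean_depth": np.asarray(self.mean_depth).tolist(),
            "n_cells": self.n_cells,
        }, indent=1))


def call_genotype(
    depth: int,
    alt_count: int,
    zygosity: bool = False,
    ambiguous_as_missing: bool = False,
) -> int:
    """Genotype one (depth, alt) observation.

    Returns 3 (missing) below 10x depth; 1 (mutant) when alt >= 3 and the
    depth-dependent VAF gate passes; 0 otherwise.  With ``zygosity`` a mutant
    call at VAF >= 0.9 becomes 2 (homozygous).  With ``ambiguous_as_missing``
    sub-gate alternate evidence (alt >= 3 but VAF below the band) returns 3
    instead of 0.
    """
    out = call_genotypes(
        np.array([[depth]]), np.array([[alt_count]]),
        zygosity=zygosity, ambiguous_as_missing=ambiguous_as_missing,
    )
    return int(out.codes[0, 0])


def call_genotypes(
    depth: np.ndarray,
    alt: np.ndarray,
    zygosity: bool = False,
    ambiguous_as_missing: bool = False,
    **matrix_kwargs,
) -> GenotypeMatrix:
    """Vectorized genotype calling over a (cells x loci) read-count pair."""
    depth = np.asarray(depth)
    alt = np.asarray(alt)
    if (alt > depth).any():
        raise ValueError("alt count exceeds depth")
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    vaf_ok = np.where(
        depth >= 100, vaf >= VAF_HIGH_BAND,
        np.where(depth >= 20, vaf >= VAF_MID_BAND, True),
    )
    mutant = (alt >= MIN_ALT) & vaf_ok
    codes = np.where(mutant, HET, WT).astype(np.int8)
    if zygosity:
        codes[mutant & (vaf >= HOM_VAF)] = HOM
    if ambiguous_as_missing:
        codes[(alt >= MIN_ALT) & ~vaf_ok] = MISSING
    codes[depth < MIN_DEPTH] = MISSING
    return GenotypeMatrix(codes, **matrix_kwargs)


def call_genotypes_from_reads(
    reads: ReadCountMatrix,
    zygosity_for_snps: bool = True,
    **kwargs,
) -> GenotypeMatrix:
    """Call a full ReadCountMatrix; SNP loci are called zygosity-aware by
    default so that dropout directions are distinguishable for ADO estimation."""
    gt = call_genotypes(
        reads.depth, reads.alt, cell_ids=reads.cell_ids,
        locus_ids=reads.locus_ids, sample_id=reads.sample_id, **kwargs,
    )
    if zygosity_for_snps and "snp" in reads.locus_class:
        snp = reads.loci_of_class("snp")
        zy = call_genotypes(reads.depth[:, snp], reads.alt[:, snp], zygosity=True)
        gt.codes[:, snp] = zy.codes
    return gt


def estimate_ado(snp_genotypes: GenotypeMatrix) -> float:
    """ADO rate from loci known to be germline-heterozygous.

    Both dropout directions count: a homozygous-reference (0) or
    homozygous-alternate (2) call at a known-het locus reflects loss of one
    allele.  Denominator is the number of non-missing calls.
    """
    codes = snp_genotypes.codes
    informative = codes != MISSING
    n = int(informative.sum())
    if n == 0:
        raise ValueError("all SNP calls are missing; cannot estimate ADO")
    dropped = int(((codes == WT) | (codes == HOM)).sum())
    return dropped / n


def compute_scvaf(reads: ReadCountMatrix, locus: int | str) -> float:
    """Pooled single-cell VAF at a locus: sum(alt reads) / sum(total reads)."""
    j = reads.locus_ids.index(locus) if isinstance(locus, str) else int(locus)
    total = int(reads.depth[:, j].sum())
    if total == 0:
        raise ValueError(f"zero total depth at locus {reads.locus_ids[j]}")
    return float(reads.alt[:, j].sum() / total)


def sample_qc(reads: ReadCountMatrix, genotypes: GenotypeMatrix) -> SampleQc:
    """Per-sample QC: ADO from SNP loci, per-locus missingness and depth."""
    snp = reads.loci_of_class("snp")
    if not snp.any():
        raise ValueError("no germline SNP loci available for ADO estimation")
    snp_gt = GenotypeMatrix(genotypes.codes[:, snp])
    return SampleQc(
        ado_rate=estimate_ado(snp_gt),
        missing_fraction=(genotypes.codes == MISSING).mean(axis=0),
        mean_depth=reads.depth.mean(axis=0),
        n_cells=genotypes.n_cells,
    )


# ---------------------------------------------------------------------------
# I/O: tab-separated genotype / read-count matrices, VCF locus annotations
# ---------------------------------------------------------------------------

def write_genotype_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Cells x loci codes as TSV: header row of locus ids, first column cell id."""
    df = pd.DataFrame(matrix.codes, index=list(matrix.cell_ids),
                      columns=list(matrix.locus_ids))
    df.index.name = "cell_id"
    df.to_csv(path, sep="\t")


def read_genotype_tsv(path: str | Path, **matrix_kwargs) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty genotype matrix (no cells or no loci)")
    codes = df.to_numpy()
    if not np.issubdtype(codes.dtype, np.integer):
        raise ValueError(f"{path}: non-integer genotype codes")
    return GenotypeMatrix(
        codes, cell_ids=tuple(map(str, df.index)),
        locus_ids=tuple(map(str, df.columns)), **matrix_kwargs,
    )


def write_readcount_tsvs(reads: ReadCountMatrix, depth_path, alt_path) -> None:
    for arr, path in ((reads.depth, depth_path), (reads.alt, alt_path)):
        df = pd.DataFrame(arr, index=list(reads.cell_ids), columns=list(reads.locus_ids))
        df.index.name = "cell_id"
        df.to_csv(path, sep="\t")


def read_readcount_tsvs(depth_path, alt_path, locus_class=None) -> ReadCountMatrix:
    d = pd.read_csv(depth_path, sep="\t", index_col=0)
    a = pd.read_csv(alt_path, sep="\t", index_col=0)
    if list(d.index) != list(a.index) or list(d.columns) != list(a.columns):
        raise ValueError("depth and alt TSVs disagree on cells or loci")
    return ReadCountMatrix(
        d.to_numpy(), a.to_numpy(), cell_ids=tuple(map(str, d.index)),
        locus_ids=tuple(map(str, d.columns)), locus_class=locus_class,
    )


def read_variant_vcf(path: str | Path) -> pd.DataFrame:
    """Locus annotations from a VCF 4.x sites file (1-based coordinates).

    Returns one row per ALT allele with CHROM/POS/REF/ALT plus gene and
    protein-change annotations when present (INFO keys GENE/AA, or the first
    ANN entry's gene and HGVS.p fields).
    """
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(str(path)):
        gene = rec.INFO.get("GENE")
        aa = rec.INFO.get("AA")
        ann = rec.INFO.get("ANN")
        if ann and (gene is None or aa is None):
            first = str(ann).split(",")[0].split("|")
            if gene is None and len(first) > 3:
                gene = first[3] or None
            if aa is None and len(first) > 10:
                aa = first[10] or None
        for alt in rec.ALT:
            rows.append({
                "chrom": rec.CHROM, "pos": rec.POS, "ref": rec.REF, "alt": alt,
                "gene": gene, "protein_change": aa,
            })
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene",
                                       "protein_change"])
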