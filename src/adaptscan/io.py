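"""Readers and writers for the interchange formats.

VCF is the canonical genotype form (v4.2, GT only, with the three INFO keys
the hard filters use and QUAL carrying the alternative-allele quality).
Coordinates are converted exactly once at this boundary: VCF positions are
1-based, BED intervals 0-based half-open.

Reading goes through cyvcf2; writing is plain text since the artifact only
ever emits biallelic SNP records it built itself.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GeneInterval, GenotypeMatrix, PhenotypeTable
from .errors import DataError

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_phenotypes",
    "write_phenotypes",
    "read_populations",
    "write_populations",
    "hard_labels",
    "read_coords",
    "write_coords",
]

_VCF_HEADER = """##fileformat=VCFv4.2
##source=adaptscan
##INFO=<ID=InbreedingCoeff,Number=1,Type=Float,Description="Inbreeding coefficient">
##INFO=<ID=HaplotypeScore,Number=1,Type=Float,Description="Haplotype score">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_STR = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(gm: GenotypeMatrix, path, annotations: pd.DataFrame | None = None) -> None:
    """Write genotypes (and optional per-site INFO annotations) as VCF v4.2."""
    ann = None
    if annotations is not None:
        if len(annotations) != gm.n_sites:
            raise DataError("annotations do not cover every site")
        ann = annotations.reset_index(drop=True)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in pd.unique(gm.chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.accessions)
            + "\n"
        )
        for j in range(gm.n_sites):
            if ann is not None:
                qual = f"{ann['alt_quality'].iloc[j]:.2f}"
                info = (
                    f"InbreedingCoeff={ann['inbreeding_coeff'].iloc[j]:.4f};"
                    f"HaplotypeScore={ann['haplotype_score'].iloc[j]:.4f};"
                    f"DP={int(ann['depth'].iloc[j])}"
                )
            else:
                qual, info = ".", "."
            gts = "\t".join(_GT_STR[int(g)] for g in gm.dosage[:, j])
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t.\tA\tT\t{qual}\t.\t{info}\tGT\t{gts}\n"
            )


def read_vcf(path):
    """Read a VCF into (GenotypeMatrix, annotations DataFrame).

    Multi-allelic and non-SNP records are skipped with a warning (the
    downstream statistics are defined for biallelic SNPs only).  Positions
    must be strictly increasing within each chromosome.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    dosages, chroms, positions = [], [], []
    ann_rows = []
    last = {}
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        if v.CHROM in last and v.POS <= last[v.CHROM]:
            raise DataError(
                f"unsorted VCF: {v.CHROM}:{v.POS} after {v.CHROM}:{last[v.CHROM]}"
            )
        last[v.CHROM] = v.POS
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt = v.gt_types.astype(np.int8)
        gt[gt == 3] = -1
        dosages.append(gt)
        chroms.append(v.CHROM)
        positions.append(v.POS)
        info = dict(v.INFO)
        ann_rows.append(
            {
                "chrom": v.CHROM,
                "pos": v.POS,
                "inbreeding_coeff": info.get("InbreedingCoeff", np.nan),
                "haplotype_score": info.get("HaplotypeScore", np.nan),
                "alt_quality": v.QUAL if v.QUAL is not None else np.nan,
                "depth": info.get("DP", np.nan),
            }
        )
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} multi-allelic/non-SNP records")
    if not dosages:
        raise DataError(f"no biallelic SNP records in {path}")
    gm = GenotypeMatrix(
        np.array(dosages, dtype=np.int8).T,
        samples,
        np.array(chroms, dtype=object),
        np.array(positions, dtype=np.int64),
    )
    return gm, pd.DataFrame(ann_rows)


def write_bed(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")


def read_bed(path) -> list:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{ln}: BED line has fewer than 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise DataError(f"{path}:{ln}: empty interval")
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            genes.append(GeneInterval(name, chrom, start, end))
    return genes


def write_phenotypes(phen: PhenotypeTable, path) -> None:
    phen.data.to_csv(path, sep="\t", float_format="%.10g")


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col="accession_id")
    return PhenotypeTable(df)


def write_populations(membership: pd.DataFrame, path) -> None:
    membership.to_csv(path, sep="\t", float_format="%.6f")


def read_populations(path) -> pd.DataFrame:
    """Membership-fraction table; every row must sum to 1 within 1e-6."""
    df = pd.read_csv(path, sep="\t", index_col="accession_id")
    sums = df.sum(axis=1)
    bad = sums[(sums - 1.0).abs() > 1e-6]
    if len(bad):
        raise DataError(
            f"{path}: membership fractions do not sum to 1 for "
            f"{list(bad.index[:5])}"
        )
    return df


def hard_labels(membership: pd.DataFrame, threshold: float = 0.8):
    """Assign non-admixed accessions to their majority population.

    Returns (labels: dict accession -> population, admixed: list) where an
    accession is non-admixed iff its top membership fraction >= threshold.
    """
    labels, admixed = {}, []
    top = membership.idxmax(axis=1)
    frac = membership.max(axis=1)
    for acc in membership.index:
        if frac[acc] >= threshold:
            labels[acc] = top[acc]
        else:
            admixed.append(acc)
    return labels, admixed


def write_coords(coords: pd.DataFrame, path) -> None:
    coords.to_csv(path, sep="\t", float_format="%.6f")


def read_coords(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="accession_id")
    bad = df[(df["lat"].abs() > 90) | (df["lon"].abs() > 180)]
    if len(bad):
        raise DataError(f"{path}: coordinates out of range for {list(bad.index[:5])}")
    return df
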