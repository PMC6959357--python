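"""Core in-memory containers shared across the pipeline.

Genotypes are diploid biallelic SNPs coded as alt-allele dosage 0/1/2 with
-1 as the missing sentinel.  Site coordinates are 1-based (VCF convention);
gene intervals are 0-based half-open (BED convention) and converted exactly
once, in the io layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Accessions x sites alt-allele dosage matrix.

    Parameters
    ----------
    dosage : int8 array, shape (n_accessions, n_sites)
        0/1/2 alt-allele counts, -1 for missing calls.
    accessions : list of str
        Accession identifiers (row labels).
    chrom : array of str, shape (n_sites,)
    pos : int array, shape (n_sites,)
        1-based positions, strictly increasing within each chromosome.
    """

    dosage: np.ndarray
    accessions: list
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (accessions x sites)")
        n_acc, n_sites = self.dosage.shape
        if len(self.accessions) != n_acc:
            raise ValueError("accession labels do not match dosage rows")
        if len(self.chrom) != n_sites or len(self.pos) != n_sites:
            raise ValueError("site coordinates do not match dosage columns")

    @property
    def n_accessions(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[1]

    def called_mask(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosage >= 0

    def alt_freq(self) -> np.ndarray:
        """Per-site alt-allele frequency over non-missing calls (nan if none)."""
        called = self.called_mask()
        n_called = called.sum(axis=0)
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def minor_allele_count(self) -> np.ndarray:
        """Per-site minor allele count over non-missing calls."""
        called = self.called_mask()
        n_called = called.sum(axis=0)
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        return np.minimum(alt, 2 * n_called - alt)

    def mean_imputed(self) -> np.ndarray:
        """Float copy with missing entries replaced by the per-site mean dosage."""
        x = self.dosage.astype(np.float64)
        miss = ~self.called_mask()
        if miss.any():
            col_mean = np.where(
                (~miss).sum(axis=0) > 0,
                np.where(miss, 0.0, x).sum(axis=0)
                / np.maximum((~miss).sum(axis=0), 1),
                0.0,
            )
            x = np.where(miss, col_mean[None, :], x)
        return x

    def accession_index(self, labels) -> np.ndarray:
        lut = {a: i for i, a in enumerate(self.accessions)}
        try:
            return np.array([lut[a] for a in labels], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"accession {e.args[0]!r} not in genotype matrix") from None

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosage[:, idx], list(self.accessions), self.chrom[idx], self.pos[idx]
        )


@dataclass
class GeneInterval:
    """A gene as a 0-based half-open interval."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty interval for {self.gene_id}")


@dataclass
class PhenotypeTable:
    """Trait values per accession; wraps a DataFrame indexed by accession_id."""

    data: pd.DataFrame

    def trait(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"trait column {name!r} not in phenotype table")
        return self.data[name]

    def aligned_vector(self, name: str, accessions) -> np.ndarray:
        """Trait values ordered to match a genotype matrix's accessions."""
        s = self.trait(name)
        missing = [a for a in accessions if a not in s.index]
        if missing:
            raise KeyError(f"accessions without phenotype: {missing[:5]}")
        return s.loc[list(accessions)].to_numpy(dtype=np.float64)


@dataclass
class SyntheticDataset:
    """A complete simulated scenario with recorded ground truth."""

    genotypes: GenotypeMatrix
    truth_pops: dict
    truth_causal: np.ndarray
    phenotypes: PhenotypeTable
    annotations: pd.DataFrame
    genes: list = field(default_factory=list)
    coords: pd.DataFrame | None = None

    def __post_init__(self):
        n = self.genotypes.n_sites
        if len(self.truth_causal) and (
            np.min(self.truth_causal) < 0 or np.max(self.truth_causal) >= n
        ):
            raise ValueError("causal site index out of range")
        if len(self.annotations) != n:
            raise ValueError("annotations must cover every site")
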