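"""Hard filtering of annotated SNP records and call-set summaries.

A record passes only if every rule holds (strict inequalities):
inbreeding coefficient > 0.1, haplotype score < 0.3, alternative-allele
quality > 30, total depth > 150, and the designated reference accession is
called homozygous reference.  Records missing a required annotation fail
the corresponding rule — conservative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix
from .errors import DataError

__all__ = [
    "FilterThresholds",
    "FilterSummary",
    "apply_hard_filters",
    "callable_positions",
    "site_frequency_spectrum",
    "concordance_stats",
    "ConcordanceStats",
]


@dataclass
class FilterThresholds:
    min_inbreeding_coeff: float = 0.1   # pass requires value > this
    max_haplotype_score: float = 0.3    # pass requires value < this
    min_alt_quality: float = 30.0       # pass requires value > this
    min_total_depth: float = 150.0      # pass requires value > this
    reference_accession_id: str | None = "MG-20"


@dataclass
class FilterSummary:
    n_input: int
    n_pass: int
    fail_counts: dict = field(default_factory=dict)
    n_callable: int | None = None

    def __post_init__(self):
        if self.n_pass > self.n_input:
            raise ValueError("n_pass exceeds n_input")


_RULES = (
    ("inbreeding_coeff", "min_inbreeding_coeff", "gt"),
    ("haplotype_score", "max_haplotype_score", "lt"),
    ("alt_quality", "min_alt_quality", "gt"),
    ("depth", "min_total_depth", "gt"),
)


def apply_hard_filters(
    annotations: pd.DataFrame,
    thresholds: FilterThresholds = FilterThresholds(),
    genotypes: GenotypeMatrix | None = None,
):
    """Evaluate the hard-filter rules per site.

    Parameters
    ----------
    annotations : DataFrame with columns inbreeding_coeff, haplotype_score,
        alt_quality, depth (NaN = annotation absent = rule fails).
    genotypes : required when the reference-homozygous rule is enabled
        (thresholds.reference_accession_id is not None).

    Returns
    -------
    (pass_mask: bool array over sites, FilterSummary)
    """
    n = len(annotations)
    pass_mask = np.ones(n, dtype=bool)
    fail_counts = {}
    for col, thr_attr, op in _RULES:
        vals = annotations[col].to_numpy(dtype=np.float64)
        thr = getattr(thresholds, thr_attr)
        with np.errstate(invalid="ignore"):
            ok = (vals > thr) if op == "gt" else (vals < thr)
        ok &= np.isfinite(vals)
        fail_counts[col] = int((~ok).sum())
        pass_mask &= ok
    if thresholds.reference_accession_id is not None:
        if genotypes is None:
            raise DataError("genotypes required for the reference hom-ref rule")
        ref_idx = genotypes.accession_index([thresholds.reference_accession_id])[0]
        ref_ok = genotypes.dosage[ref_idx, :] == 0
        fail_counts["reference_hom_ref"] = int((~ref_ok).sum())
        pass_mask &= ref_ok
    summary = FilterSummary(n_input=n, n_pass=int(pass_mask.sum()), fail_counts=fail_counts)
    return pass_mask, summary


def callable_positions(
    genotypes: GenotypeMatrix,
    pass_mask: np.ndarray | None = None,
    reference_accession_id: str | None = "MG-20",
) -> int:
    """Count passing sites with a call for >= 1 accession besides the reference."""
    called = genotypes.called_mask()
    if reference_accession_id is not None:
        ref_idx = genotypes.accession_index([reference_accession_id])[0]
        others = np.ones(genotypes.n_accessions, dtype=bool)
        others[ref_idx] = False
        ok = called[others, :].any(axis=0)
    else:
        ok = called.any(axis=0)
    if pass_mask is not None:
        ok = ok & np.asarray(pass_mask, dtype=bool)
    return int(ok.sum())


def site_frequency_spectrum(genotypes: GenotypeMatrix, folded: bool = False) -> np.ndarray:
    """Alt-allele-count spectrum over polymorphic sites.

    Bins 1..(2N-1) indexed by alt-allele count among non-missing alleles
    (folded: by minor-allele count).  Monomorphic sites are excluded, so the
    bins sum to the number of polymorphic sites.
    """
    n2 = 2 * genotypes.n_accessions
    called = genotypes.called_mask()
    n_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, genotypes.dosage, 0).sum(axis=0)
    poly = (alt > 0) & (alt < n_alleles)
    counts = alt[poly]
    if folded:
        counts = np.minimum(counts, n_alleles[poly] - counts)
    sfs = np.zeros(n2, dtype=np.int64)  # index = allele count; bin 0 unused
    np.add.at(sfs, counts, 1)
    return sfs


@dataclass
class ConcordanceStats:
    n_validated: int
    n_matched: int
    concordance: float
    enrichment: float | None = None
    fp_rate: float | None = None


def concordance_stats(
    calls: pd.Series,
    validated: pd.Series,
    retained_fraction_validated: float | None = None,
    retained_fraction_all: float | None = None,
    inbred_calls: np.ndarray | None = None,
) -> ConcordanceStats:
    """Concordance of a call set against independently validated genotypes.

    ``calls`` and ``validated`` are dosage series indexed by (chrom, pos);
    validated positions absent from the call set are ignored (they were not
    assayed in the retained set).  Fold-enrichment is the ratio of retained
    fractions; the false-positive rate is the heterozygote fraction among
    the calls of a designated fully-inbred accession, where every
    heterozygous call is assumed spurious.
    """
    if len(validated) == 0:
        raise DataError("validated call set is empty")
    common = validated.index.intersection(calls.index)
    matched = int((calls.loc[common] == validated.loc[common]).sum())
    concordance = matched / len(common) if len(common) else float("nan")
    enrichment = None
    if retained_fraction_validated is not None and retained_fraction_all:
        enrichment = retained_fraction_validated / retained_fraction_all
    fp_rate = None
    if inbred_calls is not None:
        g = np.asarray(inbred_calls)
        g = g[g >= 0]
        fp_rate = float((g == 1).mean()) if len(g) else float("nan")
    return ConcordanceStats(
        n_validated=len(common),
        n_matched=matched,
        concordance=concordance,
        enrichment=enrichment,
        fp_rate=fp_rate,
    )
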