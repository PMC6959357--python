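"""Population-genetic statistics.

Weir & Cockerham (1984) per-site F_ST between two accession groups, per-gene
mean F_ST, the +2/+1/0 pairwise genetic distance, windowed nucleotide
diversity, F_IS and the equilibrium selfing rate s = 2*F_IS/(1+F_IS),
linkage-disequilibrium r^2 with a physical-distance cap, genotype PCA and
WGS-84 geodesic distances.

The F_ST estimator uses the full variance-component decomposition with
observed heterozygote counts: a (among populations), b (among individuals
within populations), c (within individuals); F_ST = a/(a+b+c).  Negative
estimates are retained, not clamped — the permutation skew tests downstream
compare whole distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix
from .errors import DataError

__all__ = [
    "weir_fst_per_site",
    "per_gene_fst",
    "genetic_distance_matrix",
    "nucleotide_diversity",
    "inbreeding_and_selfing",
    "SelfingEstimate",
    "ld_r2",
    "pca",
    "geographic_distance",
    "vincenty_km",
]


def _group_stats(dosage: np.ndarray):
    """Per-site (n called diploids, alt freq, observed het fraction)."""
    called = dosage >= 0
    n = called.sum(axis=0).astype(np.float64)
    alt = np.where(called, dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        h = np.where(n > 0, np.where(called, dosage == 1, False).sum(axis=0) / n, np.nan)
    return n, p, h


def weir_fst_per_site(genotypes: GenotypeMatrix, group_a, group_b) -> pd.DataFrame:
    """Weir–Cockerham per-site F_ST between two disjoint accession groups.

    Returns a frame with chrom, pos, the variance components a, b, c, fst
    (NaN when the denominator is <= 0) and an ``informative`` flag requiring
    >= 2 called diploids in each group.  Uninformative or undefined sites
    are flagged, never dropped.
    """
    ia = genotypes.accession_index(group_a)
    ib = genotypes.accession_index(group_b)
    if set(ia) & set(ib):
        raise DataError("accession groups overlap")
    n1, p1, h1 = _group_stats(genotypes.dosage[ia, :])
    n2, p2, h2 = _group_stats(genotypes.dosage[ib, :])

    r = 2.0
    nbar = (n1 + n2) / r
    informative = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        fst = np.where(informative & (denom > 0), a / denom, np.nan)
    bad = ~informative
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return pd.DataFrame(
        {
            "chrom": genotypes.chrom,
            "pos": genotypes.pos,
            "a": a,
            "b": b,
            "c": c,
            "fst": fst,
            "informative": informative & np.isfinite(fst),
        }
    )


def per_gene_fst(
    track: pd.DataFrame, genes, min_snps: int = 4, weighted: bool = False
) -> pd.DataFrame:
    """Mean F_ST per gene over informative sites; genes with fewer than
    ``min_snps`` informative SNPs are omitted.

    ``weighted=True`` switches to the ratio-of-sums estimator
    sum(a)/sum(a+b+c) instead of the unweighted mean of per-site ratios.
    """
    rows = []
    chrom = track["chrom"].to_numpy()
    pos = track["pos"].to_numpy()
    ok = track["informative"].to_numpy() & np.isfinite(track["fst"].to_numpy())
    for g in genes:
        # BED half-open [start, end) against 1-based positions
        sel = ok & (chrom == g.chrom) & (pos - 1 >= g.start) & (pos - 1 < g.end)
        n_inf = int(sel.sum())
        if n_inf < min_snps:
            continue
        if weighted:
            num = track.loc[sel, "a"].sum()
            den = (track.loc[sel, ["a", "b", "c"]].sum(axis=1)).sum()
            mean_fst = num / den if den > 0 else np.nan
        else:
            mean_fst = float(track.loc[sel, "fst"].mean())
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "n_informative_snps": n_inf,
                "mean_fst": mean_fst,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "n_informative_snps", "mean_fst"]
    )


def genetic_distance_matrix(genotypes: GenotypeMatrix):
    """Pairwise distance: +2 per homozygous difference, +1 per heterozygous
    difference, 0 for identical genotypes, averaged over sites called in
    both accessions.  Returns (distance DataFrame, n_sites_used DataFrame);
    pairs with no overlapping called site are NaN.
    """
    d = genotypes.dosage.astype(np.float64)
    called = genotypes.called_mask()
    n = genotypes.n_accessions
    dist = np.zeros((n, n))
    used = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = called[i] & called
        diff = np.abs(d[i] - d)
        score = np.where(both, diff, 0.0).sum(axis=1)
        cnt = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist[i] = np.where(cnt > 0, score / cnt, np.nan)
        used[i] = cnt
    np.fill_diagonal(dist, 0.0)
    idx = pd.Index(genotypes.accessions, name="accession_id")
    return (
        pd.DataFrame(dist, index=idx, columns=idx),
        pd.DataFrame(used, index=idx, columns=idx),
    )


def nucleotide_diversity(genotypes: GenotypeMatrix, windows=None) -> pd.DataFrame:
    """Per-window pi: sum over sites of pairwise haplotype differences
    divided by C(n,2), divided by window length in bp.

    ``windows`` is a list of (chrom, start, end) 0-based half-open tuples;
    None means one window per chromosome spanning [0, max(pos)).
    """
    called = genotypes.called_mask()
    n2 = (2 * called.sum(axis=0)).astype(np.float64)
    alt = np.where(called, genotypes.dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(n2 >= 2, 2.0 * alt * (n2 - alt) / (n2 * (n2 - 1)), 0.0)
    if windows is None:
        windows = [
            (c, 0, int(genotypes.pos[genotypes.chrom == c].max()))
            for c in pd.unique(genotypes.chrom)
        ]
    rows = []
    for chrom, start, end in windows:
        if end <= start:
            raise DataError(f"empty window {chrom}:{start}-{end}")
        sel = (genotypes.chrom == chrom) & (genotypes.pos - 1 >= start) & (
            genotypes.pos - 1 < end
        )
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_sites": int(sel.sum()),
                "pi": float(per_site[sel].sum() / (end - start)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SelfingEstimate:
    per_population: pd.DataFrame  # population, h_obs, h_exp, f_is
    mean_f_is: float
    selfing_rate: float


def inbreeding_and_selfing(genotypes: GenotypeMatrix, pop_labels: dict) -> SelfingEstimate:
    """F_IS per population and the equilibrium selfing rate.

    Per population, observed and Hardy–Weinberg expected heterozygosity are
    averaged over loci; F_IS = 1 - Hobs/Hexp.  Hexp is Nei's unbiased gene
    diversity 2*p*(1-p)*2n/(2n-1): without the small-sample correction the
    plug-in 2*p*(1-p) is downward biased, which makes F_IS ~ -1/(2n-1) for a
    randomly mating population instead of 0.  The selfing rate follows from
    the mean F_IS across populations as s = 2*F_IS/(1 + F_IS).  Populations
    with Hexp = 0 at every locus are excluded with a warning.
    """
    pops = sorted({p for p in pop_labels.values()})
    rows = []
    for pop in pops:
        members = [a for a in genotypes.accessions if pop_labels.get(a) == pop]
        if len(members) < 2:
            continue
        sub = genotypes.dosage[genotypes.accession_index(members), :]
        n, p, h = _group_stats(sub)
        ok = n >= 2
        n2 = 2.0 * n[ok]  # allele count per locus
        hexp = 2 * p[ok] * (1 - p[ok]) * n2 / (n2 - 1)
        hobs = h[ok]
        mean_hexp = float(np.nanmean(hexp)) if ok.any() else 0.0
        if mean_hexp == 0.0:
            warnings.warn(f"population {pop}: Hexp is 0 at all loci; excluded")
            continue
        mean_hobs = float(np.nanmean(hobs))
        rows.append(
            {
                "population": pop,
                "h_obs": mean_hobs,
                "h_exp": mean_hexp,
                "f_is": 1.0 - mean_hobs / mean_hexp,
            }
        )
    if not rows:
        raise DataError("no population with defined F_IS")
    per_pop = pd.DataFrame(rows)
    mean_f_is = float(per_pop["f_is"].mean())
    s = 2.0 * mean_f_is / (1.0 + mean_f_is)
    return SelfingEstimate(per_pop, mean_f_is, s)


def ld_r2(
    genotypes: GenotypeMatrix,
    max_dist: int = 50_000,
    bin_width: int = 1_000,
    r2_target: float = 0.2,
    max_pairs: int | None = None,
    seed: int = 0,
):
    """r^2 (squared Pearson correlation of dosages, pairwise-complete) for
    all same-chromosome SNP pairs within ``max_dist`` bp.

    Returns (pairs DataFrame, decay DataFrame, decay_distance) where decay
    bins pair distances at ``bin_width`` and decay_distance is the upper
    edge of the first bin whose mean r^2 <= ``r2_target`` (None if never).
    Zero-variance sites yield undefined pairs, which are excluded.
    """
    d = genotypes.dosage.astype(np.float64)
    called = genotypes.called_mask()
    rows = []
    for chrom in pd.unique(genotypes.chrom):
        idx = np.flatnonzero(genotypes.chrom == chrom)
        pos = genotypes.pos[idx]
        for a_i, i in enumerate(idx):
            upper = np.searchsorted(pos, pos[a_i] + max_dist, side="right")
            js = idx[a_i + 1 : upper]
            if len(js) == 0:
                continue
            xi, ci = d[:, i], called[:, i]
            X, C = d[:, js], called[:, js]
            joint = ci[:, None] & C
            nj = joint.sum(axis=0).astype(np.float64)
            with np.errstate(invalid="ignore", divide="ignore"):
                sx = np.where(joint, xi[:, None], 0).sum(axis=0)
                sy = np.where(joint, X, 0).sum(axis=0)
                sxx = np.where(joint, xi[:, None] ** 2, 0).sum(axis=0)
                syy = np.where(joint, X**2, 0).sum(axis=0)
                sxy = np.where(joint, xi[:, None] * X, 0).sum(axis=0)
                cov = sxy - sx * sy / nj
                vx = sxx - sx**2 / nj
                vy = syy - sy**2 / nj
                r2 = cov**2 / (vx * vy)
            ok = (nj >= 2) & (vx > 0) & (vy > 0)
            for k in np.flatnonzero(ok):
                rows.append(
                    (chrom, int(genotypes.pos[i]), int(genotypes.pos[js[k]]), float(r2[k]))
                )
    pairs = pd.DataFrame(rows, columns=["chrom", "pos1", "pos2", "r2"])
    if max_pairs is not None and len(pairs) > max_pairs:
        pairs = pairs.sample(n=max_pairs, random_state=seed).reset_index(drop=True)
    if len(pairs):
        dist = pairs["pos2"] - pairs["pos1"]
        pairs = pairs.assign(distance=dist)
        bins = (dist - 1) // bin_width
        decay = (
            pairs.assign(bin=bins)
            .groupby("bin", as_index=False)
            .agg(mean_r2=("r2", "mean"), n_pairs=("r2", "size"))
        )
        decay["dist_upper"] = (decay["bin"] + 1) * bin_width
        below = decay[decay["mean_r2"] <= r2_target].sort_values("bin")
        decay_distance = int(below["dist_upper"].iloc[0]) if len(below) else None
    else:
        decay = pd.DataFrame(columns=["bin", "mean_r2", "n_pairs", "dist_upper"])
        decay_distance = None
    return pairs, decay, decay_distance


def pca(genotypes: GenotypeMatrix, n_components: int = 10):
    """PCA of the column-standardized genotype matrix.

    Missing entries are mean-imputed per site; columns are centered at 2p
    and scaled by sqrt(p(1-p)); fixed sites (p in {0,1}) are dropped.
    Returns (scores DataFrame (n x k), eigenvalues array) with eigenvalues
    non-increasing and orthogonal score columns.
    """
    n = genotypes.n_accessions
    if n_components > n:
        raise DataError("fewer accessions than requested components")
    X = genotypes.mean_imputed()
    p = X.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    X = X[:, keep]
    p = p[keep]
    Z = (X - 2 * p) / np.sqrt(p * (1 - p))
    Z -= Z.mean(axis=0)  # guard against residual column means under missingness
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    k = n_components
    scores = U[:, :k] * S[:k]
    eigenvalues = (S[:k] ** 2) / (n - 1)
    idx = pd.Index(genotypes.accessions, name="accession_id")
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=idx, columns=cols), eigenvalues


# WGS-84 ellipsoid
_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_WGS84_B = _WGS84_A * (1.0 - _WGS84_F)


def vincenty_km(lat1, lon1, lat2, lon2, max_iter: int = 200, tol: float = 1e-12) -> float:
    """Vincenty inverse geodesic distance on the WGS-84 ellipsoid, in km.

    Nearly antipodal pairs that fail to converge fall back to the last
    iterate with a warning.
    """
    if (lat1, lon1) == (lat2, lon2):
        return 0.0
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    L = np.radians(lon2 - lon1)
    U1, U2 = np.arctan((1 - _WGS84_F) * np.tan(phi1)), np.arctan(
        (1 - _WGS84_F) * np.tan(phi2)
    )
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)
    lam = L
    converged = False
    for _ in range(max_iter):
        sinl, cosl = np.sin(lam), np.cos(lam)
        sin_sigma = np.hypot(
            cosU2 * sinl, cosU1 * sinU2 - sinU1 * cosU2 * cosl
        )
        if sin_sigma == 0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cosl
        sigma = np.arctan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sinl / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        cos_2sm = (
            cos_sigma - 2 * sinU1 * sinU2 / cos2_alpha if cos2_alpha != 0 else 0.0
        )
        C = _WGS84_F / 16 * cos2_alpha * (4 + _WGS84_F * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * _WGS84_F * sin_alpha * (
            sigma
            + C
            * sin_sigma
            * (cos_2sm + C * cos_sigma * (-1 + 2 * cos_2sm**2))
        )
        if abs(lam - lam_prev) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("Vincenty iteration did not converge (near-antipodal pair)")
    u2 = cos2_alpha * (_WGS84_A**2 - _WGS84_B**2) / _WGS84_B**2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    d_sigma = (
        B
        * sin_sigma
        * (
            cos_2sm
            + B
            / 4
            * (
                cos_sigma * (-1 + 2 * cos_2sm**2)
                - B
                / 6
                * cos_2sm
                * (-3 + 4 * sin_sigma**2)
                * (-3 + 4 * cos_2sm**2)
            )
        )
    )
    return _WGS84_B * A * (sigma - d_sigma) / 1000.0


def geographic_distance(coords: pd.DataFrame) -> pd.DataFrame:
    """Symmetric accession x accession geodesic distance matrix in km."""
    bad = coords[(coords["lat"].abs() > 90) | (coords["lon"].abs() > 180)]
    if len(bad):
        raise DataError(f"coordinates out of range: {list(bad.index[:5])}")
    acc = list(coords.index)
    n = len(acc)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = vincenty_km(
                coords["lat"].iloc[i],
                coords["lon"].iloc[i],
                coords["lat"].iloc[j],
                coords["lon"].iloc[j],
            )
            out[i, j] = out[j, i] = d
    idx = pd.Index(acc, name="accession_id")
    return pd.DataFrame(out, index=idx, columns=idx)
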