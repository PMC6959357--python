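"""Mixed-model genome-wide association.

The trait model is y = X b + g + e with g ~ N(0, sigma_g^2 K) and
e ~ N(0, sigma_e^2 I).  Variance components are estimated by restricted
maximum likelihood over delta = sigma_e^2/sigma_g^2 using the spectral
(eigendecomposition) form of the restricted likelihood, with a deterministic
log-delta grid plus bounded local refinement.  The genome scan fixes the
null-model covariance and tests every SNP by generalized least squares
(the EMMAX approximation); the strongest hits can be refined by
re-estimating variance components per SNP (full EMMA).

Kinship defaults to allele-sharing IBS, K_ij = mean(1 - |x_i - x_j|/2);
a centered (VanRaden) genomic relationship matrix is available by flag and
is what the SNP-subset variance-explained estimator uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import GenotypeMatrix
from .errors import DataError, NumericalError

__all__ = [
    "kinship_matrix",
    "VarianceComponents",
    "fit_null_mixed_model",
    "restricted_loglik",
    "emmax_scan",
    "emma_refine",
    "select_top",
    "variance_explained",
    "bonferroni_threshold",
    "ScanContext",
]

_LOG_DELTA_RANGE = (-10.0, 10.0)
_N_GRID = 100


def kinship_matrix(genotypes: GenotypeMatrix, method: str = "ibs") -> pd.DataFrame:
    """Accession x accession relatedness.

    ``ibs``: mean allele-sharing, K_ij = mean_sites(1 - |x_i - x_j| / 2) over
    sites called in both accessions; unit diagonal, entries in [0, 1].
    ``centered``: VanRaden normalized cross-product W W' / (2 sum p(1-p))
    with W = X - 2p, missing genotypes mean-imputed per site.
    """
    if genotypes.n_sites == 0:
        raise DataError("no sites to compute kinship from")
    if method == "ibs":
        # pairwise-complete allele sharing via indicator products:
        # |xi - xj| = (xi - xj)^2 - 2*[xi=0][xj=2] - 2*[xi=2][xj=0]
        called = genotypes.called_mask().astype(np.float64)
        x = np.where(genotypes.dosage >= 0, genotypes.dosage, 0).astype(np.float64)
        x2 = x * x
        i0 = ((genotypes.dosage == 0)).astype(np.float64)
        i2 = ((genotypes.dosage == 2)).astype(np.float64)
        n_joint = called @ called.T
        if np.any(n_joint == 0):
            raise DataError("accession pair with no jointly called site")
        sq = x2 @ called.T + called @ x2.T - 2.0 * (x @ x.T)
        absdiff = sq - 2.0 * (i0 @ i2.T + i2 @ i0.T)
        K = 1.0 - absdiff / (2.0 * n_joint)
        K = (K + K.T) / 2.0
        np.fill_diagonal(K, 1.0)
    elif method == "centered":
        X = genotypes.mean_imputed()
        p = X.mean(axis=0) / 2.0
        keep = (p > 0) & (p < 1)
        if not keep.any():
            raise DataError("no polymorphic sites for centered kinship")
        W = X[:, keep] - 2 * p[keep]
        K = W @ W.T / (2.0 * np.sum(p[keep] * (1 - p[keep])))
    else:
        raise DataError(f"unknown kinship method {method!r}")
    idx = pd.Index(genotypes.accessions, name="accession_id")
    out = pd.DataFrame(K, index=idx, columns=idx)
    out.attrs["method"] = method
    return out


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    delta: float
    loglik: float

    def __post_init__(self):
        if not (-1e-9 <= self.h2 <= 1 + 1e-9):
            raise NumericalError(f"pseudo-heritability {self.h2} outside [0, 1]")


def _projected_spectrum(K: np.ndarray, X: np.ndarray):
    """Eigenpairs of S K S on the complement of col(X); S = I - X pinv(X)."""
    n, q = X.shape
    S = np.eye(n) - X @ np.linalg.pinv(X)
    SKS = S @ K @ S
    SKS = (SKS + SKS.T) / 2.0
    w, V = np.linalg.eigh(SKS)
    xi = w[q:]  # drop the q (numerically) zero eigenvalues of the projection
    U = V[:, q:]
    return np.maximum(xi, 0.0), U


def _spectral_ll(log_delta: float, xi: np.ndarray, eta2: np.ndarray) -> float:
    """Restricted log-likelihood profiled over sigma_g^2, at delta."""
    delta = np.exp(log_delta)
    nq = len(xi)
    denom = xi + delta
    rss = float(np.sum(eta2 / denom))
    return 0.5 * (
        nq * np.log(nq / (2 * np.pi)) - nq - nq * np.log(rss) - float(np.sum(np.log(denom)))
    )


def restricted_loglik(delta: float, y: np.ndarray, K: np.ndarray, X: np.ndarray | None = None):
    """Spectral restricted log-likelihood at delta (sigma_g^2 profiled out)."""
    y = np.asarray(y, dtype=np.float64)
    if X is None:
        X = np.ones((len(y), 1))
    xi, U = _projected_spectrum(np.asarray(K, dtype=np.float64), X)
    eta2 = (U.T @ y) ** 2
    return _spectral_ll(np.log(delta), xi, eta2)


def _fit_reml(y: np.ndarray, K: np.ndarray, X: np.ndarray, spectrum=None) -> VarianceComponents:
    y = np.asarray(y, dtype=np.float64)
    if not np.all(np.isfinite(y)):
        raise DataError("non-finite phenotype values")
    n, q = X.shape
    if n - q < 2:
        raise DataError("too few observations for REML")
    xi, U = spectrum if spectrum is not None else _projected_spectrum(K, X)
    eta2 = (U.T @ y) ** 2
    grid = np.linspace(*_LOG_DELTA_RANGE, _N_GRID)
    lls = np.array([_spectral_ll(g, xi, eta2) for g in grid])
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, _N_GRID - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_spectral_ll(g, xi, eta2),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    best = res.x if -res.fun >= lls[i] else grid[i]
    delta = float(np.exp(best))
    sigma_g2 = float(np.sum(eta2 / (xi + delta)) / (n - q))
    sigma_e2 = delta * sigma_g2
    h2 = 1.0 / (1.0 + delta)
    return VarianceComponents(sigma_g2, sigma_e2, h2, delta, _spectral_ll(best, xi, eta2))


def fit_null_mixed_model(y, K) -> VarianceComponents:
    """REML fit of the intercept-only mixed model y = mu + g + e."""
    y = np.asarray(y, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    if len(y) < 10:
        raise DataError("need at least 10 observations")
    if K.shape != (len(y), len(y)):
        raise DataError("kinship dimensions do not match phenotype")
    if not np.allclose(K, K.T, atol=1e-8):
        raise DataError("kinship matrix is not symmetric")
    return _fit_reml(y, K, np.ones((len(y), 1)))


class ScanContext:
    """Precomputed decompositions reused across scans of the same genotypes.

    Holds the eigendecomposition of K (for the GLS rotation), the projected
    spectrum of K (for per-surrogate REML refits) and the rotated genotype
    block U' G, so that scanning B surrogate phenotypes costs O(n m) each
    instead of O(n^2 m).
    """

    def __init__(self, genotypes: GenotypeMatrix, K: np.ndarray, min_mac: int = 8):
        K = np.asarray(K, dtype=np.float64)
        self.genotypes = genotypes
        self.K = K
        mac = genotypes.minor_allele_count()
        self.keep = np.flatnonzero(mac >= min_mac)
        self.mac = mac[self.keep]
        self.chrom = genotypes.chrom[self.keep]
        self.pos = genotypes.pos[self.keep]
        lam, U = np.linalg.eigh(K)
        self.lam = np.maximum(lam, 0.0)
        self.U = U
        G = genotypes.mean_imputed()[:, self.keep]
        self.UtG = U.T @ G
        self.Ut1 = U.T @ np.ones(K.shape[0])
        self.null_spectrum = _projected_spectrum(K, np.ones((K.shape[0], 1)))

    def fit_null(self, y) -> VarianceComponents:
        return _fit_reml(
            np.asarray(y, float), self.K, np.ones((len(y), 1)), spectrum=self.null_spectrum
        )

    def scan(self, y, vc: VarianceComponents) -> pd.DataFrame:
        """GLS scan with fixed covariance sigma_g^2 K + sigma_e^2 I."""
        y = np.asarray(y, dtype=np.float64)
        n = len(y)
        D = vc.sigma_g2 * self.lam + vc.sigma_e2
        if np.any(D <= 0):
            raise NumericalError("non-positive rotated covariance")
        w = 1.0 / np.sqrt(D)
        yt = w * (self.U.T @ y)
        at = w * self.Ut1
        Gt = self.UtG * w[:, None]

        aa = float(at @ at)
        ay = float(at @ yt)
        yy = float(yt @ yt)
        ag = at @ Gt
        gy = yt @ Gt
        gg = np.einsum("ij,ij->j", Gt, Gt)

        det = aa * gg - ag**2
        ok = det > 1e-12 * aa * np.maximum(gg, 1e-300)
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = (aa * gy - ag * ay) / det
            beta0 = (ay - ag * beta) / aa
            # RSS = y'y - b'X'y via the normal equations, X = [a g]
            rss = yy - beta0 * ay - beta * gy
            sigma2 = np.maximum(rss, 0.0) / (n - 2)
            se = np.sqrt(sigma2 * aa / det)
            t = beta / se
        df = n - 2
        p = np.where(ok, 2.0 * stats.t.sf(np.abs(t), df), np.nan)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        out = pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "beta": np.where(ok, beta, np.nan),
                "se": np.where(ok, se, np.nan),
                "p_value": np.where(ok, p, np.nan),
                "mac": self.mac,
                "site_index": self.keep,
            }
        )
        out["neg_log10_p"] = -np.log10(out["p_value"])
        out["refined"] = False
        return out


def emmax_scan(
    y,
    genotypes: GenotypeMatrix,
    K,
    vc: VarianceComponents | None = None,
    min_mac: int = 8,
    context: ScanContext | None = None,
) -> pd.DataFrame:
    """EMMAX genome scan: GLS per SNP with the null covariance held fixed.

    SNPs with minor allele count < ``min_mac`` are omitted.  Returns a frame
    with chrom, pos, beta, se, p_value, neg_log10_p, mac, site_index,
    refined (False).
    """
    y = np.asarray(y, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    if K.shape[0] != len(y) or genotypes.n_accessions != len(y):
        raise DataError("dimension mismatch between phenotype, kinship and genotypes")
    ctx = context if context is not None else ScanContext(genotypes, K, min_mac=min_mac)
    if vc is None:
        vc = ctx.fit_null(y)
    return ctx.scan(y, vc)


def emma_refine(
    y, genotypes: GenotypeMatrix, K, result: pd.DataFrame, top_k: int = 200
) -> pd.DataFrame:
    """Re-estimate variance components per SNP for the top hits (full EMMA).

    For each of the ``top_k`` smallest-p SNPs, REML is re-run with that SNP
    in the fixed effects and the p-value replaced by the GLS test at the
    SNP-specific optimum; the ``refined`` flag marks adjusted rows.  The SNP
    count is preserved.
    """
    y = np.asarray(y, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    X_all = genotypes.mean_imputed()
    out = result.copy().reset_index(drop=True)
    order = np.lexsort((out["pos"].to_numpy(), out["chrom"].to_numpy(), out["p_value"].to_numpy()))
    take = order[: min(top_k, len(order))]
    n = len(y)
    ones = np.ones((n, 1))
    for row in take:
        j = int(out.at[row, "site_index"])
        x = X_all[:, j]
        if np.var(x) == 0:
            continue
        X = np.column_stack([ones, x])
        vc = _fit_reml(y, K, X)
        lam, U = np.linalg.eigh(K)
        D = vc.sigma_g2 * np.maximum(lam, 0.0) + vc.sigma_e2
        w = 1.0 / np.sqrt(D)
        Xt = (U.T @ X) * w[:, None]
        yt = (U.T @ y) * w
        XtX = Xt.T @ Xt
        coef, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
        resid = yt - Xt @ coef
        sigma2 = float(resid @ resid) / (n - 2)
        cov = sigma2 * np.linalg.inv(XtX)
        se = float(np.sqrt(cov[1, 1]))
        t = coef[1] / se
        p = float(np.clip(2.0 * stats.t.sf(abs(t), n - 2), np.finfo(float).tiny, 1.0))
        out.at[row, "beta"] = coef[1]
        out.at[row, "se"] = se
        out.at[row, "p_value"] = p
        out.at[row, "neg_log10_p"] = -np.log10(p)
        out.at[row, "refined"] = True
    return out


def select_top(result: pd.DataFrame, k: int | None = None, p_threshold: float | None = None) -> pd.DataFrame:
    """Deterministic top-SNP selection: ascending p, ties broken by (chrom, pos).

    Exactly one of ``k`` (top-k) or ``p_threshold`` must be given.  If k
    exceeds the available SNPs, all are returned with a warning.
    """
    if (k is None) == (p_threshold is None):
        raise DataError("specify exactly one of k or p_threshold")
    res = result.dropna(subset=["p_value"])
    order = np.lexsort(
        (res["pos"].to_numpy(), res["chrom"].to_numpy(), res["p_value"].to_numpy())
    )
    res = res.iloc[order]
    if k is not None:
        if k > len(res):
            warnings.warn(f"requested top {k} but only {len(res)} SNPs available")
            return res.reset_index(drop=True)
        return res.head(k).reset_index(drop=True)
    return res[res["p_value"] <= p_threshold].reset_index(drop=True)


def variance_explained(
    y, genotypes: GenotypeMatrix, snp_indices, min_mac: int = 10
) -> float:
    """Fraction of phenotypic variance explained by a SNP set (GREML-style).

    Builds a centered genomic relationship matrix from the selected SNPs
    only (those with minor allele count >= ``min_mac``), fits the
    one-component REML model and returns sigma_g^2/(sigma_g^2 + sigma_e^2).
    The GRM is rescaled to unit mean diagonal so the ratio is a fraction of
    phenotypic variance even under inbreeding (where the VanRaden diagonal
    averages 1 + F, not 1).
    """
    snp_indices = np.asarray(snp_indices, dtype=np.intp)
    mac = genotypes.minor_allele_count()[snp_indices]
    kept = snp_indices[mac >= min_mac]
    if len(kept) == 0:
        raise DataError("all SNPs removed by the MAC filter")
    sub = genotypes.take_sites(kept)
    K = kinship_matrix(sub, method="centered").values
    K = K / float(np.mean(np.diag(K)))
    vc = _fit_reml(np.asarray(y, float), K, np.ones((len(y), 1)))
    return vc.h2


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    if not (0.0 < alpha < 1.0):
        raise DataError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise DataError("n_tests must be >= 1")
    return alpha / n_tests
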