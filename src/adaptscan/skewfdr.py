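"""Overlap statistics between top GWA SNPs and high-F_ST regions.

For each permutation replicate, two one-sided two-sample Kolmogorov–Smirnov
tests compare the observed top-k F_ST distribution with the replicate's:
the replicate is called skewed 'higher' (observed above permuted) when the
p-value for the observed-below alternative exceeds the p-value for the
observed-above alternative by at least a factor R (default 1000), 'lower'
for the reverse, and 'none' otherwise.  The skew false discovery rate is
the counting rule n_lower / (n_lower + n_higher); when no replicate is
skewed lower it is reported as the bound < 1/(n_higher + 1).

A second FDR compares the Spearman correlation between F_ST and the GWA
-log10(p) over the observed top-k SNPs with the same correlation in every
replicate: fdr = (number of permuted correlations above the observed) / B,
bounded by < 1/B when none is above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, exp

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "ks_one_sided",
    "ks_skew_direction",
    "SkewTestResult",
    "FdrValue",
    "fst_skew_fdr",
    "spearman_fdr",
    "SkewReport",
    "build_skew_report",
    "overlay_track",
]

_P_FLOOR = np.finfo(float).tiny  # underflow guard before forming p ratios


def _one_sided_stats(obs: np.ndarray, perm: np.ndarray):
    """(D_plus, D_minus): sup(F_obs - F_perm) and sup(F_perm - F_obs)."""
    obs = np.sort(np.asarray(obs, dtype=np.float64))
    perm = np.sort(np.asarray(perm, dtype=np.float64))
    grid = np.concatenate([obs, perm])
    f_obs = np.searchsorted(obs, grid, side="right") / len(obs)
    f_perm = np.searchsorted(perm, grid, side="right") / len(perm)
    diff = f_obs - f_perm
    return float(diff.max()), float(-diff.min())


def _asymptotic_one_sided_p(d: float, m: int, n: int) -> float:
    """One-sided two-sample KS tail with the Hodges (1958) correction, as
    used by scipy's asymptotic method.  Falls back to exp(-2 d^2 mn/(m+n))
    when the corrected expression degenerates."""
    if d <= 0:
        return 1.0
    big, small = (float(m), float(n)) if m >= n else (float(n), float(m))
    en = big * small / (big + small)
    z = np.sqrt(en) * d
    expt = (
        -2 * z**2
        - 2 * z * (big + 2 * small) / np.sqrt(big * small * (big + small)) / 3.0
    )
    return float(min(1.0, exp(expt)))


def _exact_one_sided_p(d: float, m: int, n: int) -> float:
    """Exact P(D+ >= d) under exchangeability (no ties) by lattice-path count.

    Counts monotone paths (i, j) -> (m, n) whose prefixes all satisfy
    i/m - j/n < d; the complement gives the exact tail probability.
    Integer arithmetic: the condition is i*n - j*m <= ceil(d*m*n) - 1.
    """
    if d <= 0:
        return 1.0
    limit = int(np.ceil(d * m * n - 1e-9)) - 1
    ways = np.zeros((m + 1, n + 1), dtype=object)
    ways[0, 0] = 1
    for i in range(m + 1):
        for j in range(n + 1):
            if i == 0 and j == 0:
                continue
            if i * n - j * m > limit:
                ways[i, j] = 0
                continue
            total = 0
            if i > 0:
                total += ways[i - 1, j]
            if j > 0:
                total += ways[i, j - 1]
            ways[i, j] = total
    return 1.0 - ways[m, n] / comb(m + n, m)


def ks_one_sided(obs, perm, method: str = "auto"):
    """One-sided two-sample KS p-values in both orientations.

    Returns (p_obs_higher, p_obs_lower, d_minus, d_plus) where
    p_obs_higher tests the alternative 'observed stochastically larger'
    (driven by D- = sup(F_perm - F_obs)) and p_obs_lower the reverse.
    ``method``: 'asymptotic', 'exact' (lattice-path enumeration, intended
    for min(m, n) <= 25), or 'auto' (exact at small sizes).
    """
    obs = np.asarray(obs, dtype=np.float64)
    perm = np.asarray(perm, dtype=np.float64)
    if len(obs) == 0 or len(perm) == 0:
        raise DataError("empty sample in KS test")
    m, n = len(obs), len(perm)
    d_plus, d_minus = _one_sided_stats(obs, perm)
    if method == "auto":
        method = "exact" if min(m, n) <= 25 else "asymptotic"
    if method == "exact":
        p_higher = _exact_one_sided_p(d_minus, n, m)  # D- is D+ of (perm, obs)
        p_lower = _exact_one_sided_p(d_plus, m, n)
    elif method == "asymptotic":
        p_higher = _asymptotic_one_sided_p(d_minus, m, n)
        p_lower = _asymptotic_one_sided_p(d_plus, m, n)
    else:
        raise DataError(f"unknown KS method {method!r}")
    return p_higher, p_lower, d_minus, d_plus


@dataclass
class SkewTestResult:
    replicate: int
    p_greater: float  # alternative: observed stochastically larger
    p_less: float     # alternative: observed stochastically smaller
    ratio_threshold: float
    direction: str    # 'higher' | 'lower' | 'none'


def ks_skew_direction(
    obs_fst, perm_fst, R: float = 1000.0, replicate: int = 0, method: str = "asymptotic"
) -> SkewTestResult:
    """Direction call for one replicate by the R-fold KS p-value criterion.

    'higher' when p_less / p_greater >= R (the observed-below alternative is
    R-fold less supported than observed-above), 'lower' for the reverse,
    'none' otherwise; ties give 'none'.
    """
    p_greater, p_less, _, _ = ks_one_sided(obs_fst, perm_fst, method=method)
    pg = max(p_greater, _P_FLOOR)
    pl = max(p_less, _P_FLOOR)
    if pl / pg >= R and pl > pg:
        direction = "higher"
    elif pg / pl >= R and pg > pl:
        direction = "lower"
    else:
        direction = "none"
    return SkewTestResult(replicate, p_greater, p_less, float(R), direction)


@dataclass
class FdrValue:
    """An FDR that may be exact, an upper bound ('< bound'), or undefined."""

    value: float | None
    is_bound: bool = False
    text: str = ""

    def significant(self, alpha: float) -> bool:
        """True when the (possibly bounded) fdr is <= alpha."""
        return self.value is not None and self.value <= alpha


def fst_skew_fdr(n_higher: int, n_lower: int, n_none: int = 0) -> FdrValue:
    """Counting-rule FDR for the F_ST skew.

    fdr = n_lower / (n_lower + n_higher); NA when no replicate is skewed in
    either direction; when n_lower = 0, reported as the upper bound
    < 1/(n_higher + 1).
    """
    if min(n_higher, n_lower, n_none) < 0:
        raise DataError("negative direction counts")
    total = n_higher + n_lower
    if total == 0:
        return FdrValue(None, False, "NA")
    if n_lower == 0:
        bound = 1.0 / (n_higher + 1)
        return FdrValue(bound, True, f"<{bound:.6g}")
    v = n_lower / total
    return FdrValue(v, False, f"{v:.6g}")


@dataclass
class SkewReport:
    n_higher: int
    n_lower: int
    n_none: int
    fst_skew_fdr: FdrValue
    spearman_obs: float | None = None
    n_perm_above: int | None = None
    n_perm_below: int | None = None
    spearman_fdr: FdrValue | None = None
    ratio_threshold: float = 1000.0
    p_floor: float = _P_FLOOR

    @property
    def B(self) -> int:
        return self.n_higher + self.n_lower + self.n_none

    def to_dict(self) -> dict:
        def fdr_dict(f):
            if f is None:
                return None
            return {"value": f.value, "is_bound": f.is_bound, "text": f.text}

        return {
            "B": self.B,
            "n_higher": self.n_higher,
            "n_lower": self.n_lower,
            "n_none": self.n_none,
            "fst_skew_fdr": fdr_dict(self.fst_skew_fdr),
            "spearman_obs": self.spearman_obs,
            "n_perm_above": self.n_perm_above,
            "n_perm_below": self.n_perm_below,
            "spearman_fdr": fdr_dict(self.spearman_fdr),
            "ratio_threshold": self.ratio_threshold,
            "p_floor": self.p_floor,
        }


def spearman_fdr(obs_topk: pd.DataFrame, perm_rhos, B: int):
    """Spearman-correlation FDR versus the permutation ensemble.

    ``obs_topk`` carries paired (fst, neg_log10_p); ``perm_rhos`` is the
    per-replicate Spearman correlation of the same pair.  Returns
    (rho_obs or None, n_above, n_below, FdrValue).
    """
    fst = obs_topk["fst"].to_numpy()
    score = obs_topk["neg_log10_p"].to_numpy()
    if np.all(fst == fst[0]) or np.all(score == score[0]):
        return None, None, None, FdrValue(None, False, "NA (constant vector)")
    rho_obs = float(stats.spearmanr(fst, score).statistic)
    perm_rhos = np.asarray([r for r in perm_rhos if np.isfinite(r)])
    n_above = int((perm_rhos > rho_obs).sum())
    n_below = int((perm_rhos < rho_obs).sum())
    if n_above == 0:
        fdr = FdrValue(1.0 / B, True, f"<{1.0 / B:.6g}")
    else:
        fdr = FdrValue(n_above / B, False, f"{n_above / B:.6g}")
    return rho_obs, n_above, n_below, fdr


def build_skew_report(
    obs_topk: pd.DataFrame, ensemble, R: float = 1000.0, ks_method: str = "asymptotic"
) -> SkewReport:
    """Full skew report for one trait against a permutation ensemble."""
    obs_fst = obs_topk["fst"].to_numpy()
    counts = {"higher": 0, "lower": 0, "none": 0}
    for b, rep in enumerate(ensemble.replicates):
        res = ks_skew_direction(obs_fst, rep["fst"].to_numpy(), R=R, replicate=b, method=ks_method)
        counts[res.direction] += 1
    fdr = fst_skew_fdr(counts["higher"], counts["lower"], counts["none"])
    rho_obs, n_above, n_below, sp_fdr = spearman_fdr(
        obs_topk, ensemble.spearman_rhos(), B=len(ensemble.replicates)
    )
    return SkewReport(
        n_higher=counts["higher"],
        n_lower=counts["lower"],
        n_none=counts["none"],
        fst_skew_fdr=fdr,
        spearman_obs=rho_obs,
        n_perm_above=n_above,
        n_perm_below=n_below,
        spearman_fdr=sp_fdr,
        ratio_threshold=float(R),
    )


def overlay_track(
    fst_track: pd.DataFrame,
    gwa_result: pd.DataFrame,
    snpset: pd.DataFrame,
    window: int = 10,
):
    """Genome-overlay table: mean F_ST over non-overlapping windows of
    ``window`` consecutive informative SNPs per chromosome, plus the top
    SNPs annotated with their own F_ST and -log10(p).

    Remainder windows (< ``window`` SNPs at a chromosome end) are emitted
    with ``full_window = False`` rather than dropped.
    """
    track = fst_track[fst_track["informative"] & np.isfinite(fst_track["fst"])]
    rows = []
    for chrom in pd.unique(track["chrom"]):
        sub = track[track["chrom"] == chrom].sort_values("pos")
        fst = sub["fst"].to_numpy()
        pos = sub["pos"].to_numpy()
        for start in range(0, len(sub), window):
            stop = min(start + window, len(sub))
            rows.append(
                {
                    "chrom": chrom,
                    "start_pos": int(pos[start]),
                    "end_pos": int(pos[stop - 1]),
                    "n_snps": stop - start,
                    "mean_fst": float(fst[start:stop].mean()),
                    "full_window": stop - start == window,
                }
            )
    windows = pd.DataFrame(rows)
    key = fst_track.set_index(["chrom", "pos"])["fst"]
    top = snpset.copy()
    if "fst" not in top.columns:
        top = top.assign(
            fst=key.reindex(pd.MultiIndex.from_arrays([top["chrom"], top["pos"]])).to_numpy()
        )
    top = top[["chrom", "pos", "fst", "neg_log10_p"]].reset_index(drop=True)
    return windows, top
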