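"""Structure-preserving permutation null for the F_ST / GWA overlap test.

Instead of shuffling trait values (which would destroy their correlation
with population structure), surrogate phenotypes are sampled from a
multivariate normal whose covariance is the null mixed-model fit on the
observed trait, sigma_g^2 K + sigma_e^2 I.  Each surrogate is analyzed
exactly like the observed trait — variance components re-fitted, EMMAX scan,
top-k selection — and the per-replicate top-k F_ST distributions form the
empirical null for the skew tests.

Replicate b is fully determined by (base_seed, b), so the ensemble is
order-independent and extending B preserves earlier replicates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix
from .errors import DataError, NumericalError
from .mmgwa import ScanContext, VarianceComponents, select_top

__all__ = [
    "PermutationConfig",
    "PermutationEnsemble",
    "sample_structured_phenotypes",
    "permutation_gwa_topk",
]


@dataclass
class PermutationConfig:
    B: int = 1000
    k: int = 200
    base_seed: int = 0
    min_mac: int = 8
    refit_vc: bool = True  # False = reuse the observed-trait fit (approximate)

    def validate(self):
        if self.B < 1 or self.k < 1:
            raise DataError("B and k must be >= 1")


@dataclass
class PermutationEnsemble:
    replicates: list            # per-replicate DataFrame (chrom, pos, fst, neg_log10_p)
    seeds: list
    config: PermutationConfig
    n_skipped_undefined: int = 0

    @property
    def pooled_fst(self) -> np.ndarray:
        return np.concatenate([r["fst"].to_numpy() for r in self.replicates])

    def spearman_rhos(self) -> np.ndarray:
        from scipy import stats

        out = []
        for r in self.replicates:
            rho = stats.spearmanr(r["fst"], r["neg_log10_p"]).statistic
            out.append(rho)
        return np.asarray(out)

    def save(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for b, rep in enumerate(self.replicates):
            rep.to_csv(out / f"replicate_{b:04d}.tsv", sep="\t", index=False, float_format="%.10g")
        manifest = {
            "B": self.config.B,
            "k": self.config.k,
            "base_seed": self.config.base_seed,
            "min_mac": self.config.min_mac,
            "refit_vc": self.config.refit_vc,
            "seeds": self.seeds,
            "n_skipped_undefined": self.n_skipped_undefined,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _covariance_factor(K: np.ndarray, vc: VarianceComponents) -> np.ndarray:
    """Cholesky factor of sigma_g^2 K + sigma_e^2 I, with diagonal jitter."""
    n = K.shape[0]
    V = vc.sigma_g2 * K + vc.sigma_e2 * np.eye(n)
    scale = float(np.trace(V)) / n
    for jitter in (0.0, 1e-12, 1e-10, 1e-8, 1e-6):
        try:
            return np.linalg.cholesky(V + jitter * scale * np.eye(n))
        except np.linalg.LinAlgError:
            continue
    raise NumericalError("covariance not positive definite after jitter")


def _replicate_rng(base_seed: int, b: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(base_seed), int(b))))


def sample_structured_phenotypes(
    y, K, vc: VarianceComponents, B: int, base_seed: int
) -> np.ndarray:
    """B surrogate phenotype vectors ~ N(mean(y) 1, sigma_g^2 K + sigma_e^2 I).

    Returns an array of shape (B, n).  Surrogate b depends only on
    (base_seed, b).
    """
    y = np.asarray(y, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    if K.shape != (len(y), len(y)):
        raise DataError("kinship dimensions do not match phenotype")
    L = _covariance_factor(K, vc)
    mu = float(np.mean(y))
    out = np.empty((B, len(y)))
    for b in range(B):
        z = _replicate_rng(base_seed, b).standard_normal(len(y))
        out[b] = mu + L @ z
    return out


def permutation_gwa_topk(
    surrogates: np.ndarray,
    genotypes: GenotypeMatrix,
    K,
    fst_track: pd.DataFrame,
    config: PermutationConfig,
    context: ScanContext | None = None,
    null_vc: VarianceComponents | None = None,
) -> PermutationEnsemble:
    """Run the GWA scan on every surrogate and collect top-k SNP F_ST values.

    ``fst_track`` must come from the same group contrast as the observed
    analysis.  Top-k SNPs with undefined F_ST are skipped and replaced by
    the next-ranked SNPs; the total number of such skips is recorded.
    """
    config.validate()
    surrogates = np.atleast_2d(np.asarray(surrogates, dtype=np.float64))
    if surrogates.shape[0] != config.B:
        raise DataError("surrogate count does not match config.B")
    K = np.asarray(K, dtype=np.float64)
    ctx = context if context is not None else ScanContext(genotypes, K, min_mac=config.min_mac)
    fst_lookup = fst_track.set_index(["chrom", "pos"])["fst"]
    if not config.refit_vc and null_vc is None:
        raise DataError("fast mode requires the observed-trait variance components")

    replicates, seeds = [], []
    n_skipped = 0
    for b in range(config.B):
        try:
            y_b = surrogates[b]
            vc_b = ctx.fit_null(y_b) if config.refit_vc else null_vc
            res = ctx.scan(y_b, vc_b)
            rep, skipped = attach_fst_topk(res, fst_lookup, config.k)
        except Exception as e:  # noqa: BLE001 - replicate seed must surface
            raise NumericalError(f"replicate {b} (base_seed={config.base_seed}) failed: {e}") from e
        n_skipped += skipped
        replicates.append(rep)
        seeds.append([config.base_seed, b])
    if n_skipped:
        warnings.warn(f"replaced {n_skipped} top-k SNPs with undefined F_ST")
    return PermutationEnsemble(replicates, seeds, config, n_skipped)


def attach_fst_topk(scan_result: pd.DataFrame, fst_lookup: pd.Series, k: int):
    """Top-k selection with per-SNP F_ST attached; undefined-F_ST SNPs are
    skipped and replaced by the next-ranked.  Returns (frame, n_skipped)."""
    # over-select, drop undefined, then cut to k
    cand = select_top(scan_result, k=min(len(scan_result), 3 * k))
    fst = fst_lookup.reindex(
        pd.MultiIndex.from_arrays([cand["chrom"], cand["pos"]])
    ).to_numpy()
    cand = cand.assign(fst=fst)
    defined = cand.dropna(subset=["fst"])
    # skips = undefined-F_ST SNPs displaced from the would-be top k
    n_skipped = int(cand.head(min(k, len(cand)))["fst"].isna().sum())
    top = defined.head(k).reset_index(drop=True)
    return top[["chrom", "pos", "fst", "neg_log10_p", "p_value", "mac"]], n_skipped
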