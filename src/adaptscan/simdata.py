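"""Synthetic colonization scenarios for end-to-end pipeline testing.

The generator emulates a serial-founder colonization gradient in a
predominantly selfing plant: an ancestral allele-frequency spectrum, a chain
of daughter populations whose frequencies drift away from their predecessor
(Balding–Nichols Beta model with per-step drift parameter F_k), mixed-mating
genotypes whose heterozygote deficit matches the selfing equilibrium
F_IS = s/(2 - s), and a minority of near-fixed causal loci that differentiate
the terminal population.  Phenotypes combine large-effect causal SNPs with a
polygenic background drawn with covariance proportional to the kinship
matrix, so the trait correlates with population structure the way an
overwintering-survival trait does along a climatic gradient.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    GeneInterval,
    GenotypeMatrix,
    PhenotypeTable,
    SyntheticDataset,
)
from .errors import ConfigError

__all__ = [
    "ScenarioConfig",
    "PhenotypeModel",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_annotations",
    "simulate_coordinates",
    "tile_genes",
    "simulate_dataset",
    "write_dataset",
]


@dataclass
class ScenarioConfig:
    """Parameters of a serial-founder colonization scenario.

    ``founder_drift`` lists one divergence parameter F_k in (0, 1) per
    population, applied serially along the colonization chain; strictly
    increasing values induce the expected north-bound diversity decline.
    ``causal_freq_split`` gives the target alt-allele frequency of each
    causal site in every population, e.g. ``(0.02, 0.02, 0.98)`` for loci
    near-fixed in the terminal population only.
    """

    n_pops: int = 3
    n_acc_per_pop: int = 34
    n_sites: int = 20_000
    n_chrom: int = 2
    chrom_length: int = 10_000_000
    founder_drift: tuple = (0.05, 0.15, 0.30)
    selfing_rate: float = 0.94
    n_causal: int = 0
    causal_freq_split: tuple = (0.02, 0.02, 0.98)
    maf_floor: float = 0.02
    missing_rate: float = 0.0
    deme_size: int = 1     # >1 adds local demes (subfamilies) within populations
    deme_drift: float = 0.0  # Balding–Nichols drift of deme frequencies
    ancestral_dist: str = "uniform"  # "uniform" on [0.1, 0.9] or "beta" (0.5, 0.5)
    seed: int = 0

    def validate(self) -> None:
        if self.n_pops < 1 or len(self.founder_drift) != self.n_pops:
            raise ConfigError("founder_drift must list one F_k per population")
        if any(not (0 <= f < 1) or not np.isfinite(f) for f in self.founder_drift):
            raise ConfigError("founder_drift values must lie in [0, 1)")
        if not (0.0 <= self.selfing_rate <= 1.0):
            raise ConfigError("selfing_rate must lie in [0, 1]")
        if self.n_causal > self.n_sites:
            raise ConfigError("n_causal exceeds n_sites")
        if self.n_causal and len(self.causal_freq_split) != self.n_pops:
            raise ConfigError("causal_freq_split must list one frequency per population")
        if not (0.0 <= self.maf_floor < 0.5):
            raise ConfigError("maf_floor must lie in [0, 0.5)")
        if self.n_causal and any(
            not (0.0 < f < 1.0) for f in self.causal_freq_split
        ):
            raise ConfigError("causal_freq_split frequencies must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.ancestral_dist not in ("uniform", "beta"):
            raise ConfigError("ancestral_dist must be 'uniform' or 'beta'")
        if self.deme_size < 1 or not (0.0 <= self.deme_drift < 1):
            raise ConfigError("deme_size must be >= 1 and deme_drift in [0, 1)")

    @property
    def n_accessions(self) -> int:
        return self.n_pops * self.n_acc_per_pop

    @property
    def f_is(self) -> float:
        """Equilibrium inbreeding coefficient under selfing rate s."""
        s = self.selfing_rate
        return s / (2.0 - s)


@dataclass
class PhenotypeModel:
    """Additive trait model: y = intercept + sum(beta_j x_j) + g + e.

    The polygenic term g is drawn with covariance proportional to the kinship
    matrix K, scaled so that var(g) / (var(g) + sigma_e2) = h2_poly (using
    the mean diagonal of K as the per-accession genetic variance unit).
    """

    causal_effects: tuple = ()
    h2_poly: float = 0.0
    sigma_e2: float = 1.0
    intercept: float = 0.0
    name: str = "trait"

    def validate(self) -> None:
        if not (0.0 <= self.h2_poly < 1.0):
            raise ConfigError("h2_poly must lie in [0, 1)")
        if not (self.sigma_e2 > 0) or not np.isfinite(self.sigma_e2):
            raise ConfigError("sigma_e2 must be positive and finite")
        if any(not np.isfinite(b) for b in self.causal_effects):
            raise ConfigError("causal effect sizes must be finite")


def _ancestral_freqs(rng: np.random.Generator, n: int, dist: str) -> np.ndarray:
    if dist == "uniform":
        return rng.uniform(0.1, 0.9, size=n)
    return np.clip(rng.beta(0.5, 0.5, size=n), 0.01, 0.99)


def _drift_step(rng, p_parent: np.ndarray, f: float) -> np.ndarray:
    """Balding–Nichols: daughter frequencies ~ Beta centered on the parent."""
    if f <= 0:
        return p_parent.copy()
    a = p_parent * (1.0 - f) / f
    b = (1.0 - p_parent) * (1.0 - f) / f
    return np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)


def _draw_mixed_mating(rng, p: np.ndarray, f_is: float, n_ind: int) -> np.ndarray:
    """Genotypes with heterozygote deficit F_IS relative to Hardy–Weinberg.

    Each individual x site is drawn as 'inbred' with probability F_IS
    (genotype = 2 * Bernoulli(p), no heterozygotes) and as a random union of
    gametes otherwise, so E[Hobs] = (1 - F_IS) * 2p(1-p).
    """
    m = len(p)
    inbred = rng.random((n_ind, m)) < f_is
    hw = (rng.random((n_ind, m)) < p).astype(np.int8) + (
        rng.random((n_ind, m)) < p
    ).astype(np.int8)
    ib = 2 * (rng.random((n_ind, m)) < p).astype(np.int8)
    return np.where(inbred, ib, hw).astype(np.int8)


def _site_coordinates(rng, n_sites: int, n_chrom: int, chrom_length: int):
    """Sorted unique positions, sites split evenly across chromosomes."""
    per = np.full(n_chrom, n_sites // n_chrom, dtype=int)
    per[: n_sites % n_chrom] += 1
    chroms, positions = [], []
    for c in range(n_chrom):
        pos = rng.choice(np.arange(1, chrom_length + 1), size=per[c], replace=False)
        pos.sort()
        positions.append(pos)
        chroms.extend([f"chr{c + 1}"] * per[c])
    return np.array(chroms, dtype=object), np.concatenate(positions)


def simulate_genotypes(config: ScenarioConfig):
    """Draw a genotype matrix plus truth labels under the scenario.

    Returns
    -------
    (GenotypeMatrix, truth_pops: dict accession -> 'pop<k>',
     truth_causal: int array of causal site indices,
     pop_freqs: (n_pops, n_sites) array of the realized allele frequencies)
    """
    config.validate()
    if config.n_causal and config.maf_floor > 0:
        pooled = float(np.mean(config.causal_freq_split))
        if min(pooled, 1 - pooled) < config.maf_floor:
            raise ConfigError(
                "causal_freq_split pooled frequency conflicts with maf_floor"
            )
    rng = np.random.default_rng(config.seed)
    n_sites, n_pops = config.n_sites, config.n_pops

    # serial-founder allele frequencies, redrawing sites under the MAF floor
    freqs = np.empty((n_pops, n_sites))
    todo = np.arange(n_sites)
    for _ in range(50):
        p0 = _ancestral_freqs(rng, len(todo), config.ancestral_dist)
        parent = p0
        for k in range(n_pops):
            parent = _drift_step(rng, parent, config.founder_drift[k])
            freqs[k, todo] = parent
        pooled = freqs[:, todo].mean(axis=0)
        maf = np.minimum(pooled, 1 - pooled)
        todo = todo[maf < config.maf_floor]
        if len(todo) == 0:
            break
    else:
        warnings.warn("MAF floor not reached for some sites after 50 redraws")

    truth_causal = np.array([], dtype=np.intp)
    if config.n_causal:
        truth_causal = np.sort(
            rng.choice(n_sites, size=config.n_causal, replace=False)
        )
        for k in range(n_pops):
            freqs[k, truth_causal] = config.causal_freq_split[k]

    f_is = config.f_is
    blocks, accessions, truth_pops = [], [], {}
    for k in range(n_pops):
        if config.deme_size > 1 and config.deme_drift > 0:
            # local demes: subfamily frequencies drift within the population,
            # giving the kinship matrix realistic within-population dispersion
            rows = []
            left = config.n_acc_per_pop
            while left > 0:
                take = min(config.deme_size, left)
                fam = _drift_step(rng, freqs[k], config.deme_drift)
                if config.n_causal:
                    fam[truth_causal] = freqs[k][truth_causal]
                rows.append(_draw_mixed_mating(rng, fam, f_is, take))
                left -= take
            g = np.vstack(rows)
        else:
            g = _draw_mixed_mating(rng, freqs[k], f_is, config.n_acc_per_pop)
        blocks.append(g)
        for i in range(config.n_acc_per_pop):
            name = f"ACC{k + 1}_{i + 1:03d}"
            accessions.append(name)
            truth_pops[name] = f"pop{k + 1}"
    dosage = np.vstack(blocks)

    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage = np.where(miss, np.int8(-1), dosage)

    chrom, pos = _site_coordinates(rng, n_sites, config.n_chrom, config.chrom_length)
    gm = GenotypeMatrix(dosage, accessions, chrom, pos)
    return gm, truth_pops, truth_causal, freqs


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    K: np.ndarray,
    model: PhenotypeModel,
    seed: int,
    causal_sites=(),
) -> PhenotypeTable:
    """Simulate one trait column: causal effects + polygenic term + noise."""
    model.validate()
    K = np.asarray(K, dtype=np.float64)
    n = genotypes.n_accessions
    if K.shape != (n, n):
        raise ConfigError("kinship dimensions do not match accessions")
    causal_sites = np.asarray(causal_sites, dtype=np.intp)
    if len(model.causal_effects) != len(causal_sites):
        raise ConfigError("one effect size per causal site required")

    rng = np.random.default_rng(seed)
    y = np.full(n, float(model.intercept))
    if len(causal_sites):
        X = genotypes.mean_imputed()[:, causal_sites]
        y = y + X @ np.asarray(model.causal_effects, dtype=np.float64)
    if model.h2_poly > 0:
        diag_unit = float(np.mean(np.diag(K)))
        sigma_g2 = model.h2_poly / (1.0 - model.h2_poly) * model.sigma_e2 / diag_unit
        jitter = 1e-8 * diag_unit
        L = np.linalg.cholesky(K + jitter * np.eye(n))
        y = y + np.sqrt(sigma_g2) * (L @ rng.standard_normal(n))
    y = y + np.sqrt(model.sigma_e2) * rng.standard_normal(n)
    df = pd.DataFrame({model.name: y}, index=pd.Index(genotypes.accessions, name="accession_id"))
    return PhenotypeTable(df)


# plausible GATK-style INFO ranges on either side of each hard threshold
_PASS_DRAW = {
    "inbreeding_coeff": (0.15, 0.95),
    "haplotype_score": (0.0, 0.25),
    "alt_quality": (35.0, 2000.0),
    "depth": (160.0, 3000.0),
}
_FAIL_DRAW = {
    "inbreeding_coeff": (-0.5, 0.1),
    "haplotype_score": (0.3, 3.0),
    "alt_quality": (1.0, 30.0),
    "depth": (10.0, 150.0),
}


def simulate_annotations(
    genotypes: GenotypeMatrix, fail_fractions: dict, seed: int
) -> pd.DataFrame:
    """Per-site INFO annotations with recorded filter truth.

    ``fail_fractions`` maps rule names (inbreeding_coeff, haplotype_score,
    alt_quality, depth) to the marginal probability that a site fails that
    rule; unnamed rules never fail.  The returned frame carries the emitted
    values, one boolean ``fail_<rule>`` truth column per rule, and
    ``truth_pass`` (passes every rule).
    """
    unknown = set(fail_fractions) - set(_PASS_DRAW)
    if unknown:
        raise ConfigError(f"unknown filter rules: {sorted(unknown)}")
    for k, v in fail_fractions.items():
        if not (0.0 <= v <= 1.0):
            raise ConfigError(f"fail fraction for {k} outside [0, 1]")
    rng = np.random.default_rng(seed)
    m = genotypes.n_sites
    out = {"chrom": genotypes.chrom, "pos": genotypes.pos}
    truth_pass = np.ones(m, dtype=bool)
    for rule in _PASS_DRAW:
        frac = float(fail_fractions.get(rule, 0.0))
        fails = rng.random(m) < frac
        lo_p, hi_p = _PASS_DRAW[rule]
        lo_f, hi_f = _FAIL_DRAW[rule]
        vals = np.where(
            fails, rng.uniform(lo_f, hi_f, m), rng.uniform(lo_p, hi_p, m)
        )
        if rule == "depth":
            vals = np.floor(vals)
        out[rule] = vals
        out[f"fail_{rule}"] = fails
        truth_pass &= ~fails
    out["truth_pass"] = truth_pass
    return pd.DataFrame(out)


def tile_genes(config: ScenarioConfig, sites_per_gene: int = 8) -> list:
    """Deterministic gene tiling: fixed length, fixed spacing.

    Gene length is set so a gene covers ~``sites_per_gene`` sites at the
    scenario's SNP density, giving most genes the >= 4 informative SNPs the
    per-gene F_ST summary requires.
    """
    density = config.n_sites / (config.n_chrom * config.chrom_length)
    length = max(int(round(sites_per_gene / density)), 1)
    gap = max(length // 2, 1)
    genes = []
    for c in range(config.n_chrom):
        chrom = f"chr{c + 1}"
        start, gid = 0, 1
        while start + length <= config.chrom_length:
            genes.append(
                GeneInterval(f"{chrom}g{gid:05d}", chrom, start, start + length)
            )
            start += length + gap
            gid += 1
    return genes


def simulate_coordinates(truth_pops: dict, seed: int) -> pd.DataFrame:
    """Accession lat/lon along a south-to-north archipelago gradient."""
    rng = np.random.default_rng(seed)
    centers = {}
    pops = sorted({p for p in truth_pops.values()})
    for i, p in enumerate(pops):
        centers[p] = (31.5 + 4.5 * i, 130.5 + 3.5 * i)
    rows = []
    for acc, p in truth_pops.items():
        lat0, lon0 = centers[p]
        rows.append(
            {
                "accession_id": acc,
                "lat": lat0 + rng.normal(0, 0.7),
                "lon": lon0 + rng.normal(0, 0.7),
            }
        )
    return pd.DataFrame(rows).set_index("accession_id")


def simulate_dataset(
    config: ScenarioConfig,
    model: PhenotypeModel | None = None,
    fail_fractions: dict | None = None,
) -> SyntheticDataset:
    """Full scenario: genotypes, phenotype, annotations, genes, coordinates."""
    from .mmgwa import kinship_matrix  # deferred: avoids import cycle

    gm, truth_pops, truth_causal, _ = simulate_genotypes(config)
    K = kinship_matrix(gm).values
    if model is None:
        model = PhenotypeModel(
            causal_effects=tuple(2.0 for _ in truth_causal),
            h2_poly=0.4,
            sigma_e2=1.0,
            name="overwintering",
        )
    phen = simulate_phenotypes(
        gm, K, model, seed=config.seed + 1, causal_sites=truth_causal
    )
    ann = simulate_annotations(gm, fail_fractions or {}, seed=config.seed + 2)
    genes = tile_genes(config)
    coords = simulate_coordinates(truth_pops, seed=config.seed + 3)
    return SyntheticDataset(gm, truth_pops, truth_causal, phen, ann, genes, coords)


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict:
    """Write VCF + BED + TSVs; returns the mapping of artifact names to paths."""
    from pathlib import Path

    from . import io as asio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "bed": out / "genes.bed",
        "phenotypes": out / "phenotypes.tsv",
        "populations": out / "populations.tsv",
        "coords": out / "coordinates.tsv",
        "causal": out / "truth_causal.tsv",
    }
    asio.write_vcf(dataset.genotypes, paths["vcf"], annotations=dataset.annotations)
    asio.write_bed(dataset.genes, paths["bed"])
    asio.write_phenotypes(dataset.phenotypes, paths["phenotypes"])
    pops = sorted({p for p in dataset.truth_pops.values()})
    memb = pd.DataFrame(
        0.0,
        index=pd.Index(dataset.genotypes.accessions, name="accession_id"),
        columns=pops,
    )
    for acc, p in dataset.truth_pops.items():
        memb.loc[acc, p] = 1.0
    asio.write_populations(memb, paths["populations"])
    if dataset.coords is not None:
        asio.write_coords(dataset.coords, paths["coords"])
    gm = dataset.genotypes
    pd.DataFrame(
        {
            "chrom": gm.chrom[dataset.truth_causal],
            "pos": gm.pos[dataset.truth_causal],
            "site_index": dataset.truth_causal,
        }
    ).to_csv(paths["causal"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
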