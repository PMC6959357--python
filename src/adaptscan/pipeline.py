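"""Pipeline orchestration: filter -> popgen -> GWA -> permutations -> skew.

A run is fully described by its configuration (paths, contrast, settings,
seeds); identical configuration reproduces byte-identical numeric outputs.
Per-stage wall times go to a separate ``run.log`` so logging never affects
the numeric bundle.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as asio
from . import mmgwa, popgen, skewfdr, structperm
from .errors import ConfigError
from .varfilter import FilterThresholds, apply_hard_filters

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    vcf: str = ""
    bed: str | None = None
    phenotypes: str = ""
    populations: str = ""
    coords: str | None = None
    out_dir: str = "results"
    trait: str = "overwintering"
    focal_population: str = "pop3"
    admix_threshold: float = 0.8          # non-admixed = top membership >= this
    background_max_membership: float = 0.0  # background = focal membership <= this
    filter_enabled: bool = False
    reference_accession: str = "MG-20"
    min_mac: int = 8
    top_k: int = 200
    p_threshold: float = 5e-5
    refine_top: int = 200
    variance_min_mac: int = 10
    B: int = 1000
    base_seed: int = 0
    ratio_threshold: float = 1000.0
    overlay_window: int = 10
    kinship_method: str = "ibs"
    min_gene_snps: int = 4

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("vcf", "phenotypes", "populations"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise ConfigError(f"missing input file for {name!r}: {p!r}")
        for name in ("bed", "coords"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured {name} file does not exist: {p!r}")
        if self.B < 1 or self.top_k < 1 or self.min_mac < 0:
            raise ConfigError("B, top_k must be >= 1 and min_mac >= 0")

    def analysis_dict(self) -> dict:
        """Configuration fields that determine the numeric outputs: everything
        except the output location."""
        d = asdict(self)
        d.pop("out_dir")
        return d

    def digest(self) -> str:
        blob = json.dumps(self.analysis_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a dict of output paths + report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []
    t_all = time.perf_counter()

    def stage(name):
        log_lines.append(f"[{name}] start")
        return time.perf_counter()

    def done(name, t0):
        log_lines.append(f"[{name}] {time.perf_counter() - t0:.2f}s")

    # --- load
    t0 = stage("load")
    gm, ann = asio.read_vcf(config.vcf)
    phen = asio.read_phenotypes(config.phenotypes)
    membership = asio.read_populations(config.populations)
    genes = asio.read_bed(config.bed) if config.bed else []
    if config.trait not in phen.data.columns:
        raise ConfigError(f"trait {config.trait!r} not in phenotype table")
    done("load", t0)

    # --- hard filters (optional; requires the reference accession in the VCF)
    if config.filter_enabled:
        t0 = stage("filter")
        thr = FilterThresholds(reference_accession_id=config.reference_accession)
        mask, summary = apply_hard_filters(ann, thr, genotypes=gm)
        gm = gm.take_sites(np.flatnonzero(mask))
        (out / "filter_summary.json").write_text(
            json.dumps(
                {
                    "n_input": summary.n_input,
                    "n_pass": summary.n_pass,
                    "fail_counts": summary.fail_counts,
                },
                indent=2,
            )
        )
        done("filter", t0)

    # --- group contrast: focal population vs accessions with no membership
    if config.focal_population not in membership.columns:
        raise ConfigError(f"focal population {config.focal_population!r} not in table")
    frac = membership[config.focal_population]
    in_geno = [a for a in gm.accessions if a in membership.index]
    group_a = [a for a in in_geno if frac.get(a, 0) >= config.admix_threshold]
    group_b = [a for a in in_geno if frac.get(a, 1) <= config.background_max_membership]
    if len(group_a) < 2 or len(group_b) < 2:
        raise ConfigError("contrast groups need >= 2 accessions each")

    # --- F_ST
    t0 = stage("fst")
    fst_track = popgen.weir_fst_per_site(gm, group_a, group_b)
    _write_tsv(fst_track, out / "fst_sites.tsv")
    if genes:
        gene_fst = popgen.per_gene_fst(fst_track, genes, min_snps=config.min_gene_snps)
        _write_tsv(gene_fst, out / "fst_genes.tsv")
    done("fst", t0)

    # --- GWA
    t0 = stage("gwa")
    y = phen.aligned_vector(config.trait, gm.accessions)
    Kdf = mmgwa.kinship_matrix(gm, method=config.kinship_method)
    K = Kdf.values
    Kdf.to_csv(out / "kinship.tsv", sep="\t", float_format="%.10g")
    ctx = mmgwa.ScanContext(gm, K, min_mac=config.min_mac)
    vc = ctx.fit_null(y)
    (out / "variance_components.json").write_text(
        json.dumps(
            {
                "sigma_g2": vc.sigma_g2,
                "sigma_e2": vc.sigma_e2,
                "h2": vc.h2,
                "delta": vc.delta,
                "loglik": vc.loglik,
                "kinship_method": config.kinship_method,
            },
            indent=2,
        )
    )
    scan = ctx.scan(y, vc)
    if config.refine_top:
        scan = mmgwa.emma_refine(y, gm, K, scan, top_k=config.refine_top)
    _write_tsv(scan, out / "gwa.tsv")
    fst_lookup = fst_track.set_index(["chrom", "pos"])["fst"]
    obs_topk, _ = structperm.attach_fst_topk(scan, fst_lookup, config.top_k)
    _write_tsv(obs_topk, out / "top_snps.tsv")
    done("gwa", t0)

    # --- structured permutations
    t0 = stage("permute")
    surrogates = structperm.sample_structured_phenotypes(
        y, K, vc, B=config.B, base_seed=config.base_seed
    )
    pconf = structperm.PermutationConfig(
        B=config.B, k=config.top_k, base_seed=config.base_seed, min_mac=config.min_mac
    )
    ensemble = structperm.permutation_gwa_topk(
        surrogates, gm, K, fst_track, pconf, context=ctx
    )
    ensemble.save(out / "ensemble")
    done("permute", t0)

    # --- skew report + overlay
    t0 = stage("skew")
    report = skewfdr.build_skew_report(obs_topk, ensemble, R=config.ratio_threshold)
    (out / "skew_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    windows, top = skewfdr.overlay_track(
        fst_track, scan, obs_topk, window=config.overlay_window
    )
    _write_tsv(windows, out / "overlay_windows.tsv")
    _write_tsv(top, out / "overlay_top_snps.tsv")
    done("skew", t0)

    manifest = {
        "config": config.analysis_dict(),
        "config_digest": config.digest(),
        "base_seed": config.base_seed,
        "n_accessions": gm.n_accessions,
        "n_sites": gm.n_sites,
        "group_a_size": len(group_a),
        "group_b_size": len(group_b),
        "input_digests": {
            name: hashlib.sha256(Path(getattr(config, name)).read_bytes()).hexdigest()[:16]
            for name in ("vcf", "phenotypes", "populations")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log_lines.append(f"[total] {time.perf_counter() - t_all:.2f}s")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return {"out_dir": str(out), "report": report, "manifest": manifest}
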