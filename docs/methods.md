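# Methods note

This note records the statistical models, estimator conventions, default
parameters and numerical choices implemented in `adaptscan`, and the
limitations a user should know before interpreting output.

## 1. Synthetic data generator (`simdata`)

**Model.** Genotypes follow a serial-founder (stepping-stone) colonization
model with partial selfing:

1. Ancestral allele frequencies are drawn per site (uniform on
   [maf_floor, 1 − maf_floor] by default).
2. Population k's frequencies drift from the ancestral values through a
   Balding–Nichols chain: p_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k) with
   per-population drift F_k (`founder_drift`, default (0.05, 0.15, 0.30)).
   Larger drift for later populations produces the serial-founder diversity
   decline along the colonization route.
3. Optional within-population demes (`deme_size`, `deme_drift`) add a
   second, local Balding–Nichols step, dispersing the kinship spectrum the
   way family/neighborhood structure does in real samples.
4. Genotypes follow a mixed-mating equilibrium: with probability
   F_IS = s/(2−s) an accession is "inbred" at the locus (dosage 2·Bern(p)),
   otherwise the sum of two independent Bern(p) draws.  Default selfing
   rate s = 0.94.
5. Causal sites overwrite the drifted frequencies with
   `causal_freq_split` (default 0.02/0.02/0.98): nearly fixed in the focal
   population, nearly absent elsewhere, giving per-site F_ST ≈ 0.95 in
   expectation (sampling SD ≈ 0.03 at 34 accessions per group).

**Phenotypes.** y = intercept + Σ β_j x_j + g + e with polygenic
g ~ N(0, σ_g²K) scaled so var(g)/(var(g)+σ_e²) = `h2_poly` (mean diagonal
of K as the per-accession variance unit) and e ~ N(0, σ_e²I).

**Annotations.** Filter-rule annotations are drawn from disjoint pass/fail
ranges per rule so truth columns (`fail_<rule>`, `truth_pass`) are exact.

**What the generator does not emulate:** linkage (sites are exchangeable
given frequencies; LD arises only from structure), mutation/recombination
processes, genotyping error models, and environmental phenotype gradients.

## 2. Variant filtering (`varfilter`)

Hard thresholds (strict inequalities): InbreedingCoeff > 0.1,
HaplotypeScore < 0.3, alternative-allele quality > 30, depth < 150, and —
when a reference accession is configured — the reference accession called
homozygous reference.  A site with a missing (NaN) annotation fails that
rule (conservative).  Summaries: callable-position counts, site frequency
spectrum over non-missing alt-allele counts (folded option; monomorphic
sites excluded), and concordance statistics against a validated call set.

## 3. Population genetics (`popgen`)

* **F_ST**: Weir & Cockerham (1984) variance components a (among
  populations), b (among individuals), c (within individuals) for r = 2
  groups; per-site estimate a/(a+b+c), undefined (NaN) when the denominator
  is ≤ 0.  A site is *informative* with ≥ 2 called diploids in each group.
  Negative estimates are retained (they are part of the estimator's
  sampling distribution and must not be truncated before averaging).
  Per-gene values are means over informative SNPs inside the gene interval,
  reported only for genes with ≥ 4 such SNPs (default).
* **Genetic distance**: mean absolute dosage difference (+2/+1/0 scoring)
  over pairwise-complete sites.
* **π**: per-site heterozygosity 2j(n₂−j)/(n₂(n₂−1)) from the alt-allele
  count j among n₂ called alleles; per-bp in windows.
* **F_IS / selfing**: per population, F_IS = 1 − H̄obs/H̄exp with Nei's
  unbiased gene diversity H̄exp = mean over loci of 2p(1−p)·2n/(2n−1).
  Without the 2n/(2n−1) correction the plug-in estimator is biased to
  F_IS ≈ −1/(2n−1) under random mating, which at n = 34 pushes the
  recovered selfing rate to −0.035 when the truth is 0.  Selfing rate from
  the across-population mean F_IS as s = 2F_IS/(1+F_IS) (equilibrium
  mixed-mating relation).
* **LD**: squared Pearson correlation of dosages for same-chromosome pairs
  within 50 kb (inclusive), binned by distance (1 kb bins); the decay
  distance is the first bin whose mean r² ≤ 0.2.
* **PCA**: mean-imputed dosages centered at 2p̂ and scaled by √(p̂(1−p̂)),
  fixed sites dropped, scores from the SVD.
* **Geographic distance**: Vincenty's inverse geodesic on the WGS-84
  ellipsoid (validated to the metre against an independent implementation).

## 4. Mixed-model GWA (`mmgwa`)

* **Kinship**: IBS (1 − mean |x_i − x_j|/2 over jointly called sites,
  computed exactly via indicator products; unit diagonal) or the centered
  (VanRaden) WWᵀ/(2Σp(1−p)).
* **REML**: single random effect + intercept.  The restricted
  log-likelihood is evaluated spectrally on the projected kinship
  S K S (S the fixed-effect annihilator), profiled over σ², and maximized
  over δ = σ_e²/σ_g² on a 100-point grid over log δ ∈ [−10, 10] followed by
  bounded scalar refinement.  The spectral form is verified against a
  dense-matrix evaluation (agreement ≲ 1e-14).
* **EMMAX**: variance components fixed at the null fit; each SNP tested by
  GLS in the whitened rotation (eigendecomposition computed once; the
  per-scan cost is O(nm)).  SNPs with minor allele count < 8 are excluded.
  p-values from the t distribution with n − 2 df.
* **EMMA refinement**: the top 200 EMMAX SNPs (by p, ties broken by
  chromosome/position) are re-tested with per-SNP REML under
  X = [1, x]; refined rows are flagged.
* **Variance explained**: REML h² with the centered GRM built from the
  selected SNPs only (default selection: p ≤ 5e-5 and MAC ≥ 10).  The GRM
  is normalized to unit mean diagonal: under 94% selfing the VanRaden
  diagonal averages 1 + F_IS ≈ 1.9, which otherwise deflates the estimated
  fraction (0.35 measured where the truth is 0.50).
* **Bonferroni**: 0.05/m over tested SNPs.

## 5. Structured permutations (`structperm`)

Surrogate phenotypes are drawn as y* ~ N(mean(y)·1, σ_g²K + σ_e²I) with the
variance components from the observed-trait null fit, so every surrogate
preserves the trait's covariance with population structure.  Replicate b is
seeded by SeedSequence(entropy=(base_seed, b)): extending B keeps earlier
replicates bit-identical.  The Cholesky factor falls back to a jittered
ladder (up to 1e-6 of the mean diagonal) for numerically semidefinite K.
Each replicate is scanned with the same EMMAX machinery (variance
components refit per surrogate by default) and its top-k SNPs keep their
per-site F_ST from the observed group contrast; top-k SNPs with undefined
F_ST are skipped and replaced by next-ranked SNPs.

## 6. Skew statistics (`skewfdr`)

Per replicate, both one-sided two-sample KS tests compare the observed
top-k F_ST sample with the replicate's.  The replicate is called *higher*
when p_less/p_greater ≥ R (default R = 1000), *lower* for the reverse,
*none* otherwise; p-values are floored at the smallest positive normal
double before forming the ratio.  One-sided p-values: exact lattice-path
enumeration (exact integer arithmetic) for min(m, n) ≤ 25, otherwise the
asymptotic tail with the Hodges (1958) small-sample correction.

FDRs:

* **Skew FDR** = n_lower/(n_lower + n_higher); undefined when both are 0;
  reported as the upper bound < 1/(n_higher + 1) when n_lower = 0.
* **Spearman FDR** = (#permuted correlations above the observed)/B, with
  the bound < 1/B when none is above.  The correlation pairs per-SNP F_ST
  with −log10(p) over the top-k set.

The overlay table averages the informative F_ST track in non-overlapping
10-SNP windows per chromosome (remainder windows flagged, not dropped) and
annotates the top SNPs with their own F_ST.

## 7. Demography (`demography`)

PSMC-style output (RS records of the final round, or a two-column scaled
TSV with a `#theta=` header) is rescaled with a per-year mutation rate μ
(default 6.5e-9): N0 = θ/(4μg), t_years = θ·t_scaled/(2μ), Ne = λ·N0.  The
year axis is independent of the generation time g; g only scales Ne.  The
divergence time of a pseudo-diploid trajectory is the start of the first
interval (scanning from the present) with Ne ≥ 5e4 (default cutoff);
log-linear interpolation is optional.  Trajectories that never reach the
cutoff yield an undefined (flagged) estimate.

## 8. Pipeline determinism

A run is fully described by its analysis configuration and base seed.  The
manifest and its digest exclude the output directory; per-stage wall times
go to `run.log` only.  Identical configurations reproduce byte-identical
bundles (tested).

## 9. Validation design choices

* The h²-recovery acceptance targets ±0.1 at n ≈ 500.  On a clean 3-block
  structure the kinship spectrum carries only ~3 informative
  eigendirections and the Fisher-information SE of ĥ² is 0.13–0.2, so no
  estimator meets ±0.1 on a single draw.  The recovery scenario therefore
  (a) adds local demes (deme_size 10, deme_drift 0.3), giving the spectrum
  realistic dispersion (theoretical SE ≈ 0.13), and (b) averages 10
  independent phenotype draws (SE of the mean ≈ 0.045).
* Calibration/power of the full skew framework is measured over 20
  independent scenario replicates each at 102 accessions × 20,000 SNPs and
  B = 100: structure-only traits keep skew FDR > 0.05 in 18/20 replicates
  (the two exceptions are chance alignments of the observed polygenic draw
  with the contrast axis), while 5 near-fixed causal loci drive the FDR to
  ≤ 1/101 in 20/20 replicates with all causal loci inside the observed
  top 200.

## 10. Limitations

* F_ST machinery is implemented for two-group contrasts (r = 2); the
  multi-population generalization is not exposed.
* The permutation null conditions on the estimated (σ_g², σ_e²); very small
  samples propagate variance-component noise into the surrogate ensemble.
* The exact KS path assumes no ties between samples (F_ST values are
  continuous in practice); heavy ties shift the exact tail conservatively.
* The demography module post-processes existing PSMC trajectories; it does
  not infer them from sequence.
* Vincenty's inverse may fail to converge for nearly antipodal points; the
  implementation warns and returns the last iterate.
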