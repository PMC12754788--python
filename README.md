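# tobitgwas

GWAS for quantitative traits with measurements below the limit of
detection (LOD), built around a two-step **Linear–Tobit scheme**.

Large-scale proteomics and metabolomics panels report a substantial share
of samples below each assay's LOD. The standard GWAS recipe — substitute
below-LOD values with the LOD, apply a rank-based inverse normal
transform (INT), run linear regression — detects associations well but
systematically *underestimates* effect sizes, and the attenuation grows
with the censored fraction. Attenuated estimates then corrupt downstream
analyses: a Mendelian-randomization (MR) Wald ratio β_MR = β_GO/β_GE with
a censored exposure is inflated by (1 + η)⁻¹, where
η = E[(β̂ − β)/β] < 0 is the relative attenuation.

`tobitgwas` is for statistical geneticists and biomarker analysts who
need both genome-wide speed and unbiased estimates. It provides:

* the **two-step scheme**: fast linear screening of all variants on the
  average-tie INT outcome, greedy LD clumping of the hits
  (p₁ = 5e−8, p₂ = 1e−4, r² = 0.1, 1000 kb window by default), and Tobit
  refinement of the clump leads. The Tobit likelihood
  ℓ(β, σ) = Σ_above-LOD [log φ((yᵢ − xᵢᵀβ)/σ) − log σ]
  + Σ_below-LOD log Φ((c − xᵢᵀβ)/σ)
  treats the censored block as probability mass below the
  transformed-scale threshold c (the max-tie INT value of the block), so
  its estimates are unbiased under censoring;
* the competing approaches for comparison: Cox proportional hazards on
  the flipped outcome y_cox = max(y_obs) − y_obs (with the
  Schoenfeld-residual diagnostic that reveals why this route is unsound
  here) and logistic regression on the above/below-LOD indicator;
* a seeded **simulation engine** (HWE genotypes, additive phenotypes,
  percentile or fixed-LOD censoring, Gaussian-copula LD blocks around a
  lead SNP), the **comparison metrics** (sensitivity at 5e−8, FPR
  calibration against the Binomial Wald interval, concordance, MRAE,
  signed bias η), and the **MR inflation calculus**.

## Worked example

Simulate a 6-variant locus (10 000 individuals, MAF 0.3) where only the
lead SNP is causal (β = 0.25) and half the phenotype values fall below
the LOD, then run the two-step scheme:

```python
from tobitgwas import (LdBlockSpec, simulate_ld_genotypes, assign_ld_effects,
                       simulate_phenotype, apply_censoring,
                       linear_tobit_scheme, signed_relative_bias, mr_inflation)

spec = LdBlockSpec(lead_index=0,
                   target_r=[1.0, 0.92, 0.85, 0.7, 0.55, 0.3],
                   mafs=[0.3] * 6, strategy="single_causal", lead_beta=0.25)
gm = simulate_ld_genotypes(10000, spec, seed=42)
latent = simulate_phenotype(gm.dosages, assign_ld_effects(spec), seed=43)
ph = apply_censoring(latent, 0.5)        # 50% of samples below the LOD
table = linear_tobit_scheme(gm, ph)
```

```
variant_id  position      p_value     beta  refined_beta clump_id  is_index
      snp1     10000 1.131018e-47 0.188815      0.238325     snp1      True
      snp2     20000 1.540023e-37 0.166569           NaN     snp1     False
      snp3     30000 9.051356e-35 0.160995           NaN     snp1     False
      snp4     40000 3.576398e-20 0.120736           NaN     snp1     False
      snp5     50000 6.267916e-16 0.106444           NaN     snp1     False
      snp6     60000 1.318489e-10 0.084655      0.108032     snp6      True
```

The linear screen finds every correlated variant but reports the lead at
β̂ = 0.189 — a 24% underestimate of the true 0.25. Clumping groups the
five variants with r² ≥ 0.1 under the lead (snp6, at r² ≈ 0.09, becomes
its own clump), and the Tobit refit of each lead restores the estimate to
0.238. Left uncorrected, that screening attenuation would inflate a
downstream MR Wald ratio:

```python
eta = signed_relative_bias([0.188815], true_beta=0.25)   # -0.245
mr_inflation(eta)                                        # 1.32
```

i.e. a causal estimate using this exposure association would be ~1.3-fold
too large.

## Command line

```bash
tobitgwas simulate --n 10000 --maf 0.2 --beta 0.1 --censored 0.5 --n-sim 10 --seed 1 --out-dir sim/
tobitgwas gwas --genotypes g.tsv --pheno p.tsv --model linear --out sumstats.tsv
tobitgwas linear-tobit --genotypes g.vcf --pheno p.tsv --p1 5e-8 --r2 0.1 --out two_step.tsv
tobitgwas benchmark --grid grid.json --models linear,tobit --n-sim 100 --seed 1 --out metrics.tsv
tobitgwas mr-inflation --eta -0.22
```

Genotypes are read from dosage TSV or biallelic VCF (GT field); phenotype
TSV needs `sample_id`, `value`, `lod` columns with a single LOD per
trait. Summary statistics carry a provenance header (transform policy,
INT offset, clump parameters, seed).

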