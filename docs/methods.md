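# Methods

## Problem setting

High-throughput proteomics and metabolomics assays report many samples
below the limit of detection (LOD). When such a trait is the outcome of a
genome-wide association study (GWAS), the common practice of substituting
below-LOD values with the LOD, rank-transforming, and running linear
regression yields valid detection but *attenuated* effect estimates, and
the attenuation grows with the censored fraction. Since downstream
analyses — Mendelian randomization (MR), polygenic scores, meta-analysis —
consume the effect estimates, the bias propagates. `tobitgwas` implements
the two-step remedy: screen genome-wide with fast linear regression, then
refit only the lead variants with a Tobit (censored-normal) likelihood
whose estimates are unbiased under censoring.

## Generative model

Dosages g ∈ {0, 1, 2} are drawn per individual as Binomial(2, q) at minor
allele frequency q, so genotype classes follow Hardy–Weinberg proportions
p², 2pq, q² in expectation (we simulate sampling variation in the counts
and verify HWE statistically rather than fixing the expected counts). The
latent trait is y = βg + ε with ε ~ N(0, 1); left-censoring at the LOD
records y_obs = max(y, LOD). Percentile censoring computes the LOD as the
linear-interpolation empirical quantile of each replicate's own latent
vector (the rule matters only for toy-sized vectors; it is fixed and
tested). Fixed-LOD censoring is also available for emulating manual LOD
shifts. No gene–gene or gene–environment interactions are simulated.

### LD blocks

Multi-SNP loci use a Gaussian copula: a standard-normal lead factor
z_lead and one-factor tags z_j = a_j z_lead + √(1 − a_j²) e_j, thresholded
per column at Φ⁻¹(p²) and Φ⁻¹(p² + 2pq) so the marginal genotype
frequencies obey HWE. Because thresholding attenuates correlation, the
latent a_j is found by numerically inverting the genotype-scale
correlation — computed exactly from four bivariate-normal orthant
probabilities — with a monotone (PCHIP) interpolant on an 81-point grid.
Targets beyond the attainable bound for the given MAF pair raise an error
naming the bound. The one-factor structure guarantees a positive
semi-definite latent correlation; tag–tag correlation is a_i·a_j, which is
adequate because only lead–tag LD is specified. Effects are assigned
either to the lead only (single causal) or proportionally to the signed
correlation R with the lead. Under a single causal lead the expected
marginal effect at a tag is β_lead · R · √(Var(G_lead)/Var(G_j)).

### Seeds

Every scenario owns a master seed; replicate r uses seed + r, and the
phenotype noise stream is offset by a large constant from the genotype
stream. Grid scenario seeds derive from the run seed as
(seed·7654321 + index·1000003) mod 2³¹; the wide spacing guarantees that
per-replicate sub-seeds never coincide across scenarios, which would
otherwise share noise vectors between grid cells and keep cross-scenario
averages from cancelling sampling noise. Identical (scenario, seed) pairs
produce bit-identical data.

## Outcome preprocessing

All quantitative-outcome engines see a rank-based inverse normal
transform (INT): rank r maps to Φ⁻¹((r − k)/(n − 2k + 1)) with the Blom
offset k = 3/8 (configurable). The censored block is one large tied group:

* the **linear** model assigns it the *average* rank, a central imputation
  that attenuates less than the max rank would;
* the **Tobit** model assigns it the *max* rank, so the block sits exactly
  at the transformed-scale LOD, which becomes the censoring threshold c in
  the likelihood; uncensored values are strictly above c by construction.

Ties among uncensored values (possible in real data) follow the same
declared policy. The **Cox** route flips to pseudo-time
y_cox = max(y_obs) − y_obs with above-LOD samples as events and no rank
transform; the **logistic** route keeps only the above/below-LOD
indicator.

## Fitting engines

* Linear: OLS (statsmodels), two-sided t test on the genotype term.
* Tobit: maximize Σ_unc [log φ((y_i − x_iᵀβ)/σ) − log σ] +
  Σ_cens log Φ((c − x_iᵀβ)/σ) over (β, log σ). BFGS with the analytic
  gradient, OLS warm start, gradient tolerance 1e-6 on the mean
  log-likelihood, at most 200 iterations, Nelder–Mead polish on
  line-search failure. Standard errors from the inverse observed
  information (central-difference Hessian of the analytic gradient).
  The inverse Mills ratio is evaluated through `log_ndtr` for tail
  stability. With no censored observations the threshold sits below the
  minimum and the fit reduces to the uncensored MLE (= OLS).
* Cox: lifelines `CoxPHFitter` (Efron ties — with a continuous phenotype
  the only tied block is the censored one, all non-events, so the choice
  is benign). The proportional-hazards diagnostic is the
  Grambsch–Therneau score test on scaled Schoenfeld residuals with the
  Kaplan–Meier time transform (lifelines), read at 0.05 and 5e−8.
* Logistic: statsmodels IRLS. Fits are refused (reported as
  non-converged with a diagnostic) when the minority class has fewer than
  10 observations; separation is caught and flagged rather than raised.

All genotype p-values are two-sided Wald tests. Covariates are accepted
by every engine even though the simulations use none. Variants with minor
allele count < 3 are skipped with an NA record and a reason code so
genome-wide loops survive.

## Two-step scheme

`linear_tobit_scheme` = linear screen over all variants → greedy LD
clumping (defaults p1 = 5e−8, p2 = 1e−4, r² = 0.1, 1000 kb window; LD from
the analysis sample's own dosages, no external panel) → Tobit refit of
the clump leads. Equal p-values break toward the smaller base-pair
position; the result is invariant to the on-disk variant order. A
`refine_all_significant` switch refits every p < p1 variant instead of
leads only. The Tobit fit count equals the refinement-list length, so
cost scales with loci, not variants.

## Metrics and MR inflation

Sensitivity is the fraction of non-null replicates with p < 5e−8; FPR is
read at 0.05 (calibration-checked against the Binomial(n_sim, 0.05)
Wald interval — (0.0365, 0.0635) at n_sim = 1000) and at the suggestive
1e−5 (5e−8 would give 0 for every model). Accuracy uses the mean relative
absolute error MRAE = mean|(β* − β)/β| and the signed mean relative error
η = mean((β* − β)/β); η < 0 is attenuation. Non-converged fits are
excluded from MRAE/η and counted as non-detections. When an attenuated
association is used as the exposure arm of an MR Wald ratio
β_MR = β_GO/β_GE, the causal estimate is inflated by (1 + η)⁻¹.

Because per-replicate relative errors carry sampling noise proportional
to 1/(β√(2Npq)), η is only interpretable after averaging across many
replicates and scenarios; the pooled value is the scenario-averaged bias.
The same reasoning applies to the Tobit accuracy summary: the package
reports the magnitude of the scenario-averaged signed error, in which
sampling noise cancels, alongside the per-replicate MRAE, which does not.

## Problem sizes

The benchmark grid is the package's reduced factorial: N ∈ {5000, 10000},
β ∈ {0.05, 0.1, 0.25}, MAF ∈ {0.1, 0.2, 0.4}, censored fraction
∈ {10%, 50%, 90%}, with 100–200 replicates per cell (100 in the test
suite, 200 in the reproduction script). This subset brackets the
biobank-relevant corner of the full design while staying desk-sized; the
attenuation it measures is driven almost entirely by the censored
fraction, so the reduced grid reproduces the full-scale curve. With a
fixed seed the grid is deterministic end to end.

## Known limitations

* A single LOD per trait is assumed and enforced at read time;
  batch-varying LODs must be analyzed per batch and meta-analyzed.
* No mixed-model/GRM adjustment: estimates ignore genetic relatedness, so
  the engines target unrelated-sample designs.
* The synthetic genotypes have no minor-allele-frequency spectrum,
  missingness, or imputation uncertainty; phenotypes are Gaussian before
  censoring, so skewness beyond what INT removes is not emulated. Passing
  tests demonstrate correctness of the estimators under the generative
  model, not robustness to real-data artifacts.
* The Cox engine is retained for comparison despite its systematic
  proportional-hazards violation on this design — the flip makes the
  "time" scale the outcome itself, so a genotype effect is intrinsically
  non-proportional; the Schoenfeld diagnostic makes this visible.
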