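"""Seeded simulation of genotypes, censored phenotypes, and LD-structured loci.

The generative model is the standard additive single-SNP GWAS model: dosages
g in {0, 1, 2} are drawn under Hardy-Weinberg equilibrium at a given minor
allele frequency q, the latent quantitative trait is y = beta * g + eps with
eps ~ N(0, 1), and left-censoring at a limit of detection (LOD) replaces
every value below the threshold with the threshold itself, so the recorded
data are y_obs = max(y, LOD).

Multi-SNP loci with linkage disequilibrium are generated through a Gaussian
copula: a latent standard-normal factor structure is thresholded per column
at the HWE genotype cumulative frequencies, with the latent correlation
calibrated numerically so that the *genotype-scale* Pearson correlation with
the lead variant hits its target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator
from scipy.special import ndtri

__all__ = [
    "SimulationScenario",
    "GenotypeMatrix",
    "CensoredPhenotype",
    "LdBlockSpec",
    "simulate_genotypes_hwe",
    "simulate_phenotype",
    "apply_censoring",
    "apply_lod",
    "simulate_ld_genotypes",
    "assign_ld_effects",
    "expected_marginal_effect",
    "genotype_correlation",
    "max_attainable_correlation",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulation design.

    Parameters mirror the factors varied in the study: sample size N,
    minor allele frequency q, additive effect size beta (0 under the null),
    the fraction of measurements below the LOD, the number of replicate
    datasets, and the master seed.
    """

    n_individuals: int
    maf: float
    effect_size: float
    censored_proportion: float
    n_sim: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must lie in (0, 0.5], got {self.maf}")
        if not 0.0 <= self.censored_proportion < 1.0:
            raise ValueError("censored_proportion must lie in [0, 1)")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")

    def replicate_seed(self, replicate: int) -> int:
        # per-replicate sub-seed: master seed + replicate index (auditably simple)
        return int(self.seed) + int(replicate)


@dataclass
class GenotypeMatrix:
    """n x m additive dosage matrix with per-variant metadata.

    ``realized_mafs`` is (2*n2 + n1) / (2N), the allele-count estimate of the
    minor allele frequency in the realized sample.
    """

    dosages: np.ndarray
    variant_ids: list[str]
    positions: np.ndarray
    realized_mafs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (samples x variants) array")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must contain only 0, 1, 2")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.realized_mafs is None:
            self.realized_mafs = self.dosages.mean(axis=0) / 2.0
        if len(self.variant_ids) != self.dosages.shape[1]:
            raise ValueError("variant_ids length does not match dosage columns")
        if len(self.positions) != self.dosages.shape[1]:
            raise ValueError("positions length does not match dosage columns")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column(self, j: int) -> np.ndarray:
        return np.asarray(self.dosages[:, j], dtype=float)


@dataclass
class CensoredPhenotype:
    """Observed (substituted) phenotype with its LOD and censoring flags.

    ``observed`` already carries the substitution y_obs = max(y, LOD);
    ``is_censored`` marks samples whose latent value fell below the LOD.
    ``latent`` keeps the pre-censoring values when the data are simulated.
    """

    observed: np.ndarray
    lod: float
    is_censored: np.ndarray
    latent: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.is_censored = np.asarray(self.is_censored, dtype=bool)
        if self.observed.shape != self.is_censored.shape:
            raise ValueError("observed and is_censored must have equal shape")
        if np.any(self.observed < self.lod - 1e-12):
            raise ValueError("observed values must not lie below the LOD")

    @property
    def n(self) -> int:
        return self.observed.shape[0]

    @property
    def censored_proportion(self) -> float:
        return float(self.is_censored.mean())


@dataclass
class LdBlockSpec:
    """Specification of a multi-SNP locus around a lead variant.

    ``target_r`` holds the signed genotype-scale Pearson correlations each
    variant should have with the lead (the lead itself gets 1.0);
    ``strategy`` selects how effects are assigned: a single causal lead
    (``single_causal``) or effects scaled by signed LD (``ld_proportional``).
    """

    lead_index: int
    target_r: np.ndarray
    mafs: np.ndarray
    strategy: str = "single_causal"
    lead_beta: float = 0.1

    def __post_init__(self) -> None:
        self.target_r = np.asarray(self.target_r, dtype=float)
        self.mafs = np.asarray(self.mafs, dtype=float)
        if self.target_r.shape != self.mafs.shape:
            raise ValueError("target_r and mafs must have equal length")
        if np.any(np.abs(self.target_r) > 1):
            raise ValueError("|target_r| must be <= 1")
        if not np.isclose(self.target_r[self.lead_index], 1.0):
            raise ValueError("the lead variant must have target_r = 1")
        if np.any((self.mafs <= 0) | (self.mafs > 0.5)):
            raise ValueError("mafs must lie in (0, 0.5]")
        if self.strategy not in ("single_causal", "ld_proportional"):
            raise ValueError(f"unknown strategy {self.strategy!r}")

    @property
    def n_variants(self) -> int:
        return self.target_r.shape[0]


def simulate_genotypes_hwe(
    n: int, maf: float, seed: int, n_variants: int = 1
) -> GenotypeMatrix:
    """Draw independent HWE genotypes: each dosage ~ Binomial(2, maf).

    Genotype class frequencies are then p^2 / 2pq / q^2 in expectation
    (expected counts N p^2, 2Npq, N q^2).
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must lie in (0, 0.5], got {maf}")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, maf, size=(n, n_variants)).astype(np.int8)
    ids = [f"snp{j + 1}" for j in range(n_variants)]
    positions = np.arange(1, n_variants + 1, dtype=np.int64)
    return GenotypeMatrix(dosages, ids, positions)


def simulate_phenotype(
    genotypes: np.ndarray, beta: float | np.ndarray, seed: int
) -> np.ndarray:
    """Latent additive phenotype y = g @ beta + eps, eps ~ N(0, 1).

    ``genotypes`` may be a single dosage vector with scalar ``beta`` or an
    n x m dosage matrix with a length-m effect vector.
    """
    g = np.asarray(genotypes, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    rng = np.random.default_rng(seed)
    if g.ndim == 1:
        signal = float(beta) * g
    else:
        signal = g @ np.asarray(beta, dtype=float)
    return signal + rng.standard_normal(g.shape[0])


def apply_censoring(
    latent: np.ndarray, censored_proportion: float
) -> CensoredPhenotype:
    """Left-censor at the empirical quantile of ``latent``.

    The LOD is the linear-interpolation empirical quantile at the requested
    proportion; values strictly below it are replaced by it.
    """
    latent = np.asarray(latent, dtype=float)
    if not 0.0 <= censored_proportion < 1.0:
        raise ValueError("censored_proportion must lie in [0, 1)")
    lod = float(np.quantile(latent, censored_proportion))
    return apply_lod(latent, lod)


def apply_lod(latent: np.ndarray, lod_value: float) -> CensoredPhenotype:
    """Left-censor at a fixed threshold: observed = max(latent, LOD)."""
    latent = np.asarray(latent, dtype=float)
    if not np.isfinite(lod_value):
        raise ValueError("lod_value must be finite")
    if lod_value >= latent.max():
        raise ValueError("lod_value >= max(latent): no uncensored observations")
    is_censored = latent < lod_value
    observed = np.maximum(latent, lod_value)
    return CensoredPhenotype(observed, float(lod_value), is_censored, latent=latent)


# ---------------------------------------------------------------------------
# Gaussian-copula LD blocks


def _hwe_thresholds(maf: float) -> tuple[float, float]:
    """Latent-normal cutpoints so P(dosage=0)=p^2 and P(dosage<=1)=p^2+2pq."""
    p = 1.0 - maf
    return float(ndtri(p * p)), float(ndtri(p * p + 2 * p * maf))


def genotype_correlation(latent_rho: float, maf1: float, maf2: float) -> float:
    """Genotype-scale Pearson correlation induced by latent correlation rho.

    Dosage X = 1{z > a1} + 1{z > a2}; E[XY] follows from four bivariate
    normal orthant probabilities, and HWE gives Var(X) = 2pq exactly.
    """
    if abs(latent_rho) >= 1.0:
        latent_rho = float(np.sign(latent_rho)) * 0.999999
    a1, a2 = _hwe_thresholds(maf1)
    b1, b2 = _hwe_thresholds(maf2)
    cov = np.array([[1.0, latent_rho], [latent_rho, 1.0]])
    bvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov)

    def surv(a: float, b: float) -> float:
        # P(z1 > a, z2 > b)
        return 1.0 - stats.norm.cdf(a) - stats.norm.cdf(b) + float(bvn.cdf([a, b]))

    exy = surv(a1, b1) + surv(a1, b2) + surv(a2, b1) + surv(a2, b2)
    q1, q2 = maf1, maf2
    var1 = 2 * q1 * (1 - q1)
    var2 = 2 * q2 * (1 - q2)
    return (exy - 4 * q1 * q2) / np.sqrt(var1 * var2)


@lru_cache(maxsize=256)
def _latent_rho_table(maf1: float, maf2: float):
    grid = np.linspace(-0.9999, 0.9999, 81)
    geno = np.array([genotype_correlation(r, maf1, maf2) for r in grid])
    # genotype-scale correlation is monotone in the latent correlation
    return PchipInterpolator(geno, grid), float(geno[0]), float(geno[-1])


def max_attainable_correlation(maf1: float, maf2: float) -> tuple[float, float]:
    """(most negative, most positive) genotype correlation reachable by the copula."""
    _, lo, hi = _latent_rho_table(round(maf1, 10), round(maf2, 10))
    return lo, hi


def latent_rho_for_target(target_r: float, maf1: float, maf2: float) -> float:
    """Invert the copula so the genotype-scale correlation equals target_r."""
    inv, lo, hi = _latent_rho_table(round(maf1, 10), round(maf2, 10))
    if not lo <= target_r <= hi:
        raise ValueError(
            f"target correlation {target_r:.3f} is not attainable for "
            f"MAFs ({maf1}, {maf2}); attainable range is [{lo:.3f}, {hi:.3f}]"
        )
    return float(np.clip(inv(target_r), -1.0, 1.0))


def simulate_ld_genotypes(n: int, spec: LdBlockSpec, seed: int) -> GenotypeMatrix:
    """Draw an LD block of {0,1,2} dosages with target correlations to the lead.

    One-factor latent structure: z_j = a_j * z_lead + sqrt(1 - a_j^2) * e_j
    with a_j the calibrated latent correlation, thresholded per column at the
    HWE genotype cumulative frequencies. A target of exactly +/-1 with equal
    MAFs duplicates (or mirrors) the lead column.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    m = spec.n_variants
    lead = spec.lead_index
    maf_lead = float(spec.mafs[lead])

    z_lead = rng.standard_normal(n)
    dosages = np.empty((n, m), dtype=np.int8)
    for j in range(m):
        maf_j = float(spec.mafs[j])
        r = float(spec.target_r[j])
        if j == lead or (abs(r) == 1.0 and maf_j == maf_lead):
            a = float(np.sign(r))
            z = a * z_lead
        else:
            a = latent_rho_for_target(r, maf_lead, maf_j)
            z = a * z_lead + np.sqrt(max(0.0, 1.0 - a * a)) * rng.standard_normal(n)
        t1, t2 = _hwe_thresholds(maf_j)
        dosages[:, j] = (z > t1).astype(np.int8) + (z > t2).astype(np.int8)
    ids = [f"snp{j + 1}" for j in range(m)]
    positions = np.arange(1, m + 1, dtype=np.int64) * 10_000
    return GenotypeMatrix(dosages, ids, positions)


def assign_ld_effects(spec: LdBlockSpec) -> np.ndarray:
    """Per-variant effect sizes for the two locus-simulation strategies.

    single_causal: beta_lead at the lead, zero elsewhere.
    ld_proportional: beta_j = beta_lead * R_j (signed LD with the lead).
    """
    if spec.strategy == "single_causal":
        beta = np.zeros(spec.n_variants)
        beta[spec.lead_index] = spec.lead_beta
        return beta
    return spec.lead_beta * spec.target_r


def expected_marginal_effect(
    beta_lead: float, r: float, var_lead: float, var_j: float
) -> float:
    """Marginal (tag-SNP) effect under a single causal lead.

    beta_j_hat = beta_lead * R * sqrt(Var(G_lead) / Var(G_j)).
    """
    if var_j <= 0:
        raise ValueError("var_j must be positive")
    return beta_lead * r * np.sqrt(var_lead / var_j)


def simulate_dataset(
    scenario: SimulationScenario, replicate: int = 0
) -> tuple[GenotypeMatrix, CensoredPhenotype]:
    """Genotypes + censored phenotype for one replicate of a scenario."""
    sub = scenario.replicate_seed(replicate)
    gm = simulate_genotypes_hwe(scenario.n_individuals, scenario.maf, sub)
    latent = simulate_phenotype(gm.column(0), scenario.effect_size, sub + 500_000_007)
    ph = apply_censoring(latent, scenario.censored_proportion)
    return gm, ph
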