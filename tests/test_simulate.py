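"""Generator correctness: HWE genotypes, censoring rules, LD copula."""

import numpy as np
import pytest
from scipy import stats

from tobitgwas.simulate import (
    CensoredPhenotype,
    LdBlockSpec,
    SimulationScenario,
    apply_censoring,
    apply_lod,
    assign_ld_effects,
    expected_marginal_effect,
    genotype_correlation,
    max_attainable_correlation,
    simulate_dataset,
    simulate_genotypes_hwe,
    simulate_ld_genotypes,
    simulate_phenotype,
)


class TestHweGenotypes:
    def test_genotype_counts_follow_hwe(self):
        """Observed genotype class counts pass a chi-square HWE check."""
        n, maf = 10000, 0.2
        expected = np.array([n * 0.8**2, n * 2 * 0.8 * 0.2, n * 0.2**2])
        n_pass = 0
        for seed in range(100):
            gm = simulate_genotypes_hwe(n, maf, seed)
            counts = np.bincount(gm.dosages[:, 0], minlength=3)
            p = stats.chisquare(counts, expected).pvalue
            n_pass += p > 0.001
        assert n_pass >= 97  # >=99% expected; allow binomial slack at 100 seeds

    def test_mean_dosage_symmetric_at_half(self):
        gm = simulate_genotypes_hwe(100, 0.5, seed=1)
        se = np.sqrt(2 * 0.25 / 100)
        assert abs(gm.dosages.mean() - 1.0) < 4 * se

    def test_realized_maf_sampling_distribution(self):
        """Realized MAF across seeds ~ mean q, sd sqrt(q(1-q)/(2N))."""
        mafs = [
            simulate_genotypes_hwe(5000, 0.1, seed).realized_mafs[0]
            for seed in range(1000)
        ]
        assert np.mean(mafs) == pytest.approx(0.1, abs=3 * 0.003 / np.sqrt(1000))
        assert np.std(mafs) == pytest.approx(np.sqrt(0.1 * 0.9 / 10000), rel=0.15)

    @pytest.mark.parametrize("maf", [0.0, -0.1, 0.6, 1.0])
    def test_invalid_maf_rejected(self, maf):
        with pytest.raises(ValueError):
            simulate_genotypes_hwe(100, maf, seed=0)

    def test_reproducible_bit_identical(self):
        a = simulate_genotypes_hwe(500, 0.3, seed=9)
        b = simulate_genotypes_hwe(500, 0.3, seed=9)
        assert np.array_equal(a.dosages, b.dosages)


class TestPhenotype:
    def test_null_phenotype_is_standard_normal(self):
        g = simulate_genotypes_hwe(20000, 0.2, 0).column(0)
        y = simulate_phenotype(g, 0.0, seed=5)
        assert np.var(y) == pytest.approx(1.0, rel=0.05)
        assert stats.kstest(y, "norm").pvalue > 1e-4

    def test_ols_recovers_slope(self):
        g = simulate_genotypes_hwe(100000, 0.2, 1).column(0)
        y = simulate_phenotype(g, 0.5, seed=2)
        slope, _ = np.polyfit(g, y, 1)
        se = 1.0 / np.sqrt(100000 * np.var(g))
        assert abs(slope - 0.5) < 3 * se

    def test_monomorphic_genotype_gives_pure_noise(self):
        y = simulate_phenotype(np.zeros(5000), 0.1, seed=3)
        assert np.var(y) == pytest.approx(1.0, rel=0.1)


class TestCensoring:
    def test_zero_proportion_is_identity(self, rng):
        latent = rng.standard_normal(100)
        ph = apply_censoring(latent, 0.0)
        assert np.array_equal(ph.observed, latent)
        assert not ph.is_censored.any()

    def test_exact_count_on_toy_vector(self):
        latent = np.arange(1.0, 11.0)
        ph = apply_censoring(latent, 0.3)
        # linear-interpolation 30th percentile of 1..10 is 3.7
        assert ph.lod == pytest.approx(3.7)
        assert ph.is_censored.sum() == 3
        assert np.all(ph.observed[ph.is_censored] == ph.lod)

    def test_heavy_censoring_lod_matches_normal_quantile(self, rng):
        latent = rng.standard_normal(10000)
        ph = apply_censoring(latent, 0.9)
        assert ph.lod == pytest.approx(1.2815515655446004, abs=0.06)
        assert abs(ph.censored_proportion - 0.9) <= 0.9 / 100

    def test_realized_fraction_close_to_request(self, rng):
        latent = rng.standard_normal(5000)
        for prop in (0.1, 0.5, 0.9):
            ph = apply_censoring(latent, prop)
            assert abs(ph.censored_proportion - prop) <= 1 / 5000 + 1e-12

    def test_observed_never_below_lod(self, rng):
        ph = apply_censoring(rng.standard_normal(1000), 0.4)
        assert np.all(ph.observed >= ph.lod)

    def test_full_censoring_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_censoring(rng.standard_normal(10), 1.0)


class TestApplyLod:
    def test_lod_below_minimum_censors_nothing(self, rng):
        latent = rng.standard_normal(50)
        ph = apply_lod(latent, latent.min() - 1)
        assert not ph.is_censored.any()

    def test_lod_zero_on_standard_normal_censors_half(self, rng):
        ph = apply_lod(rng.standard_normal(10000), 0.0)
        assert ph.censored_proportion == pytest.approx(0.5, abs=0.02)

    def test_enumerated_toy(self):
        ph = apply_lod(np.array([-1.0, 0.0, 1.0]), 0.5)
        assert np.allclose(ph.observed, [0.5, 0.5, 1.0])
        assert ph.censored_proportion == pytest.approx(2 / 3)

    def test_lod_above_maximum_rejected(self, rng):
        latent = rng.standard_normal(20)
        with pytest.raises(ValueError):
            apply_lod(latent, latent.max() + 1)


class TestLdBlock:
    def test_perfect_ld_duplicates_lead(self):
        spec = LdBlockSpec(0, [1.0, 1.0], [0.3, 0.3])
        gm = simulate_ld_genotypes(5000, spec, seed=4)
        assert np.array_equal(gm.dosages[:, 0], gm.dosages[:, 1])

    def test_zero_target_gives_independence(self):
        spec = LdBlockSpec(0, [1.0, 0.0], [0.3, 0.3])
        gm = simulate_ld_genotypes(10000, spec, seed=4)
        r = np.corrcoef(gm.dosages[:, 0].astype(float), gm.dosages[:, 1].astype(float))[0, 1]
        assert abs(r) < 3 / np.sqrt(10000)

    def test_hybrid_block_hits_ld_groups(self):
        """6 variants at r2>=0.8 and 6 at 0.5<=r2<0.8 land in their groups."""
        target_r = np.array([1.0] + [0.95, 0.93, 0.92, 0.91, 0.9] + [0.85, 0.8, 0.78, 0.75, 0.73, 0.71])
        spec = LdBlockSpec(0, target_r, np.full(12, 0.3))
        gm = simulate_ld_genotypes(10000, spec, seed=11)
        dos = gm.dosages.astype(float)
        r = np.array([np.corrcoef(dos[:, 0], dos[:, j])[0, 1] for j in range(12)])
        assert np.all(np.abs(r - target_r) < 0.05)
        r2 = r**2
        assert np.all(r2[:6] >= 0.8)
        assert np.all((r2[6:] >= 0.5) & (r2[6:] < 0.8))

    def test_realized_r_monotone_in_target(self):
        targets = [0.2, 0.4, 0.6, 0.8]
        spec = LdBlockSpec(0, [1.0] + targets, np.full(5, 0.25))
        gm = simulate_ld_genotypes(10000, spec, seed=2)
        dos = gm.dosages.astype(float)
        r = [np.corrcoef(dos[:, 0], dos[:, j])[0, 1] for j in range(1, 5)]
        assert np.all(np.diff(r) > 0)

    def test_infeasible_correlation_names_bound(self):
        # very different MAFs cap the attainable genotype correlation
        lo, hi = max_attainable_correlation(0.5, 0.05)
        assert hi < 0.99
        spec = LdBlockSpec(0, [1.0, 0.999], [0.5, 0.05])
        with pytest.raises(ValueError, match="attainable"):
            simulate_ld_genotypes(1000, spec, seed=0)

    def test_copula_calibration_matches_analytic_correlation(self):
        """Empirical genotype correlation matches the orthant-probability formula."""
        rho, maf1, maf2 = 0.7, 0.3, 0.2
        expected = genotype_correlation(rho, maf1, maf2)
        rng = np.random.default_rng(0)
        z1 = rng.standard_normal(200000)
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(200000)
        from tobitgwas.simulate import _hwe_thresholds

        a1, a2 = _hwe_thresholds(maf1)
        b1, b2 = _hwe_thresholds(maf2)
        g1 = (z1 > a1).astype(float) + (z1 > a2)
        g2 = (z2 > b1).astype(float) + (z2 > b2)
        assert np.corrcoef(g1, g2)[0, 1] == pytest.approx(expected, abs=0.01)


class TestEffects:
    def test_single_causal_vector(self):
        spec = LdBlockSpec(2, [0.5, 0.7, 1.0, 0.7], np.full(4, 0.3), "single_causal", 0.1)
        assert np.allclose(assign_ld_effects(spec), [0, 0, 0.1, 0])

    def test_ld_proportional_scales_by_signed_r(self):
        spec = LdBlockSpec(
            0, [1.0, 0.9, -0.8, 0.0], np.full(4, 0.3), "ld_proportional", 0.1
        )
        assert np.allclose(assign_ld_effects(spec), [0.1, 0.09, -0.08, 0.0])

    def test_marginal_effect_formula(self):
        assert expected_marginal_effect(0.1, 1.0, 0.4, 0.4) == pytest.approx(0.1)
        assert expected_marginal_effect(0.1, 0.9, 0.4, 0.4) == pytest.approx(0.09)
        assert expected_marginal_effect(0.1, 0.8, 0.42, 0.32) == pytest.approx(
            0.1 * 0.8 * np.sqrt(0.42 / 0.32)
        )
        with pytest.raises(ValueError):
            expected_marginal_effect(0.1, 0.8, 0.4, 0.0)

    def test_tag_snp_ols_slope_matches_marginal_effect(self):
        """Under a single causal lead, a tag SNP's OLS slope equals the
        marginal-effect prediction within sampling error."""
        spec = LdBlockSpec(0, [1.0, 0.8], [0.3, 0.3], "single_causal", 0.1)
        gm = simulate_ld_genotypes(100000, spec, seed=8)
        beta = assign_ld_effects(spec)
        y = simulate_phenotype(gm.dosages, beta, seed=9)
        g_tag = gm.column(1)
        slope = np.polyfit(g_tag, y, 1)[0]
        g_lead = gm.column(0)
        expected = expected_marginal_effect(
            0.1, np.corrcoef(g_lead, g_tag)[0, 1], np.var(g_lead), np.var(g_tag)
        )
        se = 1.0 / np.sqrt(100000 * np.var(g_tag))
        assert abs(slope - expected) < 3 * se


class TestScenario:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationScenario(100, 0.6, 0.1, 0.5)
        with pytest.raises(ValueError):
            SimulationScenario(100, 0.2, 0.1, 1.0)
        with pytest.raises(ValueError):
            SimulationScenario(100, 0.2, 0.1, 0.5, n_sim=0)

    def test_dataset_reproducibility(self):
        sc = SimulationScenario(500, 0.2, 0.1, 0.3, seed=77)
        gm1, ph1 = simulate_dataset(sc, 3)
        gm2, ph2 = simulate_dataset(sc, 3)
        assert np.array_equal(gm1.dosages, gm2.dosages)
        assert np.array_equal(ph1.observed, ph2.observed)

    def test_replicates_differ(self):
        sc = SimulationScenario(500, 0.2, 0.1, 0.3, seed=77)
        _, ph1 = simulate_dataset(sc, 0)
        _, ph2 = simulate_dataset(sc, 1)
        assert not np.array_equal(ph1.observed, ph2.observed)


def test_censored_phenotype_invariant_enforced():
    with pytest.raises(ValueError):
        CensoredPhenotype(np.array([-1.0, 2.0]), 0.0, np.array([True, False]))
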