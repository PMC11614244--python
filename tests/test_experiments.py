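import numpy as np
import pytest

from icmsim.experiments import (
    PerturbationSpec,
    add_exogenous_fgf4,
    concentration_conversion,
    cv_from_counts,
    fate_error,
    safd,
    sample_icd,
)
from icmsim.params import ParameterSet
from icmsim.reactions import S


class TestDefaultICD:
    def test_per_gene_means_match_map_values(self, map_params, rng):
        x = np.concatenate([sample_icd(map_params, 500, rng=rng)
                            for _ in range(4)])
        n = x.shape[0]
        for idx, mean in ((S.Nanog_mRNA, 117.0), (S.Gata6_mRNA, 117.0),
                          (S.NANOG, 482.0), (S.GATA6, 482.0)):
            se = np.sqrt(mean / n)  # Poisson marginals
            assert abs(x[:, idx].mean() - mean) < 3 * se

    def test_fair_split_of_poisson_pool_gives_independent_poisson_marginals(
            self, map_params, rng):
        """Poisson thinning: the pooled-draw-plus-binomial-split composition
        is in law two independent Poisson counts, so the empirical
        correlation vanishes and variance matches the mean."""
        x = sample_icd(map_params, 4000, rng=rng)
        r = np.corrcoef(x[:, S.NANOG], x[:, S.GATA6])[0, 1]
        assert abs(r) < 0.05
        assert x[:, S.NANOG].var() == pytest.approx(482.0, rel=0.15)

    def test_independent_split_option_equivalent_in_law(self, rng):
        p = ParameterSet(icd_split="independent")
        x = sample_icd(p, 2000, rng=rng)
        assert abs(x[:, S.NANOG].mean() - 482.0) < 3 * np.sqrt(482 / 2000)

    def test_erk_pool_high_everything_else_zero(self, map_params, rng):
        x = sample_icd(map_params, 10, rng=rng)
        assert (x[:, S.I_ERK] == 1000).all()
        for idx in (S.Fgf4_mRNA, S.FGF4, S.P_NANOG, S.M_FGFR_FGF4,
                    S.D_FGFR_FGF4, S.A_ERK):
            assert (x[:, idx] == 0).all()

    def test_zero_means_give_empty_grn_state(self, rng):
        p = ParameterSet(mean_init_mrna=0.0, mean_init_protein=0.0)
        x = sample_icd(p, 50, rng=rng)
        assert (x[:, :S.M_FGFR_FGF4] == 0).all()

    def test_symmetry_of_expected_allocations(self, map_params, rng):
        x = sample_icd(map_params, 5000, rng=rng)
        diff = x[:, S.NANOG].mean() - x[:, S.GATA6].mean()
        se = np.sqrt(2 * 482.0 / 5000)
        assert abs(diff) < 3 * se


class TestPerturbations:
    def test_uniform_variability_inflates_variance(self, map_params, rng):
        """Law of total variance: with a uniform mean layer of full
        intensity, Var = E[U] + Var(U) >> Poisson variance."""
        spec = PerturbationSpec(icp_mode="uniform_variability",
                                icp_intensity=100.0)
        x = sample_icd(map_params, 4000, spec, rng=rng)
        v = x[:, S.NANOG].var()
        m = map_params.mean_init_protein
        expect = m + (2 * m) ** 2 / 12.0   # E[U] + Var(U), U ~ Uniform(0, 2m)
        assert v > 3 * m                   # far super-Poissonian
        assert v == pytest.approx(expect, rel=0.15)

    def test_equal_linear_scales_both_genes(self, map_params, rng):
        spec = PerturbationSpec(icp_mode="equal_linear", icp_intensity=100.0,
                                n_perturbed_cells=400)
        x = sample_icd(map_params, 400, spec, rng=rng)
        assert x[:, S.NANOG].mean() == pytest.approx(964, rel=0.05)
        assert x[:, S.GATA6].mean() == pytest.approx(964, rel=0.05)

    def test_adversarial_linear_minus_100_is_double_nanog_no_gata6(
            self, map_params, rng):
        spec = PerturbationSpec(icp_mode="adversarial_linear",
                                icp_intensity=-100.0, n_perturbed_cells=300)
        x = sample_icd(map_params, 300, spec, rng=rng)
        assert x[:, S.NANOG].mean() == pytest.approx(964, rel=0.05)
        assert (x[:, S.GATA6] == 0).all()

    def test_perturbed_subset_size_respected(self, map_params, rng):
        spec = PerturbationSpec(icp_mode="equal_linear", icp_intensity=100.0,
                                n_perturbed_cells=10)
        x = sample_icd(map_params, 100, spec, rng=rng)
        inflated = (x[:, S.NANOG] + x[:, S.GATA6]) > 1400
        assert 3 <= inflated.sum() <= 17  # ~10 cells at doubled means

    def test_invalid_specs(self, map_params):
        with pytest.raises(ValueError):
            PerturbationSpec(icp_mode="wat")
        with pytest.raises(ValueError):
            PerturbationSpec(icp_mode="equal_linear", icp_intensity=150.0)
        spec = PerturbationSpec(icp_mode="equal_linear", icp_intensity=50.0,
                                n_perturbed_cells=10)
        with pytest.raises(ValueError):
            sample_icd(ParameterSet(), 5, spec, seed=0)


class TestExogenousFgf4:
    def test_mean_zero_is_noop(self, map_params):
        iv = add_exogenous_fgf4(map_params, 25, 0.0, 0.0, seed=1)
        assert (iv.counts == 0).all()

    def test_per_cell_mean_unbiased(self, map_params, rng):
        iv = add_exogenous_fgf4(map_params, 10_000, 250.0, 4.0, rng=rng)
        se = np.sqrt(2 * 250.0 / 10_000)  # compound-distribution variance 2m
        assert abs(iv.counts.mean() - 250.0) < 3 * se
        assert iv.time == pytest.approx(4.0 * 3600.0)
        assert iv.species == S.M_FGFR_FGF4

    def test_cytoplasmic_entry_option(self, rng):
        p = ParameterSet(exogenous_target="cytoplasm")
        iv = add_exogenous_fgf4(p, 5, 10.0, 0.0, rng=rng)
        assert iv.species == S.FGF4

    def test_negative_mean_rejected(self, map_params):
        with pytest.raises(ValueError):
            add_exogenous_fgf4(map_params, 5, -1.0, 0.0, seed=1)


class TestRobustnessStatistics:
    def test_binomial_baseline_formula(self):
        counts = np.full((100, 3), [10, 15, 0])
        df = cv_from_counts(counts, eta=25)
        epi = df[df.fate == "EPI"].iloc[0]
        assert epi.cv0 == pytest.approx(np.sqrt(0.6 / 10.0))
        assert epi.cv0 == pytest.approx(0.2449, abs=1e-3)

    def test_pure_binomial_counts_give_unit_ratio(self, rng):
        """Self-consistency: binomially assigned fates have CV1 ~ CV0."""
        eta, p = 100, 0.4
        epi = rng.binomial(eta, p, size=4000)
        counts = np.stack([epi, eta - epi, np.zeros_like(epi)], axis=1)
        df = cv_from_counts(counts, eta)
        assert df[df.fate == "EPI"].iloc[0].ratio == pytest.approx(1.0, abs=0.05)

    def test_zero_mean_fate_reported_missing(self):
        counts = np.tile([25, 0, 0], (10, 1))
        df = cv_from_counts(counts, 25)
        assert np.isnan(df[df.fate == "PRE"].iloc[0].cv1)

    def test_safd_examples(self, rng):
        ref = np.array([38.0, 40.0, 42.0])     # mean 40, sd 2
        assert safd(ref, ref) == 0.0
        assert safd(ref, ref + 5.0) == pytest.approx(2.5)
        big = rng.normal(50, 5, size=2000)
        assert safd(big, rng.permutation(big)) < 0.05
        assert np.isnan(safd(np.full(5, 3.0), np.full(5, 9.0)))

    def test_fate_error_signed_mean_difference(self):
        assert fate_error(np.full(10, 60.0), np.full(10, 62.0)) == pytest.approx(2.0)
        assert fate_error([1, 2, 3], [1, 2, 3]) == 0.0


class TestConcentrationConversion:
    def test_published_conversion_entries(self):
        assert concentration_conversion(0.0, 100) == 0.0
        assert round(concentration_conversion(100.0, 100), 2) == 0.99
        # the 50-copy entry is printed to one decimal (0.494... -> 0.5)
        assert round(concentration_conversion(50.0, 100), 1) == 0.5

    def test_linear_and_cell_count_invariant(self):
        g1 = concentration_conversion(200.0, 100)
        assert g1 == pytest.approx(2 * concentration_conversion(100.0, 100))
        assert concentration_conversion(100.0, 25) == pytest.approx(
            concentration_conversion(100.0, 400))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            concentration_conversion(10.0, 0)
        with pytest.raises(ValueError):
            concentration_conversion(-1.0, 10)
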