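import numpy as np
import pandas as pd
import pytest
from scipy import stats
import statsmodels.api as sm

from iqtl.io_formats import load_bundle
from iqtl.synthetic_data import (
    SimulationConfig,
    phenotype_anchors,
    simulate_cell_proportions,
    simulate_dataset,
    simulate_genotypes,
    write_dataset,
)


class TestConfigValidation:
    def test_bad_scenario(self):
        with pytest.raises(ValueError):
            SimulationConfig(scenario="wat")

    def test_means_must_be_simplex(self):
        with pytest.raises(ValueError):
            SimulationConfig(cell_means=(0.5, 0.2, 0.2, 0.2))

    def test_bad_correlation(self):
        with pytest.raises(ValueError):
            SimulationConfig(age_cell_corr=1.0)


class TestGenotypes:
    def test_dosage_range_and_shape(self):
        config = SimulationConfig(n_samples=100, n_phenotypes=4, variants_per_phenotype=10, seed=1)
        gm = simulate_genotypes(config)
        assert gm.dosages.shape == (100, 40)
        assert set(np.unique(gm.dosages)) <= {0.0, 1.0, 2.0}

    def test_fixed_half_frequency(self):
        config = SimulationConfig(
            n_samples=2000, n_phenotypes=2, variants_per_phenotype=20, maf_range=(0.5, 0.5), seed=2
        )
        gm = simulate_genotypes(config)
        assert gm.variants["af"].mean() == pytest.approx(0.5, abs=0.02)

    def test_hardy_weinberg_heterozygosity(self):
        config = SimulationConfig(
            n_samples=4000, n_phenotypes=1, variants_per_phenotype=30,
            maf_range=(0.3, 0.3), ld_rho=0.0, seed=3,
        )
        gm = simulate_genotypes(config)
        het = (gm.dosages == 1.0).mean()
        assert het == pytest.approx(2 * 0.3 * 0.7, abs=0.02)

    @staticmethod
    def _adjacent_r2(gm):
        out = []
        G = gm.dosages
        for v in range(G.shape[1] - 1):
            if G[:, v].std() == 0 or G[:, v + 1].std() == 0:
                continue
            out.append(np.corrcoef(G[:, v], G[:, v + 1])[0, 1] ** 2)
        return np.asarray(out)

    def test_no_ld_when_rho_zero(self):
        config = SimulationConfig(
            n_samples=500, n_phenotypes=2, variants_per_phenotype=40, ld_rho=0.0, seed=4
        )
        r2 = self._adjacent_r2(simulate_genotypes(config))
        assert r2.mean() < 5.0 / 500  # O(1/n) scale for independent variants

    def test_strong_ld_when_rho_high(self):
        config = SimulationConfig(
            n_samples=500, n_phenotypes=2, variants_per_phenotype=40, ld_rho=0.99,
            maf_range=(0.2, 0.5), seed=5,
        )
        r2 = self._adjacent_r2(simulate_genotypes(config))
        assert r2.mean() > 0.8

    def test_variants_land_in_cis_windows(self):
        config = SimulationConfig(n_samples=20, n_phenotypes=5, variants_per_phenotype=8, seed=6)
        gm = simulate_genotypes(config)
        anchors = phenotype_anchors(config)
        pos = gm.variants["pos"].to_numpy().reshape(5, 8)
        for p in range(5):
            assert np.all(np.abs(pos[p] - anchors[p]) <= config.half_width_bp)


class TestCellProportions:
    def test_rows_on_simplex(self, rng):
        config = SimulationConfig()
        props = simulate_cell_proportions(config, rng.uniform(45, 84, 500), rng=rng)
        np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-12)
        assert (props.to_numpy() > 0).all()

    def test_zero_age_correlation(self, rng):
        config = SimulationConfig(age_cell_corr=0.0)
        age = rng.uniform(45, 84, 1000)
        props = simulate_cell_proportions(config, age, rng=rng)
        assert abs(np.corrcoef(age, props["neutrophil"])[0, 1]) < 0.07

    def test_target_age_correlation(self, rng):
        config = SimulationConfig(age_cell_corr=0.14)
        age = rng.uniform(45, 84, 1000)
        props = simulate_cell_proportions(config, age, rng=rng)
        assert 0.09 < np.corrcoef(age, props["neutrophil"])[0, 1] < 0.19

    def test_negative_latent_correlation_propagates(self, rng):
        corr = np.eye(4)
        corr[2, 3] = corr[3, 2] = -0.9
        config = SimulationConfig(cell_latent_corr=corr)
        props = simulate_cell_proportions(config, rng.uniform(45, 84, 1500), rng=rng)
        assert np.corrcoef(props["t_cell"], props["b_cell"])[0, 1] < -0.4

    def test_non_positive_definite_rejected(self, rng):
        corr = np.full((4, 4), 1.0)
        config = SimulationConfig(cell_latent_corr=corr)
        with pytest.raises(ValueError, match="positive definite"):
            simulate_cell_proportions(config, rng.uniform(45, 84, 100), rng=rng)


class TestPhenotypes:
    def test_truth_table_one_row_per_phenotype(self, small_dataset):
        config, bundle, truth = small_dataset
        assert len(truth) == config.n_phenotypes
        assert truth["phenotype_id"].is_unique

    def test_causal_variant_in_cis_window(self, small_dataset):
        config, bundle, truth = small_dataset
        vmeta = bundle.genotypes.variants.set_index("variant_id")
        anchors = bundle.phenotypes.phenotypes.set_index("phenotype_id")["anchor"]
        for row in truth.itertuples():
            assert abs(vmeta.loc[row.variant_id, "pos"] - anchors[row.phenotype_id]) <= config.half_width_bp

    def test_null_scenario_uniform_interaction_p(self):
        from iqtl.iqtl_scan import CisWindowSpec, scan

        config = SimulationConfig(
            n_samples=300, n_phenotypes=30, variants_per_phenotype=10,
            scenario="null", maf_range=(0.2, 0.5), seed=19,
        )
        bundle, _ = simulate_dataset(config)
        result = scan(bundle, "neutrophil", CisWindowSpec.for_kind("gene"))
        p = result.pairs.loc[result.pairs["ok"], "p_gxe"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_mediated_scenario_conditional_independence(self):
        # given g*m and main effects, y carries no g*age signal
        config = SimulationConfig(
            n_samples=4000, n_phenotypes=1, variants_per_phenotype=5,
            scenario="gxtrait_mediated", age_cell_corr=0.5, b_gxe=0.75,
            maf_range=(0.3, 0.5), seed=21,
        )
        bundle, truth = simulate_dataset(config)
        vpos = list(bundle.genotypes.variants["variant_id"]).index(truth.loc[0, "variant_id"])
        g = bundle.genotypes.dosages[:, vpos]
        m = bundle.interactions["neutrophil"]
        a = bundle.interactions["age"]
        y = bundle.phenotypes.values[:, 0]
        X = sm.add_constant(np.column_stack([g, m, a, g * m, g * a]))
        fit = sm.OLS(y, X).fit()
        assert abs(fit.params[-1]) < 0.05  # g*age coefficient near zero
        assert fit.pvalues[-1] > 0.01

    def test_binary_scenario_exposure_is_bernoulli(self):
        config = SimulationConfig(
            n_samples=400, n_phenotypes=4, variants_per_phenotype=5,
            scenario="binary_e", seed=22,
        )
        bundle, _ = simulate_dataset(config)
        smoking = bundle.interactions["smoking"]
        assert set(np.unique(smoking)) == {0.0, 1.0}
        assert 0.15 < smoking.mean() < 0.45

    def test_frac_null_mixes_scenarios(self):
        config = SimulationConfig(
            n_samples=100, n_phenotypes=40, variants_per_phenotype=4,
            scenario="gxcell", frac_null=0.5, seed=23,
        )
        _, truth = simulate_dataset(config)
        counts = truth["scenario"].value_counts()
        assert counts.get("null", 0) > 5
        assert counts.get("gxcell", 0) > 5
        assert (truth.loc[truth["scenario"] == "null", "b_gxe"] == 0).all()

    def test_two_exams_share_truth_not_noise(self):
        config = SimulationConfig(
            n_samples=120, n_phenotypes=5, variants_per_phenotype=6, seed=24
        )
        bundle1, truth1 = simulate_dataset(config, noise_seed=1)
        bundle2, truth2 = simulate_dataset(config, noise_seed=2)
        pd.testing.assert_frame_equal(truth1, truth2)
        np.testing.assert_allclose(bundle1.genotypes.dosages, bundle2.genotypes.dosages)
        assert not np.allclose(bundle1.phenotypes.values, bundle2.phenotypes.values)


class TestWriteDataset:
    def test_round_trip(self, tmp_path, small_dataset):
        _, bundle, truth = small_dataset
        paths = write_dataset(bundle, truth, tmp_path / "ds")
        back = load_bundle(
            paths["phenotypes"], paths["genotypes"], paths["covariates"], paths["interactions"]
        )
        assert back.sample_ids == bundle.sample_ids
        np.testing.assert_allclose(back.genotypes.dosages, bundle.genotypes.dosages)
        np.testing.assert_allclose(back.phenotypes.values, bundle.phenotypes.values, rtol=1e-12)
        for name, vec in bundle.interactions.items():
            np.testing.assert_allclose(back.interactions[name], vec, rtol=1e-12)

    def test_vcf_round_trip(self, tmp_path, small_dataset):
        _, bundle, truth = small_dataset
        paths = write_dataset(bundle, truth, tmp_path / "ds", genotype_format="vcf")
        back = load_bundle(
            paths["phenotypes"], paths["genotypes"], paths["covariates"], paths["interactions"],
            genotype_format="vcf",
        )
        np.testing.assert_allclose(back.genotypes.dosages, bundle.genotypes.dosages)

    def test_deterministic_bytes(self, tmp_path):
        config = SimulationConfig(n_samples=40, n_phenotypes=3, variants_per_phenotype=4, seed=9)
        for sub in ("a", "b"):
            bundle, truth = simulate_dataset(config)
            write_dataset(bundle, truth, tmp_path / sub)
        for name in ("phenotypes.bed", "genotypes.tsv", "covariates.tsv", "interactions.tsv", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_distinct_seeds_differ(self, tmp_path):
        b1, _ = simulate_dataset(SimulationConfig(n_samples=40, n_phenotypes=2, variants_per_phenotype=4, seed=1))
        b2, _ = simulate_dataset(SimulationConfig(n_samples=40, n_phenotypes=2, variants_per_phenotype=4, seed=2))
        assert not np.allclose(b1.phenotypes.values, b2.phenotypes.values)
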