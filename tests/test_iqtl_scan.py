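import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from iqtl.core import PhenotypeSet
from iqtl.iqtl_scan import (
    CisWindowSpec,
    ScanConfig,
    cis_pairs,
    fit_group_model,
    fit_interaction_model,
    scan,
)
from iqtl.synthetic_data import SimulationConfig, simulate_dataset


class TestCisWindowSpec:
    def test_named_kinds(self):
        assert CisWindowSpec.for_kind("gene").half_width_bp == 1_000_000
        assert CisWindowSpec.for_kind("cpg").half_width_bp == 500_000

    def test_custom_and_invalid(self):
        assert CisWindowSpec.for_kind(1234).half_width_bp == 1234
        with pytest.raises(ValueError):
            CisWindowSpec.for_kind("weird")
        with pytest.raises(ValueError):
            CisWindowSpec("gene", 0)


def _phenotypes_at(anchors, chrom="1"):
    meta = pd.DataFrame(
        {
            "phenotype_id": [f"p{i}" for i in range(len(anchors))],
            "chrom": chrom,
            "anchor": anchors,
            "kind": "gene",
        }
    )
    return PhenotypeSet(np.zeros((3, len(anchors))), meta, ["s1", "s2", "s3"])


def _variants_at(positions, chrom="1"):
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
            "ref": "A",
            "alt": "G",
            "af": 0.3,
        }
    )


class TestCisPairs:
    def test_boundary_inclusive(self):
        pairs = cis_pairs(
            _phenotypes_at([1_000_000]), _variants_at([2_000_000]), CisWindowSpec.for_kind("gene")
        )
        assert len(pairs) == 1

    def test_one_bp_outside_excluded(self):
        pairs = cis_pairs(
            _phenotypes_at([1_000_000]), _variants_at([2_000_001]), CisWindowSpec.for_kind("gene")
        )
        assert pairs.empty

    def test_other_chromosome_excluded(self):
        pairs = cis_pairs(
            _phenotypes_at([1_000_000]), _variants_at([1_000_000], chrom="2"), CisWindowSpec.for_kind("gene")
        )
        assert pairs.empty


class TestFitInteractionModel:
    def test_noiseless_exact_interpolation(self, rng):
        n = 8
        g = rng.binomial(2, 0.5, n).astype(float)
        e = rng.normal(size=n)
        e -= e.mean()
        y = 1.0 + 2.0 * g + 3.0 * e + 4.0 * g * e
        rec = fit_interaction_model(y, g, e)
        assert rec.ok
        assert rec.b_g == pytest.approx(2.0, abs=1e-9)
        assert rec.b_e == pytest.approx(3.0, abs=1e-9)
        assert rec.b_gxe == pytest.approx(4.0, abs=1e-9)
        assert rec.se_gxe == pytest.approx(0.0, abs=1e-7)

    def test_matches_textbook_ols(self, rng):
        n = 50
        g = rng.binomial(2, 0.3, n).astype(float)
        e = rng.normal(size=n)
        e -= e.mean()
        C = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        rec = fit_interaction_model(y, g, e, C)
        oracle = sm.OLS(y, sm.add_constant(np.column_stack([g, e, g * e, C]))).fit()
        np.testing.assert_allclose(
            [rec.b_g, rec.b_e, rec.b_gxe], oracle.params[1:4], rtol=1e-8
        )
        np.testing.assert_allclose([rec.se_g, rec.se_e, rec.se_gxe], oracle.bse[1:4], rtol=1e-8)
        np.testing.assert_allclose([rec.p_g, rec.p_e, rec.p_gxe], oracle.pvalues[1:4], rtol=1e-8)
        assert rec.df_resid == n - 6

    def test_constant_zero_e_flagged(self, rng):
        n = 20
        g = rng.binomial(2, 0.5, n).astype(float)
        rec = fit_interaction_model(rng.normal(size=n), g, np.zeros(n))
        assert not rec.ok and rec.note == "rank_deficient"
        assert np.isnan(rec.b_gxe)

    def test_invariants(self, rng):
        n = 60
        g = rng.binomial(2, 0.4, n).astype(float)
        e = rng.normal(size=n)
        e -= e.mean()
        rec = fit_interaction_model(rng.normal(size=n), g, e)
        for term in ("g", "e", "gxe"):
            p = getattr(rec, f"p_{term}")
            assert 0.0 <= p <= 1.0
            assert getattr(rec, f"se_{term}") > 0
            assert getattr(rec, f"t_{term}") == pytest.approx(
                getattr(rec, f"b_{term}") / getattr(rec, f"se_{term}")
            )


class TestFitGroupModel:
    def test_full_group_equals_simple_regression(self, rng):
        n = 40
        g = rng.binomial(2, 0.5, n).astype(float)
        y = rng.normal(size=n)
        fit = fit_group_model(y, g)
        slope = np.polyfit(g, y, 1)[0]
        assert fit.b_g == pytest.approx(slope, rel=1e-10)

    def test_noiseless_group(self, rng):
        n = 30
        g = rng.binomial(2, 0.5, n).astype(float)
        mask = np.zeros(n, dtype=bool)
        mask[:15] = True
        fit = fit_group_model(2.0 * g, g, group_mask=mask)
        assert fit.b_g == pytest.approx(2.0, abs=1e-10)
        assert fit.n == 15

    def test_matches_ols_oracle(self, rng):
        n = 50
        g = rng.binomial(2, 0.3, n).astype(float)
        C = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        mask = rng.random(n) < 0.6
        fit = fit_group_model(y, g, C, mask)
        oracle = sm.OLS(y[mask], sm.add_constant(np.column_stack([g, C])[mask])).fit()
        assert fit.b_g == pytest.approx(oracle.params[1], rel=1e-8)
        assert fit.se_g == pytest.approx(oracle.bse[1], rel=1e-8)
        assert fit.p_g == pytest.approx(oracle.pvalues[1], rel=1e-8)

    def test_degenerate_group_errors(self, rng):
        g = rng.binomial(2, 0.5, 10).astype(float)
        mask = np.zeros(10, dtype=bool)
        mask[:3] = True
        with pytest.raises(ValueError, match="degenerate"):
            fit_group_model(np.zeros(10), g, group_mask=mask)


class TestScan:
    def test_recovers_causal_variants(self):
        config = SimulationConfig(
            n_samples=500,
            n_phenotypes=10,
            variants_per_phenotype=20,
            scenario="gxcell",
            b_gxe=1.0,
            noise_sd=0.5,
            maf_range=(0.1, 0.5),
            seed=11,
        )
        bundle, truth = simulate_dataset(config)
        result = scan(bundle, "neutrophil", CisWindowSpec.for_kind("gene"))
        merged = result.top.merge(truth, on="phenotype_id", suffixes=("", "_true"))
        hits = (merged["variant_id"] == merged["variant_id_true"]).sum()
        assert hits >= 9

    def test_batched_equals_per_pair(self, small_dataset):
        _, bundle, _ = small_dataset
        from iqtl.preprocess import center

        result = scan(bundle, "neutrophil", CisWindowSpec.for_kind("gene"))
        e = center(bundle.interactions["neutrophil"])
        C = bundle.covariate_matrix
        vpos = {v: i for i, v in enumerate(bundle.genotypes.variants["variant_id"])}
        ppos = {p: i for i, p in enumerate(bundle.phenotypes.phenotypes["phenotype_id"])}
        sample = result.pairs.sample(n=30, random_state=0)
        for row in sample.itertuples():
            y = bundle.phenotypes.values[:, ppos[row.phenotype_id]]
            g = bundle.genotypes.dosages[:, vpos[row.variant_id]]
            rec = fit_interaction_model(y, g, e, C)
            for field in ("b_g", "se_g", "p_g", "b_e", "b_gxe", "se_gxe", "t_gxe", "p_gxe"):
                assert getattr(row, field) == pytest.approx(getattr(rec, field), rel=1e-9, abs=1e-300)

    def test_zero_e_flags_everything(self, small_dataset):
        _, bundle, _ = small_dataset
        bundle.interactions["flat"] = np.zeros(len(bundle.sample_ids))
        result = scan(bundle, "flat", CisWindowSpec.for_kind("gene"))
        assert not result.pairs["ok"].any()
        assert len(result.skipped) == bundle.phenotypes.n_phenotypes

    def test_permuting_e_destroys_signal(self, small_dataset):
        _, bundle, truth = small_dataset
        from iqtl.preprocess import center

        e = center(bundle.interactions["neutrophil"])
        rng = np.random.default_rng(5)
        perm = rng.permutation(e)
        ppos = {p: i for i, p in enumerate(bundle.phenotypes.phenotypes["phenotype_id"])}
        vpos = {v: i for i, v in enumerate(bundle.genotypes.variants["variant_id"])}
        p_orig, p_perm = [], []
        for row in truth.itertuples():
            y = bundle.phenotypes.values[:, ppos[row.phenotype_id]]
            g = bundle.genotypes.dosages[:, vpos[row.variant_id]]
            p_orig.append(fit_interaction_model(y, g, e, bundle.covariate_matrix).p_gxe)
            p_perm.append(fit_interaction_model(y, g, perm, bundle.covariate_matrix).p_gxe)
        assert np.median(p_orig) < 1e-6
        assert np.median(p_perm) > 0.05

    def test_top_is_smallest_interaction_p(self, small_dataset):
        _, bundle, _ = small_dataset
        result = scan(bundle, "neutrophil", CisWindowSpec.for_kind("gene"))
        for row in result.top.itertuples():
            sub = result.pairs[result.pairs["phenotype_id"] == row.phenotype_id]
            assert row.p_gxe == sub["p_gxe"].min()

    def test_maf_columns_reported(self, small_dataset):
        _, bundle, _ = small_dataset
        result = scan(
            bundle, "neutrophil", CisWindowSpec.for_kind("gene"), ScanConfig(0.01, 0.05)
        )
        assert (result.pairs["maf_lower_half"] > 0.05).all()
        assert (result.pairs["maf_upper_half"] > 0.05).all()
        assert (result.pairs["maf"] > 0.01).all()
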