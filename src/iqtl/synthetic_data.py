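"""Synthetic cohort generation.

Produces genotype, cell-proportion, trait, covariate and molecular
phenotype data with the statistical structure the scan assumes:
biallelic dosages in Hardy-Weinberg proportions with optional AR(1)
linkage between adjacent variants, simplex-valued cell proportions from
a latent-Gaussian softmax with a configurable age correlation, and
phenotypes generated from the linear interaction model under several
scenarios (including a mediated one where any apparent G-by-age signal
arises purely through the age / cell-proportion correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, PhenotypeSet, standardize
from .iqtl_scan import CPG_WINDOW_BP, GENE_WINDOW_BP

__all__ = [
    "SCENARIOS",
    "SimulationConfig",
    "phenotype_anchors",
    "simulate_genotypes",
    "simulate_cell_proportions",
    "simulate_phenotypes",
    "simulate_dataset",
    "write_dataset",
]

SCENARIOS = ("null", "gxcell", "gxtrait_direct", "gxtrait_mediated", "binary_e")

_CHROM = "1"
_CIS_SPREAD_BP = 50_000  # variants land within +/- this of their phenotype's anchor


@dataclass
class SimulationConfig:
    """Knobs of the generative model; one instance fully determines a dataset."""

    n_samples: int = 800
    n_phenotypes: int = 200
    variants_per_phenotype: int = 50
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.0
    phenotype_kind: str = "gene"
    cell_types: tuple = ("neutrophil", "monocyte", "t_cell", "b_cell")
    cell_means: tuple = (0.55, 0.10, 0.25, 0.10)
    cell_latent_corr: object = None  # K x K; identity when None
    cell_latent_sd: float = 0.3
    age_range: tuple = (45.0, 84.0)
    age_cell_corr: float = 0.14
    age_cell_type: str = "neutrophil"
    scenario: str = "gxcell"
    b_g: float = 0.5
    b_e: float = 0.3
    b_gxe: float = 0.5
    frac_null: float = 0.0
    noise_sd: float = 1.0
    n_covariates: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        means = np.asarray(self.cell_means, dtype=float)
        if len(means) != len(self.cell_types):
            raise ValueError("cell_means length does not match cell_types")
        if np.any(means <= 0) or not np.isclose(means.sum(), 1.0):
            raise ValueError("cell mean proportions must be positive and sum to 1")
        if not abs(self.age_cell_corr) < 1:
            raise ValueError("|age_cell_corr| must be < 1")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.age_cell_type not in self.cell_types:
            raise ValueError("age_cell_type must be one of cell_types")
        if not 0.0 <= self.frac_null <= 1.0:
            raise ValueError("frac_null must be in [0, 1]")

    @property
    def half_width_bp(self) -> int:
        return GENE_WINDOW_BP if self.phenotype_kind == "gene" else CPG_WINDOW_BP


def phenotype_anchors(config: SimulationConfig) -> np.ndarray:
    """1-based anchor positions, spaced so cis blocks never overlap."""
    spacing = 2 * config.half_width_bp + 100_000
    return (np.arange(config.n_phenotypes, dtype=np.int64) + 1) * spacing


def simulate_genotypes(config: SimulationConfig, rng=None) -> GenotypeMatrix:
    """Dosages as the sum of two latent-Gaussian-threshold haplotypes.

    Adjacent variants share an AR(1) latent correlation ``ld_rho``
    (applied along the variant order), giving tunable allelic linkage;
    per-variant allele frequencies are drawn uniformly from ``maf_range``.
    """
    rng = rng if rng is not None else np.random.default_rng((config.seed, 1))
    n = config.n_samples
    vpp = config.variants_per_phenotype
    anchors = phenotype_anchors(config)

    positions = np.empty(config.n_phenotypes * vpp, dtype=np.int64)
    for p, anchor in enumerate(anchors):
        offs = np.sort(rng.choice(2 * _CIS_SPREAD_BP + 1, size=vpp, replace=False))
        positions[p * vpp : (p + 1) * vpp] = anchor - _CIS_SPREAD_BP + offs

    V = positions.size
    # frequencies follow the same mixing rate as the latent haplotype chain:
    # under strong linkage adjacent variants share a frequency, otherwise the
    # phi correlation between their alleles (and hence dosage r^2) is capped
    # well below the latent correlation
    freqs = np.empty(V)
    fresh = rng.uniform(config.maf_range[0], config.maf_range[1], size=V)
    keep_prev = rng.random(V) < config.ld_rho
    freqs[0] = fresh[0]
    for v in range(1, V):
        freqs[v] = freqs[v - 1] if keep_prev[v] else fresh[v]
    from scipy.stats import norm

    thresholds = norm.ppf(freqs)
    rho = config.ld_rho
    innov_scale = np.sqrt(1.0 - rho**2)
    n_hap = 2 * n
    alleles = np.empty((n_hap, V), dtype=np.uint8)
    z = rng.standard_normal(n_hap)
    alleles[:, 0] = z < thresholds[0]
    for v in range(1, V):
        z = rho * z + innov_scale * rng.standard_normal(n_hap)
        alleles[:, v] = z < thresholds[v]
    dosages = (alleles[0::2] + alleles[1::2]).astype(float)

    af = dosages.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        {
            "variant_id": [f"var_{_CHROM}_{pos}" for pos in positions],
            "chrom": _CHROM,
            "pos": positions,
            "ref": "A",
            "alt": "G",
            "af": af,
        }
    )
    sample_ids = [f"s{i:04d}" for i in range(n)]
    return GenotypeMatrix(dosages, variants, sample_ids)


def simulate_cell_proportions(config: SimulationConfig, age, rng=None) -> pd.DataFrame:
    """Simplex-valued proportions from a latent-Gaussian softmax.

    Latent scores are correlated according to ``cell_latent_corr``; the
    chosen cell type's latent takes a linear age term calibrated so the
    realized age/proportion correlation lands near ``age_cell_corr``.
    """
    rng = rng if rng is not None else np.random.default_rng((config.seed, 2))
    age_z = standardize(age)
    n = age_z.size
    K = len(config.cell_types)
    corr = np.eye(K) if config.cell_latent_corr is None else np.asarray(config.cell_latent_corr, float)
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError("cell_latent_corr must be positive definite") from None
    u = rng.standard_normal((n, K)) @ L.T
    k = config.cell_types.index(config.age_cell_type)
    alpha = config.age_cell_corr
    u[:, k] = alpha * age_z + np.sqrt(1.0 - alpha**2) * u[:, k]
    latents = np.log(np.asarray(config.cell_means, float)) + config.cell_latent_sd * u
    expl = np.exp(latents - latents.max(axis=1, keepdims=True))
    props = expl / expl.sum(axis=1, keepdims=True)
    return pd.DataFrame(props, columns=list(config.cell_types))


def simulate_phenotypes(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    proportions: pd.DataFrame,
    age,
    sex,
    covariates,
    noise_seed: int = 0,
):
    """Phenotype values plus ground truth for the configured scenario.

    Returns ``(PhenotypeSet, truth, gen_vars)``. ``truth`` has one row
    per phenotype (causal variant, generative coefficients, scenario and
    the implied mediation effects); ``gen_vars`` maps the name of the
    generation-side interaction variable to its raw vector.

    Structural randomness (causal-variant choice, covariate effects, the
    binary exposure) is keyed only by ``config.seed``, so calling again
    with a different ``noise_seed`` re-draws the noise while keeping the
    truth fixed -- a second "exam" of the same cohort.
    """
    struct_rng = np.random.default_rng((config.seed, 11))
    noise_rng = np.random.default_rng((config.seed, 13, noise_seed))
    n = config.n_samples
    P = config.n_phenotypes
    vpp = config.variants_per_phenotype
    anchors = phenotype_anchors(config)
    covmat = np.asarray(covariates, dtype=float)
    m_std = standardize(proportions[config.age_cell_type].to_numpy())
    age_z = standardize(age)

    scenario = config.scenario
    gen_vars = {}
    if scenario in ("null", "gxcell", "gxtrait_mediated"):
        e_gen = m_std
    elif scenario == "gxtrait_direct":
        e_gen = age_z
    else:  # binary_e
        smoking = (struct_rng.random(n) < 0.3).astype(float)
        gen_vars["smoking"] = smoking
        e_gen = smoking - smoking.mean()

    a_true = float(np.corrcoef(age_z, m_std)[0, 1])
    values = np.empty((n, P))
    truth_rows = []
    dosages = genotypes.dosages
    vids = genotypes.variants["variant_id"].to_numpy()
    for p in range(P):
        offset = int(struct_rng.integers(vpp))
        is_null = scenario != "null" and struct_rng.random() < config.frac_null
        b_cov = struct_rng.normal(0.0, 0.3, covmat.shape[1]) if covmat.size else np.empty(0)
        ci = p * vpp + offset
        g = dosages[:, ci]
        if is_null:
            b_g = b_e = b_gxe = 0.0
            row_scenario = "null"
        else:
            b_g, b_e = config.b_g, config.b_e
            b_gxe = 0.0 if scenario == "null" else config.b_gxe
            row_scenario = scenario
        y = b_g * g + b_e * e_gen + b_gxe * g * e_gen
        if covmat.size:
            y = y + covmat @ b_cov
        y = y + noise_rng.normal(0.0, config.noise_sd, n)
        values[:, p] = y
        if row_scenario == "gxtrait_mediated":
            true_acme, true_ade = a_true * b_gxe, 0.0
        elif row_scenario == "gxtrait_direct":
            true_acme, true_ade = 0.0, b_gxe
        else:
            true_acme, true_ade = np.nan, np.nan
        truth_rows.append(
            {
                "phenotype_id": f"phen_{p:04d}",
                "variant_id": vids[ci],
                "b_g": b_g,
                "b_e": b_e,
                "b_gxe": b_gxe,
                "scenario": row_scenario,
                "true_acme": true_acme,
                "true_ade": true_ade,
            }
        )

    phen_meta = pd.DataFrame(
        {
            "phenotype_id": [f"phen_{p:04d}" for p in range(P)],
            "chrom": _CHROM,
            "anchor": anchors,
            "kind": config.phenotype_kind,
        }
    )
    ps = PhenotypeSet(values, phen_meta, list(genotypes.sample_ids))
    return ps, pd.DataFrame(truth_rows), gen_vars


def simulate_dataset(config: SimulationConfig, noise_seed: int = 0):
    """Full cohort: genotypes, traits, proportions, phenotypes, truth.

    Returns ``(DatasetBundle, truth)``. The bundle's ``interactions``
    hold standardized cell-proportion variables (one per cell type, in
    per-SD units so generative interaction coefficients are directly
    comparable to scan estimates), standardized ``age``, raw 0/1 ``sex``
    and, for the binary scenario, the 0/1 ``smoking`` exposure.
    """
    from .io_formats import DatasetBundle

    geno = simulate_genotypes(config)
    rng_traits = np.random.default_rng((config.seed, 2))
    age = rng_traits.uniform(config.age_range[0], config.age_range[1], config.n_samples)
    sex = (rng_traits.random(config.n_samples) < 0.5).astype(float)
    props = simulate_cell_proportions(config, age, rng=rng_traits)
    rng_cov = np.random.default_rng((config.seed, 3))
    covariates = pd.DataFrame(
        rng_cov.standard_normal((config.n_samples, config.n_covariates)),
        columns=[f"cov{i + 1}" for i in range(config.n_covariates)],
        index=geno.sample_ids,
    )
    ps, truth, gen_vars = simulate_phenotypes(
        config, geno, props, age, sex, covariates.to_numpy(), noise_seed=noise_seed
    )
    interactions = {name: standardize(props[name].to_numpy()) for name in config.cell_types}
    interactions["age"] = standardize(age)
    interactions["sex"] = sex
    interactions.update(gen_vars)
    bundle = DatasetBundle(
        genotypes=geno,
        phenotypes=ps,
        interactions=interactions,
        covariates=covariates,
        sample_ids=list(geno.sample_ids),
    )
    return bundle, truth


def write_dataset(bundle, truth: pd.DataFrame, out_dir, genotype_format: str = "dosage_tsv") -> dict:
    """Write the bundle as plain-text files; returns the path map.

    Re-reading with :func:`iqtl.io_formats.load_bundle` reproduces the
    bundle (to serialized precision). Output is byte-deterministic for a
    fixed config seed.
    """
    from pathlib import Path

    from . import io_formats

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": out / "phenotypes.bed",
        "genotypes": out / ("genotypes.vcf" if genotype_format == "vcf" else "genotypes.tsv"),
        "covariates": out / "covariates.tsv",
        "interactions": out / "interactions.tsv",
        "truth": out / "truth.tsv",
    }
    io_formats.write_phenotype_bed(bundle.phenotypes, paths["phenotypes"])
    if genotype_format == "vcf":
        io_formats.write_vcf(bundle.genotypes, paths["genotypes"])
    elif genotype_format == "dosage_tsv":
        io_formats.write_dosage_tsv(bundle.genotypes, paths["genotypes"])
    else:
        raise ValueError(f"unknown genotype format {genotype_format!r}")
    bundle.covariates.to_csv(paths["covariates"], sep="\t", index_label="sample_id", float_format="%.17g")
    inter = pd.DataFrame(bundle.interactions, index=bundle.sample_ids)
    inter.to_csv(paths["interactions"], sep="\t", index_label="sample_id", float_format="%.17g")
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.17g")
    return {k: str(v) for k, v in paths.items()}
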