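"""Readers and writers for the text formats the pipeline touches.

Phenotypes follow the tensorQTL-style BED convention (``chrom, start,
end, phenotype_id`` then one column per sample; the ``end`` column is
the 1-based anchor and ``start = end - 1``). Genotypes come from a
biallelic VCF (GT or DS) or a plain variant-by-sample dosage TSV.
Covariates and interaction variables are sample-by-variable TSVs keyed
by sample id. All reader/writer pairs round-trip losslessly at the
serialized precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, PhenotypeSet

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "DatasetBundle",
    "RESULT_COLUMNS",
    "read_phenotype_bed",
    "write_phenotype_bed",
    "read_genotypes",
    "write_dosage_tsv",
    "write_vcf",
    "read_covariates",
    "write_results",
    "read_results",
    "read_config",
    "load_bundle",
]

#: stable leading column order of results TSVs
RESULT_COLUMNS = [
    "phenotype_id",
    "variant_id",
    "chrom",
    "pos",
    "maf",
    "maf_lower_half",
    "maf_upper_half",
    "b_g",
    "se_g",
    "p_g",
    "b_gxe",
    "se_gxe",
    "p_gxe",
    "p_eigenmt",
    "q_bh",
    "direction",
]

_FLOAT_FMT = "%.12g"  # >= 10 significant digits


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class DatasetBundle:
    """Aligned genotypes, phenotypes, interaction variables and covariates.

    All components share ``sample_ids`` in identical order; downstream
    modules may assume positional alignment.
    """

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeSet
    interactions: dict
    covariates: pd.DataFrame
    sample_ids: list

    def __post_init__(self):
        self.sample_ids = list(self.sample_ids)
        for name, ids in (
            ("genotypes", self.genotypes.sample_ids),
            ("phenotypes", self.phenotypes.sample_ids),
            ("covariates", list(self.covariates.index)),
        ):
            if list(ids) != self.sample_ids:
                raise ValueError(f"{name} sample ids are not aligned with the bundle")
        for name, vec in self.interactions.items():
            if np.asarray(vec).shape != (len(self.sample_ids),):
                raise ValueError(f"interaction {name!r} is not one value per sample")

    @property
    def covariate_matrix(self) -> np.ndarray:
        return self.covariates.to_numpy(dtype=float)


def read_phenotype_bed(path, kind: str = "gene") -> PhenotypeSet:
    """Read a tensorQTL-convention phenotype BED.

    The ``end`` column is interpreted as the 1-based anchor (TSS or CpG
    position). Non-numeric values and duplicated phenotype ids raise
    :class:`FormatError` naming the offending line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 5:
        raise FormatError(f"{path}: need chrom/start/end/phenotype_id plus sample columns")
    df.columns = [df.columns[0].lstrip("#")] + list(df.columns[1:])
    chrom = df.iloc[:, 0].astype(str)
    try:
        start = df.iloc[:, 1].astype(np.int64)
        end = df.iloc[:, 2].astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer coordinate ({exc})") from None
    pid = df.iloc[:, 3]
    dup = pid[pid.duplicated()]
    if not dup.empty:
        line = dup.index[0] + 2  # 1-based, counting the header
        raise FormatError(f"{path}: duplicated phenotype_id {dup.iloc[0]!r} at line {line}")
    sample_cols = list(df.columns[4:])
    try:
        values = df[sample_cols].astype(float).to_numpy()
    except ValueError:
        for i, row in df[sample_cols].iterrows():
            if pd.to_numeric(row, errors="coerce").isna().to_numpy().any() != row.isna().to_numpy().any():
                raise FormatError(f"{path}: non-numeric value at line {i + 2}") from None
        raise
    if (start != end - 1).any():
        log.warning("%s: start != end - 1 on some rows; using end as the anchor", path)
    meta = pd.DataFrame(
        {"phenotype_id": pid.to_numpy(), "chrom": chrom.to_numpy(), "anchor": end.to_numpy(), "kind": kind}
    )
    return PhenotypeSet(values.T, meta, sample_cols)


def write_phenotype_bed(phenotypes: PhenotypeSet, path) -> None:
    """Write the BED counterpart of :func:`read_phenotype_bed` (0-based start)."""
    meta = phenotypes.phenotypes
    out = pd.DataFrame(
        {
            "#chr": meta["chrom"],
            "start": meta["anchor"].astype(np.int64) - 1,
            "end": meta["anchor"].astype(np.int64),
            "phenotype_id": meta["phenotype_id"],
        }
    )
    vals = pd.DataFrame(phenotypes.values.T, columns=phenotypes.sample_ids)
    pd.concat([out, vals], axis=1).to_csv(path, sep="\t", index=False, float_format="%.17g")


def _dosage_from_gt(genotypes) -> np.ndarray:
    out = np.empty(len(genotypes))
    for i, gt in enumerate(genotypes):
        alleles = gt[:-1]  # last entry is the phased flag
        out[i] = np.nan if any(a < 0 for a in alleles) else float(sum(alleles))
    return out


def read_genotypes(path, format: str = "dosage_tsv", impute_missing: bool = True) -> GenotypeMatrix:
    """Load dosages from a VCF (GT or DS) or a dosage TSV.

    VCF: dosage is the alternate-allele count from GT (or the DS value
    when present); multi-allelic records are skipped with a warning;
    missing genotypes become missing entries and the allele frequency is
    computed from the remaining samples. Missing dosages are mean-imputed
    per variant unless ``impute_missing=False``.
    """
    if format == "vcf":
        gm = _read_vcf(path)
    elif format == "dosage_tsv":
        gm = _read_dosage_tsv(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return gm.mean_impute() if impute_missing else gm


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, meta = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            log.warning("skipping multi-allelic record %s:%d", v.CHROM, v.POS)
            continue
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
            dose = np.where((dose < 0) | (dose > 2), np.nan, dose)
        else:
            dose = _dosage_from_gt(v.genotypes)
        cols.append(dose)
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        meta.append((vid, str(v.CHROM), int(v.POS), v.REF, v.ALT[0]))
    if not cols:
        raise FormatError(f"{path}: no usable biallelic records")
    dosages = np.column_stack(cols)
    with np.errstate(invalid="ignore"):
        af = np.nanmean(dosages, axis=0) / 2.0
    variants = pd.DataFrame(meta, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    variants["af"] = af
    return GenotypeMatrix(dosages, variants, samples)


def _read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = ["variant_id", "chrom", "pos", "ref", "alt"]
    if list(df.columns[:5]) != needed:
        raise FormatError(f"{path}: leading columns must be {needed}")
    sample_cols = list(df.columns[5:])
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns")
    try:
        dosages = df[sample_cols].astype(float).to_numpy().T
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric dosage ({exc})") from None
    with np.errstate(invalid="ignore"):
        af = np.nanmean(dosages, axis=0) / 2.0
    variants = df[needed].copy()
    variants["af"] = af
    return GenotypeMatrix(dosages, variants, sample_cols)


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    meta = genotypes.variants[["variant_id", "chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    vals = pd.DataFrame(genotypes.dosages.T, columns=genotypes.sample_ids)
    pd.concat([meta, vals], axis=1).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write a minimal VCFv4.2 with GT (integral dosages) or DS otherwise."""
    gm = genotypes
    integral = bool(np.all(np.isnan(gm.dosages) | (gm.dosages == np.round(gm.dosages))))
    fmt = "GT" if integral else "DS"
    contigs = list(dict.fromkeys(gm.variants["chrom"].astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        if fmt == "GT":
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        else:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(map(str, gm.sample_ids)) + "\n")
        order = np.lexsort((gm.variants["pos"].to_numpy(), gm.variants["chrom"].astype(str).to_numpy()))
        for j in order:
            row = gm.variants.iloc[j]
            if fmt == "GT":
                _gt = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
                calls = ["./." if np.isnan(d) else _gt[float(d)] for d in gm.dosages[:, j]]
            else:
                calls = ["." if np.isnan(d) else ("%.6g" % d) for d in gm.dosages[:, j]]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['variant_id']}\t{row['ref']}\t{row['alt']}"
                f"\t.\t.\t.\t{fmt}\t" + "\t".join(calls) + "\n"
            )


def read_covariates(path, sample_ids=None) -> pd.DataFrame:
    """Numeric sample-by-variable TSV keyed by a leading sample-id column.

    When ``sample_ids`` is given, rows are reordered to match and any
    missing sample raises an error listing the ids.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric covariate value ({exc})") from None
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise ValueError(f"{path}: samples missing from file: {missing}")
        df = df.loc[list(sample_ids)]
    return df


def write_results(records, path) -> None:
    """Write iQTL records as a TSV with the stable leading column order."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        from dataclasses import asdict

        df = pd.DataFrame([asdict(r) for r in records])
    if df.empty and not len(df.columns):
        df = pd.DataFrame(columns=RESULT_COLUMNS)
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col == "direction" else np.nan
    extras = [c for c in df.columns if c not in RESULT_COLUMNS]
    df[RESULT_COLUMNS + extras].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "direction": str})


def read_config(path) -> dict:
    """Parse a ``key=value`` config file; values cast to int/float if possible."""
    out = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}: expected key=value, got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        for cast in (int, float):
            try:
                value = cast(value)
                break
            except ValueError:
                continue
        out[key] = value
    return out


def load_bundle(
    bed_path,
    genotype_path,
    covariates_path,
    interactions_path,
    genotype_format: str = "dosage_tsv",
    kind: str = "gene",
) -> DatasetBundle:
    """Read all components and align them (once) to the BED sample order."""
    phenotypes = read_phenotype_bed(bed_path, kind=kind)
    sample_ids = list(phenotypes.sample_ids)
    genotypes = read_genotypes(genotype_path, format=genotype_format).subset_samples(sample_ids)
    covariates = read_covariates(covariates_path, sample_ids=sample_ids)
    inter_df = read_covariates(interactions_path, sample_ids=sample_ids)
    interactions = {c: inter_df[c].to_numpy() for c in inter_df.columns}
    return DatasetBundle(
        genotypes=genotypes,
        phenotypes=phenotypes,
        interactions=interactions,
        covariates=covariates,
        sample_ids=sample_ids,
    )
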