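"""Shared data containers for the interaction-QTL pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "PhenotypeSet", "standardize"]


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicated {what}: {dups[:5]}")


def standardize(x) -> np.ndarray:
    """Center and scale to unit (population) variance."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


@dataclass
class GenotypeMatrix:
    """Sample-by-variant dosage matrix with per-variant metadata.

    Attributes
    ----------
    dosages
        ``(n_samples, n_variants)`` array of alternate-allele dosages in
        ``[0, 2]``; ``nan`` marks missing calls.
    variants
        Frame with columns ``variant_id, chrom, pos, ref, alt, af``.
        ``pos`` is 1-based; ``af`` is the alternate-allele frequency over
        non-missing calls.
    sample_ids
        Ordered sample identifiers, one per dosage row.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: list

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = list(self.sample_ids)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("dosage rows do not match number of samples")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage columns do not match number of variants")
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.variants["variant_id"], "variant ids")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency per variant, derived from ``af``."""
        af = self.variants["af"].to_numpy(dtype=float)
        return np.minimum(af, 1.0 - af)

    def mean_impute(self) -> "GenotypeMatrix":
        """Return a copy with missing dosages replaced by the variant mean.

        No-op (returns ``self``) when the matrix is already complete.
        """
        if not np.isnan(self.dosages).any():
            return self
        filled = self.dosages.copy()
        col_mean = np.nanmean(filled, axis=0)
        rows, cols = np.where(np.isnan(filled))
        filled[rows, cols] = col_mean[cols]
        return GenotypeMatrix(filled, self.variants.copy(), list(self.sample_ids))

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        """Reorder/subset rows to the given sample identifiers."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValueError(f"samples missing from genotypes: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return GenotypeMatrix(self.dosages[idx], self.variants.copy(), list(sample_ids))


@dataclass
class PhenotypeSet:
    """Sample-by-phenotype molecular values plus per-phenotype anchors.

    ``phenotypes`` has columns ``phenotype_id, chrom, anchor, kind`` where
    ``anchor`` is the 1-based TSS or CpG position and ``kind`` is
    ``"gene"`` or ``"cpg"``.
    """

    values: np.ndarray
    phenotypes: pd.DataFrame
    sample_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x phenotypes)")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("value rows do not match number of samples")
        if self.values.shape[1] != len(self.phenotypes):
            raise ValueError("value columns do not match number of phenotypes")
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.phenotypes["phenotype_id"], "phenotype ids")
        self.phenotypes = self.phenotypes.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotypes)

    def subset_samples(self, sample_ids) -> "PhenotypeSet":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValueError(f"samples missing from phenotypes: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return PhenotypeSet(self.values[idx], self.phenotypes.copy(), list(sample_ids))
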