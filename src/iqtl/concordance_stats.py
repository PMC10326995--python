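"""Reproducibility, sharing, replication and inflation statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GenotypeMatrix

__all__ = [
    "Pi1Result",
    "ORResult",
    "OverlapResult",
    "storey_pi0",
    "pi1_reproducibility",
    "nominal_replication_rate",
    "inflation_lambda",
    "ld_r2",
    "normalized_overlap",
    "haldane_anscombe_or",
    "allelic_concordance",
    "median_abs_effect",
]


@dataclass
class Pi1Result:
    pi1: float
    pi0: float
    lambda_used: float
    n_pairs: int
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.reason is None


@dataclass
class ORResult:
    odds_ratio: float
    p_value: float
    table: tuple
    corrected: bool


@dataclass
class OverlapResult:
    normalized_overlap: float
    n_matched: int
    n_query: int
    n_validation: int


def storey_pi0(p, lam: float) -> float:
    """Fixed-lambda point estimate of the null proportion.

    ``pi0 = #{p_i > lambda} / (n * (1 - lambda))``, clamped to [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must be in (0, 1)")
    pi0 = np.mean(p > lam) / (1.0 - lam)
    return float(np.clip(pi0, 0.0, 1.0))


def pi1_reproducibility(validation_p) -> Pi1Result:
    """pi1 with the sample-size-dependent lambda rule.

    Undefined for 20 or fewer pairs; lambda 0.5 for 21..100 pairs;
    lambda 0.85 above 100 pairs.
    """
    p = np.asarray(validation_p, dtype=float)
    n = p.size
    if n <= 20:
        return Pi1Result(np.nan, np.nan, np.nan, n, reason="20 or fewer validation pairs")
    lam = 0.5 if n <= 100 else 0.85
    pi0 = storey_pi0(p, lam)
    return Pi1Result(1.0 - pi0, pi0, lam, n)


def nominal_replication_rate(validation_p, alpha: float = 0.05) -> float:
    p = np.asarray(validation_p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    return float(np.mean(p < alpha))


def inflation_lambda(p) -> float:
    """Median observed chi-square (1 df) over the null median.

    p-values are mapped to chi-square statistics through the upper-tail
    quantile function; exactly 1.0 when the median p is 0.5.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.isf(0.5, df=1))


def ld_r2(dosages, pairs) -> np.ndarray:
    """Squared Pearson correlation of dosage vectors for index pairs.

    Constant variants yield ``nan`` for their pairs.
    """
    G = np.asarray(dosages, dtype=float)
    out = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        gi, gj = G[:, i], G[:, j]
        if gi.std() == 0 or gj.std() == 0:
            out[k] = np.nan
            continue
        r = np.corrcoef(gi, gj)[0, 1]
        out[k] = r * r
    return out


def normalized_overlap(
    query,
    validation,
    genotypes: GenotypeMatrix,
    r2_min: float = 0.5,
    window_bp: int = 1_000_000,
) -> OverlapResult:
    """Fraction of query variants tagged by the validation set.

    A query variant is tagged if it matches a validation variant by id
    or is within ``window_bp`` with dosage ``r^2 >= r2_min``. The value
    is the tagged count divided by ``min(|query|, |validation|)``, capped
    at 1.
    """
    query = list(dict.fromkeys(query))
    validation = list(dict.fromkeys(validation))
    if not query or not validation:
        raise ValueError("query and validation sets must be non-empty")
    meta = genotypes.variants.set_index("variant_id")
    for v in query + validation:
        if v not in meta.index:
            raise KeyError(f"unknown variant id {v!r}")
    vset = set(validation)
    vmeta = meta.loc[validation]
    idx_of = {v: i for i, v in enumerate(genotypes.variants["variant_id"])}
    G = genotypes.dosages
    n_matched = 0
    for qv in query:
        if qv in vset:
            n_matched += 1
            continue
        q_chrom, q_pos = meta.loc[qv, "chrom"], meta.loc[qv, "pos"]
        near = vmeta[(vmeta["chrom"] == q_chrom) & (np.abs(vmeta["pos"] - q_pos) <= window_bp)]
        gq = G[:, idx_of[qv]]
        if gq.std() == 0:
            continue
        for vv in near.index:
            gv = G[:, idx_of[vv]]
            if gv.std() == 0:
                continue
            r = np.corrcoef(gq, gv)[0, 1]
            if r * r >= r2_min:
                n_matched += 1
                break
    value = min(1.0, n_matched / min(len(query), len(validation)))
    return OverlapResult(value, n_matched, len(query), len(validation))


def haldane_anscombe_or(table) -> ORResult:
    """Odds ratio of a 2x2 table with zero-cell correction.

    If any cell is zero, 0.5 is added to ALL cells before forming
    ``(a*d)/(b*c)``. The two-sided significance comes from an exact
    conditional test on the original, uncorrected counts.
    """
    t = np.asarray(table, dtype=float).reshape(2, 2)
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must contain non-negative integer counts")
    corrected = bool(np.any(t == 0))
    tc = t + 0.5 if corrected else t
    odds = (tc[0, 0] * tc[1, 1]) / (tc[0, 1] * tc[1, 0])
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return ORResult(float(odds), float(p), tuple(map(tuple, t.astype(int))), corrected)


def allelic_concordance(query_b, validation_b) -> float:
    """Fraction of pairs with the same effect-size sign (zeros excluded)."""
    qb = np.asarray(query_b, dtype=float)
    vb = np.asarray(validation_b, dtype=float)
    if qb.size == 0 or qb.shape != vb.shape:
        raise ValueError("effect vectors must be non-empty and aligned")
    nz = (qb != 0) & (vb != 0)
    if not nz.any():
        raise ValueError("no pairs with non-zero effects in both sets")
    return float(np.mean(np.sign(qb[nz]) == np.sign(vb[nz])))


def median_abs_effect(validation_b) -> float:
    """Absolute value of the median effect size."""
    b = np.asarray(validation_b, dtype=float)
    if b.size == 0:
        raise ValueError("empty effect vector")
    return float(abs(np.median(b)))
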