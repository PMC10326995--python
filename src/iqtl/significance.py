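"""Hierarchical multiple-testing correction and cross-exam combination.

Per phenotype, the top nominal interaction p-value is corrected by the
effective number of independent variants in its cis window (eigenvalue
decomposition of the local genotype correlation matrix), then a
Benjamini-Hochberg step-up is applied across phenotypes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import GenotypeMatrix

__all__ = [
    "EIGENMT_WINDOW",
    "EIGENMT_VAR_THRESHOLD",
    "eigenmt_meff",
    "bh_adjust",
    "significance_calls",
    "combine_exams",
]

EIGENMT_WINDOW = 200
EIGENMT_VAR_THRESHOLD = 0.99


def eigenmt_meff(genotype_block, window_size: int = EIGENMT_WINDOW,
                 var_threshold: float = EIGENMT_VAR_THRESHOLD) -> int:
    """Effective number of independent tests in a genotype block.

    Variants are partitioned into consecutive windows of at most
    ``window_size``; within each window the variant-variant Pearson
    correlation matrix is eigendecomposed and the window contributes the
    smallest ``k`` such that the top-k eigenvalues sum to at least
    ``var_threshold`` times the trace. The total is capped at the number
    of variants.
    """
    G = np.asarray(genotype_block, dtype=float)
    if G.ndim != 2 or G.shape[1] < 1:
        raise ValueError("need a 2-D block with at least one variant")
    if np.any(G.std(axis=0) == 0):
        raise ValueError("zero-variance variant in block; filter upstream")
    V = G.shape[1]
    total = 0
    for start in range(0, V, window_size):
        sub = G[:, start : start + window_size]
        m = sub.shape[1]
        if m == 1:
            total += 1
            continue
        corr = np.corrcoef(sub, rowvar=False)
        ev = np.linalg.eigvalsh(corr)[::-1]
        ev = np.clip(ev, 0.0, None)
        cs = np.cumsum(ev)
        k = int(np.searchsorted(cs, var_threshold * m - 1e-10)) + 1
        total += min(k, m)
    return min(total, V)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significance_calls(
    top: pd.DataFrame,
    pairs: pd.DataFrame,
    genotypes: GenotypeMatrix,
    fdr: float = 0.05,
    window_size: int = EIGENMT_WINDOW,
    var_threshold: float = EIGENMT_VAR_THRESHOLD,
) -> pd.DataFrame:
    """Phenotype-level corrected calls from a scan's top/pairs tables.

    ``m_eff`` is computed on the variants actually tested for each
    phenotype (rows of ``pairs``); ``p_eigenmt = min(1, p_top * m_eff)``;
    ``q_bh`` is BH-adjusted across phenotypes; ``significant`` flags
    ``q_bh < fdr``.
    """
    vpos = {v: i for i, v in enumerate(genotypes.variants["variant_id"])}
    tested = pairs.groupby("phenotype_id")["variant_id"].apply(list)
    rows = []
    for row in top.itertuples():
        vids = tested.get(row.phenotype_id, [])
        idx = [vpos[v] for v in vids]
        m_eff = eigenmt_meff(genotypes.dosages[:, idx], window_size, var_threshold)
        rows.append(
            {
                "phenotype_id": row.phenotype_id,
                "variant_id": row.variant_id,
                "p_top": row.p_gxe,
                "n_tested": len(idx),
                "m_eff": m_eff,
                "p_eigenmt": min(1.0, row.p_gxe * m_eff),
            }
        )
    calls = pd.DataFrame(rows)
    if calls.empty:
        return calls.assign(q_bh=[], significant=[])
    calls["q_bh"] = bh_adjust(calls["p_eigenmt"].to_numpy())
    calls["significant"] = calls["q_bh"] < fdr
    return calls


def combine_exams(calls_exam1: pd.DataFrame, calls_exam2: pd.DataFrame,
                  labels=("exam1", "exam2"), p_col: str = "p_gxe") -> pd.DataFrame:
    """Union significant phenotypes across two exams.

    For phenotypes significant in both, the exam with the smaller
    interaction p-value wins; equal p-values keep the earlier exam.
    An ``exam`` provenance column is added.
    """
    parts = []
    for rank, (calls, label) in enumerate(zip((calls_exam1, calls_exam2), labels)):
        sub = calls[calls["significant"]].copy()
        sub["exam"] = label
        sub["_rank"] = rank
        parts.append(sub)
    merged = pd.concat(parts, ignore_index=True)
    merged = merged.sort_values(["phenotype_id", p_col, "_rank"], kind="mergesort")
    merged = merged.drop_duplicates("phenotype_id", keep="first")
    return merged.drop(columns="_rank").reset_index(drop=True)
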