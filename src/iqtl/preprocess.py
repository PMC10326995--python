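"""Transformations and filters applied before and after the cis scan.

Covers the rank-based inverse normal transform with tie-breaking noise,
SD-based outlier exclusion, mean-centering of interaction variables, the
two-half interaction-aware MAF filter, and greedy sentinel collapsing of
CpG records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TransformSpec",
    "inverse_normal_transform",
    "exclude_outliers",
    "center",
    "half_split",
    "interaction_maf_filter",
    "collapse_sentinels",
]


@dataclass(frozen=True)
class TransformSpec:
    """Parameters of the inverse normal transform and outlier rule.

    ``tie_noise_scale`` is the SD of the noise added before ranking
    (variance 1e-16 by default, i.e. SD 1e-8), ``outlier_k`` the SD
    multiple for exclusion, and ``rank_offset`` the offset ``c`` in the
    rank-to-quantile map ``(rank - c) / (n - 2c + 1)``.
    """

    tie_noise_scale: float = 1e-8
    outlier_k: float = 3.0
    rank_offset: float = 0.5

    def __post_init__(self):
        if self.tie_noise_scale < 0:
            raise ValueError("tie_noise_scale must be >= 0")
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be > 0")
        if not 0.0 <= self.rank_offset <= 0.5:
            raise ValueError("rank_offset must be in [0, 0.5]")


def inverse_normal_transform(values, spec: TransformSpec | None = None, seed=None) -> np.ndarray:
    """Map values to standard-normal quantiles of their (perturbed) ranks.

    A small amount of Gaussian noise (``spec.tie_noise_scale``) is added
    before ranking to break ties; output quantiles are evaluated at
    ``(rank - c) / (n - 2c + 1)`` with ``c = spec.rank_offset``. Missing
    values stay missing.
    """
    spec = spec or TransformSpec()
    x = np.asarray(values, dtype=float)
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    v = x[mask]
    if spec.tie_noise_scale > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, spec.tie_noise_scale, size=n)
    elif np.all(v == v[0]):
        raise ValueError("all values identical and tie_noise_scale = 0: ranks undefined")
    ranks = stats.rankdata(v, method="average")
    c = spec.rank_offset
    q = (ranks - c) / (n - 2.0 * c + 1.0)
    out = np.full(x.shape, np.nan)
    out[mask] = stats.norm.ppf(q)
    return out


def exclude_outliers(values, k: float = 3.0) -> np.ndarray:
    """Inclusion mask: False where ``|value - mean| > k * SD``.

    Mean and SD (population) are computed on non-missing values; missing
    values are marked included (they carry no information to exclude on).
    """
    x = np.asarray(values, dtype=float)
    mask = np.isfinite(x)
    if mask.sum() < 2:
        raise ValueError("need at least 2 non-missing values")
    mu = x[mask].mean()
    sd = x[mask].std()
    keep = np.ones(x.shape, dtype=bool)
    if np.isfinite(k) and sd > 0:
        keep[mask] = np.abs(x[mask] - mu) <= k * sd
    return keep


def center(values) -> np.ndarray:
    """Subtract the mean of the non-missing values; missing preserved."""
    x = np.asarray(values, dtype=float)
    mask = np.isfinite(x)
    if mask.sum() < 1:
        raise ValueError("need at least 1 non-missing value")
    out = x.copy()
    out[mask] = x[mask] - x[mask].mean()
    return out


def half_split(e) -> tuple[np.ndarray, np.ndarray]:
    """Split sample indices into lower/upper halves by rank of ``e``.

    With odd ``n`` the median sample goes to the lower half; ties at the
    boundary are resolved by stable sort on sample order.
    """
    e = np.asarray(e, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("interaction variable has missing values")
    n = e.size
    order = np.argsort(e, kind="stable")
    n_lower = (n + 1) // 2
    return order[:n_lower], order[n_lower:]


def interaction_maf_filter(dosages, e, threshold: float) -> np.ndarray:
    """Keep variants with MAF above ``threshold`` in BOTH halves of ``e``.

    Samples are split into lower/upper halves by rank of the interaction
    variable; per half, ``MAF = min(f, 1 - f)`` with ``f`` the mean dosage
    divided by 2. Returns a boolean variant mask.
    """
    G = np.asarray(dosages, dtype=float)
    lower, upper = half_split(e)
    if min(lower.size, upper.size) < 2:
        raise ValueError("need at least 2 samples per half")
    masks = []
    for idx in (lower, upper):
        f = G[idx].mean(axis=0) / 2.0
        maf = np.minimum(f, 1.0 - f)
        masks.append(maf > threshold)
    return masks[0] & masks[1]


def collapse_sentinels(
    records: pd.DataFrame,
    window_bp: int = 1000,
    chrom_col: str = "chrom",
    pos_col: str = "anchor",
    p_col: str = "p_gxe",
    id_col: str = "variant_id",
) -> pd.DataFrame:
    """Greedy sentinel selection of CpG-variant records.

    Repeatedly takes the remaining record with smallest ``p_col``
    (ties broken by smaller ``pos_col`` then lexicographic ``id_col``),
    emits it as a sentinel, and discards all records whose anchor lies
    within ``window_bp`` of it on the same chromosome. The output is
    independent of input ordering and sentinels are pairwise more than
    ``window_bp`` apart.
    """
    for col in (chrom_col, pos_col, p_col, id_col):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    ordered = records.sort_values([p_col, pos_col, id_col], kind="mergesort")
    kept_pos: dict = {}
    kept_rows = []
    for row in ordered.itertuples():
        chrom = getattr(row, chrom_col)
        pos = getattr(row, pos_col)
        taken = kept_pos.get(chrom)
        if taken is not None and np.any(np.abs(np.asarray(taken) - pos) <= window_bp):
            continue
        kept_pos.setdefault(chrom, []).append(pos)
        kept_rows.append(row.Index)
    return records.loc[kept_rows]
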