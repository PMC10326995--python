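"""Cis interaction-QTL scanning.

Fits the linear model ``Y ~ G + E + GxE + C`` (OLS with intercept, the
GxE column being the elementwise product of dosage and the centered
interaction variable) for every cis phenotype-variant pair that survives
the MAF filters, and reports per-term estimates, standard errors,
t-statistics and two-sided t-distribution p-values.

The scan uses a batched normal-equations implementation: the shared
columns ``[1, E, C]`` are pre-reduced once per phenotype and each
variant only contributes rank-two updates, so per-pair cost does not
scale with sample size. ``fit_interaction_model`` provides the
equivalent single-pair route; the two must agree to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .core import GenotypeMatrix, PhenotypeSet
from .preprocess import center, half_split, interaction_maf_filter

__all__ = [
    "GENE_WINDOW_BP",
    "CPG_WINDOW_BP",
    "CisWindowSpec",
    "ScanConfig",
    "IQTLRecord",
    "GroupFit",
    "ScanResult",
    "cis_pairs",
    "fit_interaction_model",
    "fit_group_model",
    "scan",
]

GENE_WINDOW_BP = 1_000_000
CPG_WINDOW_BP = 500_000


@dataclass(frozen=True)
class CisWindowSpec:
    """Cis window definition: variants within ``half_width_bp`` of the anchor."""

    kind: str
    half_width_bp: int

    def __post_init__(self):
        if self.half_width_bp <= 0:
            raise ValueError("half_width_bp must be > 0")

    @classmethod
    def for_kind(cls, kind) -> "CisWindowSpec":
        """Build a spec from ``"gene"``, ``"cpg"`` or an explicit width in bp."""
        if isinstance(kind, (int, np.integer)):
            return cls("custom", int(kind))
        if kind == "gene":
            return cls("gene", GENE_WINDOW_BP)
        if kind == "cpg":
            return cls("cpg", CPG_WINDOW_BP)
        raise ValueError(f"unknown window kind {kind!r}")


@dataclass(frozen=True)
class ScanConfig:
    """Thresholds of the variant filters applied before fitting."""

    maf_global: float = 0.01
    maf_interaction: float = 0.05


@dataclass
class IQTLRecord:
    """One phenotype-variant interaction test."""

    phenotype_id: str = ""
    variant_id: str = ""
    chrom: str = ""
    pos: int = -1
    b_g: float = np.nan
    se_g: float = np.nan
    t_g: float = np.nan
    p_g: float = np.nan
    b_e: float = np.nan
    se_e: float = np.nan
    t_e: float = np.nan
    p_e: float = np.nan
    b_gxe: float = np.nan
    se_gxe: float = np.nan
    t_gxe: float = np.nan
    p_gxe: float = np.nan
    n: int = 0
    df_resid: int = 0
    maf: float = np.nan
    maf_lower_half: float = np.nan
    maf_upper_half: float = np.nan
    ok: bool = True
    note: str = ""


@dataclass
class GroupFit:
    """Genotype effect from ``y ~ g + C`` within one sample group."""

    b_g: float = np.nan
    se_g: float = np.nan
    t_g: float = np.nan
    p_g: float = np.nan
    n: int = 0
    df_resid: int = 0
    ok: bool = True
    note: str = ""


@dataclass
class ScanResult:
    """All-pair records, top association per phenotype, skipped phenotypes."""

    pairs: pd.DataFrame
    top: pd.DataFrame
    skipped: list = field(default_factory=list)


def _chol_solve(XtX: np.ndarray, Xty: np.ndarray):
    """Solve the normal equations; return (beta, inv diag) or None if deficient."""
    try:
        c, low = linalg.cho_factor(XtX, lower=True)
    except linalg.LinAlgError:
        return None
    d = np.abs(np.diag(c))
    if d.min() <= 1e-8 * max(d.max(), 1.0):
        return None
    beta = linalg.cho_solve((c, low), Xty)
    inv = linalg.cho_solve((c, low), np.eye(XtX.shape[0]))
    return beta, np.diag(inv)


def _t_pvalues(t: np.ndarray, df: int) -> np.ndarray:
    return 2.0 * stats.t.sf(np.abs(t), df)


def cis_pairs(phenotypes: PhenotypeSet, variants: pd.DataFrame, spec: CisWindowSpec) -> pd.DataFrame:
    """Enumerate cis pairs: same chromosome, ``|pos - anchor| <= half_width``.

    Returns a frame with ``phenotype_idx, variant_idx, phenotype_id,
    variant_id`` (boundary inclusive; empty result allowed).
    """
    out_p, out_v = [], []
    by_chrom = {}
    vdf = variants.reset_index(drop=True)
    for chrom, grp in vdf.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        by_chrom[chrom] = (pos[order], grp.index.to_numpy()[order])
    for pi, row in enumerate(phenotypes.phenotypes.itertuples()):
        entry = by_chrom.get(row.chrom)
        if entry is None:
            continue
        pos_sorted, idx_sorted = entry
        lo = np.searchsorted(pos_sorted, row.anchor - spec.half_width_bp, side="left")
        hi = np.searchsorted(pos_sorted, row.anchor + spec.half_width_bp, side="right")
        if hi > lo:
            out_p.append(np.full(hi - lo, pi))
            out_v.append(idx_sorted[lo:hi])
    if not out_p:
        return pd.DataFrame(columns=["phenotype_idx", "variant_idx", "phenotype_id", "variant_id"])
    p_idx = np.concatenate(out_p)
    v_idx = np.concatenate(out_v)
    return pd.DataFrame(
        {
            "phenotype_idx": p_idx,
            "variant_idx": v_idx,
            "phenotype_id": phenotypes.phenotypes["phenotype_id"].to_numpy()[p_idx],
            "variant_id": vdf["variant_id"].to_numpy()[v_idx],
        }
    )


def fit_interaction_model(y, g, e, C=None, **meta) -> IQTLRecord:
    """OLS fit of ``y ~ 1 + g + e + g*e + C`` for a single pair.

    ``e`` must already be centered. A rank-deficient design yields a
    flagged record (``ok=False``) with missing estimates rather than an
    exception. Keyword arguments fill the record's identity fields.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    e = np.asarray(e, dtype=float)
    n = y.size
    cols = [np.ones(n), g, e, g * e]
    if C is not None and np.size(C):
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape[0] != n:
            C = C.T
        cols.extend(C.T)
    X = np.column_stack(cols)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("missing values in design or response; impute/mask first")
    rec = IQTLRecord(n=n, **meta)
    sol = _chol_solve(X.T @ X, X.T @ y)
    if sol is None:
        rec.ok = False
        rec.note = "rank_deficient"
        return rec
    beta, inv_diag = sol
    resid = y - X @ beta
    df = n - X.shape[1]
    rec.df_resid = df
    if df <= 0:
        rec.ok = False
        rec.note = "no_residual_df"
        return rec
    sigma2 = float(resid @ resid) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(sigma2 * inv_diag, 0.0))
        t = beta / se
    p = _t_pvalues(t, df)
    for i, term in ((1, "g"), (2, "e"), (3, "gxe")):
        setattr(rec, f"b_{term}", float(beta[i]))
        setattr(rec, f"se_{term}", float(se[i]))
        setattr(rec, f"t_{term}", float(t[i]))
        setattr(rec, f"p_{term}", float(p[i]))
    return rec


def fit_group_model(y, g, C=None, group_mask=None) -> GroupFit:
    """OLS of ``y ~ 1 + g + C`` restricted to samples where ``group_mask``."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if group_mask is None:
        group_mask = np.ones(y.size, dtype=bool)
    group_mask = np.asarray(group_mask, dtype=bool)
    cols = [np.ones(y.size), g]
    if C is not None and np.size(C):
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if C.shape[0] != y.size:
            C = C.T
        cols.extend(C.T)
    X = np.column_stack(cols)[group_mask]
    yy = y[group_mask]
    if yy.size < X.shape[1] + 3:
        raise ValueError("degenerate group: fewer than p + 3 samples")
    fit = GroupFit(n=int(yy.size), df_resid=int(yy.size - X.shape[1]))
    sol = _chol_solve(X.T @ X, X.T @ yy)
    if sol is None:
        fit.ok = False
        fit.note = "rank_deficient"
        return fit
    beta, inv_diag = sol
    resid = yy - X @ beta
    sigma2 = float(resid @ resid) / fit.df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(max(sigma2 * inv_diag[1], 0.0))
        t = beta[1] / se
    fit.b_g = float(beta[1])
    fit.se_g = float(se)
    fit.t_g = float(t)
    fit.p_g = float(_t_pvalues(np.array([t]), fit.df_resid)[0])
    return fit


_PAIR_COLUMNS = [f.name for f in fields(IQTLRecord)]


def scan(bundle, e_name: str, spec: CisWindowSpec, config: ScanConfig | None = None) -> ScanResult:
    """Scan all cis pairs for one interaction variable.

    Applies the global MAF filter, then the two-half interaction-aware
    MAF filter, and fits every surviving pair with the batched
    implementation. The top record per phenotype is the one with the
    smallest interaction p-value (ties broken by smaller variant position
    then variant id). Phenotypes with no surviving variants, or with no
    successfully fitted pair, are reported in ``skipped``.
    """
    config = config or ScanConfig()
    geno = bundle.genotypes.mean_impute()
    G_all = geno.dosages
    if np.isnan(G_all).any():
        raise ValueError("genotypes contain fully-missing variants")
    e = center(bundle.interactions[e_name])
    if not np.all(np.isfinite(e)):
        raise ValueError("interaction variable has missing values")
    n = e.size

    f_all = G_all.mean(axis=0) / 2.0
    maf_all = np.minimum(f_all, 1.0 - f_all)
    keep = maf_all > config.maf_global
    keep &= interaction_maf_filter(G_all, e, config.maf_interaction)

    lower, upper = half_split(e)
    f_lo = G_all[lower].mean(axis=0) / 2.0
    f_hi = G_all[upper].mean(axis=0) / 2.0
    maf_lo = np.minimum(f_lo, 1.0 - f_lo)
    maf_hi = np.minimum(f_hi, 1.0 - f_hi)

    C = bundle.covariate_matrix
    Z = np.column_stack([np.ones(n), e] + ([C[:, i] for i in range(C.shape[1])] if C.size else []))
    q = Z.shape[1]
    p_cols = q + 2
    df = n - p_cols
    ZtZ = Z.T @ Z

    pair_index = cis_pairs(bundle.phenotypes, geno.variants, spec)
    vmeta = geno.variants
    records = []
    top_rows = []
    skipped = []
    anchors = bundle.phenotypes.phenotypes["anchor"].to_numpy()

    for pi, grp in pair_index.groupby("phenotype_idx", sort=True):
        pid = bundle.phenotypes.phenotypes.loc[pi, "phenotype_id"]
        vidx = grp["variant_idx"].to_numpy()
        vidx = vidx[keep[vidx]]
        if vidx.size == 0:
            skipped.append(pid)
            continue
        y = bundle.phenotypes.values[:, pi]
        if not np.all(np.isfinite(y)):
            raise ValueError(f"phenotype {pid} has missing values; preprocess first")
        G = G_all[:, vidx]
        W = G * e[:, None]
        ZtG = Z.T @ G
        ZtW = Z.T @ W
        gg = np.einsum("ij,ij->j", G, G)
        gw = np.einsum("ij,ij->j", G, W)
        ww = np.einsum("ij,ij->j", W, W)
        Zty = Z.T @ y
        Gty = G.T @ y
        Wty = W.T @ y
        yty = float(y @ y)

        m = vidx.size
        beta_all = np.full((m, 3), np.nan)
        se_all = np.full((m, 3), np.nan)
        ok_all = np.zeros(m, dtype=bool)
        XtX = np.empty((p_cols, p_cols))
        XtX[:q, :q] = ZtZ
        Xty = np.empty(p_cols)
        Xty[:q] = Zty
        for j in range(m):
            XtX[:q, q] = ZtG[:, j]
            XtX[q, :q] = ZtG[:, j]
            XtX[:q, q + 1] = ZtW[:, j]
            XtX[q + 1, :q] = ZtW[:, j]
            XtX[q, q] = gg[j]
            XtX[q, q + 1] = XtX[q + 1, q] = gw[j]
            XtX[q + 1, q + 1] = ww[j]
            Xty[q] = Gty[j]
            Xty[q + 1] = Wty[j]
            sol = _chol_solve(XtX, Xty)
            if sol is None:
                continue
            beta, inv_diag = sol
            rss = max(yty - float(beta @ Xty), 0.0)
            sigma2 = rss / df
            ok_all[j] = True
            # term order within beta: [1, e, C..., g, g*e]
            for k, col in enumerate((q, 1, q + 1)):
                beta_all[j, k] = beta[col]
                se_all[j, k] = np.sqrt(max(sigma2 * inv_diag[col], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_all = beta_all / se_all
        p_all = _t_pvalues(t_all, df)

        sub = pd.DataFrame(
            {
                "phenotype_id": pid,
                "variant_id": vmeta["variant_id"].to_numpy()[vidx],
                "chrom": vmeta["chrom"].to_numpy()[vidx],
                "pos": vmeta["pos"].to_numpy()[vidx],
                "b_g": beta_all[:, 0],
                "se_g": se_all[:, 0],
                "t_g": t_all[:, 0],
                "p_g": p_all[:, 0],
                "b_e": beta_all[:, 1],
                "se_e": se_all[:, 1],
                "t_e": t_all[:, 1],
                "p_e": p_all[:, 1],
                "b_gxe": beta_all[:, 2],
                "se_gxe": se_all[:, 2],
                "t_gxe": t_all[:, 2],
                "p_gxe": p_all[:, 2],
                "n": n,
                "df_resid": df,
                "maf": maf_all[vidx],
                "maf_lower_half": maf_lo[vidx],
                "maf_upper_half": maf_hi[vidx],
                "ok": ok_all,
                "note": np.where(ok_all, "", "rank_deficient"),
                "anchor": anchors[pi],
            }
        )
        records.append(sub)
        fitted = sub[sub["ok"] & np.isfinite(sub["p_gxe"])]
        if fitted.empty:
            skipped.append(pid)
        else:
            best = fitted.sort_values(["p_gxe", "pos", "variant_id"], kind="mergesort").iloc[0]
            top_rows.append(best)

    empty_cols = _PAIR_COLUMNS + ["anchor"]
    pairs = pd.concat(records, ignore_index=True) if records else pd.DataFrame(columns=empty_cols)
    top = (
        pd.DataFrame(top_rows).reset_index(drop=True)
        if top_rows
        else pd.DataFrame(columns=empty_cols)
    )
    return ScanResult(pairs=pairs, top=top, skipped=skipped)
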