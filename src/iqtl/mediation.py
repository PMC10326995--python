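"""Mediated moderation: does a G-by-mediator interaction carry a
G-by-moderator effect?

Two linear models are fitted by OLS:

* mediator model:  ``g*m ~ 1 + g + w + g*w + m + C``  (path coefficient
  ``a`` = coefficient of ``g*w``)
* outcome model:   ``y ~ 1 + g + w + g*w + m + g*m + C``  (``b`` =
  coefficient of ``g*m``; direct effect = coefficient of ``g*w``)

Point estimates use the product of coefficients (``acme = a*b``,
``ade = direct``, ``total = acme + ade``), which coincides with the
simulation-based estimator for linear links. Inference is by
nonparametric bootstrap (resampling whole sample rows), with
bias-corrected and accelerated (BCa) intervals and two-sided bootstrap
p-values floored at ``1/n_boot``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from scipy.special import ndtr, ndtri

__all__ = [
    "ModelFit",
    "MediationResult",
    "GroupInflation",
    "fit_mediator_model",
    "fit_outcome_model",
    "bca_interval",
    "mediated_moderation",
    "screen_gxm_inflation",
]


@dataclass
class ModelFit:
    """OLS coefficient record with named terms."""

    names: list
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_resid: int

    def __getitem__(self, name: str) -> float:
        return float(self.coef[self.names.index(name)])

    @property
    def a(self) -> float:
        """Path coefficient of the g*w column (mediator model)."""
        return self["g:w"]

    @property
    def b(self) -> float:
        """Coefficient of the g*m column (outcome model)."""
        return self["g:m"]

    @property
    def direct(self) -> float:
        """Coefficient of the g*w column (outcome model)."""
        return self["g:w"]


@dataclass
class MediationResult:
    acme: float
    ade: float
    total: float
    prop_mediated: float
    ci_acme: tuple
    ci_ade: tuple
    ci_total: tuple
    ci_prop: tuple
    p_acme: float
    p_ade: float
    p_total: float
    n_boot: int
    seed: object = None
    prop_defined: bool = True


@dataclass
class GroupInflation:
    lam: float
    n: int
    low_confidence: bool


def _center(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x - x.mean()


def _cov_block(C, n) -> np.ndarray:
    if C is None or not np.size(C):
        return np.empty((n, 0))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.shape[0] != n:
        C = C.T
    return C


def _mediator_design(g, w, m, C):
    n = g.size
    X = np.column_stack([np.ones(n), g, w, g * w, m, _cov_block(C, n)])
    names = ["intercept", "g", "w", "g:w", "m"] + [f"c{i}" for i in range(X.shape[1] - 5)]
    return X, g * m, names


def _outcome_design(y, g, w, m, C):
    n = g.size
    X = np.column_stack([np.ones(n), g, w, g * w, m, g * m, _cov_block(C, n)])
    names = ["intercept", "g", "w", "g:w", "m", "g:m"] + [f"c{i}" for i in range(X.shape[1] - 6)]
    return X, np.asarray(y, dtype=float), names


def _ols_fit(X, y, names) -> ModelFit:
    XtX = X.T @ X
    try:
        c, low = linalg.cho_factor(XtX, lower=True)
    except linalg.LinAlgError:
        raise ValueError("rank-deficient design") from None
    d = np.abs(np.diag(c))
    if d.min() <= 1e-8 * max(d.max(), 1.0):
        raise ValueError("rank-deficient design")
    beta = linalg.cho_solve((c, low), X.T @ y)
    resid = y - X @ beta
    df = y.size - X.shape[1]
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df
    inv_diag = np.diag(linalg.cho_solve((c, low), np.eye(X.shape[1])))
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(sigma2 * inv_diag, 0.0))
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return ModelFit(list(names), beta, se, t, p, df)


def fit_mediator_model(g, w, m, C=None) -> ModelFit:
    """Fit ``g*m ~ 1 + g + w + g*w + m + C`` (inputs centered internally)."""
    g, w, m = _center(g), _center(w), _center(m)
    X, resp, names = _mediator_design(g, w, m, C)
    return _ols_fit(X, resp, names)


def fit_outcome_model(y, g, w, m, C=None) -> ModelFit:
    """Fit ``y ~ 1 + g + w + g*w + m + g*m + C`` (g, w, m centered internally)."""
    g, w, m = _center(g), _center(w), _center(m)
    X, resp, names = _outcome_design(y, g, w, m, C)
    return _ols_fit(X, resp, names)


def _solve_beta(X, y):
    """Coefficients only; None when the (sub)design is deficient."""
    XtX = X.T @ X
    try:
        c, low = linalg.cho_factor(XtX, lower=True)
    except linalg.LinAlgError:
        return None
    d = np.abs(np.diag(c))
    if d.min() <= 1e-8 * max(d.max(), 1.0):
        return None
    return linalg.cho_solve((c, low), X.T @ y)


def _loo_coefs(X, y) -> np.ndarray:
    """Leave-one-out OLS coefficients via the rank-one downdate identity."""
    XtX = X.T @ X
    c, low = linalg.cho_factor(XtX, lower=True)
    A_inv = linalg.cho_solve((c, low), np.eye(X.shape[1]))
    beta = A_inv @ (X.T @ y)
    U = X @ A_inv
    h = np.einsum("ij,ij->i", U, X)
    r = y - X @ beta
    return beta[None, :] - U * (r / (1.0 - h))[:, None]


def bca_interval(boot, point: float, jackknife, level: float = 0.95) -> tuple:
    """Bias-corrected and accelerated bootstrap interval.

    ``z0`` comes from the fraction of bootstrap draws below the point
    estimate; the acceleration from the jackknife third-moment formula.
    A degenerate bootstrap distribution returns ``[point, point]``.
    """
    boot = np.asarray(boot, dtype=float)
    jack = np.asarray(jackknife, dtype=float)
    B = boot.size
    if B < 100:
        raise ValueError("need at least 100 bootstrap draws for BCa")
    if np.ptp(boot) == 0:
        return (point, point)
    frac = np.clip(np.mean(boot < point), 0.5 / B, 1.0 - 0.5 / B)
    z0 = ndtri(frac)
    d = jack.mean() - jack
    denom = (d**2).sum() ** 1.5
    a = float((d**3).sum() / (6.0 * denom)) if denom > 0 else 0.0
    alpha = 1.0 - level
    out = []
    for za in (ndtri(alpha / 2.0), ndtri(1.0 - alpha / 2.0)):
        zadj = z0 + (z0 + za) / (1.0 - a * (z0 + za))
        out.append(float(np.quantile(boot, ndtr(zadj))))
    return tuple(out)


def _boot_p(draws: np.ndarray, n_boot: int) -> float:
    lo = np.mean(draws <= 0.0)
    hi = np.mean(draws >= 0.0)
    return float(np.clip(2.0 * min(lo, hi), 1.0 / n_boot, 1.0))


def mediated_moderation(
    y,
    g,
    w,
    m,
    C=None,
    n_boot: int = 1000,
    level: float = 0.95,
    seed=None,
    truncate_prop: bool = False,
) -> MediationResult:
    """Point estimates, BCa intervals and bootstrap p-values for the
    mediated moderation of a G-by-W effect through G-by-M.

    ``truncate_prop`` clips the proportion mediated (point and draws) to
    [0, 1] before summarizing; by default the raw ratio is reported.
    Bootstrap draws that yield a rank-deficient design are redrawn, with
    a cap of ``10 * n_boot`` attempts.
    """
    y = np.asarray(y, dtype=float)
    g, w, m = _center(g), _center(w), _center(m)
    n = y.size
    Xm, resp_m, _ = _mediator_design(g, w, m, C)
    Xo, resp_o, _ = _outcome_design(y, g, w, m, C)
    A_IDX, B_IDX, DIR_IDX = 3, 5, 3

    fit_m = fit_mediator_model(g, w, m, C)
    fit_o = fit_outcome_model(y, g, w, m, C)
    acme = fit_m.a * fit_o.b
    ade = fit_o.direct
    total = acme + ade
    prop_defined = total != 0.0
    prop = acme / total if prop_defined else np.nan
    if truncate_prop and prop_defined:
        prop = float(np.clip(prop, 0.0, 1.0))

    rng = np.random.default_rng(seed)
    acme_b = np.empty(n_boot)
    ade_b = np.empty(n_boot)
    attempts = 0
    k = 0
    while k < n_boot:
        attempts += 1
        if attempts > 10 * n_boot:
            raise RuntimeError("too many rank-deficient bootstrap draws")
        idx = rng.integers(0, n, n)
        bm = _solve_beta(Xm[idx], resp_m[idx])
        if bm is None:
            continue
        bo = _solve_beta(Xo[idx], resp_o[idx])
        if bo is None:
            continue
        acme_b[k] = bm[A_IDX] * bo[B_IDX]
        ade_b[k] = bo[DIR_IDX]
        k += 1
    total_b = acme_b + ade_b

    loo_m = _loo_coefs(Xm, resp_m)
    loo_o = _loo_coefs(Xo, resp_o)
    acme_j = loo_m[:, A_IDX] * loo_o[:, B_IDX]
    ade_j = loo_o[:, DIR_IDX]
    total_j = acme_j + ade_j

    ci_acme = bca_interval(acme_b, acme, acme_j, level)
    ci_ade = bca_interval(ade_b, ade, ade_j, level)
    ci_total = bca_interval(total_b, total, total_j, level)
    if prop_defined:
        with np.errstate(divide="ignore", invalid="ignore"):
            prop_b = acme_b / total_b
            prop_j = acme_j / total_j
        if truncate_prop:
            prop_b = np.clip(prop_b, 0.0, 1.0)
            prop_j = np.clip(prop_j, 0.0, 1.0)
        finite = np.isfinite(prop_b)
        ci_prop = (
            bca_interval(prop_b[finite], prop, prop_j[np.isfinite(prop_j)], level)
            if finite.sum() >= 100
            else (np.nan, np.nan)
        )
    else:
        ci_prop = (np.nan, np.nan)

    return MediationResult(
        acme=float(acme),
        ade=float(ade),
        total=float(total),
        prop_mediated=float(prop),
        ci_acme=ci_acme,
        ci_ade=ci_ade,
        ci_total=ci_total,
        ci_prop=ci_prop,
        p_acme=_boot_p(acme_b, n_boot),
        p_ade=_boot_p(ade_b, n_boot),
        p_total=_boot_p(total_b, n_boot),
        n_boot=n_boot,
        seed=seed,
        prop_defined=prop_defined,
    )


def screen_gxm_inflation(records, bundle, cell_name: str, direction_col: str = "direction") -> dict:
    """Inflation of G-by-cell interaction p-values among trait iQTLs.

    For each record (a phenotype-variant pair carrying a direction
    call), the interaction model is refitted with the cell-type variable
    as E; inflation lambda is computed separately for the
    positive/negative ("directional") and "uncertain" groups. Groups
    with fewer than 10 pairs are flagged low-confidence.
    """
    from .iqtl_scan import fit_interaction_model
    from .preprocess import center

    e = center(bundle.interactions[cell_name])
    C = bundle.covariate_matrix
    ppos = {p: i for i, p in enumerate(bundle.phenotypes.phenotypes["phenotype_id"])}
    vpos = {v: i for i, v in enumerate(bundle.genotypes.variants["variant_id"])}
    groups: dict = {"directional": [], "uncertain": []}
    dosages = bundle.genotypes.mean_impute().dosages
    for row in records.itertuples():
        direction = getattr(row, direction_col)
        key = "directional" if direction in ("positive", "negative") else "uncertain"
        y = bundle.phenotypes.values[:, ppos[row.phenotype_id]]
        gvec = dosages[:, vpos[row.variant_id]]
        rec = fit_interaction_model(y, gvec, e, C)
        if rec.ok and np.isfinite(rec.p_gxe):
            groups[key].append(rec.p_gxe)
    out = {}
    for key, ps in groups.items():
        if ps:
            out[key] = GroupInflation(inflation_lambda_safe(ps), len(ps), len(ps) < 10)
        else:
            out[key] = GroupInflation(np.nan, 0, True)
    return out


def inflation_lambda_safe(p) -> float:
    """Inflation lambda with underflowed p-values nudged off zero."""
    from .concordance_stats import inflation_lambda

    p = np.asarray(p, dtype=float)
    return inflation_lambda(np.clip(p, np.nextafter(0, 1), 1.0))
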