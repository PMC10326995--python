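"""Direction-of-effect classification for significant iQTLs.

Continuous interaction variables use a three-category rule based on the
main-effect p-value and the sign of the product of the genotype main
effect and the interaction effect. Binary variables use a four-category
rule from separate per-group genotype fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iqtl_scan import GroupFit

__all__ = [
    "CONTINUOUS_CATEGORIES",
    "BINARY_CATEGORIES",
    "DirectionCall",
    "classify_continuous",
    "classify_binary",
    "annotate_directions",
]

CONTINUOUS_CATEGORIES = ("positive", "negative", "uncertain")
BINARY_CATEGORIES = ("no_effect_in_one", "magnitude_difference", "opposite_effect", "uncertain")


@dataclass
class DirectionCall:
    category: str
    evidence: dict = field(default_factory=dict)


def classify_continuous(p_g: float, b_g: float, b_gxe: float, alpha: float = 0.05) -> DirectionCall:
    """Three-category direction call for a continuous interaction variable.

    Non-significant genotype main effect (``p_g >= alpha``) or missing
    estimates give ``uncertain``; otherwise the sign of ``b_g * b_gxe``
    determines ``positive`` / ``negative`` (a zero product, a
    measure-zero boundary, is ``uncertain``).
    """
    evidence = {"p_g": p_g, "b_g": b_g, "b_gxe": b_gxe}
    if not (np.isfinite(p_g) and np.isfinite(b_g) and np.isfinite(b_gxe)):
        return DirectionCall("uncertain", {**evidence, "flag": "missing_estimates"})
    if not p_g < alpha:
        return DirectionCall("uncertain", evidence)
    product = b_g * b_gxe
    if product > 0:
        return DirectionCall("positive", evidence)
    if product < 0:
        return DirectionCall("negative", evidence)
    return DirectionCall("uncertain", {**evidence, "flag": "zero_product"})


def classify_binary(fit_group0: GroupFit, fit_group1: GroupFit, alpha: float = 0.05) -> DirectionCall:
    """Four-category direction call from two per-group genotype fits."""
    evidence = {"fit_group0": fit_group0, "fit_group1": fit_group1}
    for fit in (fit_group0, fit_group1):
        if not fit.ok or not (np.isfinite(fit.p_g) and np.isfinite(fit.b_g)):
            return DirectionCall("uncertain", {**evidence, "flag": "degenerate_fit"})
    sig0 = fit_group0.p_g < alpha
    sig1 = fit_group1.p_g < alpha
    if not sig0 and not sig1:
        return DirectionCall("uncertain", evidence)
    if sig0 != sig1:
        return DirectionCall("no_effect_in_one", evidence)
    product = fit_group0.b_g * fit_group1.b_g
    if product > 0:
        return DirectionCall("magnitude_difference", evidence)
    if product < 0:
        return DirectionCall("opposite_effect", evidence)
    return DirectionCall("uncertain", {**evidence, "flag": "zero_product"})


def annotate_directions(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Add a ``direction`` column (continuous rule) to a results frame."""
    for col in ("p_g", "b_g", "b_gxe"):
        if col not in results.columns:
            raise ValueError(f"results missing column {col!r}")
    out = results.copy()
    out["direction"] = [
        classify_continuous(r.p_g, r.b_g, r.b_gxe, alpha).category for r in results.itertuples()
    ]
    return out
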