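"""Single-cell-type interaction comparator model.

OLS of expression on {intercept, genotype, one cell type's proportion,
genotype x proportion}, with a configurable sign-restriction rule that sets
the interaction p-value to 1 when the product of the interaction and
genotype main-effect coefficients falls on the null side.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.stats

RULES = ("opposite_signs_null", "same_signs_null")

# granulocytes/neutrophils are nulled on opposite signs; the other major
# types on same signs (direction per cell type is configurable)
DEFAULT_RULES = {
    "granulocyte": "opposite_signs_null",
    "neutrophil": "opposite_signs_null",
}
DEFAULT_RULE = "same_signs_null"


@dataclass
class WestraResult:
    snp_id: str
    gene_id: str
    cell_type: str
    intercept: float
    beta_g: float
    beta_c: float
    beta_inter: float
    p_inter: float
    p_after_restriction: float


def fit_westra(
    y: np.ndarray,
    g: np.ndarray,
    c: np.ndarray,
    snp_id: str = "",
    gene_id: str = "",
    cell_type: str = "",
) -> WestraResult:
    """OLS interaction fit; ``p_inter`` is the two-sided t-test p-value of
    the interaction coefficient."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    c = np.asarray(c, dtype=float)
    n = len(y)
    if not (len(g) == len(c) == n):
        raise ValueError("inputs must be sample-aligned")
    if n < 5:
        raise ValueError("need at least 5 samples")
    x = np.column_stack([np.ones(n), g, c, g * c])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("collinear design (constant genotype or proportion?)")
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    df = n - x.shape[1]
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(x.T @ x)
    se_inter = float(np.sqrt(sigma2 * xtx_inv[3, 3]))
    if se_inter == 0.0:
        p_inter = 0.0 if coef[3] != 0 else 1.0
    else:
        t = coef[3] / se_inter
        p_inter = float(2.0 * scipy.stats.t.sf(abs(t), df))
    return WestraResult(
        snp_id=snp_id,
        gene_id=gene_id,
        cell_type=cell_type,
        intercept=float(coef[0]),
        beta_g=float(coef[1]),
        beta_c=float(coef[2]),
        beta_inter=float(coef[3]),
        p_inter=p_inter,
        p_after_restriction=p_inter,
    )


def apply_sign_restriction(res: WestraResult, rule: str) -> WestraResult:
    """Set the p-value to 1 when the coefficient-product condition holds.

    ``opposite_signs_null``: p -> 1 if beta_inter * beta_g < 0;
    ``same_signs_null``:     p -> 1 if beta_inter * beta_g > 0.
    Strict inequalities: a zero product leaves p unchanged under both rules.
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}")
    product = res.beta_inter * res.beta_g
    nulled = (product < 0) if rule == "opposite_signs_null" else (product > 0)
    return replace(res, p_after_restriction=1.0 if nulled else res.p_inter)


def rule_for_cell_type(cell_type: str, overrides: dict[str, str] | None = None) -> str:
    rules = dict(DEFAULT_RULES)
    if overrides:
        rules.update(overrides)
    return rules.get(cell_type, DEFAULT_RULE)
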