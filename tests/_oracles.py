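"""Independent reference implementations used only to check the package.

These deliberately use different algorithms from the package code: an
accelerated projected-gradient NNLS, explicit enumeration for exact tests,
textbook closed forms for OLS, and loop-based trimming for TMM.
"""

from __future__ import annotations

import math

import numpy as np


def projected_gradient_nnls(
    a: np.ndarray, y: np.ndarray, max_iter: int = 200_000, tol: float = 1e-10
) -> np.ndarray:
    """Accelerated projected gradient (FISTA) on the non-negative orthant.

    Columns are normalized to unit length first (a diagonal preconditioner);
    convergence is declared on the KKT residual: the gradient must vanish on
    the active coordinates and be non-negative on the zero coordinates.
    """
    a = np.asarray(a, dtype=float)
    y = np.asarray(y, dtype=float)
    norms = np.linalg.norm(a, axis=0)
    norms[norms == 0] = 1.0
    an = a / norms
    lip = np.linalg.norm(an, 2) ** 2
    if lip == 0:
        return np.zeros(a.shape[1])
    step = 1.0 / lip
    x = np.zeros(a.shape[1])
    z = x.copy()
    t = 1.0
    aty = an.T @ y
    ata = an.T @ an
    scale = max(1.0, float(np.max(np.abs(aty))))
    for _ in range(max_iter):
        grad = ata @ z - aty
        x_new = np.maximum(z - step * grad, 0.0)
        t_new = (1.0 + math.sqrt(1.0 + 4.0 * t * t)) / 2.0
        z = x_new + ((t - 1.0) / t_new) * (x_new - x)
        x, t = x_new, t_new
        g_x = ata @ x - aty
        kkt = max(
            float(np.max(np.abs(g_x[x > 0]), initial=0.0)),
            float(np.max(-g_x[x == 0], initial=0.0)),
        )
        if kkt < tol * scale:
            break
    # polish: exact least squares on the support identified by the iteration
    support = x > 1e-12
    if support.any():
        sol, *_ = np.linalg.lstsq(an[:, support], y, rcond=None)
        if (sol >= -1e-12).all():
            polished = np.zeros_like(x)
            polished[support] = np.maximum(sol, 0.0)
            g_p = ata @ polished - aty
            kkt_p = max(
                float(np.max(np.abs(g_p[polished > 0]), initial=0.0)),
                float(np.max(-g_p[polished == 0], initial=0.0)),
            )
            if kkt_p <= kkt:
                x = polished
    return x / norms


def ols_solution(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Textbook OLS: coefficients, standard errors, residual df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = len(y) - x.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    return beta, se, df


def fisher_two_sided(table: list[list[int]]) -> float:
    """Two-sided Fisher exact p by enumerating the hypergeometric support
    and summing probabilities <= that of the observed table."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(x: int) -> float:
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    p_obs = pmf(a)
    return sum(p for x in range(lo, hi + 1) if (p := pmf(x)) <= p_obs * (1 + 1e-12))


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment by hand."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def tmm_pair_factor(
    y: np.ndarray, y_ref: np.ndarray, trim_m: float = 0.3, trim_a: float = 0.05
) -> float:
    """Brute-force trimmed weighted mean of M-values for one sample pair,
    trimming by explicit sorting rather than rank arithmetic."""
    lib, lib_ref = y.sum(), y_ref.sum()
    idx = [i for i in range(len(y)) if y[i] > 0 and y_ref[i] > 0]
    m = {i: math.log2((y[i] / lib) / (y_ref[i] / lib_ref)) for i in idx}
    a = {i: 0.5 * math.log2((y[i] / lib) * (y_ref[i] / lib_ref)) for i in idx}
    w = {
        i: (1.0 - y[i] / lib) / (y[i] / lib)
        + (1.0 - y_ref[i] / lib_ref) / (y_ref[i] / lib_ref)
        for i in idx
    }
    n = len(idx)
    n_drop_m = math.floor(n * trim_m)
    n_drop_a = math.floor(n * trim_a)
    by_m = sorted(idx, key=lambda i: m[i])
    by_a = sorted(idx, key=lambda i: a[i])
    keep_m = set(by_m[n_drop_m : n - n_drop_m])
    keep_a = set(by_a[n_drop_a : n - n_drop_a])
    keep = keep_m & keep_a
    if not keep:
        return 1.0
    num = sum(m[i] / w[i] for i in keep)
    den = sum(1.0 / w[i] for i in keep)
    return 2.0 ** (num / den)


def ranksum_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by full enumeration (tiny n only)."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    na = len(a)
    obs = ranks[:na].sum()
    sums = [sum(combo) for combo in combinations(ranks, na)]
    mean = np.mean(sums)
    extreme = sum(1 for s in sums if abs(s - mean) >= abs(obs - mean) - 1e-12)
    return extreme / len(sums)
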