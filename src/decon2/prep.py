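"""Expression normalization for the two downstream consumers.

Two preparation paths exist:

* cell-proportion modelling: TMM -> log2(x+1) -> per-gene z-scaling;
* eQTL deconvolution: log2(x+1) -> per-gene covariate correction by OLS ->
  re-exponentiation back to a positive, count-like scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.linalg

from .matrices import CovariateTable, ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "tmm_normalize",
    "log2_plus_one",
    "zscale_genes",
    "correct_and_exponentiate",
    "prepare_for_cell",
    "prepare_for_eqtl",
]


def _tmm_factor(
    y: np.ndarray,
    y_ref: np.ndarray,
    lib: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference."""
    keep = (y > 0) & (y_ref > 0)
    if not keep.any():
        return 1.0
    p = y[keep] / lib
    p_ref = y_ref[keep] / lib_ref
    m = np.log2(p / p_ref)
    a = 0.5 * np.log2(p * p_ref)
    # delta-method precision weights on count fractions; the library-size
    # factors are dropped so the factor is invariant to rescaling a sample
    w = (1.0 - p) / p + (1.0 - p_ref) / p_ref
    n = m.size
    # double trimming: drop trim_m of each M tail and trim_a of each A tail
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    # ordinal ranks (stable) so exact ties trim identically to a plain sort
    rank_m = pd.Series(m).rank(method="first").to_numpy()
    rank_a = pd.Series(a).rank(method="first").to_numpy()
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not sel.any() or w[sel].sum() <= 0:
        return 1.0
    f = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_normalize(
    counts: ExpressionMatrix, trim_m: float = 0.3, trim_a: float = 0.05
) -> ExpressionMatrix:
    """Between-sample normalization via trimmed means of M-values.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean of those fractions (deterministic).  Returned values
    are counts divided by the effective library size (library size times the
    TMM factor) and scaled to counts-per-million, so rescaling any one
    sample's counts leaves the output invariant.  Per-sample factors are
    stored in ``meta["tmm_factors"]``.
    """
    if counts.state != "raw_counts":
        raise ValueError("tmm_normalize expects raw counts")
    if counts.data.shape[1] < 2:
        raise ValueError("tmm_normalize needs at least 2 samples")
    vals = counts.values
    lib = vals.sum(axis=0)
    for j, tot in enumerate(lib):
        if tot <= 0:
            raise ValueError(
                f"sample {counts.sample_ids[j]!r} has zero total count"
            )
    # reference: upper-quartile fraction closest to the mean fraction
    with np.errstate(divide="ignore"):
        f75 = np.array(
            [np.quantile(vals[:, j], 0.75) / lib[j] for j in range(vals.shape[1])]
        )
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_factor(vals[:, j], vals[:, ref], lib[j], lib[ref], trim_m, trim_a)
            for j in range(vals.shape[1])
        ]
    )
    # normalize factors to geometric mean 1, as is conventional
    factors = factors / np.exp(np.mean(np.log(factors)))
    eff = lib * factors
    out = vals / eff[np.newaxis, :] * 1e6
    df = pd.DataFrame(out, index=counts.data.index, columns=counts.data.columns)
    meta = dict(counts.meta)
    meta["tmm_factors"] = pd.Series(factors, index=counts.sample_ids)
    meta["tmm_reference"] = counts.sample_ids[ref]
    return ExpressionMatrix(df, state="tmm", meta=meta)


def log2_plus_one(expr: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(x + offset)."""
    if (expr.values < 0).any():
        raise ValueError("log transform requires non-negative values")
    df = np.log2(expr.data + offset)
    state = "tmm_log2" if expr.state in ("tmm", "raw_counts") else expr.state
    return ExpressionMatrix(df, state=state, meta=dict(expr.meta))


def zscale_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each gene row to mean 0, unit variance (ddof=1).

    Zero-variance genes become all-zero rows and are recorded in
    ``zero_variance_genes`` so model training can skip them.
    """
    if expr.data.shape[1] < 2:
        raise ValueError("zscale_genes needs at least 2 samples")
    vals = expr.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    sd[sd == 0] = 1.0
    out = (vals - mean) / sd
    out[flat, :] = 0.0
    df = pd.DataFrame(out, index=expr.data.index, columns=expr.data.columns)
    flagged = tuple(np.asarray(expr.gene_ids)[flat])
    return ExpressionMatrix(
        df, state="tmm_log2_scaled", zero_variance_genes=flagged, meta=dict(expr.meta)
    )


def build_design(covs: pd.DataFrame) -> pd.DataFrame:
    """Intercept + numeric columns as-is + one-hot (drop-first) categoricals."""
    pieces = [pd.Series(1.0, index=covs.index, name="intercept")]
    for col in covs.columns:
        s = covs[col]
        if s.dtype.kind in "biufc" and s.dtype.kind != "b":
            pieces.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            for c in dummies.columns:
                pieces.append(dummies[c])
    return pd.concat(pieces, axis=1)


def _check_full_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    _, r, piv = scipy.linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < x.shape[1]:
        bad = [design.columns[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")


def correct_and_exponentiate(
    expr: ExpressionMatrix,
    covs: CovariateTable | None = None,
    log_offset: float = 1.0,
) -> ExpressionMatrix:
    """Regress log2 expression on covariates; exponentiate residual + gene mean.

    Per gene, an OLS of ``log2(x + offset)`` on the covariate design is fit;
    the output is ``2 ** (residual + gene mean)``, which keeps values positive
    and on a count-like scale.  With no covariates this is the identity up to
    the log offset.
    """
    vals = expr.values
    if (vals < 0).any():
        raise ValueError("correction requires non-negative expression input")
    logv = np.log2(vals + log_offset)  # genes x samples
    if covs is None or covs.data.shape[1] == 0:
        design = pd.DataFrame(
            {"intercept": np.ones(len(expr.sample_ids))}, index=expr.sample_ids
        )
    else:
        design = build_design(covs.aligned_to(expr.sample_ids))
    _check_full_rank(design)
    x = design.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(x, logv.T, rcond=None)
    resid = logv.T - x @ beta  # samples x genes
    gene_mean = logv.mean(axis=1)
    corrected = np.power(2.0, resid.T + gene_mean[:, np.newaxis])
    df = pd.DataFrame(corrected, index=expr.data.index, columns=expr.data.columns)
    return ExpressionMatrix(df, state="corrected_linear", meta=dict(expr.meta))


def prepare_for_cell(
    counts: ExpressionMatrix, trim_m: float = 0.3, trim_a: float = 0.05
) -> ExpressionMatrix:
    """Full preparation for cell-proportion modelling: TMM, log2(x+1), z-scale."""
    return zscale_genes(log2_plus_one(tmm_normalize(counts, trim_m, trim_a)))


def prepare_for_eqtl(
    counts: ExpressionMatrix,
    covs: CovariateTable | None = None,
    log_offset: float = 1.0,
) -> ExpressionMatrix:
    """Full preparation for eQTL deconvolution: covariate-corrected linear scale."""
    return correct_and_exponentiate(counts, covs, log_offset=log_offset)
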