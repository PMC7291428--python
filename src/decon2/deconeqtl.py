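"""Decomposition of bulk cis-eQTL effects into cell-type interaction effects.

The bulk expression of a gene is modelled as a proportion-weighted sum of
per-cell-type contributions,

    y = sum_k beta_k * c_k + sum_k gamma_k * (g_k x c_k) + e,

with no intercept and no genotype main-effect term, fit by non-negative least
squares (all beta_k, gamma_k >= 0).  Because a negative allelic effect would
be truncated at zero, each interaction term may use either dosage coding
(g or 2-g).  Allowing at most one term to deviate from the shared orientation
limits the search to (2k)+2 configurations; the configuration with the lowest
residual sum of squares wins.  Each cell type's interaction is then tested by
comparing the best full model against the best reduced model (that cell
type's interaction removed, its own encoding search) with an F test on
(1, n - 2k) degrees of freedom, and p-values are FDR-corrected per cell type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .matrices import (
    CellQuantMatrix,
    ExpressionMatrix,
    GenotypeDosageMatrix,
    ScaledProportions,
    common_samples,
)

log = logging.getLogger(__name__)

Encoding = tuple[bool, ...]  # True = swapped (g -> 2 - g) for that interaction term

__all__ = [
    "scale_proportions",
    "enumerate_encodings",
    "fit_nnls_interaction",
    "choose_encoding",
    "anova_interaction_test",
    "deconvolute",
    "fdr_per_celltype",
    "DeconEqtlResult",
    "FitRecord",
]


def scale_proportions(
    props: CellQuantMatrix,
    cell_types: list[str] | None = None,
    collinearity_warn: float = 0.75,
) -> ScaledProportions:
    """Rescale each sample's selected cell types to sum to 100.

    Cell-type pairs whose proportions correlate at |Pearson R| >= the warning
    threshold are logged: strong collinearity makes interaction attribution
    unreliable.
    """
    if cell_types is None:
        cell_types = props.cell_types
    missing = [c for c in cell_types if c not in props.data.columns]
    if missing:
        raise ValueError(f"cell types not present: {missing}")
    sub = props.data[list(cell_types)].astype(float)
    sums = sub.sum(axis=1)
    zero = sums.index[sums <= 0].tolist()
    if zero:
        raise ValueError(f"samples with all-zero selected proportions: {zero[:5]}")
    scaled = sub.div(sums, axis=0) * 100.0
    if len(cell_types) > 1:
        corr = scaled.corr()
        for i, a in enumerate(cell_types):
            for b in cell_types[i + 1 :]:
                r = corr.loc[a, b]
                if np.isfinite(r) and abs(r) >= collinearity_warn:
                    log.warning(
                        "cell-type proportions %r and %r are collinear (R=%.3f)",
                        a,
                        b,
                        r,
                    )
    return ScaledProportions(scaled)


def _term_encodings(n_terms: int) -> list[Encoding]:
    """Distinct orientation patterns with at most one term deviating from the
    majority, for a model with ``n_terms`` interaction terms."""
    if n_terms == 0:
        return [()]
    encs = {(False,) * n_terms, (True,) * n_terms}
    for i in range(n_terms):
        encs.add(tuple(j == i for j in range(n_terms)))
        encs.add(tuple(j != i for j in range(n_terms)))
    return sorted(encs)


def enumerate_encodings(k: int) -> list[Encoding]:
    """All allowed genotype-orientation configurations for k interaction terms.

    Returns the deduplicated set: both uniform orientations plus every
    single-term deviation — (2k)+2 configurations for k >= 3, 4 for k = 2
    (single-term deviations from either orientation coincide there), and 2
    for k = 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return _term_encodings(k)


@dataclass(frozen=True)
class FitRecord:
    """One NNLS solve: coefficients and residual sum of squares."""

    betas: tuple[float, ...]  # proportion main effects, one per cell type
    gammas: tuple[float, ...]  # interaction effects, one per retained term
    encoding: Encoding  # orientation per retained interaction term
    drop_term: int | None
    rss: float


def _design(
    g: np.ndarray,
    c: np.ndarray,
    encoding: Encoding,
    drop_term: int | None,
) -> tuple[np.ndarray, list[int]]:
    k = c.shape[1]
    terms = [j for j in range(k) if j != drop_term]
    if len(encoding) != len(terms):
        raise ValueError(
            f"encoding length {len(encoding)} does not match {len(terms)} terms"
        )
    cols = [c[:, j] for j in range(k)]
    for enc, j in zip(encoding, terms):
        gj = 2.0 - g if enc else g
        cols.append(gj * c[:, j])
    return np.column_stack(cols), terms


def fit_nnls_interaction(
    y: np.ndarray,
    g: np.ndarray,
    c: ScaledProportions | np.ndarray,
    encoding: Encoding,
    drop_term: int | None = None,
) -> FitRecord:
    """Solve the non-negative interaction model for one gene/SNP.

    ``encoding`` gives the orientation of each retained interaction term in
    cell-type order; with ``drop_term`` set, that cell type's interaction is
    omitted (the reduced model).  No intercept and no genotype main effect
    are included.
    """
    cv = c.data.to_numpy(dtype=float) if isinstance(c, ScaledProportions) else np.asarray(c, float)
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    n, k = cv.shape
    if not (len(y) == len(g) == n):
        raise ValueError("y, g and proportions must be sample-aligned")
    if n <= 2 * k:
        raise ValueError(f"need n > 2k samples (n={n}, k={k})")
    x, terms = _design(g, cv, encoding, drop_term)
    coef, rnorm = scipy.optimize.nnls(x, y)
    return FitRecord(
        betas=tuple(float(b) for b in coef[:k]),
        gammas=tuple(float(gm) for gm in coef[k:]),
        encoding=tuple(encoding),
        drop_term=drop_term,
        rss=float(rnorm**2),
    )


def choose_encoding(fits: list[FitRecord]) -> FitRecord:
    """The fit with minimal rss; ties broken by fewest swapped terms, then
    lexicographic encoding order (deterministic)."""
    if not fits:
        raise ValueError("no fits supplied")
    return min(fits, key=lambda f: (f.rss, sum(f.encoding), f.encoding))


def anova_interaction_test(
    rss_full: float,
    rss_reduced: float,
    n: int,
    k: int,
    tol: float = 1e-9,
) -> tuple[float, float]:
    """F test of the full model against a one-term-reduced model.

    F = ((rss_reduced - rss_full) / 1) / (rss_full / (n - 2k)); tiny negative
    numerators from numerical tolerance are clamped to 0 (p = 1), and a
    saturated fit (rss_full = rss_reduced = 0) yields p = 1.
    """
    df2 = n - 2 * k
    if df2 <= 0:
        raise ValueError(f"need n > 2k (n={n}, k={k})")
    num = rss_reduced - rss_full
    if num < 0:
        if num < -max(tol, tol * rss_reduced):
            raise ValueError("full model rss exceeds reduced model rss")
        num = 0.0
    denom = rss_full / df2
    if denom == 0.0:  # saturated (or subnormal-underflow) full fit
        if num <= tol:
            return 0.0, 1.0
        return float("inf"), 0.0
    f_stat = num / denom
    p = float(scipy.stats.f.sf(f_stat, 1, df2))
    return float(f_stat), p


@dataclass
class DeconEqtlResult:
    """Per (SNP, gene) deconvolution across all cell types."""

    snp_id: str
    gene_id: str
    cell_types: tuple[str, ...]
    betas: tuple[float, ...]
    gammas: tuple[float, ...]
    encoding: Encoding
    rss_full: float
    rss_reduced: tuple[float, ...]
    f_stats: tuple[float, ...]
    p_values: tuple[float, ...]
    fdr: tuple[float, ...] | None = None

    def directions(self) -> dict[str, int]:
        """Sign of each cell type's interaction effect for the coded allele:
        +1 under as-is orientation, -1 under swapped, 0 when gamma is 0."""
        out = {}
        for ct, gm, enc in zip(self.cell_types, self.gammas, self.encoding):
            out[ct] = 0 if gm == 0.0 else (-1 if enc else 1)
        return out


@dataclass
class DeconEqtlResults:
    """Container for all deconvoluted pairs plus skip diagnostics."""

    results: list[DeconEqtlResult]
    cell_types: tuple[str, ...]
    skipped: list[tuple[str, str, str]] = field(default_factory=list)
    n_samples: int = 0

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row: dict = {"snp_id": r.snp_id, "gene_id": r.gene_id, "rss_full": r.rss_full}
            for i, ct in enumerate(r.cell_types):
                row[f"{ct}_beta"] = r.betas[i]
                row[f"{ct}_gamma"] = r.gammas[i]
                row[f"{ct}_encoding"] = "swapped" if r.encoding[i] else "as-is"
                row[f"{ct}_rss_reduced"] = r.rss_reduced[i]
                row[f"{ct}_F"] = r.f_stats[i]
                row[f"{ct}_p"] = r.p_values[i]
                if r.fdr is not None:
                    row[f"{ct}_fdr"] = r.fdr[i]
            rows.append(row)
        return pd.DataFrame(rows)


def _decon_one(
    y: np.ndarray, g: np.ndarray, c: np.ndarray, k: int
) -> tuple[FitRecord, list[FitRecord], list[float], list[float]]:
    full = choose_encoding(
        [fit_nnls_interaction(y, g, c, enc) for enc in _term_encodings(k)]
    )
    n = len(y)
    reduced_best, f_stats, p_values = [], [], []
    for j in range(k):
        red = choose_encoding(
            [
                fit_nnls_interaction(y, g, c, enc, drop_term=j)
                for enc in _term_encodings(k - 1)
            ]
        )
        f_stat, p = anova_interaction_test(full.rss, red.rss, n, k)
        reduced_best.append(red)
        f_stats.append(f_stat)
        p_values.append(p)
    return full, reduced_best, f_stats, p_values


def deconvolute(
    pairs: pd.DataFrame,
    expr: ExpressionMatrix,
    geno: GenotypeDosageMatrix,
    props: ScaledProportions,
) -> DeconEqtlResults:
    """Run the full/reduced NNLS model with encoding search for each pair.

    ``pairs`` needs columns ``snp_id`` and ``gene_id``; duplicates are
    dropped.  Samples are intersected across the three inputs.  Unresolvable
    SNPs/genes and zero-variance dosages are skipped with a logged warning
    and reported in the result's ``skipped`` list.
    """
    if expr.state != "corrected_linear":
        raise ValueError("deconvolution expects covariate-corrected linear expression")
    samples = common_samples(expr, geno, props)
    k = len(props.cell_types)
    if len(samples) <= 2 * k:
        raise ValueError(
            f"need more than 2k={2 * k} shared samples, got {len(samples)}"
        )
    log.info("deconvoluting over %d shared samples", len(samples))
    c = props.data.loc[samples].to_numpy(dtype=float)
    expr_sub = expr.data[samples]
    geno_sub = geno.data[samples]
    seen: set[tuple[str, str]] = set()
    results: list[DeconEqtlResult] = []
    skipped: list[tuple[str, str, str]] = []
    for snp_id, gene_id in pairs[["snp_id", "gene_id"]].itertuples(index=False):
        key = (str(snp_id), str(gene_id))
        if key in seen:
            continue
        seen.add(key)
        if key[0] not in geno_sub.index:
            skipped.append((*key, "unknown snp"))
            log.warning("skipping %s/%s: unknown snp", *key)
            continue
        if key[1] not in expr_sub.index:
            skipped.append((*key, "unknown gene"))
            log.warning("skipping %s/%s: unknown gene", *key)
            continue
        g = geno_sub.loc[key[0]].to_numpy(dtype=float)
        if np.isnan(g).any():
            skipped.append((*key, "missing dosages"))
            log.warning("skipping %s/%s: missing dosages", *key)
            continue
        if np.ptp(g) == 0.0:
            skipped.append((*key, "zero-variance dosage"))
            log.warning("skipping %s/%s: zero-variance dosage", *key)
            continue
        y = expr_sub.loc[key[1]].to_numpy(dtype=float)
        full, reduced, f_stats, p_values = _decon_one(y, g, c, k)
        results.append(
            DeconEqtlResult(
                snp_id=key[0],
                gene_id=key[1],
                cell_types=tuple(props.cell_types),
                betas=full.betas,
                gammas=full.gammas,
                encoding=full.encoding,
                rss_full=full.rss,
                rss_reduced=tuple(r.rss for r in reduced),
                f_stats=tuple(f_stats),
                p_values=tuple(p_values),
            )
        )
    if skipped:
        log.info("skipped %d of %d pairs", len(skipped), len(seen))
    return DeconEqtlResults(
        results=results,
        cell_types=tuple(props.cell_types),
        skipped=skipped,
        n_samples=len(samples),
    )


def fdr_per_celltype(results: DeconEqtlResults) -> DeconEqtlResults:
    """Benjamini-Hochberg correction applied separately per cell type."""
    if len(results) < 1:
        raise ValueError("no results to correct")
    k = len(results.cell_types)
    adjusted = np.empty((len(results), k))
    for j in range(k):
        pvec = np.array([r.p_values[j] for r in results])
        adjusted[:, j] = multipletests(pvec, method="fdr_bh")[1]
    for i, r in enumerate(results):
        r.fdr = tuple(float(v) for v in adjusted[i])
    return results
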