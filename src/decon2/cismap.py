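"""Minimal cis-eQTL discovery to produce top-effect SNP-gene lists.

SNPs are filtered on MAF (>= 0.01), call rate (= 1) and Hardy-Weinberg
equilibrium (chi-square p >= 1e-4); candidate pairs are SNPs within 250 kb of
a gene's center; association is a per-pair simple linear regression with BH
FDR over all pairs and the smallest-p significant SNP per gene reported as
the top effect.  This is a deliberately simple stand-in mapper, sufficient
for synthetic data; it performs no covariate adjustment or permutations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .matrices import ExpressionMatrix, GenotypeDosageMatrix, common_samples

log = logging.getLogger(__name__)

POSITION_COLUMNS = ["feature_id", "chrom", "start", "end"]

__all__ = ["snp_filters", "cis_pairs", "map_cis_eqtls", "hwe_chi_square_p"]


def hwe_chi_square_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square Hardy-Weinberg test on genotype counts."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return float(scipy.stats.chi2.sf(stat, 1))


def snp_filters(
    geno: GenotypeDosageMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 0.0001,
    call_rate_req: float = 1.0,
) -> list[str]:
    """SNP ids passing MAF >= maf_min, call rate >= call_rate_req and
    HWE p >= hwe_p_min (all boundaries inclusive).

    HWE is computed on hard calls; fractional dosages are rounded for the
    genotype counts, with a warning when > 5% of a SNP's dosages are more
    than 0.1 from an integer.
    """
    retained = []
    for snp_id, row in geno.data.iterrows():
        d = row.to_numpy(dtype=float)
        called = d[np.isfinite(d)]
        call_rate = len(called) / len(d) if len(d) else 0.0
        if call_rate < call_rate_req or len(called) == 0:
            continue
        freq = called.mean() / 2.0
        maf = min(freq, 1.0 - freq)
        if maf < maf_min:
            continue
        hard = np.rint(called)
        off = np.abs(called - hard) > 0.1
        if off.mean() > 0.05:
            log.warning(
                "snp %s: %.0f%% of dosages far from integer; HWE uses rounded calls",
                snp_id,
                100 * off.mean(),
            )
        counts = [int((hard == v).sum()) for v in (0.0, 1.0, 2.0)]
        if hwe_chi_square_p(*counts) < hwe_p_min:
            continue
        retained.append(str(snp_id))
    return retained


def _check_positions(pos: pd.DataFrame, what: str) -> pd.DataFrame:
    missing = [c for c in POSITION_COLUMNS if c not in pos.columns]
    if missing:
        raise ValueError(f"{what} positions lack columns: {missing}")
    if (pos["start"] > pos["end"]).any():
        raise ValueError(f"{what} positions with start > end")
    return pos


def cis_pairs(
    snps: pd.DataFrame, genes: pd.DataFrame, window: int = 250_000
) -> pd.DataFrame:
    """SNP-gene pairs with |snp_pos - gene_center| <= window on the same
    chromosome; gene_center = floor((start + end) / 2).  Coordinates are
    1-based inclusive (not BED-style half-open)."""
    snps = _check_positions(snps, "snp")
    genes = _check_positions(genes, "gene")
    g = genes.assign(center=((genes["start"] + genes["end"]) // 2).astype(int))
    rows = []
    for chrom, gsub in g.groupby("chrom", sort=True):
        ssub = snps[snps["chrom"] == chrom]
        if ssub.empty:
            continue
        for gene_id, center in zip(gsub["feature_id"], gsub["center"]):
            near = ssub[(ssub["start"] - center).abs() <= window]
            for snp_id in near["feature_id"]:
                rows.append((str(snp_id), str(gene_id)))
    out = pd.DataFrame(rows, columns=["snp_id", "gene_id"])
    return out.sort_values(["gene_id", "snp_id"], kind="stable").reset_index(drop=True)


def map_cis_eqtls(
    expr: ExpressionMatrix,
    geno: GenotypeDosageMatrix,
    pairs: pd.DataFrame,
    fdr_alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simple linear regression of expression on dosage per pair.

    Returns ``(all_pairs, top_effects)``: the former has beta/p/fdr per pair
    (BH over all pairs), the latter the smallest-p SNP per gene among pairs
    significant at ``fdr <= fdr_alpha``.
    """
    samples = common_samples(expr, geno)
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples")
    e = expr.data[samples]
    d = geno.data[samples]
    rows = []
    for snp_id, gene_id in pairs[["snp_id", "gene_id"]].itertuples(index=False):
        if snp_id not in d.index or gene_id not in e.index:
            log.warning("skipping %s/%s: unresolvable feature", snp_id, gene_id)
            continue
        g = d.loc[snp_id].to_numpy(dtype=float)
        y = e.loc[gene_id].to_numpy(dtype=float)
        if np.ptp(g) == 0.0:
            continue
        res = scipy.stats.linregress(g, y)
        rows.append((snp_id, gene_id, float(res.slope), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["snp_id", "gene_id", "beta", "p"])
    if out.empty:
        return out.assign(fdr=[]), out.assign(fdr=[])
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    sig = out[out["fdr"] <= fdr_alpha]
    top = (
        sig.loc[sig.groupby("gene_id")["p"].idxmin()]
        .sort_values(["gene_id", "snp_id"], kind="stable")
        .reset_index(drop=True)
    )
    return out, top
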