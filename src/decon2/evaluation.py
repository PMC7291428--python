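"""Validation statistics: allelic concordance, Fisher comparisons, effect-size
tests and gene-set enrichment.

The "direction" of a deconvoluted interaction effect is the sign implied by
its chosen genotype orientation (as-is -> +1 for the coded allele, swapped ->
-1); the interaction coefficient itself is non-negative by construction.
Reference effects are harmonized to the same coded allele before comparison.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .deconeqtl import DeconEqtlResults

__all__ = [
    "decon_directions",
    "allelic_concordance",
    "concordance_fisher",
    "effect_size_comparison",
    "enrichment_fisher",
]

REFERENCE_COLUMNS = ["snp_id", "gene_id", "cell_type", "effect"]


def decon_directions(
    results: DeconEqtlResults,
    fdr_max: float | None = None,
    coded_alleles: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Long table of per-(snp, gene, cell type) effect directions.

    ``coded_alleles`` optionally maps snp_id to the allele coded as dosage 2
    in the deconvolution input, enabling harmonization against references.
    """
    rows = []
    for r in results:
        for j, ct in enumerate(r.cell_types):
            if fdr_max is not None:
                if r.fdr is None or r.fdr[j] > fdr_max:
                    continue
            direction = 0 if r.gammas[j] == 0.0 else (-1 if r.encoding[j] else 1)
            rows.append(
                {
                    "snp_id": r.snp_id,
                    "gene_id": r.gene_id,
                    "cell_type": ct,
                    "direction": direction,
                    "coded_allele": (coded_alleles or {}).get(r.snp_id, ""),
                }
            )
    return pd.DataFrame(
        rows, columns=["snp_id", "gene_id", "cell_type", "direction", "coded_allele"]
    )


def allelic_concordance(
    decon: pd.DataFrame,
    reference: pd.DataFrame,
    cell_type_map: dict[str, str] | None = None,
) -> dict:
    """Directional agreement between deconvoluted and reference effects.

    ``decon`` needs columns snp_id/gene_id/cell_type/direction (and optionally
    coded_allele); ``reference`` needs snp_id/gene_id/cell_type/effect (and
    optionally coded_allele).  When both sides carry a coded allele and they
    differ for a pair, the reference effect sign is flipped.  Pairs with a
    zero effect on either side are excluded from the rate and counted
    separately.
    """
    missing = [c for c in REFERENCE_COLUMNS if c not in reference.columns]
    if missing:
        raise ValueError(f"reference table lacks columns: {missing}")
    d = decon.copy()
    if cell_type_map:
        d["cell_type"] = d["cell_type"].map(lambda c: cell_type_map.get(c, c))
    merged = d.merge(
        reference,
        on=["snp_id", "gene_id", "cell_type"],
        suffixes=("_decon", "_ref"),
    )
    if merged.empty:
        raise ValueError("no overlapping (snp, gene, cell type) entries")
    effect = merged["effect"].to_numpy(dtype=float)
    if "coded_allele_decon" in merged.columns and "coded_allele_ref" in merged.columns:
        both = (merged["coded_allele_decon"].astype(str) != "") & (
            merged["coded_allele_ref"].astype(str) != ""
        )
        flip = both & (
            merged["coded_allele_decon"].astype(str)
            != merged["coded_allele_ref"].astype(str)
        )
        effect = np.where(flip, -effect, effect)
    direction = merged["direction"].to_numpy(dtype=float)
    nonzero = (direction != 0) & (effect != 0)
    concordant = int(np.sum(np.sign(direction[nonzero]) == np.sign(effect[nonzero])))
    discordant = int(nonzero.sum()) - concordant
    total = concordant + discordant
    return {
        "n_concordant": concordant,
        "n_discordant": discordant,
        "n_excluded_zero": int((~nonzero).sum()),
        "rate": concordant / total if total else float("nan"),
    }


def concordance_fisher(a: dict, b: dict, correction_m: int = 1) -> float:
    """Two-sided Fisher exact test between two concordant/discordant counts,
    Bonferroni-multiplied by ``correction_m`` and capped at 1."""
    table = [
        [a["n_concordant"], a["n_discordant"]],
        [b["n_concordant"], b["n_discordant"]],
    ]
    if sum(table[0]) == 0 or sum(table[1]) == 0:
        raise ValueError("both groups need nonzero totals")
    _, p = scipy.stats.fisher_exact(table, alternative="two-sided")
    return min(1.0, float(p) * correction_m)


def effect_size_comparison(
    group_a: Sequence[float],
    group_b: Sequence[float],
    test: str = "wilcoxon_ranksum",
) -> float:
    """Two-sided p-value comparing two groups of (absolute) effect sizes.

    ``wilcoxon_ranksum``: Mann-Whitney U; ``t_test``: Welch t;
    ``f_variance``: variance-ratio F test.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if test == "wilcoxon_ranksum":
        # exact null distribution for small tie-free samples, else asymptotic
        pooled = np.concatenate([a, b])
        small = len(a) <= 20 and len(b) <= 20
        method = "exact" if small and len(np.unique(pooled)) == len(pooled) else "asymptotic"
        return float(
            scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )
    if test == "t_test":
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise ValueError("both groups constant; t test undefined")
        return float(scipy.stats.ttest_ind(a, b, equal_var=False).pvalue)
    if test == "f_variance":
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va == 0 or vb == 0:
            raise ValueError("constant group; variance-ratio test undefined")
        f = va / vb
        dfa, dfb = len(a) - 1, len(b) - 1
        p = 2.0 * min(
            scipy.stats.f.sf(f, dfa, dfb), scipy.stats.f.cdf(f, dfa, dfb)
        )
        return float(min(1.0, p))
    raise ValueError(f"unknown test {test!r}")


def enrichment_fisher(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> tuple[float, float]:
    """Two-sided Fisher exact test of overlap between two gene sets within a
    universe; returns (odds_ratio, p).  The odds ratio may be 0 or inf."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sa, sb = set(set_a), set(set_b)
    if not sa <= uni or not sb <= uni:
        raise ValueError("sets must be subsets of the universe")
    n11 = len(sa & sb)
    n10 = len(sa - sb)
    n01 = len(sb - sa)
    n00 = len(uni) - n11 - n10 - n01
    odds, p = scipy.stats.fisher_exact([[n11, n10], [n01, n00]], "two-sided")
    if math.isnan(odds):
        odds = float("inf") if n11 > 0 else 0.0
    return float(odds), float(p)
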