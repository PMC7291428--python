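"""Typed matrix containers shared across the pipeline.

All containers wrap a :class:`pandas.DataFrame` and validate the invariants
of their role (orientation, uniqueness of identifiers, value ranges).  The
expression container additionally carries a ``state`` tag recording which
normalization steps have been applied, so downstream consumers can refuse
input that was prepared for the other branch of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

EXPRESSION_STATES = (
    "raw_counts",
    "tmm",
    "tmm_log2",
    "tmm_log2_scaled",
    "corrected_linear",
)


def _check_unique(ids: Iterable[str], what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values plus a normalization-state tag."""

    data: pd.DataFrame  # genes x samples
    state: str = "raw_counts"
    zero_variance_genes: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in EXPRESSION_STATES:
            raise ValueError(f"unknown expression state {self.state!r}")
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.state in ("raw_counts", "corrected_linear") and (vals < 0).any():
            raise ValueError(f"negative values not allowed in state {self.state!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.data.loc[:, list(samples)],
            state=self.state,
            zero_variance_genes=self.zero_variance_genes,
            meta=dict(self.meta),
        )


@dataclass
class CovariateTable:
    """Sample-level covariates (numeric or categorical columns)."""

    data: pd.DataFrame  # samples x covariates

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "covariate names")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def aligned_to(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        """Reorder rows to ``sample_ids``; missing samples or NA values are errors."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValueError(f"covariate table lacks samples: {missing[:5]}")
        sub = self.data.loc[list(sample_ids)]
        if sub.isna().to_numpy().any():
            bad = sub.columns[sub.isna().any(axis=0)].tolist()
            raise ValueError(f"missing covariate values after alignment in: {bad}")
        return sub


@dataclass
class CellQuantMatrix:
    """Sample-by-cell-type quantities; measured (FACS-like) or predicted."""

    data: pd.DataFrame  # samples x cell types
    kind: str = "measured"  # {measured, predicted}

    def __post_init__(self) -> None:
        if self.kind not in ("measured", "predicted"):
            raise ValueError(f"unknown kind {self.kind!r}")
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "cell types")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("cell quantities contain non-finite values")
        if self.kind == "measured" and (vals < 0).any():
            raise ValueError("measured cell quantities must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class GenotypeDosageMatrix:
    """SNP-by-sample dosages in [0, 2] (hard calls or imputed)."""

    data: pd.DataFrame  # snps x samples

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "snp ids")
        _check_unique(self.data.columns, "sample ids")
        vals = self.data.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if ((finite < 0) | (finite > 2)).any():
            raise ValueError("dosages must lie within [0, 2]")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ScaledProportions:
    """Sample-by-cell-type proportions rescaled so each row sums to 100."""

    data: pd.DataFrame  # samples x cell types

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "cell types")
        vals = self.data.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("scaled proportions must be >= 0")
        sums = vals.sum(axis=1)
        if np.abs(sums - 100.0).max() > 1e-6:
            raise ValueError("each sample's proportions must sum to 100")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)


def common_samples(*objs) -> list[str]:
    """Ordered intersection of sample ids, following the first argument's order."""
    first = objs[0].sample_ids
    keep = set(first)
    for o in objs[1:]:
        keep &= set(o.sample_ids)
    return [s for s in first if s in keep]
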