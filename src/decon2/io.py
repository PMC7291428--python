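"""Readers and writers for the TSV/VCF/JSON artifacts used by the pipeline.

TSV is the canonical tabular format: UTF-8, tab-separated, '.' decimal
separator, first column the row identifier.  Readers are gzip-transparent
(pandas handles .gz paths) and validate shape, uniqueness and NA policy per
matrix kind.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import (
    CellQuantMatrix,
    CovariateTable,
    ExpressionMatrix,
    GenotypeDosageMatrix,
)

MATRIX_KINDS = ("expression", "genotype", "proportions", "covariates")

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_pairs",
    "read_positions",
    "read_vcf_dosages",
]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated row id(s): {dups[:5]}")
    if pd.Index(df.columns).has_duplicates:
        raise ValueError(f"{path}: duplicated column ids")
    return df


def _numeric(df: pd.DataFrame, path, allow_na: bool) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce").astype(float)
    bad = out.isna() & ~df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at line {r + 2}, "
            f"column {df.columns[c]!r}"
        )
    if not allow_na and out.isna().to_numpy().any():
        r, c = np.argwhere(out.isna().to_numpy())[0]
        raise ValueError(f"{path}: missing value at line {r + 2}, column {df.columns[c]!r}")
    return out


def read_matrix(path: str | Path, kind: str, **kwargs):
    """Read a typed matrix from TSV.

    Kinds: ``expression`` (genes x samples) -> ExpressionMatrix,
    ``genotype`` (snps x samples) -> GenotypeDosageMatrix,
    ``proportions`` (samples x cell types) -> CellQuantMatrix,
    ``covariates`` (samples x covariates) -> CovariateTable.
    """
    if kind not in MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}")
    df = _read_tsv(path)
    if kind == "expression":
        return ExpressionMatrix(
            _numeric(df, path, allow_na=False),
            state=kwargs.get("state", "raw_counts"),
        )
    if kind == "genotype":
        return GenotypeDosageMatrix(_numeric(df, path, allow_na=False))
    if kind == "proportions":
        return CellQuantMatrix(
            _numeric(df, path, allow_na=False), kind=kwargs.get("quant_kind", "measured")
        )
    # covariates: keep categorical columns as strings; NA rejected at alignment
    return CovariateTable(df.convert_dtypes())


def write_matrix(
    df: pd.DataFrame, path: str | Path, index_name: str = "id", float_format: str = "%.10g"
) -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format=float_format)


def read_pairs(path: str | Path) -> pd.DataFrame:
    """SNP-gene pair list with columns snp_id, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("snp_id", "gene_id") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: pair list lacks columns {missing}")
    return df[["snp_id", "gene_id"]]


def read_positions(path: str | Path) -> pd.DataFrame:
    """Feature positions: feature_id, chrom, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("feature_id", "chrom", "start", "end") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: position table lacks columns {missing}")
    df["feature_id"] = df["feature_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def read_vcf_dosages(path: str | Path) -> GenotypeDosageMatrix:
    """Extract a dosage matrix from a VCF: the DS FORMAT field when present,
    otherwise hard-called GT counted as 0/1/2 copies of the ALT allele."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, rows = [], []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            row = np.asarray(ds, dtype=float).reshape(-1)
        else:
            # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012=False maps 3->unknown)
            row = np.array(
                [0.0 if t == 0 else 1.0 if t == 1 else 2.0 if t == 3 else np.nan
                 for t in var.gt_types]
            )
        snp_ids.append(vid)
        rows.append(row)
    return GenotypeDosageMatrix(
        pd.DataFrame(np.vstack(rows), index=snp_ids, columns=samples)
    )
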