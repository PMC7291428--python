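from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from decon2.matrices import (
    CellQuantMatrix,
    ExpressionMatrix,
    GenotypeDosageMatrix,
    ScaledProportions,
)


def expression_from_array(
    arr, state="raw_counts", gene_prefix="gene", sample_prefix="sample"
) -> ExpressionMatrix:
    arr = np.asarray(arr, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=[f"{gene_prefix}{i}" for i in range(arr.shape[0])],
            columns=[f"{sample_prefix}{j}" for j in range(arr.shape[1])],
        ),
        state=state,
    )


def proportions_from_array(arr, cell_types=None, kind="measured") -> CellQuantMatrix:
    arr = np.asarray(arr, dtype=float)
    cell_types = cell_types or [f"ct{j}" for j in range(arr.shape[1])]
    return CellQuantMatrix(
        pd.DataFrame(
            arr,
            index=[f"sample{j}" for j in range(arr.shape[0])],
            columns=cell_types,
        ),
        kind=kind,
    )


def scaled_from_dirichlet(n, conc, seed=0, cell_types=None) -> ScaledProportions:
    rng = np.random.default_rng(seed)
    conc = np.asarray(conc, dtype=float)
    vals = rng.dirichlet(conc, size=n) * 100.0
    cell_types = cell_types or [f"ct{j}" for j in range(len(conc))]
    return ScaledProportions(
        pd.DataFrame(
            vals, index=[f"sample{j}" for j in range(n)], columns=cell_types
        )
    )


def genotypes_from_array(arr, snp_prefix="snp") -> GenotypeDosageMatrix:
    arr = np.asarray(arr, dtype=float)
    return GenotypeDosageMatrix(
        pd.DataFrame(
            arr,
            index=[f"{snp_prefix}{i}" for i in range(arr.shape[0])],
            columns=[f"sample{j}" for j in range(arr.shape[1])],
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
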