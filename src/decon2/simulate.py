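"""Synthetic data generation with exported ground truth.

Generates Hardy-Weinberg genotypes, Dirichlet cell proportions, bulk
expression that follows the proportion-weighted interaction model (with
cell-type-restricted genotype effects and Gaussian noise on the linear
scale), and paired raw-count / measured-proportion data for training the
cell-proportion models.  Everything is reproducible bit-exactly from the
configuration's seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import CellQuantMatrix, ExpressionMatrix, GenotypeDosageMatrix

log = logging.getLogger(__name__)

# six-type whole-blood panel; granulocyte-dominant (~70% of leukocytes)
DEFAULT_CELL_TYPES = ("granulocyte", "monoCD14", "CD4T", "CD8T", "B", "NK")
DEFAULT_CONCENTRATIONS = (70.0, 15.0, 6.0, 5.0, 3.0, 1.0)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_genotypes",
    "simulate_proportions",
    "simulate_bulk",
    "simulate_facs_training",
]


@dataclass
class SimulationConfig:
    n_samples: int = 200
    n_genes: int = 50
    n_snps: int = 50
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    maf: float | tuple[float, ...] = 0.3
    # (gene index, cell type) -> signed interaction effect; negative values
    # are realized under the swapped dosage orientation
    interactions: dict = field(default_factory=dict)
    beta_range: tuple[float, float] = (1.0, 5.0)
    noise_sd: float = 0.1
    # raw-count / measured-proportion training pair
    n_signature_genes: int = 5
    n_background_genes: int = 50
    signature_free: tuple[str, ...] = ()
    count_noise: str = "gaussian"  # or "nb"
    nb_dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cell_types) != len(self.concentrations):
            raise ValueError("cell_types and concentrations must align")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("Dirichlet concentrations must be > 0")
        mafs = self.maf if isinstance(self.maf, (tuple, list)) else (self.maf,)
        if any(not (0.0 < m <= 0.5) for m in mafs):
            raise ValueError("maf must lie in (0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Realized ground truth of one bulk simulation."""

    proportions: pd.DataFrame  # samples x cell types, scaled to 100
    genotypes: pd.DataFrame  # snps x samples
    betas: pd.DataFrame  # genes x cell types
    gammas: pd.DataFrame  # long: gene_id, snp_id, cell_type, gamma (signed)
    pairs: pd.DataFrame  # gene_id, snp_id tested pairs
    noise_sd: float
    seed: int
    n_clipped: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "n_clipped": self.n_clipped,
            "betas": self.betas.to_dict(),
            "gammas": self.gammas.to_dict(orient="records"),
            "pairs": self.pairs.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def simulate_genotypes(
    n: int,
    maf_vector,
    seed: int = 0,
    snp_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> GenotypeDosageMatrix:
    """Hard-call genotypes drawn Binomial(2, maf) per SNP (HWE sampling)."""
    maf = np.atleast_1d(np.asarray(maf_vector, dtype=float))
    if ((maf <= 0) | (maf > 0.5)).any():
        raise ValueError("maf must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, maf[:, np.newaxis], size=(len(maf), n)).astype(float)
    snp_ids = snp_ids or [f"snp{i}" for i in range(len(maf))]
    sample_ids = sample_ids or [f"sample{j}" for j in range(n)]
    return GenotypeDosageMatrix(pd.DataFrame(dosages, index=snp_ids, columns=sample_ids))


def simulate_proportions(
    n: int,
    concentrations,
    seed: int = 0,
    cell_types: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> CellQuantMatrix:
    """Dirichlet proportion draws scaled to percentages (rows sum to 100)."""
    conc = np.asarray(concentrations, dtype=float)
    if (conc <= 0).any():
        raise ValueError("concentrations must be > 0")
    rng = np.random.default_rng(seed)
    props = rng.dirichlet(conc, size=n) * 100.0
    cell_types = cell_types or [f"ct{j}" for j in range(len(conc))]
    sample_ids = sample_ids or [f"sample{j}" for j in range(n)]
    return CellQuantMatrix(
        pd.DataFrame(props, index=sample_ids, columns=cell_types), kind="measured"
    )


def simulate_bulk(
    config: SimulationConfig,
    props: CellQuantMatrix | None = None,
    geno: GenotypeDosageMatrix | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Bulk expression following the proportion-weighted interaction model.

    Per gene i (paired cyclically with SNP i mod n_snps):

        y_j = sum_k c_jk * (beta_ik + gamma_ik * g_enc,j) + noise

    with c in percent, signed gammas from ``config.interactions`` realized
    via the matching dosage orientation, and Gaussian noise of sd
    ``noise_sd``.  Negative implied values are clipped at 0 (count logged).
    ``props``/``geno`` may be supplied to share a cohort with other
    generators; otherwise they are drawn here.
    """
    rng = np.random.default_rng(config.seed)
    sample_ids = [f"sample{j}" for j in range(config.n_samples)]
    gene_ids = [f"gene{i}" for i in range(config.n_genes)]
    snp_ids = [f"snp{i}" for i in range(config.n_snps)]
    maf = (
        np.asarray(config.maf, dtype=float)
        if isinstance(config.maf, (tuple, list))
        else np.full(config.n_snps, float(config.maf))
    )
    g_seed, p_seed = int(rng.integers(2**31)), int(rng.integers(2**31))
    if geno is None:
        geno = simulate_genotypes(
            config.n_samples, maf, seed=g_seed, snp_ids=snp_ids, sample_ids=sample_ids
        )
    else:
        sample_ids = list(geno.sample_ids)
        snp_ids = list(geno.snp_ids)
    if props is None:
        props = simulate_proportions(
            config.n_samples,
            config.concentrations,
            seed=p_seed,
            cell_types=list(config.cell_types),
            sample_ids=sample_ids,
        )
    k = len(config.cell_types)
    c = props.data.to_numpy()
    lo, hi = config.beta_range
    betas = rng.uniform(lo, hi, size=(config.n_genes, k))
    gamma_rows = []
    expr = np.zeros((config.n_genes, config.n_samples))
    pair_rows = []
    n_clipped = 0
    for i, gene in enumerate(gene_ids):
        snp = snp_ids[i % config.n_snps]
        pair_rows.append({"snp_id": snp, "gene_id": gene})
        g = geno.data.loc[snp].to_numpy()
        y = c @ betas[i]
        for j, ct in enumerate(config.cell_types):
            gamma = float(config.interactions.get((i, ct), 0.0))
            if gamma == 0.0:
                continue
            g_enc = g if gamma > 0 else 2.0 - g
            y = y + abs(gamma) * g_enc * c[:, j]
            gamma_rows.append(
                {"gene_id": gene, "snp_id": snp, "cell_type": ct, "gamma": gamma}
            )
        if config.noise_sd > 0:
            y = y + rng.normal(0.0, config.noise_sd, size=len(y))
        neg = y < 0
        n_clipped += int(neg.sum())
        y[neg] = 0.0
        expr[i] = y
    if n_clipped:
        log.info("clipped %d negative bulk values to 0", n_clipped)
    truth = SyntheticTruth(
        proportions=props.data.div(props.data.sum(axis=1), axis=0) * 100.0,
        genotypes=geno.data,
        betas=pd.DataFrame(betas, index=gene_ids, columns=list(config.cell_types)),
        gammas=pd.DataFrame(
            gamma_rows, columns=["gene_id", "snp_id", "cell_type", "gamma"]
        ),
        pairs=pd.DataFrame(pair_rows, columns=["snp_id", "gene_id"]),
        noise_sd=config.noise_sd,
        seed=config.seed,
        n_clipped=n_clipped,
    )
    em = ExpressionMatrix(
        pd.DataFrame(expr, index=gene_ids, columns=sample_ids),
        state="corrected_linear",
    )
    return em, truth


def simulate_facs_training(
    config: SimulationConfig,
    props: CellQuantMatrix | None = None,
) -> tuple[ExpressionMatrix, CellQuantMatrix, dict[str, list[str]]]:
    """Paired raw-count expression and measured proportions for model training.

    Each cell type (unless listed in ``signature_free``) gets
    ``n_signature_genes`` genes whose counts track its proportion linearly
    (distinct scales, multiplicative noise of sd ``noise_sd``); the remaining
    ``n_background_genes`` genes are proportion-independent background.
    Returns (expression, measured proportions, true signature-gene map).
    """
    rng = np.random.default_rng(config.seed)
    sample_ids = [f"sample{j}" for j in range(config.n_samples)]
    p_seed = int(rng.integers(2**31))
    if props is None:
        props = simulate_proportions(
            config.n_samples,
            config.concentrations,
            seed=p_seed,
            cell_types=list(config.cell_types),
            sample_ids=sample_ids,
        )
    else:
        sample_ids = list(props.sample_ids)
    rows = []
    gene_ids = []
    signatures: dict[str, list[str]] = {ct: [] for ct in config.cell_types}
    for j, ct in enumerate(config.cell_types):
        if ct in config.signature_free:
            continue
        for s in range(config.n_signature_genes):
            gene = f"sig_{ct}_{s}"
            gene_ids.append(gene)
            signatures[ct].append(gene)
            scale = rng.uniform(50.0, 500.0)
            mu = scale * props.data[ct].to_numpy()
            rows.append(_noisy_counts(mu, config, rng))
    for b in range(config.n_background_genes):
        gene = f"bg_{b}"
        gene_ids.append(gene)
        mu = np.full(config.n_samples, rng.uniform(100.0, 5000.0))
        rows.append(_noisy_counts(mu, config, rng, force_noise=True))
    expr = ExpressionMatrix(
        pd.DataFrame(np.vstack(rows), index=gene_ids, columns=sample_ids),
        state="raw_counts",
    )
    return expr, props, signatures


def _noisy_counts(
    mu: np.ndarray, config: SimulationConfig, rng: np.random.Generator,
    force_noise: bool = False,
) -> np.ndarray:
    """Non-negative counts around mu; Gaussian multiplicative noise by default,
    negative-binomial sampling in "nb" mode."""
    if config.count_noise == "nb":
        r = config.nb_dispersion
        p = r / (r + np.maximum(mu, 1e-9))
        return rng.negative_binomial(r, p).astype(float)
    sd = config.noise_sd if (config.noise_sd > 0 or not force_noise) else 0.01
    out = mu * (1.0 + rng.normal(0.0, sd, size=len(mu))) if sd > 0 else mu.copy()
    return np.clip(out, 0.0, None)


def write_simulation(
    config: SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write one coherent simulated cohort (TSVs + truth.json) to a directory.

    A single set of samples shares its proportions between the
    signature/background genes (for training the proportion models) and the
    interaction-model genes (for eQTL deconvolution), so the staged pipeline
    can run end-to-end on the output.  A ready-to-use ``run_config.yaml``
    pointing at the written files is included.
    """
    import yaml

    from . import io as dio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sample_ids = [f"sample{j}" for j in range(config.n_samples)]
    props = simulate_proportions(
        config.n_samples,
        config.concentrations,
        seed=int(rng.integers(2**31)),
        cell_types=list(config.cell_types),
        sample_ids=sample_ids,
    )
    bulk, truth = simulate_bulk(config, props=props)
    facs_expr, _, signatures = simulate_facs_training(config, props=props)
    # one counts matrix: signature/background genes plus the interaction genes
    counts = pd.concat([facs_expr.data, bulk.data])
    paths = {
        "counts": out / "counts.tsv",
        "eqtl_expression": out / "eqtl_expression.tsv",
        "genotypes": out / "genotypes.tsv",
        "proportions": out / "proportions.tsv",
        "pairs": out / "pairs.tsv",
        "truth": out / "truth.json",
        "signatures": out / "signatures.json",
        "sim_config": out / "sim_config.json",
        "run_config": out / "run_config.yaml",
    }
    dio.write_matrix(counts, paths["counts"], index_name="gene_id")
    dio.write_matrix(bulk.data, paths["eqtl_expression"], index_name="gene_id")
    dio.write_matrix(truth.genotypes, paths["genotypes"], index_name="snp_id")
    dio.write_matrix(truth.proportions, paths["proportions"], index_name="sample_id")
    truth.pairs.to_csv(paths["pairs"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    paths["signatures"].write_text(json.dumps(signatures, indent=2, sort_keys=True))
    cfg = asdict(config)
    cfg["interactions"] = {f"{i}|{ct}": v for (i, ct), v in config.interactions.items()}
    paths["sim_config"].write_text(json.dumps(cfg, indent=2, sort_keys=True))
    run_cfg = {
        "counts": "counts.tsv",
        "facs_counts": "counts.tsv",
        "facs_proportions": "proportions.tsv",
        "genotypes": "genotypes.tsv",
        "pairs": "pairs.tsv",
        "cell_types": list(config.cell_types),
        "seed": config.seed,
    }
    paths["run_config"].write_text(yaml.safe_dump(run_cfg, sort_keys=True))
    return paths
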