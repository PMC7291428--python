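"""End-to-end orchestration: prep -> cell train/predict -> cis -> eqtl -> eval.

A run is driven by a :class:`RunConfig` (YAML file or keyword arguments).
Every stage writes its artifacts under the output directory, and a manifest
(JSON, no timestamps so reruns are byte-identical) records inputs,
parameters, seed, package version and the stages completed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as dio
from .cismap import cis_pairs, map_cis_eqtls, snp_filters
from .deconcell import fit_elastic_net, predict_proportions
from .deconeqtl import deconvolute, fdr_per_celltype, scale_proportions
from .prep import prepare_for_cell, prepare_for_eqtl

log = logging.getLogger(__name__)

STAGES = ("prep", "cell", "cis", "eqtl", "eval")


@dataclass
class RunConfig:
    """Validated parameters of one pipeline run.

    Defaults carry the published method's stated values: MAF >= 0.01,
    HWE p >= 1e-4, 250 kb cis window, FDR 0.05, 100 CV iterations with a
    0.7 training fraction and a 0.8 signature-selection threshold.
    """

    counts: str = ""
    facs_counts: str = ""  # raw counts of the training cohort
    facs_proportions: str = ""  # measured proportions of the training cohort
    genotypes: str = ""
    covariates: str = ""
    proportions: str = ""  # precomputed proportions; empty -> predict
    pairs: str = ""  # SNP-gene list; empty -> run the cis mapper
    snp_positions: str = ""
    gene_positions: str = ""
    cell_types: tuple[str, ...] = ()
    maf_min: float = 0.01
    hwe_p_min: float = 0.0001
    window: int = 250_000
    fdr_alpha: float = 0.05
    cv_iterations: int = 100
    train_frac: float = 0.7
    signature_threshold: float = 0.8
    seed: int = 42
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must lie in [0, 0.5]")
        if not (0.0 <= self.hwe_p_min <= 1.0):
            raise ValueError("hwe_p_min must lie in [0, 1]")
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if not (0.0 < self.fdr_alpha <= 1.0):
            raise ValueError("fdr_alpha must lie in (0, 1]")
        if self.cv_iterations < 1:
            raise ValueError("cv_iterations must be >= 1")
        if not (0.0 < self.train_frac < 1.0):
            raise ValueError("train_frac must lie in (0, 1)")
        if not (0.0 <= self.signature_threshold <= 1.0):
            raise ValueError("signature_threshold must lie in [0, 1]")
        self.cell_types = tuple(self.cell_types)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        base = Path(path).parent
        cfg = cls(**raw)
        # resolve relative paths against the config file location
        for f in dataclasses.fields(cls):
            v = getattr(cfg, f.name)
            if f.name.endswith(("counts", "genotypes", "covariates", "proportions",
                                "pairs", "positions")) and isinstance(v, str) and v:
                p = Path(v)
                if not p.is_absolute():
                    setattr(cfg, f.name, str(base / p))
        return cfg


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the staged workflow; returns the manifest dict.

    Partial artifacts are retained on failure and the manifest records the
    failing stage before the exception propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages": [],
        "artifacts": {},
        "failure": None,
    }

    def _save() -> None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    try:
        # ---- prep -------------------------------------------------------
        bulk_raw = dio.read_matrix(config.counts, "expression", state="raw_counts")
        covs = (
            dio.read_matrix(config.covariates, "covariates")
            if config.covariates
            else None
        )
        bulk_scaled = prepare_for_cell(bulk_raw)
        bulk_linear = prepare_for_eqtl(bulk_raw, covs)
        dio.write_matrix(bulk_scaled.data, out / "expression_scaled.tsv", "gene_id")
        dio.write_matrix(bulk_linear.data, out / "expression_corrected.tsv", "gene_id")
        manifest["artifacts"]["expression_scaled"] = "expression_scaled.tsv"
        manifest["artifacts"]["expression_corrected"] = "expression_corrected.tsv"
        manifest["stages"].append("prep")
        _save()

        # ---- cell: train on the paired cohort, predict on the bulk ------
        if config.proportions:
            props = dio.read_matrix(config.proportions, "proportions")
        else:
            facs_expr = dio.read_matrix(
                config.facs_counts, "expression", state="raw_counts"
            )
            facs_props = dio.read_matrix(config.facs_proportions, "proportions")
            facs_scaled = prepare_for_cell(facs_expr)
            cell_types = config.cell_types or tuple(facs_props.cell_types)
            models = []
            model_dir = out / "models"
            model_dir.mkdir(exist_ok=True)
            for ct in cell_types:
                model = fit_elastic_net(
                    facs_scaled, facs_props, ct, seed=config.seed
                )
                model.to_json(model_dir / f"{ct}.json")
                models.append(model)
            props = predict_proportions(models, bulk_scaled)
            dio.write_matrix(
                props.data, out / "predicted_proportions.tsv", "sample_id"
            )
            manifest["artifacts"]["predicted_proportions"] = "predicted_proportions.tsv"
        manifest["stages"].append("cell")
        _save()

        # ---- cis (optional): derive the pair list -----------------------
        geno = dio.read_matrix(config.genotypes, "genotype")
        if config.pairs:
            pairs = dio.read_pairs(config.pairs)
            manifest["stages"].append("cis")  # provided externally; recorded as done
        else:
            snp_pos = dio.read_positions(config.snp_positions)
            gene_pos = dio.read_positions(config.gene_positions)
            keep = snp_filters(
                geno, maf_min=config.maf_min, hwe_p_min=config.hwe_p_min
            )
            snp_pos = snp_pos[snp_pos["feature_id"].isin(keep)]
            candidates = cis_pairs(snp_pos, gene_pos, window=config.window)
            _, top = map_cis_eqtls(
                bulk_linear, geno, candidates, fdr_alpha=config.fdr_alpha
            )
            pairs = top[["snp_id", "gene_id"]]
            top.to_csv(out / "top_effects.tsv", sep="\t", index=False)
            manifest["artifacts"]["top_effects"] = "top_effects.tsv"
            manifest["stages"].append("cis")
        _save()

        # ---- eqtl -------------------------------------------------------
        cell_types = list(config.cell_types or props.cell_types)
        scaled = scale_proportions(props, cell_types)
        results = fdr_per_celltype(deconvolute(pairs, bulk_linear, geno, scaled))
        frame = results.to_frame()
        frame.to_csv(
            out / "decon_results.tsv", sep="\t", index=False, float_format="%.10g"
        )
        manifest["artifacts"]["decon_results"] = "decon_results.tsv"
        manifest["stages"].append("eqtl")
        _save()

        # ---- eval: significant-interaction summary per cell type --------
        summary_rows = []
        for ct in cell_types:
            col = f"{ct}_fdr"
            n_sig = int((frame[col] <= config.fdr_alpha).sum()) if col in frame else 0
            summary_rows.append({"cell_type": ct, "n_tested": len(frame), "n_significant": n_sig})
        summary = pd.DataFrame(summary_rows)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        manifest["artifacts"]["summary"] = "summary.tsv"
        manifest["stages"].append("eval")
        _save()
    except Exception as exc:
        manifest["failure"] = {
            "stage": STAGES[len(manifest["stages"])] if len(manifest["stages"]) < len(STAGES) else "unknown",
            "error": str(exc),
        }
        _save()
        raise
    return manifest
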