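"""End-to-end orchestration: preprocess -> cluster -> dropout -> impute.

A ``RunConfig`` fixes every input, output and seed; ``run_impute`` executes
the stages in order, optionally caching the clustering and
dropout-probability intermediates keyed by a hash of the stage-relevant
configuration, and writes a machine-readable JSON report (seeds, cluster
sizes, per-sub-model training losses, number of imputed entries).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .clustering import cluster_cells
from .dropout import DropoutProbMatrix, compute_dropout_matrix
from .imputer import ImputationConfig, impute_matrix
from .matrix import (ExpressionMatrix, filter_empty, load_matrix,
                     log_transform, normalize_library, save_matrix)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything an end-to-end imputation run needs."""

    input_path: str
    output_path: str
    input_format: str = "csv"
    output_format: str | None = None   # defaults to the input format
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    tsne_dims: int = 3
    tsne_seed: int = 1
    k_max: int | None = None
    log_transform: bool = True         # False = no-log variant
    counts_out: bool = False           # back-transform output to counts space
    dp_output_path: str | None = None
    labels_output_path: str | None = None
    report_path: str | None = None
    cache_dir: str | None = None

    def stage_hash(self) -> str:
        """Hash of the fields that determine clustering and DP results."""
        key = json.dumps({
            "input": str(self.input_path), "fmt": self.input_format,
            "dims": self.tsne_dims, "seed": self.tsne_seed,
            "k_max": self.k_max, "log": self.log_transform,
            "T": self.imputation.dp_threshold,
        }, sort_keys=True)
        return hashlib.sha256(key.encode()).hexdigest()[:16]


def preprocess_stage(m: ExpressionMatrix, log: bool = True) -> ExpressionMatrix:
    out = normalize_library(filter_empty(m))
    return log_transform(out) if log else out


def run_impute(cfg: RunConfig) -> dict:
    """Execute the full pipeline and return the run report."""
    report: dict = {"version": __version__, "stages": {}}
    try:
        raw = load_matrix(cfg.input_path, cfg.input_format)
    except Exception as exc:
        raise RuntimeError(f"[load] {exc}") from exc

    try:
        m = preprocess_stage(raw, log=cfg.log_transform)
    except Exception as exc:
        raise RuntimeError(f"[preprocess] {exc}") from exc
    report["stages"]["preprocess"] = {
        "n_genes": m.n_genes, "n_cells": m.n_cells, "space": m.space,
    }

    cache = Path(cfg.cache_dir) / f"stage_{cfg.stage_hash()}.npz" if cfg.cache_dir else None
    labels = dp_values = None
    if cache is not None and cache.exists():
        with np.load(cache) as z:
            labels, dp_values = z["labels"], z["dp"]
        logger.info("loaded cached clustering/DP from %s", cache)

    try:
        if labels is None:
            _, clustering = cluster_cells(
                m, dims=cfg.tsne_dims, seed=cfg.tsne_seed, k_max=cfg.k_max
            )
            labels = clustering.labels
    except Exception as exc:
        raise RuntimeError(f"[cluster] {exc}") from exc
    report["stages"]["cluster"] = {
        "k": int(labels.max()) + 1,
        "sizes": np.bincount(labels).tolist(),
        "tsne_seed": cfg.tsne_seed,
    }

    try:
        if dp_values is None:
            from .clustering import CellClustering
            k = int(labels.max()) + 1
            cc = CellClustering(labels, k, np.zeros((k, cfg.tsne_dims)))
            dp = compute_dropout_matrix(m, cc, threshold=cfg.imputation.dp_threshold)
            dp_values = dp.dp
        dp = DropoutProbMatrix(dp_values, list(m.gene_ids), list(m.cell_ids),
                               cfg.imputation.dp_threshold)
    except Exception as exc:
        raise RuntimeError(f"[dropout] {exc}") from exc
    report["stages"]["dropout"] = {
        "mean_dp": float(dp.dp.mean()),
        "threshold": cfg.imputation.dp_threshold,
    }

    if cache is not None and not cache.exists():
        cache.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(cache, labels=labels, dp=dp.dp)

    try:
        imputed, imp_report = impute_matrix(m, dp, labels, cfg.imputation)
    except Exception as exc:
        raise RuntimeError(f"[impute] {exc}") from exc
    report["stages"]["impute"] = imp_report
    if cfg.counts_out:
        # undo log then library normalisation, using the original filtered
        # library sizes
        filtered = filter_empty(raw)
        libsizes = filtered.values.sum(axis=0)
        vals = np.expm1(imputed.values) if imputed.space == "log_cpm" \
            else imputed.values
        vals = vals * (libsizes[None, :] / 1e6)
        imputed = ExpressionMatrix(vals, list(imputed.gene_ids),
                                   list(imputed.cell_ids), "counts")
    report["space"] = imputed.space
    report["seeds"] = {"tsne": cfg.tsne_seed, "imputation": cfg.imputation.seed}

    out_fmt = cfg.output_format or cfg.input_format
    save_matrix(imputed, cfg.output_path, out_fmt)
    if cfg.dp_output_path:
        save_matrix(
            ExpressionMatrix(dp.dp, list(m.gene_ids), list(m.cell_ids), "cpm"),
            cfg.dp_output_path, "tsv",
        )
    if cfg.labels_output_path:
        with open(cfg.labels_output_path, "w") as fh:
            fh.write("cell_id\tcluster\n")
            for cid, lab in zip(m.cell_ids, labels):
                fh.write(f"{cid}\t{lab}\n")
    if cfg.report_path:
        with open(cfg.report_path, "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def impute_in_memory(
    raw: ExpressionMatrix,
    cfg: ImputationConfig | None = None,
    log: bool = True,
    tsne_seed: int = 1,
    k_max: int | None = None,
) -> tuple[ExpressionMatrix, np.ndarray, DropoutProbMatrix, dict]:
    """Library-level pipeline on an in-memory counts matrix.

    Returns (imputed matrix in log/cpm space, cluster labels, DP matrix,
    report).
    """
    cfg = cfg or ImputationConfig()
    m = preprocess_stage(raw, log=log)
    _, clustering = cluster_cells(m, seed=tsne_seed, k_max=k_max)
    dp = compute_dropout_matrix(m, clustering, threshold=cfg.dp_threshold)
    imputed, report = impute_matrix(m, dp, clustering.labels, cfg)
    return imputed, clustering.labels, dp, report
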