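"""End-to-end orchestration: standardize -> log -> screen -> penalized fit
-> interactome -> scores, with optional prediction/overlap/screen stages.

Every artifact is written into the run directory and recorded, with a
SHA-256 content hash, in ``summary.json``. A rerun with the same config is
bit-identical (no timestamps enter any output)."""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .matrixio import read_matrix, write_matrix, read_gene_map
from .preprocess import standardize, log_transform
from .univariate import fit_all_pairs, call_significant
from .multivariate import fit_all_multivariate, write_multivariate_fits
from .interactome import two_way_cluster, export_network, write_sif, suggest_k
from .scores import (
    compute_scores,
    cluster_patients,
    cluster_vs_clinical,
    screen_zscore,
    screen_consistency,
)
from .targets import load_targets, putative_direct, write_pairs

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("triomics")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self._t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise PipelineError(f"stage {self.name!r} failed: {exc}") from exc
        log.info("stage %s: done in %.2fs", self.name, time.perf_counter() - self._t0)


def _read_clinical(path) -> dict[str, dict[str, str]]:
    """Long-format TSV (sample_id, variable, value) -> variable -> sample -> value."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, dict[str, str]] = {}
    for _, row in frame.iterrows():
        out.setdefault(str(row.iloc[1]), {})[str(row.iloc[0])] = str(row.iloc[2])
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict (also written as
    ``summary.json`` in the output directory)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config": config.to_dict(),
        "versions": {"triomics": __version__},
    }
    artifacts: list[Path] = []

    with _Stage("load"):
        protein_raw = read_matrix(config.proteins, "protein")
        mrna_raw = read_matrix(config.mrna, "mRNA")
        mirna_raw = read_matrix(config.mirna, "miRNA")
        gene_map = read_gene_map(config.gene_map)

    with _Stage("preprocess"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            protein_std, prot_params = standardize(protein_raw, config.delta0)
            mrna_std, mrna_params = standardize(mrna_raw, config.delta0)
            mirna_std, mirna_params = standardize(mirna_raw, config.delta0)
        dropped = {
            "protein": prot_params.dropped,
            "mrna": mrna_params.dropped,
            "mirna": mirna_params.dropped,
        }
        summary["dropped_features"] = dropped
        # a protein survives only if both it and its mapped mRNA survived
        mrna_alive = set(mrna_std.feature_ids)
        keep_prot = [
            p for p in protein_std.feature_ids
            if p in gene_map and gene_map[p] in mrna_alive
        ]
        if not keep_prot:
            raise ValueError("no protein has a surviving mapped mRNA")
        protein_std = protein_std.subset_features(keep_prot)
        logP = log_transform(protein_std)
        logE = log_transform(mrna_std)
        logM = log_transform(mirna_std)
        for params, name in (
            (prot_params, "standardization_protein.tsv"),
            (mrna_params, "standardization_mrna.tsv"),
            (mirna_params, "standardization_mirna.tsv"),
        ):
            params.write(outdir / name)
            artifacts.append(outdir / name)
        for mat, name in ((logP, "log_protein.tsv"), (logE, "log_mrna.tsv"), (logM, "log_mirna.tsv")):
            write_matrix(mat, outdir / name)
            artifacts.append(outdir / name)

    with _Stage("univariate"):
        table = fit_all_pairs(logP, logE, logM, gene_map)
        table.write(outdir / "univariate.tsv")
        artifacts.append(outdir / "univariate.tsv")
        assoc = call_significant(table, config.target_fdr)
        neg, pos = assoc.counts_by_sign()
        summary["univariate"] = {
            "n_tests": table.n_tests,
            "n_proteins": len(table.protein_ids),
            "n_mirnas": len(table.mirna_ids),
            "p_star": assoc.fdr.p_star,
            "n_significant": assoc.fdr.n_significant,
            "fdr_hat": assoc.fdr.fdr_hat if np.isfinite(assoc.fdr.fdr_hat) else None,
            "n_negative": neg,
            "n_positive": pos,
        }

    with _Stage("multivariate"):
        fits = fit_all_multivariate(
            logP, logE, logM, gene_map, table,
            alpha_level=config.prescreen_alpha,
            cv_folds=config.cv_folds,
            cv_seed=config.cv_seed,
            penalize_gamma=config.penalize_gamma,
            lambda_rule=config.lambda_rule,
        )
        write_multivariate_fits(
            fits, outdir / "multivariate_coefficients.tsv", outdir / "multivariate_summary.tsv"
        )
        artifacts += [outdir / "multivariate_coefficients.tsv", outdir / "multivariate_summary.tsv"]
        summary["multivariate"] = {
            "selected_per_protein": {f.protein_id: len(f.beta_hats) for f in fits},
            "cv_folds": config.cv_folds,
            "cv_seed": config.cv_seed,
        }

    with _Stage("interactome"):
        row_k = config.row_k or suggest_k(
            assoc.beta, k_max=min(10, len(assoc.protein_ids)), seed=config.cv_seed
        )
        col_k = config.col_k or suggest_k(
            assoc.beta.T, k_max=min(25, len(assoc.mirna_ids)), seed=config.cv_seed
        )
        clusters = two_way_cluster(assoc, row_k, col_k)
        with open(outdir / "clusters.tsv", "w", encoding="utf-8") as handle:
            handle.write("id\taxis\tcluster\n")
            for pid, lab in clusters.row_labels.items():
                handle.write(f"{pid}\tprotein\t{lab}\n")
            for mid, lab in clusters.col_labels.items():
                handle.write(f"{mid}\tmirna\t{lab}\n")
        artifacts.append(outdir / "clusters.tsv")
        clusters.row_tree.write_json(outdir / "protein_tree.json")
        clusters.col_tree.write_json(outdir / "mirna_tree.json")
        artifacts += [outdir / "protein_tree.json", outdir / "mirna_tree.json"]
        edges = export_network(assoc, config.edge_threshold)
        write_sif(edges, outdir / "network.sif")
        artifacts.append(outdir / "network.sif")
        summary["interactome"] = {
            "row_k": int(row_k),
            "col_k": int(col_k),
            "n_edges": len(edges),
        }

    with _Stage("scores"):
        score_matrix = compute_scores(fits, logM)
        write_matrix(score_matrix.to_matrix(), outdir / "patient_scores.tsv")
        artifacts.append(outdir / "patient_scores.tsv")
        tree, labels = cluster_patients(score_matrix, config.patient_k)
        tree.write_json(outdir / "patient_tree.json")
        artifacts.append(outdir / "patient_tree.json")
        summary["scores"] = {"patient_k": config.patient_k}
        if config.clinical:
            clinical = _read_clinical(config.clinical)
            tests = {}
            for variable, mapping in sorted(clinical.items()):
                try:
                    result = cluster_vs_clinical(labels, mapping)
                    tests[variable] = {"p": result.p_value, "test": result.test}
                except ValueError as exc:
                    tests[variable] = {"error": str(exc)}
            summary["scores"]["clinical_association"] = tests

    if config.targets:
        with _Stage("target_overlap"):
            db = load_targets(config.targets)
            pairs = putative_direct(assoc, db, gene_map, config.min_algorithms)
            write_pairs(pairs, outdir / "putative_direct.tsv")
            artifacts.append(outdir / "putative_direct.tsv")
            summary["target_overlap"] = {"n_pairs": len(pairs)}

    if config.screen:
        with _Stage("screen"):
            z = screen_zscore(read_matrix(config.screen, "zscore"), config.screen_threshold)
            validated = screen_consistency(assoc, z)
            write_pairs(validated, outdir / "screen_validated.tsv")
            artifacts.append(outdir / "screen_validated.tsv")
            summary["screen"] = {"n_validated": len(validated)}

    summary["manifest"] = {
        p.name: _sha256(p) for p in sorted(artifacts, key=lambda p: p.name)
    }
    with open(outdir / "summary.json", "w", encoding="utf-8") as handle:
        json.dump(summary, handle, indent=1, sort_keys=True)
    return summary
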