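"""End-to-end pipeline: simulate -> DE -> signature -> network -> analysis.

A run takes a PipelineConfig (thresholds + seed) and either an input
expression matrix or a SimConfig, executes every stage in order, writes
all stage outputs as TSV, and records a manifest with the config
snapshot, per-file SHA-256 digests and the headline counts (DE per
grade, signature size, TF count, possible and selected links,
activator/repressor split). Every threshold actually used is logged so
defaults and overrides stay auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import analysis as an
from . import de as de_mod
from . import io as io_mod
from . import network as net_mod
from . import signature as sig_mod
from .io import ExpressionMatrix, PipelineConfig, TUMOR_GRADES
from .simulate import SimConfig, simulate_cohort, simulate_mutation_layer

logger = logging.getLogger("gliomanet")


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    sim_config: SimConfig | None = None,
    expr: ExpressionMatrix | None = None,
    tf_category: str = "TF",
    annotations: io_mod.AnnotationTable | None = None,
) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    Exactly one of ``sim_config`` / ``expr`` must be provided. When
    simulating, the planted TF set is used; otherwise the TF set comes
    from ``annotations[tf_category]`` intersected with the signature.
    """
    if (sim_config is None) == (expr is None):
        raise ValueError("provide exactly one of sim_config or expr")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": [],
        "digests": {},
        "counts": {},
    }
    files: dict[str, Path] = {}

    def record(stage: str, **paths: Path) -> None:
        manifest["stages"].append(stage)
        for key, path in paths.items():
            files[f"{stage}:{key}"] = path

    # --- simulate / load -------------------------------------------------
    truth = None
    if sim_config is not None:
        sim_config = dataclasses.replace(sim_config, seed=config.seed)
        logger.info("simulate: %s", sim_config)
        expr, truth = simulate_cohort(sim_config)
        expr_path = outdir / "expression.tsv"
        meta_path = outdir / "metadata.tsv"
        io_mod.write_expression(expr, expr_path, meta_path)
        coeff_path = outdir / "true_coefficients.tsv"
        truth.coeff_matrix.to_csv(coeff_path, sep="\t", index_label="tf")
        record("simulate", expression=expr_path, metadata=meta_path, truth=coeff_path)
        tf_set = list(truth.coeff_matrix.index)
    else:
        if annotations is None or tf_category not in annotations:
            raise ValueError("real-data runs need a TF annotation category")
        tf_set = sorted(annotations[tf_category])

    lr = io_mod.to_log_ratios(expr)
    lr_path = outdir / "log_ratios.tsv"
    io_mod.write_log_ratios(lr, lr_path)
    record("log_ratios", log_ratios=lr_path)

    # --- differential expression -----------------------------------------
    logger.info("de: q_threshold=%g", config.q_threshold)
    tables = {
        g: de_mod.call_states(expr, g, q_threshold=config.q_threshold)
        for g in TUMOR_GRADES
    }
    de_paths = {}
    for g, t in tables.items():
        p = outdir / f"states_{g}.tsv"
        t.table.to_csv(p, sep="\t", index_label="gene")
        de_paths[g] = p
    record("de", **{f"states_{g}": p for g, p in de_paths.items()})
    counts = de_mod.de_counts_by_grade(tables)
    counts.to_csv(outdir / "de_counts.tsv", sep="\t", index_label="grade")
    record("de_counts", counts=outdir / "de_counts.tsv")
    trend_r, trend_p = de_mod.grade_trend(counts["total"].to_numpy())
    manifest["counts"]["de_per_grade"] = counts["total"].to_dict()
    manifest["counts"]["grade_trend_r"] = trend_r
    manifest["counts"]["grade_trend_p"] = trend_p

    for direction in (de_mod.UNDER, de_mod.OVER):
        part = de_mod.exclusive_subsets(tables, direction)
        rows = [
            {"subset": "+".join(sorted(k)), "n_genes": len(v)}
            for k, v in sorted(part.cells.items(), key=lambda kv: sorted(kv[0]))
        ]
        p = outdir / f"venn_{direction.lower()}.tsv"
        pd.DataFrame(rows, columns=["subset", "n_genes"]).to_csv(p, sep="\t", index=False)
        record(f"venn_{direction.lower()}", partition=p)

    # --- signature --------------------------------------------------------
    logger.info("signature: lfc_threshold=%g", config.lfc_threshold)
    signature = sig_mod.derive_signature(tables, lr, lfc_threshold=config.lfc_threshold)
    sig_path = outdir / "signature.tsv"
    signature.table.to_csv(sig_path, sep="\t", index_label="gene")
    record("signature", signature=sig_path)
    manifest["counts"]["signature_size"] = len(signature)

    # --- network ----------------------------------------------------------
    sig_tfs = [t for t in tf_set if t in set(signature.genes)]
    logger.info(
        "network: p_threshold=%g, %d TFs x %d signature genes",
        config.network_p_threshold,
        len(sig_tfs),
        len(signature),
    )
    network = net_mod.infer_network(
        signature, lr, sig_tfs, p_threshold=config.network_p_threshold
    )
    edge_path = outdir / "edges.tsv"
    io_mod.write_edge_list(network, edge_path)
    record("network", edges=edge_path)
    manifest["counts"]["tf_count"] = len(sig_tfs)
    manifest["counts"]["possible_links"] = network.summary["possible_links"]
    manifest["counts"]["possible_links_self_excluded"] = network.summary[
        "possible_links_self_excluded"
    ]
    manifest["counts"]["selected_links"] = network.summary["selected_links"]
    manifest["counts"]["activators"] = network.summary["activators"]
    manifest["counts"]["repressors"] = network.summary["repressors"]
    manifest["counts"]["genes_without_regulators"] = len(
        network.summary["genes_without_regulators"]
    )
    manifest["counts"]["tfs_without_targets"] = len(
        network.summary["tfs_without_targets"]
    )

    # --- analysis ----------------------------------------------------------
    hubs = an.hub_ranking(network, tf_set=sig_tfs, lr=lr)
    hub_path = outdir / "hubs.tsv"
    hubs.to_csv(hub_path, sep="\t", index_label="tf")
    record("analyze", hubs=hub_path)

    if truth is not None:
        mut = simulate_mutation_layer(truth, "methylation")
        contrast = hubs["expression_contrast"]
        mmap = an.mutation_expression_map(
            contrast.dropna(), mut, deviation_threshold=config.deviation_threshold
        )
        mmap_path = outdir / "mutation_map.tsv"
        mmap.to_csv(mmap_path, sep="\t", index_label="tf")
        record("mutation_map", mutation_map=mmap_path)

    # --- manifest -----------------------------------------------------------
    for key, path in files.items():
        manifest["digests"][key] = io_mod.hash_file(path)
    if (
        manifest["counts"]["selected_links"]
        > manifest["counts"]["possible_links"]
    ):  # conservation check; cannot happen unless a stage corrupted its output
        raise RuntimeError("selected links exceed possible links")
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
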