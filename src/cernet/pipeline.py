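"""End-to-end orchestration: simulate/read -> DE -> correlations -> sponge
-> network, with a run manifest recording per-stage counts and warnings."""

from __future__ import annotations

import json
import logging
import math
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .containers import RNA_CLASSES, ExpressionMatrix, GroundTruth
from .coexpression import filter_cerna_pairs, filter_mirna_target_pairs
from .de import call_de
from .design import MetadataDesign, generate_design
from .errors import CernetError
from .io import (
    file_checksum,
    read_expression_tsv,
    read_interactions_tsv,
    read_metadata_tsv,
    write_expression_tsv,
    write_ground_truth,
    write_network,
    write_pairs_tsv,
)
from .simulate import generate_interactions, simulate_counts
from .sponge import (
    audit_network,
    build_network,
    mirna_universe,
    network_summary,
    recovery_metrics,
    sponge_test,
)

logger = logging.getLogger(__name__)

_SPONGE_COLUMNS = ["circ_id", "mrna_id", "k", "K", "n", "N", "pvalue", "pcc", "shared_mirnas"]


def _prepare_inputs(config: PipelineConfig, outdir: Path):
    """Simulate or read the count matrices, metadata and interactions."""
    checksums: dict[str, str] = {}
    if config.simulate is not None:
        sim = config.simulate
        sim.seed = config.seed
        design = generate_design(
            config.tissues, config.conditions, config.replicates, config.seed
        )
        matrices, truth = simulate_counts(design, sim)
        feature_ids = {cls: matrices[(cls, design.tissues[0])].feature_ids for cls in RNA_CLASSES}
        interactions = generate_interactions(truth, sim, feature_ids)
        metadata = design.sample_table()
        simdir = outdir / "inputs"
        simdir.mkdir(parents=True, exist_ok=True)
        for (cls, tissue), mat in matrices.items():
            write_expression_tsv(mat, simdir / f"{cls}_{tissue}.counts.tsv")
        metadata.to_csv(simdir / "metadata.tsv", sep="\t", index=False)
        interactions.to_csv(simdir / "interactions.tsv", sep="\t", index=False)
        write_ground_truth(truth, simdir / "ground_truth.json")
        md = MetadataDesign(metadata, config.conditions)
        return matrices, md, interactions, truth, checksums

    paths = config.inputs
    metadata = read_metadata_tsv(paths.metadata)
    checksums[str(paths.metadata)] = file_checksum(paths.metadata)
    interactions = read_interactions_tsv(paths.interactions)
    checksums[str(paths.interactions)] = file_checksum(paths.interactions)
    md = MetadataDesign(metadata, config.conditions)
    matrices: dict[tuple[str, str], ExpressionMatrix] = {}
    for cls, per_tissue in paths.counts.items():
        for tissue, path in per_tissue.items():
            matrices[(cls, tissue)] = read_expression_tsv(path, cls, tissue)
            checksums[str(path)] = file_checksum(path)
    return matrices, md, interactions, None, checksums


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full screen and return the manifest (also written as JSON)."""
    config.validate()
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrices, design, interactions, truth, checksums = _prepare_inputs(config, outdir)
    th = config.thresholds
    min_abs_log2fc = math.log2(th.fc_threshold)
    tissues = sorted({tissue for _, tissue in matrices})

    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "input_checksums": checksums,
        "stages": {},
        "warnings": [],
    }
    warnings = manifest["warnings"]

    for tissue in tissues:
        expr = {cls: matrices[(cls, tissue)] for cls in RNA_CLASSES if (cls, tissue) in matrices}
        missing = [cls for cls in RNA_CLASSES if cls not in expr]
        if missing:
            raise CernetError(f"tissue {tissue!r}: missing count matrices for {missing}")

        de_tables = {
            cls: call_de(
                expr[cls],
                design,
                pseudocount=th.pseudocount,
                min_abs_log2fc=min_abs_log2fc,
                p_alpha=th.de_alpha,
                fdr_alpha=th.mrna_fdr,
            )
            for cls in RNA_CLASSES
        }
        de_all = pd.concat(de_tables.values(), ignore_index=True)
        de_all.to_csv(outdir / f"de_{tissue}.tsv", sep="\t", index=False, float_format="%.10g")

        cond_vec = None
        if config.correlation_pooling == "within_condition":
            cond_vec = design.condition_of(expr["miRNA"].sample_ids).to_numpy()

        neg = filter_mirna_target_pairs(
            de_tables, interactions, expr, scc_threshold=th.scc_threshold, conditions=cond_vec
        )
        if neg.attrs.get("n_skipped"):
            warnings.append(
                f"{tissue}: skipped {neg.attrs['n_skipped']} interaction rows with unknown features"
            )
        if neg.attrs.get("n_undefined"):
            warnings.append(
                f"{tissue}: excluded {neg.attrs['n_undefined']} constant-expression pairs"
            )
        write_pairs_tsv(neg, outdir / f"pairs_negative_{tissue}.tsv")

        cand = filter_cerna_pairs(
            de_tables, neg, expr, pcc_threshold=th.pcc_threshold, conditions=cond_vec
        )
        write_pairs_tsv(cand, outdir / f"pairs_cerna_{tissue}.tsv")

        if len(cand):
            universe = mirna_universe(
                interactions,
                de_mirnas=set(
                    de_tables["miRNA"].loc[de_tables["miRNA"]["significant"], "feature_id"]
                ),
                mode=config.universe_mode,
                profiled_mirnas=set(expr["miRNA"].feature_ids),
            )
            sponge = sponge_test(
                cand, neg, universe, alpha=th.sponge_alpha, bh_correct=config.sponge_bh
            )
        else:
            universe = 0
            sponge = pd.DataFrame(columns=_SPONGE_COLUMNS)
            sponge.attrs["n_tested"] = 0
        write_pairs_tsv(sponge, outdir / f"sponge_{tissue}.tsv")

        network = build_network(neg, sponge, de_tables, tissue=tissue)
        violations = audit_network(
            network, pcc_threshold=th.pcc_threshold, alpha=th.sponge_alpha
        )
        if violations:
            raise CernetError(f"tissue {tissue!r}: network audit failed: {violations[:3]}")
        write_network(network, outdir, f"network_{tissue}")

        stage = {
            "n_features": {cls: expr[cls].shape[0] for cls in RNA_CLASSES},
            "n_samples": expr["miRNA"].shape[1],
            "dispersion": {
                cls: de_tables[cls].attrs["dispersion"] for cls in RNA_CLASSES
            },
            "n_de": {
                cls: int(de_tables[cls]["significant"].sum()) for cls in RNA_CLASSES
            },
            "mirna_pairs_tested": int(neg.attrs.get("n_tested", 0)),
            "mirna_pairs_retained": int(len(neg)),
            "cerna_pairs_tested": int(cand.attrs.get("n_tested", 0)),
            "cerna_pairs_retained": int(len(cand)),
            "sponge_tested": int(sponge.attrs.get("n_tested", 0)),
            "sponge_retained": int(len(sponge)),
            "mirna_universe": int(universe),
            "network": network_summary(network),
        }
        if truth is not None:
            stage["recovery"] = recovery_metrics(network, truth)
        manifest["stages"][tissue] = stage

    manifest["runtime_seconds"] = round(time.time() - t0, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
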