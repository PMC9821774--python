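"""Readers and writers: TSV tables, GraphML networks, JSON manifests.

All tabular formats are tab-delimited UTF-8 with ``#`` comment lines
ignored; graphs are GraphML; ground truth and manifests are JSON.
Serialization is deterministic (sorted nodes and edges) so outputs can
be diffed and hashed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GroundTruth
from .errors import ParseError
from .sponge import network_summary


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc


def read_expression_tsv(path, rna_class: str, tissue: str) -> ExpressionMatrix:
    """Read a counts TSV (first column feature IDs, header sample IDs).

    Malformed cells are reported with their feature/sample location and
    1-based data line number.
    """
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected a feature-ID column plus sample columns")
    feature_col = raw.columns[0]
    features = raw[feature_col]
    dup = features[features.duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate feature ID {dup.iloc[0]!r}")
    samples = list(raw.columns[1:])
    if len(set(samples)) != len(samples):
        seen = set()
        dup_s = next(s for s in samples if s in seen or seen.add(s))
        raise ParseError(f"{path}: duplicate sample ID {dup_s!r}")
    data = np.empty((len(raw), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        col = pd.to_numeric(raw[sample], errors="coerce")
        bad = col.isna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"{path}: non-numeric count at line {i + 2} "
                f"(feature {features.iloc[i]!r}, sample {sample!r})"
            )
        vals = col.to_numpy(dtype=float)
        if (vals < 0).any():
            i = int(np.argmax(vals < 0))
            raise ParseError(
                f"{path}: negative count at line {i + 2} "
                f"(feature {features.iloc[i]!r}, sample {sample!r})"
            )
        if not np.array_equal(vals, np.round(vals)):
            i = int(np.argmax(vals != np.round(vals)))
            raise ParseError(
                f"{path}: non-integer count at line {i + 2} "
                f"(feature {features.iloc[i]!r}, sample {sample!r})"
            )
        data[:, j] = vals.astype(np.int64)
    counts = pd.DataFrame(data, index=pd.Index(features, name=feature_col), columns=samples)
    return ExpressionMatrix(counts=counts, rna_class=rna_class, tissue=tissue)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    out = matrix.counts.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = _read_tsv(path)
    required = {"sample_id", "tissue", "condition", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata columns {sorted(missing)}")
    dup = meta["sample_id"][meta["sample_id"].duplicated()]
    if len(dup):
        raise ParseError(f"{path}: duplicate sample ID {dup.iloc[0]!r}")
    return meta


def read_interactions_tsv(path) -> pd.DataFrame:
    table = _read_tsv(path)
    required = {"mirna_id", "target_id", "target_type"}
    missing = required - set(table.columns)
    if missing:
        raise ParseError(f"{path}: missing interaction columns {sorted(missing)}")
    bad = ~table["target_type"].isin(["circRNA", "mRNA"])
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        raise ParseError(
            f"{path}: invalid target_type {table['target_type'].iloc[i]!r} at line {i + 2}"
        )
    return table.drop_duplicates(ignore_index=True)


def write_pairs_tsv(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


def write_network(network: nx.Graph, outdir, prefix: str) -> dict[str, Path]:
    """Write GraphML, edge-list TSV, node-attribute TSV and summary JSON.

    Nodes are sorted lexicographically and edges by (type, endpoints) so
    the serialization is reproducible byte-for-byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ordered = nx.Graph(**network.graph)
    for v in sorted(network.nodes):
        ordered.add_node(v, **network.nodes[v])
    edges = sorted(
        (
            (data["edge_type"], *sorted((u, v)), data)
            for u, v, data in network.edges(data=True)
        ),
        key=lambda e: e[:3],
    )
    for _, u, v, data in edges:
        ordered.add_edge(u, v, **data)

    paths = {
        "graphml": outdir / f"{prefix}.graphml",
        "edges": outdir / f"{prefix}.edges.tsv",
        "nodes": outdir / f"{prefix}.nodes.tsv",
        "summary": outdir / f"{prefix}.summary.json",
    }
    nx.write_graphml(ordered, paths["graphml"])

    edge_rows = [
        {
            "source": u,
            "target": v,
            "edge_type": etype,
            "coefficient": data.get("coefficient", ""),
            "pvalue": data.get("pvalue", ""),
            "shared_mirnas": data.get("shared_mirnas", ""),
        }
        for etype, u, v, data in edges
    ]
    pd.DataFrame(
        edge_rows,
        columns=["source", "target", "edge_type", "coefficient", "pvalue", "shared_mirnas"],
    ).to_csv(paths["edges"], sep="\t", index=False, float_format="%.10g")

    node_rows = [
        {
            "node_id": v,
            "node_type": ordered.nodes[v]["node_type"],
            "direction": ordered.nodes[v].get("direction", "none"),
            "degree": ordered.degree[v],
        }
        for v in ordered.nodes
    ]
    pd.DataFrame(
        node_rows, columns=["node_id", "node_type", "direction", "degree"]
    ).to_csv(paths["nodes"], sep="\t", index=False)

    paths["summary"].write_text(
        json.dumps(network_summary(network), indent=2, sort_keys=True)
    )
    return paths


def read_network_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
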