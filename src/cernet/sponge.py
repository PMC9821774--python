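"""Shared-sponge hypergeometric test and ceRNA network assembly.

For a candidate circRNA-mRNA pair, let N be the size of the miRNA
universe, K the number of miRNAs negatively paired with the circRNA,
n the number negatively paired with the mRNA, and k the number shared.
Under the null that the two regulator sets are drawn independently, the
shared count follows Hypergeometric(N, K, n); the pair's p-value is the
upper tail P(X >= k). Pairs with p < 0.05 (strict) become the circ-mRNA
edges of the tripartite ceRNA network; the miRNA edges are the retained
negative pairs that witness each shared sponge.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .containers import GroundTruth
from .errors import AssemblyError, ConfigurationError

logger = logging.getLogger(__name__)

NODE_TYPE_OF_EDGE = {
    "circ_mirna": ("circRNA", "miRNA"),
    "mirna_mrna": ("miRNA", "mRNA"),
    "circ_mrna": ("circRNA", "mRNA"),
}


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Summed in log space over the valid support, so large N is handled
    without under/overflow. ``k <= min(K, n)`` is required.
    """
    k, N, K, n = int(k), int(N), int(K), int(n)
    if N < 0 or not (0 <= K <= N) or not (0 <= n <= N):
        raise ConfigurationError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if k > min(K, n):
        raise ConfigurationError(f"k={k} exceeds min(K, n)={min(K, n)}")
    lo = max(0, n - (N - K))  # support lower bound: overlap forced by pigeonhole
    if k <= lo:
        return 1.0
    j = np.arange(k, min(K, n) + 1)
    logpmf = _log_comb(K, j) + _log_comb(N - K, n - j) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(logpmf))))


def mirna_universe(
    interactions: pd.DataFrame,
    de_mirnas: set[str] | None = None,
    mode: str = "interactions_de",
    profiled_mirnas: set[str] | None = None,
) -> int:
    """Size of the miRNA universe N for the sponge test.

    Modes: ``interactions_de`` (default) — distinct interaction-table
    miRNAs that are DE; ``interactions_all`` — all interaction-table
    miRNAs; ``profiled`` — all profiled miRNAs.
    """
    table_mirnas = set(interactions["mirna_id"])
    if mode == "interactions_de":
        if de_mirnas is None:
            raise ConfigurationError("mode 'interactions_de' requires de_mirnas")
        return len(table_mirnas & de_mirnas)
    if mode == "interactions_all":
        return len(table_mirnas)
    if mode == "profiled":
        if profiled_mirnas is None:
            raise ConfigurationError("mode 'profiled' requires profiled_mirnas")
        return len(profiled_mirnas)
    raise ConfigurationError(f"unknown universe mode {mode!r}")


def sponge_test(
    candidate_pairs: pd.DataFrame,
    retained_mirna_pairs: pd.DataFrame,
    universe_size: int,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Hypergeometric shared-sponge test over candidate circRNA-mRNA pairs.

    Regulator sets are taken from the retained negative pairs. Pairs are
    kept when the tail probability is strictly below ``alpha`` (applied to
    BH-adjusted values when ``bh_correct`` is set; raw by default).

    Returns the retained SpongeEdge table with columns circ_id, mrna_id,
    k, K, n, N, pvalue, pcc, shared_mirnas; ``attrs['n_tested']`` records
    the number of candidates tested.
    """
    if universe_size <= 0:
        raise ConfigurationError("miRNA universe is empty")
    mirnas_of: dict[tuple[str, str], set[str]] = {}
    for rec in retained_mirna_pairs.itertuples(index=False):
        key = ("circRNA" if rec.pair_type == "mirna_circ" else "mRNA", rec.id_b)
        mirnas_of.setdefault(key, set()).add(rec.id_a)

    rows = []
    for rec in candidate_pairs.itertuples(index=False):
        set_circ = mirnas_of.get(("circRNA", rec.id_a), set())
        set_mrna = mirnas_of.get(("mRNA", rec.id_b), set())
        K, n = len(set_circ), len(set_mrna)
        if K > universe_size or n > universe_size:
            raise ConfigurationError(
                f"regulator set larger than the universe (K={K}, n={n}, N={universe_size})"
            )
        shared = set_circ & set_mrna
        k = len(shared)
        rows.append(
            {
                "circ_id": rec.id_a,
                "mrna_id": rec.id_b,
                "k": k,
                "K": K,
                "n": n,
                "N": universe_size,
                "pvalue": hypergeom_sf(k, universe_size, K, n),
                "pcc": rec.coefficient,
                "shared_mirnas": ";".join(sorted(shared)),
            }
        )
    table = pd.DataFrame(
        rows, columns=["circ_id", "mrna_id", "k", "K", "n", "N", "pvalue", "pcc", "shared_mirnas"]
    )
    n_tested = len(table)
    if bh_correct and n_tested:
        from .de import bh_adjust

        table["pvalue_adj"] = bh_adjust(table["pvalue"].to_numpy())
        table = table[table["pvalue_adj"] < alpha].reset_index(drop=True)
    else:
        table = table[table["pvalue"] < alpha].reset_index(drop=True)
    table.attrs.update(n_tested=n_tested, bh_correct=bh_correct)
    return table


def build_network(
    retained_mirna_pairs: pd.DataFrame,
    sponge_edges: pd.DataFrame,
    de_tables: dict[str, pd.DataFrame] | None = None,
    tissue: str = "",
) -> nx.Graph:
    """Assemble the tripartite ceRNA network.

    The graph contains exactly the nodes incident to a retained edge: each
    sponge-tested circRNA-mRNA edge plus, for every shared miRNA, the two
    negative edges witnessing it. Node attributes carry the RNA class and
    DE direction; edge attributes carry type, coefficient and (for
    circ-mRNA edges) the sponge p-value and shared miRNA list.
    """
    coef_of: dict[tuple[str, str], float] = {}
    for rec in retained_mirna_pairs.itertuples(index=False):
        coef_of[(rec.id_a, rec.id_b)] = rec.coefficient

    directions: dict[tuple[str, str], str] = {}
    if de_tables:
        for cls, tab in de_tables.items():
            for rec in tab.itertuples(index=False):
                directions[(cls, rec.feature_id)] = rec.direction

    g = nx.Graph(tissue=tissue)

    def add_node(node_id: str, node_type: str) -> None:
        g.add_node(
            node_id,
            node_type=node_type,
            direction=directions.get((node_type, node_id), "none"),
        )

    for rec in sponge_edges.itertuples(index=False):
        shared = [m for m in rec.shared_mirnas.split(";") if m]
        add_node(rec.circ_id, "circRNA")
        add_node(rec.mrna_id, "mRNA")
        g.add_edge(
            rec.circ_id,
            rec.mrna_id,
            edge_type="circ_mrna",
            coefficient=float(rec.pcc),
            pvalue=float(rec.pvalue),
            shared_mirnas=";".join(sorted(shared)),
        )
        for mi in shared:
            for target in (rec.circ_id, rec.mrna_id):
                if (mi, target) not in coef_of:
                    raise AssemblyError(
                        f"sponge edge ({rec.circ_id}, {rec.mrna_id}) references miRNA "
                        f"{mi!r} without a retained negative pair to {target!r}"
                    )
            add_node(mi, "miRNA")
            g.add_edge(
                mi, rec.circ_id,
                edge_type="circ_mirna", coefficient=coef_of[(mi, rec.circ_id)],
            )
            g.add_edge(
                mi, rec.mrna_id,
                edge_type="mirna_mrna", coefficient=coef_of[(mi, rec.mrna_id)],
            )
    return g


def extract_subnetwork(
    network: nx.Graph, anchor_ids
) -> tuple[nx.Graph, pd.DataFrame]:
    """Induced subgraph of the anchors plus all their neighbors.

    Also reports, per anchor, how many circRNAs, miRNAs and mRNAs are its
    direct neighbors (the "regulated by X circRNAs and Y miRNAs" style of
    subnetwork summary). Missing anchors yield an empty network and a
    warning.
    """
    present = [a for a in anchor_ids if a in network]
    for a in anchor_ids:
        if a not in network:
            logger.warning("anchor %r not present in the network", a)
    nodes = set(present)
    for a in present:
        nodes.update(network.neighbors(a))
    sub = network.subgraph(nodes).copy()

    rows = []
    for a in present:
        neigh = list(network.neighbors(a))
        counts = {"circRNA": 0, "miRNA": 0, "mRNA": 0}
        for v in neigh:
            counts[network.nodes[v]["node_type"]] += 1
        rows.append(
            {
                "anchor": a,
                "node_type": network.nodes[a]["node_type"],
                "n_circRNA": counts["circRNA"],
                "n_miRNA": counts["miRNA"],
                "n_mRNA": counts["mRNA"],
            }
        )
    report = pd.DataFrame(
        rows, columns=["anchor", "node_type", "n_circRNA", "n_miRNA", "n_mRNA"]
    )
    return sub, report


def network_summary(network: nx.Graph) -> dict:
    """Node/edge counts by type, circRNA-mRNA pair count, degree distributions."""
    node_counts = {"circRNA": 0, "miRNA": 0, "mRNA": 0}
    degrees: dict[str, list[int]] = {"circRNA": [], "miRNA": [], "mRNA": []}
    for v, data in network.nodes(data=True):
        node_counts[data["node_type"]] += 1
        degrees[data["node_type"]].append(network.degree[v])
    edge_counts = {"circ_mirna": 0, "mirna_mrna": 0, "circ_mrna": 0}
    for _, _, data in network.edges(data=True):
        edge_counts[data["edge_type"]] += 1
    return {
        "tissue": network.graph.get("tissue", ""),
        "n_circRNA": node_counts["circRNA"],
        "n_miRNA": node_counts["miRNA"],
        "n_mRNA": node_counts["mRNA"],
        "n_edges": dict(edge_counts),
        "n_circ_mrna_pairs": edge_counts["circ_mrna"],
        "degree_distribution": {cls: sorted(d) for cls, d in degrees.items()},
    }


def network_triads(network: nx.Graph) -> set[tuple[str, str, str]]:
    """All (circRNA, miRNA, mRNA) triads realized in the network."""
    triads = set()
    for u, v, data in network.edges(data=True):
        if data.get("edge_type") != "circ_mrna":
            continue
        circ, mrna = (u, v) if network.nodes[u]["node_type"] == "circRNA" else (v, u)
        for mi in data.get("shared_mirnas", "").split(";"):
            if mi and network.has_edge(mi, circ) and network.has_edge(mi, mrna):
                triads.add((circ, mi, mrna))
    return triads


def recovery_metrics(network: nx.Graph, truth: GroundTruth) -> dict:
    """Precision/recall/F1 of planted triads.

    A planted triad is recovered when its circ-mRNA edge and both its
    negative miRNA edges are present. With no emitted triads, precision is
    1 by convention (no false positives); with no planted triads, recall
    is 1.
    """
    emitted = network_triads(network)
    planted = set(truth.planted_triads)
    tp = len(emitted & planted)
    precision = tp / len(emitted) if emitted else 1.0
    recall = tp / len(planted) if planted else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return {
        "n_emitted": len(emitted),
        "n_planted": len(planted),
        "n_recovered": tp,
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def audit_network(
    network: nx.Graph, pcc_threshold: float = 0.9, alpha: float = 0.05
) -> list[str]:
    """Post-hoc structural audit; returns a list of violation messages.

    Checks tripartite typing (no within-class edges, only the three legal
    edge types), and that every circ-mRNA edge satisfies PCC >
    ``pcc_threshold``, sponge p < ``alpha``, and has at least one shared
    miRNA present with both witnessing negative edges.
    """
    violations = []
    for v, data in network.nodes(data=True):
        if data.get("node_type") not in ("circRNA", "miRNA", "mRNA"):
            violations.append(f"node {v!r} has invalid type {data.get('node_type')!r}")
    for u, v, data in network.edges(data=True):
        etype = data.get("edge_type")
        if etype not in NODE_TYPE_OF_EDGE:
            violations.append(f"edge ({u}, {v}) has invalid type {etype!r}")
            continue
        types = {network.nodes[u]["node_type"], network.nodes[v]["node_type"]}
        if types != set(NODE_TYPE_OF_EDGE[etype]):
            violations.append(
                f"edge ({u}, {v}) of type {etype} joins node types {sorted(types)}"
            )
        if etype == "circ_mrna":
            if not data["coefficient"] > pcc_threshold:
                violations.append(
                    f"circ_mrna edge ({u}, {v}) PCC {data['coefficient']} <= {pcc_threshold}"
                )
            if not data["pvalue"] < alpha:
                violations.append(
                    f"circ_mrna edge ({u}, {v}) sponge p {data['pvalue']} >= {alpha}"
                )
            witnesses = [m for m in data.get("shared_mirnas", "").split(";") if m]
            ok = any(
                network.has_edge(m, u) and network.has_edge(m, v) for m in witnesses
            )
            if not ok:
                violations.append(
                    f"circ_mrna edge ({u}, {v}) has no shared-miRNA witness with both "
                    "negative edges present"
                )
    return violations
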