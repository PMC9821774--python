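"""Hypergeometric sponge test, network assembly, audit and recovery metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import cernet
from cernet.errors import AssemblyError, ConfigurationError

from .oracles import hypergeom_sf_exact


class TestHypergeomSf:
    def test_k_zero_is_one(self):
        assert cernet.hypergeom_sf(0, 50, 10, 5) == 1.0

    def test_forced_overlap_is_one(self):
        # all 10 population members are successes: the 5 draws overlap surely
        assert cernet.hypergeom_sf(5, 10, 10, 5) == 1.0

    def test_derived_example_matches_exact_enumeration(self):
        expected = float(hypergeom_sf_exact(4, 20, 8, 6))
        assert cernet.hypergeom_sf(4, 20, 8, 6) == pytest.approx(expected, abs=1e-12)

    def test_nonincreasing_in_k(self):
        vals = [cernet.hypergeom_sf(k, 40, 12, 9) for k in range(10)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_cross_check_against_scipy_at_scale(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            N = int(rng.integers(5, 5000))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert cernet.hypergeom_sf(k, N, K, n) == pytest.approx(
                hypergeom.sf(k - 1, N, K, n), rel=1e-9, abs=1e-12
            )

    def test_domain_errors(self):
        with pytest.raises(ConfigurationError):
            cernet.hypergeom_sf(3, 10, 12, 5)
        with pytest.raises(ConfigurationError):
            cernet.hypergeom_sf(6, 10, 5, 5)


def _pairs(rows):
    return pd.DataFrame(
        rows, columns=["id_a", "id_b", "pair_type", "method", "coefficient", "n_samples"]
    )


def _neg_pairs(circ_mirnas, mrna_mirnas, circ="c1", mrna="g1"):
    rows = [
        (mi, circ, "mirna_circ", "spearman", -0.95, 6) for mi in circ_mirnas
    ] + [(mi, mrna, "mirna_mrna", "spearman", -0.92, 6) for mi in mrna_mirnas]
    return _pairs(rows)


def _candidates(circ="c1", mrna="g1", pcc=0.97):
    df = _pairs([(circ, mrna, "circ_mrna", "pearson", pcc, 6)])
    df["common_mirnas"] = ""
    return df


class TestSpongeTest:
    def test_no_shared_mirna_gives_p_one_and_exclusion(self):
        edges = cernet.sponge_test(
            _candidates(), _neg_pairs(["m1", "m2"], ["m3"]), universe_size=50
        )
        assert len(edges) == 0 and edges.attrs["n_tested"] == 1

    def test_full_overlap_matches_oracle(self):
        neg = _neg_pairs(["m1", "m2", "m3"], ["m1", "m2", "m3"])
        edges = cernet.sponge_test(_candidates(), neg, universe_size=100)
        expected = float(hypergeom_sf_exact(3, 100, 3, 3))
        assert len(edges) == 1
        assert edges.iloc[0].pvalue == pytest.approx(expected, abs=1e-12)
        assert edges.iloc[0].shared_mirnas == "m1;m2;m3"

    def test_boundary_alpha_excluded(self):
        """p exactly equal to alpha fails the strict '<' gate (K=n=k=1,
        N=20 gives p = 1/20)."""
        neg = _neg_pairs(["m1"], ["m1"])
        p = cernet.hypergeom_sf(1, 20, 1, 1)
        assert p == pytest.approx(0.05)
        edges = cernet.sponge_test(_candidates(), neg, universe_size=20, alpha=p)
        assert len(edges) == 0

    def test_empty_universe_rejected(self):
        with pytest.raises(ConfigurationError):
            cernet.sponge_test(_candidates(), _neg_pairs(["m1"], ["m1"]), 0)

    def test_universe_modes(self):
        inter = pd.DataFrame(
            {
                "mirna_id": ["m1", "m2", "m3"],
                "target_id": ["c1", "c1", "g1"],
                "target_type": ["circRNA", "circRNA", "mRNA"],
            }
        )
        assert cernet.mirna_universe(inter, de_mirnas={"m1", "m9"}) == 1
        assert cernet.mirna_universe(inter, mode="interactions_all") == 3
        assert cernet.mirna_universe(inter, mode="profiled", profiled_mirnas=set("abcd")) == 4


class TestBuildNetwork:
    def test_empty_sponge_edges_give_empty_network(self):
        net = cernet.build_network(_neg_pairs(["m1"], ["m1"]), _candidates().iloc[:0])
        assert net.number_of_nodes() == 0 and net.number_of_edges() == 0
        summary = cernet.network_summary(net)
        assert (summary["n_circRNA"], summary["n_miRNA"], summary["n_mRNA"]) == (0, 0, 0)

    def test_minimal_triad(self):
        neg = _neg_pairs(["m1"], ["m1"])
        edges = cernet.sponge_test(_candidates(), neg, universe_size=50)
        net = cernet.build_network(neg, edges)
        assert net.number_of_nodes() == 3 and net.number_of_edges() == 3
        summary = cernet.network_summary(net)
        assert (summary["n_circRNA"], summary["n_miRNA"], summary["n_mRNA"]) == (1, 1, 1)
        assert summary["n_circ_mrna_pairs"] == 1
        assert cernet.network_triads(net) == {("c1", "m1", "g1")}
        assert cernet.audit_network(net) == []

    def test_dangling_reference_rejected(self):
        edges = _candidates()
        edges = edges.rename(columns={"id_a": "circ_id", "id_b": "mrna_id"})
        edges["pvalue"] = 0.01
        edges["pcc"] = 0.97
        edges["shared_mirnas"] = "mX"
        with pytest.raises(AssemblyError):
            cernet.build_network(_neg_pairs(["m1"], ["m1"]), edges)

    def test_node_set_is_union_of_edge_endpoints(self, recovery_manifest):
        _, outdir = recovery_manifest
        net = cernet.io.read_network_graphml(outdir / "network_hypothalamus.graphml")
        endpoints = {v for e in net.edges for v in e}
        assert endpoints == set(net.nodes)


class TestSubnetworkAndSummary:
    @pytest.fixture()
    def wired_network(self):
        """Anchor mRNA g1 regulated by 3 circRNAs through 2 miRNAs."""
        rows = []
        for circ in ("c1", "c2", "c3"):
            for mi in ("m1", "m2"):
                rows.append((mi, circ, "mirna_circ", "spearman", -0.95, 6))
        rows += [(mi, "g1", "mirna_mrna", "spearman", -0.9, 6) for mi in ("m1", "m2")]
        neg = _pairs(rows)
        cand = pd.concat([_candidates(c, "g1") for c in ("c1", "c2", "c3")],
                         ignore_index=True)
        edges = cernet.sponge_test(cand, neg, universe_size=200)
        assert len(edges) == 3
        return cernet.build_network(neg, edges)

    def test_anchor_report_counts(self, wired_network):
        sub, report = cernet.extract_subnetwork(wired_network, ["g1"])
        row = report.iloc[0]
        assert (row.n_circRNA, row.n_miRNA) == (3, 2)
        assert set(sub.nodes) == {"g1", "c1", "c2", "c3", "m1", "m2"}

    def test_absent_anchor_gives_empty_network(self, wired_network):
        sub, report = cernet.extract_subnetwork(wired_network, ["nope"])
        assert sub.number_of_nodes() == 0 and report.empty

    def test_mrna_anchor_of_minimal_triad_returns_whole_triad(self):
        neg = _neg_pairs(["m1"], ["m1"])
        edges = cernet.sponge_test(_candidates(), neg, universe_size=50)
        net = cernet.build_network(neg, edges)
        sub, _ = cernet.extract_subnetwork(net, ["g1"])
        assert set(sub.nodes) == {"c1", "m1", "g1"} and sub.number_of_edges() == 3

    def test_summary_permutation_invariance(self, wired_network):
        import networkx as nx

        relabeled = nx.Graph(**wired_network.graph)
        for v in reversed(list(wired_network.nodes)):
            relabeled.add_node(v, **wired_network.nodes[v])
        for u, v, d in wired_network.edges(data=True):
            relabeled.add_edge(u, v, **d)
        assert cernet.network_summary(relabeled) == cernet.network_summary(wired_network)


class TestRecoveryMetrics:
    def test_perfect_recovery(self):
        neg = _neg_pairs(["m1"], ["m1"])
        edges = cernet.sponge_test(_candidates(), neg, universe_size=50)
        net = cernet.build_network(neg, edges)
        truth = cernet.GroundTruth(
            planted_de={("circRNA", "c1", "up"), ("mRNA", "g1", "up")},
            planted_triads=[("c1", "m1", "g1")],
            planted_interactions=[("m1", "c1", "circRNA"), ("m1", "g1", "mRNA")],
        )
        m = cernet.recovery_metrics(net, truth)
        assert m["precision"] == m["recall"] == m["f1"] == 1.0

    def test_empty_network_conventions(self):
        import networkx as nx

        truth = cernet.GroundTruth(planted_triads=[("c1", "m1", "g1")])
        m = cernet.recovery_metrics(nx.Graph(), truth)
        assert m["recall"] == 0.0 and m["precision"] == 1.0
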