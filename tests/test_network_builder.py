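import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from integranet import network_builder as nb
from integranet.expression_clusters import (ExpressionSet, GeneCluster,
                                            RegulatorCall)
from integranet.target_integration import Edge

COLS = ["t0", "t1", "t2", "t3"]


def _cluster(cid, members, klass="MGC"):
    cen = pd.Series([1.0, -1.0, 0.0, 1.0], index=COLS)
    return GeneCluster(cid, set(members), cen, klass)


def _expr(rows):
    return ExpressionSet(pd.DataFrame.from_dict(rows, orient="index",
                                                columns=COLS))


class TestEdgeSign:
    def test_mirna_edges_always_repress(self):
        sign, lc = nb.edge_sign("m1", "g1", {"m1": "miRNA"}, None)
        assert sign == "-" and not lc

    def test_tf_sign_follows_correlation(self):
        expr = _expr({"T": [1, 2, 3, 4], "gp": [2, 4, 6, 8],
                      "gn": [4, 3, 2, 1]})
        types = {"T": "TF"}
        assert nb.edge_sign("T", "gp", types, expr)[0] == "+"
        assert nb.edge_sign("T", "gn", types, expr)[0] == "-"

    def test_missing_profile_flags_low_confidence(self):
        expr = _expr({"T": [1, 2, 3, 4]})
        sign, lc = nb.edge_sign("T", "unknown", {"T": "TF"}, expr)
        assert lc


class TestBuildNetwork:
    def _inputs(self):
        clusters = [_cluster("c1", {"g1", "g2"}, "MGC")]
        calls = [RegulatorCall("T1", "TF", "c1", "correlated", 0.95),
                 RegulatorCall("m1", "miRNA", "c1", "anti-correlated",
                               -0.9)]
        types = {"T1": "TF", "m1": "miRNA", "g1": "mRNA", "g2": "mRNA"}
        return clusters, calls, types

    def test_chip_wins_over_prediction_for_same_pair(self):
        clusters, calls, types = self._inputs()
        chip = [Edge("T1", "g1", "chipseq")]
        pred = [Edge("T1", "g1", "predicted")]
        net = nb.build_network(clusters, calls, chip, pred, [],
                               node_types=types)
        assert net.number_of_edges() == 1
        assert net.edges["T1", "g1"]["evidence"] == "chipseq"
        assert net.edges["T1", "g1"]["step"] == 2

    def test_no_edges_prunes_everything(self):
        clusters, calls, types = self._inputs()
        net = nb.build_network(clusters, [], [], [], [], node_types=types)
        assert net.number_of_nodes() == 0
        kept = nb.build_network(clusters, [], [], [], [], node_types=types,
                                keep_isolated=True)
        assert set(kept.nodes) == {"g1", "g2"}

    def test_prediction_skipped_for_tfs_with_chip_data(self):
        clusters, calls, types = self._inputs()
        chip = [Edge("T1", "g1", "chipseq")]
        pred = [Edge("T1", "g2", "predicted")]
        net = nb.build_network(clusters, calls, chip, pred, [],
                               node_types=types)
        assert not net.has_edge("T1", "g2")

    def test_master_nodes_gain_step7_edges(self):
        clusters, calls, types = self._inputs()
        types["T9"] = "TF"
        pred = [Edge("T9", "g1", "predicted")]
        net = nb.build_network(clusters, calls, [], pred, [],
                               master_tfs=["T9"], node_types=types)
        assert net.nodes["T9"]["role"] == "master"
        assert net.edges["T9", "g1"]["step"] == 7

    def test_step7_edges_touch_a_master(self):
        clusters, calls, types = self._inputs()
        types["T9"] = "TF"
        mirna = [Edge("m1", "g1", "predicted")]
        pred = [Edge("T9", "g2", "predicted")]
        net = nb.build_network(clusters, calls, [], pred, mirna,
                               master_tfs=["T9"], node_types=types)
        masters = {n for n, d in net.nodes(data=True)
                   if d.get("role") == "master"}
        for u, v, d in net.edges(data=True):
            assert d["step"] in {2, 3, 4, 7}
            if d["step"] == 7:
                assert u in masters or v in masters

    def test_tf_mirna_id_collision_rejected(self):
        clusters, calls, types = self._inputs()
        types["dual"] = "TF"
        with pytest.raises(ValueError):
            nb.build_network(clusters, calls, [], [], [],
                             node_types={**types, "dual": "TF"},
                             master_mirnas=["dual"])

    def test_deterministic_rebuild(self):
        clusters, calls, types = self._inputs()
        chip = [Edge("T1", "g1", "chipseq")]
        mirna = [Edge("m1", "g2", "predicted")]
        a = nb.build_network(clusters, calls, chip, [], mirna,
                             node_types=types)
        b = nb.build_network(clusters, calls, chip, [], mirna,
                             node_types=types)
        assert nx.utils.graphs_equal(a, b)


class TestEgoSubnetwork:
    def _net(self):
        g = nx.DiGraph()
        for n in "afbx":
            g.add_node(n, node_type="mRNA")
        g.add_edge("a", "f", sign="+")
        g.add_edge("f", "b", sign="+")
        g.add_edge("a", "b", sign="-")
        return g

    def test_chain_with_chord_keeps_all_three_edges(self):
        ego = nb.ego_subnetwork(self._net(), "f")
        assert set(ego.edges) == {("a", "f"), ("f", "b"), ("a", "b")}

    def test_isolated_node(self):
        ego = nb.ego_subnetwork(self._net(), "x")
        assert set(ego.nodes) == {"x"} and ego.number_of_edges() == 0

    def test_idempotent(self):
        ego = nb.ego_subnetwork(self._net(), "f")
        again = nb.ego_subnetwork(ego, "f")
        assert nx.utils.graphs_equal(ego, again)

    def test_unknown_node(self):
        with pytest.raises(KeyError):
            nb.ego_subnetwork(self._net(), "zz")


def _typed_net(edges, types, classes=None):
    g = nx.DiGraph()
    classes = classes or {}
    for n, t in types.items():
        g.add_node(n, node_type=t, cluster_class=classes.get(n, "none"))
    for u, v, s in edges:
        g.add_edge(u, v, sign=s)
    return g


class TestFindFfls:
    TYPES = {"T": "TF", "M": "miRNA", "G": "mRNA"}

    def test_sign_algebra_coherent(self):
        # T activates G directly; T -| M -| G gives (-)(-) = + indirectly
        net = _typed_net([("T", "G", "+"), ("T", "M", "-"), ("M", "G", "-")],
                         self.TYPES, {"G": "MGC"})
        (motif,), n_skip = nb.find_ffls(net)
        assert motif.coherence == "coherent"
        assert motif.category == "C1"

    def test_sign_algebra_incoherent(self):
        net = _typed_net([("T", "G", "+"), ("T", "M", "+"), ("M", "G", "-")],
                         self.TYPES, {"G": "PGC"})
        (motif,), _ = nb.find_ffls(net)
        assert motif.coherence == "incoherent"
        assert motif.category == "I2"

    def test_unclassified_targets_excluded_but_counted(self):
        net = _typed_net([("T", "G", "+"), ("T", "M", "+"), ("M", "G", "-")],
                         self.TYPES)
        motifs, n_skip = nb.find_ffls(net)
        assert motifs == [] and n_skip == 1

    def test_matches_brute_force_on_random_networks(self):
        rng = np.random.default_rng(7)
        for trial in range(50):
            n = int(rng.integers(20, 61))
            types, classes = {}, {}
            for i in range(n):
                t = ["TF", "miRNA", "mRNA"][int(rng.integers(0, 3))]
                types[f"n{i}"] = t
                classes[f"n{i}"] = ["MGC", "PGC", "none"][
                    int(rng.integers(0, 3))]
            edges = []
            names = sorted(types)
            for _ in range(int(rng.integers(30, 150))):
                u, v = rng.choice(names, size=2, replace=False)
                edges.append((u, v, "+" if rng.random() < 0.5 else "-"))
            net = _typed_net(edges, types, classes)
            found, n_skip = nb.find_ffls(net)
            # oracle: exhaustive typed-triple enumeration
            oracle = set()
            skip = 0
            for t, m, g in itertools.permutations(names, 3):
                if (types[t] == "TF" and types[m] == "miRNA"
                        and types[g] == "mRNA" and net.has_edge(t, m)
                        and net.has_edge(m, g) and net.has_edge(t, g)):
                    if classes[g] == "none":
                        skip += 1
                    else:
                        oracle.add((t, m, g))
            assert {(f.tf, f.mirna, f.target) for f in found} == oracle
            assert n_skip == skip


class TestFeedbackLoops:
    def test_two_cycle_negative(self):
        net = _typed_net([("A", "B", "+"), ("B", "A", "-")],
                         {"A": "TF", "B": "TF"})
        assert nb.find_feedback_loops(net) == [(("A", "B"), "-")]

    def test_three_cycle_sign_product(self):
        net = _typed_net([("A", "B", "+"), ("B", "C", "-"),
                          ("C", "A", "-")], {n: "TF" for n in "ABC"})
        assert nb.find_feedback_loops(net) == [(("A", "B", "C"), "+")]

    def test_acyclic_empty(self):
        net = _typed_net([("A", "B", "+"), ("B", "C", "+")],
                         {n: "TF" for n in "ABC"})
        assert nb.find_feedback_loops(net) == []

    def test_matches_brute_force_on_random_networks(self):
        rng = np.random.default_rng(11)
        for trial in range(50):
            n = int(rng.integers(5, 31))
            names = [f"n{i}" for i in range(n)]
            edges = []
            seen = set()
            for _ in range(int(rng.integers(10, 80))):
                u, v = rng.choice(names, size=2, replace=False)
                if (u, v) not in seen:
                    seen.add((u, v))
                    edges.append((u, v, "+" if rng.random() < 0.5 else "-"))
            net = _typed_net(edges, {m: "TF" for m in names})
            found = nb.find_feedback_loops(net, max_len=3)
            oracle = set()
            for a, b in itertools.permutations(names, 2):
                if a < b and net.has_edge(a, b) and net.has_edge(b, a):
                    sign = (nb._sign_value(net.edges[a, b]["sign"])
                            * nb._sign_value(net.edges[b, a]["sign"]))
                    oracle.add(((a, b), "+" if sign > 0 else "-"))
            for a, b, c in itertools.permutations(names, 3):
                if a == min(a, b, c) and net.has_edge(a, b) \
                        and net.has_edge(b, c) and net.has_edge(c, a):
                    sign = (nb._sign_value(net.edges[a, b]["sign"])
                            * nb._sign_value(net.edges[b, c]["sign"])
                            * nb._sign_value(net.edges[c, a]["sign"]))
                    oracle.add(((a, b, c), "+" if sign > 0 else "-"))
            assert set(found) == oracle

    def test_max_len_bound(self):
        with pytest.raises(ValueError):
            nb.find_feedback_loops(nx.DiGraph(), max_len=1)


class TestMotifBias:
    def _motifs(self, spec):
        out = []
        i = 0
        for (coherence, klass), n in spec.items():
            for _ in range(n):
                cat = ("I" if coherence == "incoherent" else "C") + \
                    ("1" if klass == "myelination" else "2")
                out.append(nb.FflMotif(f"T{i}", f"m{i}", f"g{i}", coherence,
                                       klass, cat))
                i += 1
        return out

    def test_perfect_association_exact_p(self):
        motifs = self._motifs({("incoherent", "myelination"): 5,
                               ("coherent", "proliferation"): 5})
        res = nb.motif_bias_test(motifs)
        assert res["table"] == [[5, 0], [0, 5]]
        # two-sided Fisher exact: 2 / C(10,5) = 0.00793
        assert res["p"] == pytest.approx(2 / math.comb(10, 5))

    def test_balanced_table_p_one(self):
        motifs = self._motifs({("incoherent", "myelination"): 1,
                               ("incoherent", "proliferation"): 1,
                               ("coherent", "myelination"): 1,
                               ("coherent", "proliferation"): 1})
        assert nb.motif_bias_test(motifs)["p"] == 1.0

    def test_distinct_targets_counted_once(self):
        m = nb.FflMotif("T1", "m1", "gX", "incoherent", "myelination", "I1")
        m2 = nb.FflMotif("T2", "m2", "gX", "incoherent", "myelination",
                         "I1")
        res = nb.motif_bias_test([m, m2])
        assert res["table"][0][0] == 1  # one distinct target
        assert res["motif_counts"]["I1"] == 2

    def test_cell_sum_equals_distinct_labelled_targets(self):
        motifs = self._motifs({("incoherent", "myelination"): 3,
                               ("coherent", "proliferation"): 2})
        res = nb.motif_bias_test(motifs)
        assert sum(sum(r) for r in res["table"]) == 5

    def test_degenerate_table_p_one(self):
        motifs = self._motifs({("incoherent", "myelination"): 2})
        assert nb.motif_bias_test(motifs)["p"] == 1.0

    def test_no_motifs_rejected(self):
        with pytest.raises(ValueError):
            nb.motif_bias_test([])
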