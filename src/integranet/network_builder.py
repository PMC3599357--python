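"""Assembly of the integrated TF/miRNA regulatory network and motif census.

The network is grown step-wise: cluster genes seed the node set (step 0);
TFs and miRNAs whose expression tracks the clusters join as regulators
(step 1); TF edges come from ChIP-Seq where available (step 2) and from
binding-model prediction for TFs without ChIP data (step 3); miRNA->mRNA
edges come from target-prediction consensus (step 4); master TFs and
miRNAs enter as additional nodes (steps 5-6) whose edges are filled in
from ChIP then prediction (step 7). miRNA edges are always repressive;
TF edge signs follow the expression correlation between regulator and
target. Feedforward loops (TF -> gene, TF -> miRNA -> gene) are classified
as coherent when the direct sign equals the product of the indirect signs,
and by the target gene's cluster class into the four categories
I1 (incoherent, myelination), I2 (incoherent, proliferation),
C1 (coherent, myelination) and C2 (coherent, proliferation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .expression_clusters import ExpressionSet, GeneCluster, RegulatorCall
from .target_integration import Edge

log = logging.getLogger(__name__)

LOW_CONFIDENCE_R = 0.3


@dataclass(frozen=True)
class FflMotif:
    tf: str
    mirna: str
    target: str
    coherence: str  # {"coherent", "incoherent"}
    target_class: str  # {"myelination", "proliferation"}
    category: str  # {"I1", "I2", "C1", "C2"}


_CATEGORY = {
    ("incoherent", "myelination"): "I1",
    ("incoherent", "proliferation"): "I2",
    ("coherent", "myelination"): "C1",
    ("coherent", "proliferation"): "C2",
}


def _sign_value(s: str) -> int:
    return 1 if s == "+" else -1


def edge_sign(regulator: str, target: str, node_types: dict[str, str],
              expression: ExpressionSet | None) -> tuple[str, bool]:
    """Sign an edge: miRNA regulators always repress; TFs follow correlation.

    Returns (sign, low_confidence). TF signs with |r| < 0.3, or with a
    missing expression profile, are flagged low-confidence (defaulting to
    activation when no profile exists).
    """
    if node_types.get(regulator) == "miRNA":
        return "-", False
    if (expression is None or regulator not in expression.values.index
            or target not in expression.values.index):
        return "+", True
    a = expression.values.loc[regulator].to_numpy(dtype=float)
    b = expression.values.loc[target].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        return "+", True
    r = float(np.corrcoef(a, b)[0, 1])
    return ("+" if r >= 0 else "-"), abs(r) < LOW_CONFIDENCE_R


def _add_edge(g: nx.DiGraph, regulator: str, target: str, sign: str,
              evidence: str, step: int, low_confidence: bool = False) -> None:
    """Add an edge honouring the chipseq > predicted evidence precedence."""
    if g.has_edge(regulator, target):
        existing = g.edges[regulator, target]
        if existing["evidence"] == "chipseq" or evidence == "predicted":
            return
    if regulator == target:
        log.warning("self-loop %s -> %s from %s evidence", regulator,
                    target, evidence)
    g.add_edge(regulator, target, sign=sign, evidence=evidence, step=step,
               low_confidence=low_confidence)


def build_network(
    irgcs: list[GeneCluster],
    regulator_calls: list[RegulatorCall],
    chip_edges: list[Edge],
    predicted_tf_edges: list[Edge],
    mirna_edges: list[Edge],
    master_tfs: list[str] = (),
    master_mirnas: list[str] = (),
    expression: ExpressionSet | None = None,
    node_types: dict[str, str] | None = None,
    keep_isolated: bool = False,
) -> nx.DiGraph:
    """Assemble the regulatory network step by step.

    *node_types* maps every id to its type ("TF", "miRNA" or "mRNA"); ids
    not listed default to "mRNA". Edges among the current node set are
    added with their provenance step; ChIP evidence always wins over
    prediction for the same ordered pair. Isolated nodes are pruned unless
    *keep_isolated*.
    """
    node_types = dict(node_types or {})
    tf_ids = {n for n, t in node_types.items() if t == "TF"}
    mirna_ids = {n for n, t in node_types.items() if t == "miRNA"}
    collisions = tf_ids & mirna_ids
    if collisions:
        raise ValueError(f"ids typed both TF and miRNA: {sorted(collisions)}")

    g = nx.DiGraph()

    def ntype(node: str) -> str:
        return node_types.get(node, "mRNA")

    # Step 0: IRGC genes as candidate nodes
    gene_class = {}
    for c in irgcs:
        klass = c.cluster_class
        for gid in c.members:
            gene_class[gid] = klass
            g.add_node(gid, node_type=ntype(gid), role="target-only",
                       cluster_class=klass)

    # Step 1: correlated/anti-correlated TFs and miRNAs
    for call in regulator_calls:
        cluster = next((c for c in irgcs if c.cluster_id == call.cluster_id), None)
        klass = cluster.cluster_class if cluster is not None else "none"
        if call.regulator in g.nodes and g.nodes[call.regulator]["role"] != "target-only":
            continue
        g.add_node(call.regulator, node_type=call.regulator_type,
                   role=call.relation, cluster_class=klass)
        node_types[call.regulator] = call.regulator_type

    core_nodes = set(g.nodes)

    def sign_of(reg: str, tgt: str) -> tuple[str, bool]:
        return edge_sign(reg, tgt, node_types, expression)

    # Steps 2-4: edges among current nodes
    chip_tfs = {e.regulator for e in chip_edges}
    for e in chip_edges:
        if e.regulator in core_nodes and e.target in core_nodes:
            s, lc = sign_of(e.regulator, e.target)
            _add_edge(g, e.regulator, e.target, s, "chipseq", 2, lc)
    for e in predicted_tf_edges:
        if e.regulator in chip_tfs:
            continue  # prediction only for TFs lacking ChIP data
        if e.regulator in core_nodes and e.target in core_nodes:
            s, lc = sign_of(e.regulator, e.target)
            _add_edge(g, e.regulator, e.target, s, "predicted", 3, lc)
    for e in mirna_edges:
        if e.regulator in core_nodes and e.target in core_nodes:
            _add_edge(g, e.regulator, e.target, "-", "predicted", 4)

    # Steps 5-6: master regulators as additional nodes
    new_nodes = []
    for tf in master_tfs:
        if node_types.get(tf) == "miRNA":
            raise ValueError(f"master TF {tf!r} already typed as miRNA")
        if tf not in g.nodes:
            g.add_node(tf, node_type="TF", role="master", cluster_class="none")
            new_nodes.append(tf)
        else:
            g.nodes[tf]["role"] = "master"
        node_types[tf] = "TF"
    for mi in master_mirnas:
        if node_types.get(mi) == "TF":
            raise ValueError(f"master miRNA {mi!r} already typed as TF")
        if mi not in g.nodes:
            g.add_node(mi, node_type="miRNA", role="master",
                       cluster_class="none")
            new_nodes.append(mi)
        else:
            g.nodes[mi]["role"] = "master"
        node_types[mi] = "miRNA"

    # Step 7: edges between the new regulators and existing nodes
    new_set = set(new_nodes)
    if new_set:
        all_nodes = set(g.nodes)
        for e in chip_edges:
            if (e.regulator in new_set or e.target in new_set) and \
                    e.regulator in all_nodes and e.target in all_nodes:
                s, lc = sign_of(e.regulator, e.target)
                _add_edge(g, e.regulator, e.target, s, "chipseq", 7, lc)
        for e in predicted_tf_edges:
            if e.regulator in chip_tfs:
                continue
            if (e.regulator in new_set or e.target in new_set) and \
                    e.regulator in all_nodes and e.target in all_nodes:
                s, lc = sign_of(e.regulator, e.target)
                _add_edge(g, e.regulator, e.target, s, "predicted", 7, lc)
        for e in mirna_edges:
            if (e.regulator in new_set or e.target in new_set) and \
                    e.regulator in all_nodes and e.target in all_nodes:
                _add_edge(g, e.regulator, e.target, "-", "predicted", 7)

    if not keep_isolated:
        isolated = [n for n in g.nodes if g.degree(n) == 0]
        g.remove_nodes_from(isolated)
    return g


def ego_subnetwork(network: nx.DiGraph, node: str) -> nx.DiGraph:
    """Focal node, its direct regulators and targets, and all edges among them."""
    if node not in network.nodes:
        raise KeyError(f"unknown node {node!r}")
    nodes = {node} | set(network.predecessors(node)) | set(network.successors(node))
    return network.subgraph(nodes).copy()


def find_ffls(network: nx.DiGraph) -> tuple[list[FflMotif], int]:
    """All feedforward loops TF -> gene with a miRNA intermediary.

    Emits every triple (T: TF, M: miRNA, G: mRNA) with edges T->G, T->M and
    M->G. Coherent iff sign(T->G) = sign(T->M) * sign(M->G). Motifs whose
    target gene carries no MGC/PGC class are excluded; their count is
    returned alongside the motif list.
    """
    motifs: list[FflMotif] = []
    n_unclassified = 0
    tfs = [n for n, d in network.nodes(data=True) if d.get("node_type") == "TF"]
    for t in sorted(tfs):
        succ = set(network.successors(t))
        mirnas = [m for m in succ
                  if network.nodes[m].get("node_type") == "miRNA"]
        for m in sorted(mirnas):
            for gtarget in sorted(set(network.successors(m)) & succ):
                if network.nodes[gtarget].get("node_type") != "mRNA":
                    continue
                direct = _sign_value(network.edges[t, gtarget]["sign"])
                indirect = (_sign_value(network.edges[t, m]["sign"])
                            * _sign_value(network.edges[m, gtarget]["sign"]))
                coherence = "coherent" if direct == indirect else "incoherent"
                klass = network.nodes[gtarget].get("cluster_class", "none")
                if klass == "MGC":
                    tclass = "myelination"
                elif klass == "PGC":
                    tclass = "proliferation"
                else:
                    n_unclassified += 1
                    continue
                motifs.append(FflMotif(t, m, gtarget, coherence, tclass,
                                       _CATEGORY[(coherence, tclass)]))
    return motifs, n_unclassified


def find_feedback_loops(network: nx.DiGraph,
                        max_len: int = 3) -> list[tuple[tuple[str, ...], str]]:
    """Simple directed cycles up to *max_len*, with the loop sign.

    Each cycle is reported once in canonical rotation (lexicographically
    smallest starting node); the sign is the product of its edge signs
    ('+' positive loop, '-' negative loop).
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    out = []
    for cycle in nx.simple_cycles(network, length_bound=max_len):
        start = min(range(len(cycle)), key=lambda i: cycle[i])
        canon = tuple(cycle[start:] + cycle[:start])
        prod = 1
        for a, b in zip(canon, canon[1:] + (canon[0],)):
            prod *= _sign_value(network.edges[a, b]["sign"])
        out.append((canon, "+" if prod > 0 else "-"))
    return sorted(out)


def motif_bias_test(motifs: list[FflMotif]) -> dict:
    """2x2 coherence-by-class counts with a two-sided Fisher exact test.

    Rows are {incoherent, coherent}, columns {myelination, proliferation}.
    The tested table counts DISTINCT target genes per cell (a gene caught
    in many loops is counted once); motif-level counts are also reported.
    """
    if not motifs:
        raise ValueError("no motifs to test")
    distinct = {("incoherent", "myelination"): set(),
                ("incoherent", "proliferation"): set(),
                ("coherent", "myelination"): set(),
                ("coherent", "proliferation"): set()}
    motif_counts = {k: 0 for k in distinct}
    for m in motifs:
        key = (m.coherence, m.target_class)
        distinct[key].add(m.target)
        motif_counts[key] += 1
    table = [[len(distinct[("incoherent", "myelination")]),
              len(distinct[("incoherent", "proliferation")])],
             [len(distinct[("coherent", "myelination")]),
              len(distinct[("coherent", "proliferation")])]]
    rows_ok = all(sum(r) > 0 for r in table)
    cols_ok = all(table[0][j] + table[1][j] > 0 for j in range(2))
    if not (rows_ok and cols_ok):
        log.warning("degenerate 2x2 table %s; p = 1", table)
        p = 1.0
    else:
        _, p = stats.fisher_exact(table, alternative="two-sided")
    return {
        "table": table,
        "motif_counts": {"".join(("I" if c == "incoherent" else "C",
                                  "1" if t == "myelination" else "2")): n
                         for (c, t), n in motif_counts.items()},
        "p": float(p),
    }
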