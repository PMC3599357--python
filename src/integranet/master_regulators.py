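"""Master-regulator discovery for coexpressed clusters.

A master regulator drives a coexpressed cluster even though its own
expression does not track the cluster (it may lag, or be regulated
post-transcriptionally). Master TFs are found by R-score enrichment: each
gene's binding score for a TF is converted to a rank-based percentile
R in (0, 1], the cluster statistic is the mean R of its members, and
significance comes from comparing to randomly drawn same-size clusters,
Bonferroni-corrected across the TFs tested (cutoff 0.05). Master miRNAs
are found by hypergeometric enrichment of their predicted targets among
the cluster members, with no multiplicity correction (cutoff 0.05),
mirroring the asymmetry of the original analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class EnrichmentResult:
    regulator: str
    cluster_id: str
    statistic: float  # mean R, or overlap count k
    p: float
    adjusted_p: float
    significant: bool
    N: int = 0
    K: int = 0
    n: int = 0
    k: int = 0


def r_scores(binding_scores: dict[str, float]) -> dict[str, float]:
    """Rank-based percentile R = ascending-rank / N, average rank on ties.

    Higher binding score implies higher R; the maximum R is 1 when the top
    score is untied.
    """
    if len(binding_scores) < 2:
        raise ValueError("need at least 2 scored targets")
    targets = sorted(binding_scores)
    vals = np.array([binding_scores[t] for t in targets], dtype=float)
    ranks = stats.rankdata(vals, method="average")
    n = len(vals)
    return {t: float(r) / n for t, r in zip(targets, ranks)}


def master_tfs(
    cluster: set[str],
    rtable: dict[str, dict[str, float]],
    universe: set[str],
    n_random: int = 9999,
    seed: int = 0,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    cluster_id: str = "cluster",
) -> list[EnrichmentResult]:
    """R-score enrichment of a cluster against same-size random clusters.

    For each regulator in *rtable* the statistic is the mean R over cluster
    members; the null is *n_random* uniform same-size draws from *universe*;
    p = (1 + #{null mean >= observed}) / (n_random + 1). Bonferroni across
    the regulators tested (or none, with correction="none").
    """
    if n_random < 99:
        raise ValueError("n_random must be >= 99")
    if not cluster <= universe:
        raise ValueError("cluster must be a subset of the universe")
    if len(cluster) > len(universe):
        raise ValueError("cluster larger than universe")
    rng = np.random.default_rng(seed)
    uni = sorted(universe)
    m = len(rtable)
    # same-size clusters drawn without replacement: random keys, take the
    # smallest |cluster| per row
    keys = rng.random((n_random, len(uni)))
    draws = np.argpartition(keys, len(cluster) - 1, axis=1)[:, :len(cluster)]
    results = []
    for reg in sorted(rtable):
        rs = rtable[reg]
        r_uni = np.array([rs.get(t, 0.0) for t in uni])
        member_idx = [i for i, t in enumerate(uni) if t in cluster]
        observed = float(r_uni[member_idx].mean())
        null_means = r_uni[draws].mean(axis=1)
        p = (1 + int((null_means >= observed - 1e-12).sum())) / (n_random + 1)
        adj = min(1.0, p * m) if correction == "bonferroni" else p
        results.append(EnrichmentResult(reg, cluster_id, observed, p, adj,
                                        adj <= alpha))
    return results


def master_mirnas(
    cluster: set[str],
    mirna_targets: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
    correction: str = "none",
    cluster_id: str = "cluster",
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of each miRNA's targets in the cluster.

    Population N = genes in *universe* (expressed genes that are a
    predicted target of at least one miRNA); successes K = the miRNA's
    targets within the universe; sample n = cluster size; observed k =
    the miRNA's targets within the cluster. p = P(X >= k).
    """
    if not cluster <= universe:
        raise ValueError("cluster must be a subset of the universe")
    N = len(universe)
    if N == 0:
        raise ValueError("empty universe")
    n = len(cluster)
    m = len(mirna_targets)
    results = []
    for mirna in sorted(mirna_targets):
        targets = mirna_targets[mirna] & universe
        K = len(targets)
        k = len(targets & cluster)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        adj = min(1.0, p * m) if correction == "bonferroni" else p
        results.append(EnrichmentResult(mirna, cluster_id, float(k), p, adj,
                                        adj <= alpha, N, K, n, k))
    return results
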