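"""Injury-response gene clusters and their correlated regulators.

The first stage of network inference identifies clusters of genes that are
coexpressed across an injury/development time-course and dynamically
regulated after nerve crush (injury response gene clusters, IRGCs), then
finds transcription factors and miRNAs whose expression tracks, or mirrors,
each cluster centroid.

Clusters whose centroid drops immediately after crush (relative to the
uninjured baseline) are labelled myelination gene clusters (MGC); clusters
with the reciprocal pattern are proliferation gene clusters (PGC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)


@dataclass
class ExpressionSet:
    """A feature x timepoint expression matrix with presence calls."""

    values: pd.DataFrame
    presence: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if self.presence is None:
            self.presence = pd.DataFrame(
                True, index=self.values.index, columns=self.values.columns)
        if self.presence.shape != self.values.shape:
            raise ValueError("presence matrix must match values shape")

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def timepoints(self) -> pd.Index:
        return self.values.columns


@dataclass
class GeneCluster:
    cluster_id: str
    members: set[str]
    centroid: pd.Series  # indexed by timepoint labels
    cluster_class: str = "unassigned"  # {"MGC", "PGC", "unassigned"}

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")


@dataclass(frozen=True)
class RegulatorCall:
    regulator: str
    regulator_type: str  # {"TF", "miRNA"}
    cluster_id: str
    relation: str  # {"correlated", "anti-correlated"}
    r: float


def call_expressed(expr: ExpressionSet) -> set[str]:
    """Features called present in at least one data point."""
    mask = expr.presence.any(axis=1)
    return set(expr.values.index[mask])


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; NaN when either vector has zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def find_irgcs(
    expr: ExpressionSet,
    k: int,
    myelin_genes: set[str],
    injury_pre: list[str],
    injury_post: list[str],
    alpha: float = 0.05,
    merge_r: float = 0.85,
    assign_r: float = 0.8,
    seed: int = 0,
) -> list[GeneCluster]:
    """Find injury response gene clusters.

    Pipeline: (a) k-means on per-gene z-scored profiles; (b) keep clusters
    that contain at least one known myelin gene and whose member genes are
    differentially expressed pre- vs post-crush (two-sample t-test on the
    per-gene pre-crush and post-crush means, p < *alpha*); (c) merge kept
    clusters whose centroids correlate at Pearson r >= *merge_r*; (d) final
    membership = every expressed gene with r >= *assign_r* to a merged
    centroid, assigned to its best-r centroid; (e) label each cluster MGC if
    the centroid falls immediately post-crush relative to baseline, else PGC.

    Returns an empty list (with a warning) when no cluster survives (b).
    """
    genes = list(expr.values.index)
    if k > len(genes):
        raise ValueError(f"k={k} exceeds number of genes ({len(genes)})")
    if k < 2:
        raise ValueError("k must be >= 2")
    vals = expr.values.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - mu) / sd

    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(z)

    pre_idx = [expr.values.columns.get_loc(c) for c in injury_pre]
    post_idx = [expr.values.columns.get_loc(c) for c in injury_post]

    kept: list[set[str]] = []
    for c in range(k):
        members = {g for g, lbl in zip(genes, labels) if lbl == c}
        if not members or not (members & myelin_genes):
            continue
        midx = [i for i, g in enumerate(genes) if g in members]
        pre_means = vals[midx][:, pre_idx].mean(axis=1)
        post_means = vals[midx][:, post_idx].mean(axis=1)
        if len(midx) < 2:
            continue
        _, p = stats.ttest_ind(pre_means, post_means)
        if np.isnan(p) or p >= alpha:
            continue
        kept.append(members)

    if not kept:
        log.warning("no cluster passed the myelin-gene / differential filter")
        return []

    # (c) merge kept clusters with correlated centroids (transitive closure)
    def centroid_of(members: set[str]) -> np.ndarray:
        midx = [i for i, g in enumerate(genes) if g in members]
        return z[midx].mean(axis=0)

    merged = [set(m) for m in kept]
    changed = True
    while changed:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                r = _pearson(centroid_of(merged[i]), centroid_of(merged[j]))
                if not np.isnan(r) and r >= merge_r:
                    merged[i] |= merged.pop(j)
                    changed = True
                    break
            if changed:
                break

    centroids = [centroid_of(m) for m in merged]

    # (d) reassign all expressed genes to best centroid with r >= assign_r
    final_members: list[set[str]] = [set() for _ in merged]
    for i, g in enumerate(genes):
        rs = np.array([_pearson(z[i], c) for c in centroids])
        rs = np.where(np.isnan(rs), -np.inf, rs)
        best = int(np.argmax(rs))
        if rs[best] >= assign_r:
            final_members[best].add(g)

    out: list[GeneCluster] = []
    cid = 1
    for members, cen in zip(final_members, centroids):
        if not members:
            continue
        midx = [i for i, g in enumerate(genes) if g in members]
        cen = z[midx].mean(axis=0)  # recompute from final members
        baseline = cen[pre_idx].mean()
        first_post = cen[post_idx[0]]
        klass = "MGC" if first_post < baseline else "PGC"
        out.append(GeneCluster(
            cluster_id=f"cluster{cid}",
            members=members,
            centroid=pd.Series(cen, index=expr.values.columns),
            cluster_class=klass,
        ))
        cid += 1
    return out


def filter_mirna_expression(
    mirna_expr: ExpressionSet,
    probeset_map: dict[str, tuple[str, str]],
    control_probesets: set[str],
    alpha: float = 0.05,
) -> ExpressionSet:
    """Collapse duplicate miRNA probesets to one filtered row per miRNA.

    A miRNA is dropped when its expression never rises above the average of
    the control probesets, or when one duplicate probeset exceeds the other
    at every timepoint and a one-sided Mann-Whitney U test across timepoints
    is significant at *alpha* (an irreconcilable duplicate disagreement).
    Surviving rows are the per-timepoint mean of the two duplicates.
    """
    if not control_probesets:
        raise ValueError("control probeset set must be non-empty")
    vals = mirna_expr.values
    missing_controls = control_probesets - set(vals.index)
    if missing_controls:
        raise ValueError(f"control probesets absent: {sorted(missing_controls)}")
    control_mean = vals.loc[sorted(control_probesets)].to_numpy().mean()

    rows = {}
    for mirna, probes in probeset_map.items():
        if len(probes) != 2:
            raise ValueError(f"{mirna}: expected exactly 2 probesets, got {len(probes)}")
        a = vals.loc[probes[0]].to_numpy(dtype=float)
        b = vals.loc[probes[1]].to_numpy(dtype=float)
        if max(a.max(), b.max()) < control_mean:
            log.info("dropping %s: below control-probeset average", mirna)
            continue
        dominant = None
        if (a > b).all():
            dominant, other = a, b
        elif (b > a).all():
            dominant, other = b, a
        if dominant is not None:
            _, p = stats.mannwhitneyu(dominant, other,
                                      alternative="greater", method="exact")
            if p < alpha:
                log.info("dropping %s: duplicate probesets disagree (p=%.4g)",
                         mirna, p)
                continue
        rows[mirna] = (a + b) / 2.0

    out_vals = pd.DataFrame.from_dict(rows, orient="index",
                                      columns=vals.columns)
    out_vals.index.name = vals.index.name
    return ExpressionSet(out_vals)


def correlate_regulators(
    candidates: ExpressionSet,
    clusters: list[GeneCluster],
    regulator_type: str,
    timepoint_map: dict[str, str] | None = None,
    r_cut: float = 0.8,
) -> list[RegulatorCall]:
    """Call regulators whose profiles (anti-)correlate with cluster centroids.

    *timepoint_map* aligns candidate timepoint labels to centroid timepoint
    labels when the two platforms sampled different days (e.g. miRNA days
    0/4/14 matched to mRNA days 0/4/10). At least 3 mapped points are
    required for Pearson r to be meaningful.
    """
    if timepoint_map is None:
        common = [c for c in candidates.values.columns]
        timepoint_map = {c: c for c in common}
    cand_cols = list(timepoint_map.keys())
    if len(cand_cols) < 3:
        raise ValueError("need at least 3 mapped timepoints for correlation")
    calls: list[RegulatorCall] = []
    for cluster in clusters:
        cen = np.array([cluster.centroid[timepoint_map[c]] for c in cand_cols])
        for reg in candidates.values.index:
            prof = candidates.values.loc[reg, cand_cols].to_numpy(dtype=float)
            r = _pearson(prof, cen)
            if np.isnan(r):
                log.info("no call for %s vs %s: zero-variance profile",
                         reg, cluster.cluster_id)
                continue
            if r >= r_cut:
                calls.append(RegulatorCall(reg, regulator_type,
                                           cluster.cluster_id, "correlated", r))
            elif r <= -r_cut:
                calls.append(RegulatorCall(reg, regulator_type,
                                           cluster.cluster_id, "anti-correlated", r))
    return calls


def clusters_to_frame(clusters: list[GeneCluster]) -> pd.DataFrame:
    """Cluster assignments as a tidy table (gene, cluster, class)."""
    rows = []
    for c in clusters:
        for g in sorted(c.members):
            rows.append((g, c.cluster_id, c.cluster_class))
    return pd.DataFrame(rows, columns=["gene", "cluster", "class"])
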