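"""One-command orchestration of the network-inference workflow.

The pipeline executes the eight construction steps in order — cluster
identification, regulator correlation, ChIP-derived edges, predicted TF
edges, miRNA target consensus, master TF and master miRNA discovery, and
edge fill-in for the master nodes — writing every intermediate artifact to
the output directory together with a manifest. A single global seed
deterministically derives per-module sub-seeds, so identical config plus
seed yields byte-identical outputs.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression_clusters as ec
from . import io_formats as iof
from . import master_regulators as mr
from . import network_builder as nb
from . import phylo_tfbs as pt
from . import target_integration as ti
from . import tssvote as tv

log = logging.getLogger(__name__)

_KNOWN_SECTIONS = {"seed", "paths", "cluster", "tfbs", "targets", "master",
                   "network"}
_KNOWN_KEYS = {
    "paths": {"annotation", "genome", "tracks", "pwms", "tree",
              "mrna_expression", "mrna_presence", "mirna_expression",
              "mirna_probesets", "mirna_controls", "myelin_genes",
              "target_lists", "peaks", "utrs", "mirna_mature", "rp_track",
              "validated_tss"},
    "cluster": {"k", "alpha", "merge_r", "assign_r", "r_cut", "injury_pre",
                "injury_post", "timepoint_map"},
    "tfbs": {"n_perm", "alpha", "cutoff", "w_floor"},
    "targets": {"min_methods", "min_overlap_bp"},
    "master": {"n_random", "alpha", "correction"},
    "network": {"keep_isolated"},
}


@dataclass
class PipelineConfig:
    base_dir: Path
    seed: int = 0
    paths: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    tfbs: dict = field(default_factory=dict)
    targets: dict = field(default_factory=dict)
    master: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)

    def path(self, key: str) -> Path | None:
        rel = self.paths.get(key)
        return self.base_dir / rel if rel is not None else None


@dataclass
class PipelineResult:
    clusters: list
    regulator_calls: list
    tss_predictions: dict
    chip_edges: list
    predicted_edges: list
    mirna_edges: list
    binding_results: list
    binding_scores: dict  # tf -> {gene target -> score}
    master_tf_results: list
    master_mirna_results: list
    master_tfs: list
    master_mirnas: list
    network: object
    motifs: list
    n_unclassified_motifs: int
    motif_bias: dict | None
    feedback_loops: list


def load_config(toml_path: str | Path) -> PipelineConfig:
    """Parse and validate the TOML pipeline config; unknown keys rejected."""
    toml_path = Path(toml_path)
    with open(toml_path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    for section, allowed in _KNOWN_KEYS.items():
        extra = set(raw.get(section, {})) - allowed
        if extra:
            raise ValueError(f"unknown keys in [{section}]: {sorted(extra)}")
    cfg = PipelineConfig(
        base_dir=toml_path.parent,
        seed=int(raw.get("seed", 0)),
        paths=raw.get("paths", {}),
        cluster=raw.get("cluster", {}),
        tfbs=raw.get("tfbs", {}),
        targets=raw.get("targets", {}),
        master=raw.get("master", {}),
        network=raw.get("network", {}),
    )
    for key, rel in cfg.paths.items():
        if key == "peaks":
            for tf, p in rel.items():
                if not (cfg.base_dir / p).exists():
                    raise FileNotFoundError(f"peaks[{tf}]: {p} not found")
        elif key == "target_lists":
            for p in rel:
                if not (cfg.base_dir / p).exists():
                    raise FileNotFoundError(f"target list {p} not found")
        elif not (cfg.base_dir / rel).exists():
            raise FileNotFoundError(f"paths.{key}: {rel} not found")
    return cfg


def _read_presence(cfg: PipelineConfig, values: pd.DataFrame) -> pd.DataFrame:
    p = cfg.path("mrna_presence")
    if p is None:
        return pd.DataFrame(True, index=values.index, columns=values.columns)
    df = pd.read_csv(p, sep="\t", index_col=0)
    return df.astype(bool).loc[values.index, values.columns]


def _promoter_sequence(genome: dict[str, str], iv) -> str:
    return genome[iv.chrom][iv.start:iv.end]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Run all steps and write intermediates, the network and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    cluster_seed = seed % 2**31
    tfbs_seed = (seed + 1) % 2**31
    master_seed = (seed + 2) % 2**31

    annotation = iof.read_annotation(config.path("annotation"))
    genome = iof.read_fasta(config.path("genome"))
    annotation.chrom_lengths = {c: len(s) for c, s in genome.items()}
    tracks, reference = iof.load_tracks(config.path("tracks"))
    pwms = iof.read_pwms(config.path("pwms"))
    tree = iof.read_tree(config.path("tree"))
    phylo = pt.PhyloWeights(tree, reference)

    mrna_values = iof.read_expression_tsv(config.path("mrna_expression"))
    mrna = ec.ExpressionSet(mrna_values, _read_presence(config, mrna_values))
    myelin = set(config.path("myelin_genes").read_text().split())

    ccfg = config.cluster
    injury_pre = list(ccfg.get("injury_pre", []))
    injury_post = list(ccfg.get("injury_post", []))
    timepoint_map = dict(ccfg.get("timepoint_map", {}))

    # ------------------------------------------------------------ step 0
    expressed = ec.call_expressed(mrna)
    expr_sub = ec.ExpressionSet(
        mrna.values.loc[sorted(expressed)],
        mrna.presence.loc[sorted(expressed)])
    clusters = ec.find_irgcs(
        expr_sub, k=int(ccfg.get("k", 12)), myelin_genes=myelin,
        injury_pre=injury_pre, injury_post=injury_post,
        alpha=float(ccfg.get("alpha", 0.05)),
        merge_r=float(ccfg.get("merge_r", 0.85)),
        assign_r=float(ccfg.get("assign_r", 0.8)), seed=cluster_seed)
    ec.clusters_to_frame(clusters).to_csv(out / "clusters.tsv", sep="\t",
                                          index=False)
    log.info("step 0: %d IRGCs over %d genes", len(clusters),
             sum(len(c.members) for c in clusters))

    # ------------------------------------------------------------ step 1
    tf_ids = sorted(annotation.tf_ids)
    r_cut = float(ccfg.get("r_cut", 0.8))
    tf_expr = ec.ExpressionSet(
        mrna.values.loc[[t for t in tf_ids if t in mrna.values.index]])
    tf_calls = ec.correlate_regulators(tf_expr, clusters, "TF", None, r_cut)

    mirna_raw = iof.read_expression_tsv(config.path("mirna_expression"))
    probes = pd.read_csv(config.path("mirna_probesets"), sep="\t", dtype=str)
    probeset_map = {r.mirna: (r.probe1, r.probe2)
                    for r in probes.itertuples(index=False)}
    controls = set(config.path("mirna_controls").read_text().split())
    mirna_expr = ec.filter_mirna_expression(
        ec.ExpressionSet(mirna_raw), probeset_map, controls,
        alpha=float(ccfg.get("alpha", 0.05)))
    mirna_calls = ec.correlate_regulators(mirna_expr, clusters, "miRNA",
                                          timepoint_map, r_cut)
    regulator_calls = tf_calls + mirna_calls
    pd.DataFrame(
        [(c.regulator, c.regulator_type, c.cluster_id, c.relation,
          round(c.r, 4)) for c in regulator_calls],
        columns=["regulator", "type", "cluster", "relation", "r"]).to_csv(
        out / "regulators.tsv", sep="\t", index=False)
    log.info("step 1: %d TF and %d miRNA regulator calls",
             len(tf_calls), len(mirna_calls))

    # ------------------------------------- miRNA TSS prediction (for 2/3)
    tss_predictions = {}
    for mid in sorted(annotation.mirnas):
        tss_predictions[mid] = tv.predict_tss(mid, annotation, tracks)
    pd.DataFrame(
        [(p.mirna, p.category, p.tss, round(p.score, 3), p.n_tied_windows,
          p.promoter.start, p.promoter.end, p.strand)
         for p in tss_predictions.values()],
        columns=["mirna", "category", "tss", "score", "n_tied",
                 "promoter_start", "promoter_end", "strand"]).to_csv(
        out / "tss_predictions.tsv", sep="\t", index=False)

    # ------------------------------------------------------------ step 2
    tcfg = config.targets
    min_overlap = int(tcfg.get("min_overlap_bp", 1))
    gene_tss_table = {
        g: (rec.interval.chrom, rec.tss, rec.interval.oriented_strand())
        for g, rec in annotation.genes.items()}
    mirna_tss_table = {
        m: (annotation.mirnas[m].interval.chrom, p.tss, p.strand)
        for m, p in tss_predictions.items()}
    chip_edges: list[ti.Edge] = []
    peak_paths = config.paths.get("peaks", {})
    if peak_paths:
        for tf in sorted(peak_paths):
            peaks = ti.PeakSet(tf, iof.read_bed(config.base_dir / peak_paths[tf]))
            chip_edges += ti.peaks_to_targets(
                peaks, gene_tss_table, *ti.MRNA_WINDOW, min_overlap)
            chip_edges += ti.peaks_to_targets(
                peaks, mirna_tss_table, *ti.MIRNA_WINDOW, min_overlap)
    else:
        log.info("no ChIP peak files configured; steps 2/7 use prediction only")
    log.info("step 2: %d ChIP edges", len(chip_edges))

    # ------------------------------------------------------------ step 3
    fcfg = config.tfbs
    cutoff = fcfg.get("cutoff", "default")
    w_floor = float(fcfg.get("w_floor", 0.0))
    spaces: list[pt.SearchSpace] = []
    seqs: dict[str, list[str]] = {}
    for g in sorted(expressed & set(annotation.genes)):
        chrom, tss, strand = gene_tss_table[g]
        iv = tv.mrna_promoter(chrom, tss, strand,
                              chrom_len=annotation.chrom_lengths.get(chrom))
        space = pt.SearchSpace(g, [iv])
        spaces.append(space)
        seqs[g] = [_promoter_sequence(genome, i) for i in space.intervals]
    for m in sorted(annotation.mirnas):
        space = pt.SearchSpace(m, [tss_predictions[m].promoter])
        spaces.append(space)
        seqs[m] = [_promoter_sequence(genome, i) for i in space.intervals]

    rp_path = config.path("rp_track")
    if rp_path is not None:
        _extend_with_rp(spaces, seqs, genome, annotation, rp_path)

    sites_by_pwm: dict[str, list[pt.BindingSite]] = {}
    pwm_tf = {p.id: p.tf_id for p in pwms}
    for pwm in pwms:
        all_sites = []
        for space in spaces:
            found = pt.scan_pwm(space, seqs[space.target], pwm, cutoff)
            all_sites += pt.annotate_conservation(found, tracks.alignment,
                                                  phylo, w_floor)
        sites_by_pwm[pwm.id] = all_sites
    pvals = pt.binding_pvalues(sites_by_pwm,
                               spaces, n_perm=int(fcfg.get("n_perm", 999)),
                               seed=tfbs_seed)
    raw_results = []
    binding_scores: dict[str, dict[str, float]] = {}
    for pwm in pwms:
        by_target: dict[str, list[pt.BindingSite]] = {}
        for s in sites_by_pwm[pwm.id]:
            by_target.setdefault(s.target, []).append(s)
        for space in spaces:
            t = space.target
            sites = by_target.get(t, [])
            score = pt.binding_score(sites) if sites else 0.0
            raw_results.append(pt.BindingResult(
                pwm.tf_id, pwm.id, t, len(sites), score,
                pvals[(pwm.id, t)]))
            if t in annotation.genes:
                tf_scores = binding_scores.setdefault(pwm.tf_id, {})
                tf_scores[t] = max(tf_scores.get(t, 0.0), score)
    tf_n_pwms = {tf: len({p.id for p in pwms if p.tf_id == tf})
                 for tf in {p.tf_id for p in pwms}}
    binding_results = pt.tf_targets(raw_results, tf_n_pwms,
                                    alpha=float(fcfg.get("alpha", 0.005)))
    pd.DataFrame(
        [(r.tf, r.pwm_id, r.target, r.n_sites, f"{r.score:.6g}", r.raw_p,
          r.adjusted_p, r.is_target) for r in binding_results],
        columns=["tf", "pwm", "target", "n_sites", "score", "raw_p",
                 "adjusted_p", "is_target"]).to_csv(
        out / "binding_results.tsv", sep="\t", index=False)
    predicted_edges = [ti.Edge(r.tf, r.target, "predicted")
                       for r in binding_results if r.is_target]
    log.info("step 3: %d predicted TF edges", len(predicted_edges))

    # ------------------------------------------------------------ step 4
    lists = []
    for p in config.paths.get("target_lists", []):
        df = pd.read_csv(config.base_dir / p, sep="\t", dtype=str)
        lists.append(ti.TargetPairSet(
            Path(p).stem, frozenset((r.mirna, r.gene)
                                    for r in df.itertuples(index=False))))
    mirna_edges = ti.consensus_mirna_targets(
        lists, int(tcfg.get("min_methods", 2))) if lists else []
    log.info("step 4: %d consensus miRNA edges", len(mirna_edges))

    # --------------------------------------------------------- steps 5-6
    mcfg = config.master
    n_random = int(mcfg.get("n_random", 9999))
    m_alpha = float(mcfg.get("alpha", 0.05))
    correction = mcfg.get("correction", "bonferroni")
    gene_universe = expressed & set(annotation.genes)
    rtable = {tf: mr.r_scores({g: sc.get(g, 0.0) for g in gene_universe})
              for tf, sc in sorted(binding_scores.items())
              if len(gene_universe) >= 2}
    master_tf_results = []
    for i, c in enumerate(clusters):
        members = c.members & gene_universe
        if not members:
            continue
        master_tf_results += mr.master_tfs(
            members, rtable, gene_universe, n_random=n_random,
            seed=master_seed + i, alpha=m_alpha, correction=correction,
            cluster_id=c.cluster_id)
    master_tfs = sorted({r.regulator for r in master_tf_results
                         if r.significant})

    mirna_target_map: dict[str, set[str]] = {}
    for e in mirna_edges:
        mirna_target_map.setdefault(e.regulator, set()).add(e.target)
    targeted_universe = expressed & set().union(
        *mirna_target_map.values()) if mirna_target_map else set()
    master_mirna_results = []
    for c in clusters:
        sample = c.members & targeted_universe
        if not sample or not targeted_universe:
            continue
        master_mirna_results += mr.master_mirnas(
            sample, mirna_target_map, targeted_universe, alpha=m_alpha,
            cluster_id=c.cluster_id)
    master_mirnas = sorted({r.regulator for r in master_mirna_results
                            if r.significant})
    _write_master_tables(out, master_tf_results, master_mirna_results)
    log.info("steps 5-6: %d master TFs, %d master miRNAs",
             len(master_tfs), len(master_mirnas))

    # --------------------------------------------------------- steps 0-7
    node_types = {g: ("TF" if rec.gene_type == "TF" else "mRNA")
                  for g, rec in annotation.genes.items()}
    node_types.update({m: "miRNA" for m in annotation.mirnas})
    sign_expr = _signing_expression(mrna, mirna_expr, timepoint_map)
    network = nb.build_network(
        clusters, regulator_calls, chip_edges, predicted_edges, mirna_edges,
        master_tfs, master_mirnas, expression=sign_expr,
        node_types=node_types,
        keep_isolated=bool(config.network.get("keep_isolated", False)))
    for fmt, name in (("edge_tsv", "network_edges.tsv"),
                      ("graphml", "network.graphml"),
                      ("sif", "network.sif")):
        iof.write_network(network, out / name, fmt)
    log.info("step 7 complete: %d nodes, %d edges",
             network.number_of_nodes(), network.number_of_edges())

    motifs, n_unclassified = nb.find_ffls(network)
    pd.DataFrame([(m.tf, m.mirna, m.target, m.coherence, m.target_class,
                   m.category) for m in motifs],
                 columns=["tf", "mirna", "target", "coherence", "class",
                          "category"]).to_csv(out / "motifs.tsv", sep="\t",
                                              index=False)
    bias = nb.motif_bias_test(motifs) if motifs else None
    loops = nb.find_feedback_loops(network)

    files = sorted(p.name for p in out.iterdir() if p.is_file()
                   and p.name != "manifest.tsv")
    pd.DataFrame({"file": files}).to_csv(out / "manifest.tsv", sep="\t",
                                         index=False)
    return PipelineResult(
        clusters, regulator_calls, tss_predictions, chip_edges,
        predicted_edges, mirna_edges, binding_results, binding_scores,
        master_tf_results, master_mirna_results, master_tfs, master_mirnas,
        network, motifs, n_unclassified, bias, loops)


def _signing_expression(mrna: ec.ExpressionSet, mirna: ec.ExpressionSet,
                        timepoint_map: dict[str, str]) -> ec.ExpressionSet:
    """Merge mRNA and miRNA profiles onto the shared injury timepoints."""
    if not timepoint_map:
        return mrna
    mirna_cols = list(timepoint_map)
    mrna_cols = [timepoint_map[c] for c in mirna_cols]
    a = mrna.values[mrna_cols]
    a.columns = mirna_cols
    b = mirna.values[mirna_cols]
    return ec.ExpressionSet(pd.concat([a, b]))


def _extend_with_rp(spaces, seqs, genome, annotation, rp_path) -> None:
    """Add distal intervals where the regulatory-potential track exceeds 0.1.

    The RP BED's score column (column 5) is thresholded at 0.1; qualifying
    intervals are clipped to the -100 kb .. gene-end range of each gene
    whose chromosome they share.
    """
    df = pd.read_csv(rp_path, sep="\t", header=None)
    rp = [iof.GenomicInterval(r[0], int(r[1]), int(r[2]))
          for r in df.itertuples(index=False)
          if len(r) < 5 or float(r[4]) > 0.1]
    by_target = {s.target: s for s in spaces}
    for g, rec in sorted(annotation.genes.items()):
        if g not in by_target:
            continue
        iv = rec.interval
        if iv.oriented_strand() == "+":
            lo, hi = max(0, rec.tss - 100_000), iv.end
        else:
            lo, hi = iv.start, rec.tss + 100_000 + 1
        extra = []
        for r in rp:
            if r.chrom == iv.chrom and r.start < hi and r.end > lo:
                extra.append(iof.GenomicInterval(
                    r.chrom, max(r.start, lo), min(r.end, hi), iv.strand))
        if extra:
            space = pt.SearchSpace(g, by_target[g].intervals + extra)
            idx = spaces.index(by_target[g])
            spaces[idx] = space
            by_target[g] = space
            seqs[g] = [genome[i.chrom][i.start:i.end]
                       for i in space.intervals]


def _write_master_tables(out: Path, tf_results, mirna_results) -> None:
    pd.DataFrame(
        [(r.regulator, r.cluster_id, round(r.statistic, 4), r.p,
          r.adjusted_p, r.significant) for r in tf_results],
        columns=["regulator", "cluster", "mean_R", "p", "adjusted_p",
                 "significant"]).to_csv(out / "master_tfs.tsv", sep="\t",
                                        index=False)
    pd.DataFrame(
        [(r.regulator, r.cluster_id, r.N, r.K, r.n, r.k, r.p, r.adjusted_p,
          r.significant) for r in mirna_results],
        columns=["regulator", "cluster", "N", "K", "n", "k", "p",
                 "adjusted_p", "significant"]).to_csv(
        out / "master_mirnas.tsv", sep="\t", index=False)
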