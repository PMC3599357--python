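"""Internally consistent toy datasets with planted ground truth.

The generator lays out a small genome (genes on fixed slots, miRNAs in
intergenic gaps or inside host genes), plants two reciprocal coexpression
clusters (a dip-and-recover "myelination" shape and a spike-and-decay
"proliferation" shape), TSS evidence features in exactly one window of
each miRNA's search range, PWM consensus sites with cross-species
alignment cover in the promoters of planted TF targets, ChIP peaks over
planted ChIP-TF targets, duplicate miRNA probesets with controls, and
three miRNA target lists in which planted pairs appear in at least two
lists and decoys in exactly one. Every emitted file parses through the
package's own readers, and a ground-truth record of planted cluster
memberships, TSSs, edges and master regulators is returned alongside.

All randomness flows from one seed; the same seed yields byte-identical
output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as iof
from .io_formats import GenomicInterval

GENE_SLOT = 30_000
GENE_LEN = 5_000
FIRST_SLOT = 15_000
PRE_LEN = 80
MIRNA_GAP_OFFSET = 8_000  # pre-miRNA distance from the flanking gene
SITE_OFFSETS_GENE = (-9_000, -7_000, -5_000, -3_000, -1_000)
SITE_OFFSETS_MIRNA = (-1_800, -1_300, -800, -300, 200)
TSS_WINDOW_INDEX = 30  # planted winning window, counted from the pre-miRNA
TSS_WINDOW_INDEX_INTRAGENIC = 10
CONSENSUS_PROB = 0.85
OFF_PROB = 0.05

MRNA_TIMEPOINTS = ["injury_d0", "injury_d4", "injury_d7", "injury_d10",
                   "dev_d2", "dev_d4", "dev_d10"]
INJURY_PRE = ["injury_d0"]
INJURY_POST = ["injury_d4", "injury_d7", "injury_d10"]
MIRNA_TIMEPOINTS = ["mirna_d0", "mirna_d4", "mirna_d14"]
TIMEPOINT_MAP = {"mirna_d0": "injury_d0", "mirna_d4": "injury_d4",
                 "mirna_d14": "injury_d10"}

# dip-and-recover (myelination) and spike-and-decay (proliferation) shapes
SHAPE_MGC = np.array([1.2, -1.5, -0.7, 0.9, -0.8, 0.2, 1.1])
SHAPE_PGC = np.array([-1.0, 1.4, 0.8, -0.6, 1.0, -0.1, -1.2])
EXPR_BASE = 8.0
EXPR_SCALE = 1.5
CONTROL_LEVEL = 6.0


@dataclass
class ScenarioConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 60
    n_tfs: int = 8
    n_chip_tfs: int = 2
    n_mirnas: int = 12
    intragenic_fraction: float = 1 / 3
    n_species: int = 5
    n_clusters: int = 2
    genes_per_cluster: int = 15
    noise_sigma: float = 0.1
    edge_density: float = 1.0
    peak_fp_rate: float = 0.05
    peak_fn_rate: float = 0.05
    tss_feature_completeness: float = 1.0

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.chrom_length, self.n_genes,
               self.n_tfs, self.n_mirnas, self.n_species) <= 0:
            raise ValueError("all counts must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        for r in (self.peak_fp_rate, self.peak_fn_rate,
                  self.tss_feature_completeness, self.intragenic_fraction):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        per_chrom = math.ceil(self.n_genes / self.n_chromosomes)
        if FIRST_SLOT + per_chrom * GENE_SLOT > self.chrom_length:
            raise ValueError("chromosomes too short for the requested genes")


@dataclass
class GroundTruth:
    cluster_members: dict[str, set[str]] = field(default_factory=dict)
    cluster_class: dict[str, str] = field(default_factory=dict)
    tss: dict[str, int] = field(default_factory=dict)
    tss_window: dict[str, tuple[int, int]] = field(default_factory=dict)
    edges: set[tuple[str, str, str, str]] = field(default_factory=set)
    # (regulator, target, sign, edge_type in {tf_gene, tf_mirna, mirna_gene})
    master_tfs: set[str] = field(default_factory=set)
    master_mirnas: set[str] = field(default_factory=set)
    regulator_profiles: dict[str, str] = field(default_factory=dict)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate_scenario(config: ScenarioConfig, out_dir: str | Path) -> GroundTruth:
    """Emit a complete scenario into *out_dir* and return the planted truth."""
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    for sub in ("tracks", "peaks", "truth"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    truth = GroundTruth()

    # ------------------------------------------------------------------
    # genome layout
    # ------------------------------------------------------------------
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome = {c: rng.integers(0, 4, size=config.chrom_length,
                              dtype=np.int8) for c in chroms}

    n_coding = config.n_genes - config.n_tfs
    tf_ids = [f"TF{i + 1}" for i in range(config.n_tfs)]
    gene_ids = tf_ids + [f"g{i + 1}" for i in range(n_coding)]
    per_chrom = math.ceil(config.n_genes / config.n_chromosomes)
    gene_pos: dict[str, GenomicInterval] = {}
    slots: list[tuple[str, int, str]] = []  # (chrom, slot index, gene id)
    for idx, gid in enumerate(gene_ids):
        chrom = chroms[idx // per_chrom]
        slot = idx % per_chrom
        start = FIRST_SLOT + slot * GENE_SLOT
        strand = "+" if slot % 2 == 0 else "-"
        gene_pos[gid] = GenomicInterval(chrom, start, start + GENE_LEN, strand)
        slots.append((chrom, slot, gid))

    def gene_tss(gid: str) -> int:
        iv = gene_pos[gid]
        return iv.start if iv.strand == "+" else iv.end - 1

    # cluster memberships (coding, non-TF genes)
    n_pc = min(config.genes_per_cluster,
               n_coding // (config.n_clusters + 1) if config.n_clusters else 0)
    coding = [g for g in gene_ids if not g.startswith("TF")]
    cluster_ids = [f"c{i + 1}" for i in range(config.n_clusters)]
    pos = 0
    for i, cid in enumerate(cluster_ids):
        members = set(coding[pos:pos + n_pc])
        pos += n_pc
        truth.cluster_members[cid] = members
        truth.cluster_class[cid] = "MGC" if i % 2 == 0 else "PGC"
    background_genes = coding[pos:]

    # miRNAs: intergenic ones in gaps after '+'-strand gene slots, intragenic
    # ones inside background host genes of matching strand
    n_intragenic = int(round(config.intragenic_fraction * config.n_mirnas))
    n_intergenic = config.n_mirnas - n_intragenic
    mirna_ids = [f"mirna{i + 1}" for i in range(config.n_mirnas)]
    plus_slots = [(c, s, g) for (c, s, g) in slots
                  if s % 2 == 0 and s + 1 < per_chrom and s >= 8]
    if len(plus_slots) < n_intergenic:
        raise ValueError("not enough intergenic gaps for the requested miRNAs")
    host_candidates = [g for g in background_genes
                       if g not in set().union(*truth.cluster_members.values())
                       ][:n_intragenic] if n_intragenic else []
    if len(host_candidates) < n_intragenic:
        raise ValueError("not enough background genes to host intragenic miRNAs")

    mirna_pos: dict[str, GenomicInterval] = {}
    mirna_host: dict[str, str | None] = {}
    for i in range(n_intergenic):
        mid = mirna_ids[i]
        chrom, slot, gid = plus_slots[i]
        gene_end = gene_pos[gid].end
        next_start = gene_pos[gid].start + GENE_SLOT
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            start = gene_end + MIRNA_GAP_OFFSET
            iv = GenomicInterval(chrom, start, start + PRE_LEN, "+")
        else:
            end = next_start - MIRNA_GAP_OFFSET
            iv = GenomicInterval(chrom, end - PRE_LEN, end, "-")
        mirna_pos[mid] = iv
        mirna_host[mid] = None
    for j in range(n_intragenic):
        mid = mirna_ids[n_intergenic + j]
        host = host_candidates[j]
        hiv = gene_pos[host]
        if hiv.strand == "+":
            start = hiv.start + 3_000
            iv = GenomicInterval(hiv.chrom, start, start + PRE_LEN, "+")
        else:
            end = hiv.end - 3_000
            iv = GenomicInterval(hiv.chrom, end - PRE_LEN, end, "-")
        mirna_pos[mid] = iv
        mirna_host[mid] = host

    rows = []
    for gid in gene_ids:
        iv = gene_pos[gid]
        kind = "tf" if gid.startswith("TF") else "gene"
        rows.append((gid, kind, iv.chrom, iv.start + 1, iv.end, iv.strand, ""))
    for mid in mirna_ids:
        iv = mirna_pos[mid]
        rows.append((mid, "mirna", iv.chrom, iv.start + 1, iv.end, iv.strand,
                     mirna_host[mid] or ""))
    pd.DataFrame(rows, columns=iof.ANNOTATION_COLUMNS).to_csv(
        out / "annotation.tsv", sep="\t", index=False)

    # ------------------------------------------------------------------
    # planted TSSs and feature tracks
    # ------------------------------------------------------------------
    species = [f"S{i + 1}" for i in range(config.n_species)]
    reference = species[0]
    feature_tracks: dict[str, list[GenomicInterval]] = {
        f: [] for f in iof.TSS_FEATURES}
    align_tracks: dict[str, list[GenomicInterval]] = {sp: [] for sp in species}
    # the reference species aligns everywhere (self-alignment)
    for c in chroms:
        align_tracks[reference].append(
            GenomicInterval(c, 0, config.chrom_length))

    for mid in mirna_ids:
        iv = mirna_pos[mid]
        host = mirna_host[mid]
        widx = TSS_WINDOW_INDEX_INTRAGENIC if host else TSS_WINDOW_INDEX
        if iv.strand == "+":
            hi = iv.start - widx * 100
            window = (hi - 100, hi)
            tss = window[0]
        else:
            lo = iv.end + widx * 100
            window = (lo, lo + 100)
            tss = window[1] - 1
        truth.tss[mid] = tss
        truth.tss_window[mid] = window
        for feat in iof.TSS_FEATURES:
            if rng.random() < config.tss_feature_completeness:
                feature_tracks[feat].append(
                    GenomicInterval(iv.chrom, window[0] + 30, window[0] + 70))
        for sp in species[1:]:
            align_tracks[sp].append(
                GenomicInterval(iv.chrom, window[0], window[1]))

    # ------------------------------------------------------------------
    # PWMs and planted binding sites
    # ------------------------------------------------------------------
    pwm_len = 10
    consensus = {tf: "".join("ACGT"[b] for b in
                             rng.integers(0, 4, size=pwm_len))
                 for tf in tf_ids}
    pwms = []
    for tf in tf_ids:
        mat = np.full((4, pwm_len), math.log(OFF_PROB / 0.25))
        for j, base in enumerate(consensus[tf]):
            mat["ACGT".index(base), j] = math.log(CONSENSUS_PROB / 0.25)
        pwms.append(iof.Pwm(f"PWM_{tf}", tf, mat))
    iof.write_pwms(pwms, out / "pwms.txt")

    # species tree: two cherries plus an outgroup
    newick = _make_tree(species)
    (out / "tree.nwk").write_text(newick + "\n")
    conserved_species_in_sites = species[:4]  # reference + three others

    def scaled(n: int) -> int:
        return int(round(config.edge_density * n))

    def pick(seq: list[str], n: int) -> list[str]:
        return list(seq)[:n]

    c_members = [sorted(truth.cluster_members[c]) for c in cluster_ids]
    m1 = c_members[0] if c_members else []
    m2 = c_members[1] if len(c_members) > 1 else m1

    chip_tfs = tf_ids[:config.n_chip_tfs]
    # regulator roles: TF1, TF2 track cluster 1 / 2 (ChIP-backed); TF3 tracks
    # cluster 2 and TF4 mirrors cluster 1 (prediction-backed); TF5 is the
    # planted master of cluster 1.
    tf_profile = {tf_ids[0]: "c1", tf_ids[1]: "c2"}
    predicted_assign = {}
    if config.n_tfs >= 3:
        tf_profile[tf_ids[2]] = "c2"
    if config.n_tfs >= 4:
        tf_profile[tf_ids[3]] = "anti-c1"
    master_tf = tf_ids[4] if config.n_tfs >= 5 else None

    intergenic_mirnas = mirna_ids[:n_intergenic]
    mirna_profile = {}
    for i, mid in enumerate(intergenic_mirnas[:6]):
        mirna_profile[mid] = ["c1", "c1", "anti-c1", "c2", "c2", "c2"][i]
    master_mirna = mirna_ids[-1] if config.n_mirnas >= 2 else None
    low_mirna = intergenic_mirnas[7] if n_intergenic >= 8 else None
    if low_mirna in mirna_profile:
        low_mirna = None

    # planted target assignments
    chip_targets: dict[str, list[str]] = {}
    if config.n_chip_tfs >= 1:
        chip_targets[tf_ids[0]] = pick(m1, scaled(6)) + \
            pick(intergenic_mirnas[:3], scaled(3))
    if config.n_chip_tfs >= 2:
        chip_targets[tf_ids[1]] = pick(m2, scaled(6))
    if config.n_tfs >= 3:
        predicted_assign[tf_ids[2]] = pick(m2[5:], scaled(5)) + \
            pick(intergenic_mirnas[4:6], scaled(2))
    if config.n_tfs >= 4:
        predicted_assign[tf_ids[3]] = pick(m1[5:], scaled(4))
    if master_tf:
        predicted_assign[master_tf] = pick(m1, scaled(10))
        if scaled(10) > 0:
            truth.master_tfs.add(master_tf)

    def plant_site(tf: str, target: str) -> None:
        """Write PWM consensus copies into a target's promoter region.

        Offsets are shifted per TF so sites of different TFs planted in the
        same promoter never overwrite each other.
        """
        shift = 30 * tf_ids.index(tf)
        if target in gene_pos:
            iv = gene_pos[target]
            tss, strand = gene_tss(target), iv.strand
            offsets = [o + shift for o in SITE_OFFSETS_GENE]
        else:
            tss = truth.tss[target]
            strand = mirna_pos[target].strand
            offsets = [o + shift for o in SITE_OFFSETS_MIRNA]
        chrom = (gene_pos[target] if target in gene_pos
                 else mirna_pos[target]).chrom
        word = consensus[tf]
        codes = np.array(["ACGT".index(b) for b in word], dtype=np.int8)
        for off in offsets:
            p = tss + off if strand == "+" else tss - off
            genome[chrom][p:p + pwm_len] = codes
            for sp in conserved_species_in_sites[1:]:
                align_tracks[sp].append(
                    GenomicInterval(chrom, p - 15, p + pwm_len + 15))

    for tf, targets in {**chip_targets, **predicted_assign}.items():
        planted_for_prediction = tf in predicted_assign
        for t in targets:
            sign = _edge_sign_truth(tf_profile.get(tf), t, truth,
                                    mirna_profile, master=tf == master_tf)
            etype = "tf_mirna" if t.startswith("mirna") else "tf_gene"
            truth.edges.add((tf, t, sign, etype))
            if planted_for_prediction:
                plant_site(tf, t)

    for feat, ivs in feature_tracks.items():
        iof.write_bed(ivs, out / "tracks" / f"{feat}.bed")
    for sp, ivs in align_tracks.items():
        iof.write_bed(sorted(ivs), out / "tracks" / f"align_{sp}.bed")
    with open(out / "tracks" / "conserved_species.tsv", "w") as fh:
        fh.write("mirna\tspecies\n")
        for mid in mirna_ids:
            fh.write(f"{mid}\t{','.join(species)}\n")
    with open(out / "tracks" / "tracks.yaml", "w") as fh:
        fh.write("features:\n")
        for feat in iof.TSS_FEATURES:
            fh.write(f"  {feat}: tracks/{feat}.bed\n")
        fh.write("alignment:\n")
        for sp in species:
            fh.write(f"  {sp}: tracks/align_{sp}.bed\n")
        fh.write("conserved_species: tracks/conserved_species.tsv\n")
        fh.write(f"reference: {reference}\n")

    # ------------------------------------------------------------------
    # ChIP peaks
    # ------------------------------------------------------------------
    n_planted_peaks = 0
    for tf in chip_tfs:
        peaks = []
        for t in chip_targets.get(tf, []):
            if t in gene_pos:
                iv, tss = gene_pos[t], gene_tss(t)
            else:
                iv, tss = mirna_pos[t], truth.tss[t]
            strand = iv.strand
            lo = tss - 600 if strand == "+" else tss + 400
            peak = GenomicInterval(iv.chrom, lo, lo + 200)
            n_planted_peaks += 1
            if rng.random() < config.peak_fn_rate:
                continue  # dropped peak (false negative)
            peaks.append(peak)
        n_bg = int(round(config.peak_fp_rate * max(1, len(peaks))))
        for _ in range(n_bg):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            p = int(rng.integers(0, config.chrom_length - 200))
            peaks.append(GenomicInterval(chrom, p, p + 200))
        iof.write_bed(peaks, out / "peaks" / f"{tf}.bed")

    # ------------------------------------------------------------------
    # genome FASTA (after site planting)
    # ------------------------------------------------------------------
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    with open(out / "genome.fasta", "w") as fh:
        for c in chroms:
            fh.write(f">{c}\n")
            seq = bases[genome[c]].tobytes().decode()
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")

    # ------------------------------------------------------------------
    # expression matrices
    # ------------------------------------------------------------------
    shapes = {"c1": SHAPE_MGC, "c2": SHAPE_PGC,
              "anti-c1": -SHAPE_MGC, "anti-c2": -SHAPE_PGC}

    def profile(shape_key: str | None) -> np.ndarray:
        if shape_key is None:
            base = rng.normal(0, 1, size=len(MRNA_TIMEPOINTS))
        else:
            base = shapes[shape_key]
        return (EXPR_BASE + EXPR_SCALE * base
                + rng.normal(0, config.noise_sigma, size=len(base)))

    mrna_rows, presence_rows = {}, {}
    for i, cid in enumerate(cluster_ids):
        key = "c1" if truth.cluster_class[cid] == "MGC" else "c2"
        for g in sorted(truth.cluster_members[cid]):
            mrna_rows[g] = profile(key)
            presence_rows[g] = np.ones(len(MRNA_TIMEPOINTS), dtype=int)
    absent = set(background_genes[-2:])
    for g in background_genes:
        mrna_rows[g] = profile(None)
        presence_rows[g] = np.zeros(len(MRNA_TIMEPOINTS), dtype=int) \
            if g in absent else np.ones(len(MRNA_TIMEPOINTS), dtype=int)
    for tf in tf_ids:
        mrna_rows[tf] = profile(tf_profile.get(tf))
        presence_rows[tf] = np.ones(len(MRNA_TIMEPOINTS), dtype=int)
    mrna = pd.DataFrame.from_dict(mrna_rows, orient="index",
                                  columns=MRNA_TIMEPOINTS)
    mrna.index.name = "feature"
    mrna = mrna.loc[sorted(mrna.index)]
    mrna.round(4).to_csv(out / "mrna_expression.tsv", sep="\t")
    presence = pd.DataFrame.from_dict(presence_rows, orient="index",
                                      columns=MRNA_TIMEPOINTS)
    presence.index.name = "feature"
    presence.loc[sorted(presence.index)].to_csv(
        out / "mrna_presence.tsv", sep="\t")

    injury_idx = [MRNA_TIMEPOINTS.index(TIMEPOINT_MAP[c])
                  for c in MIRNA_TIMEPOINTS]
    mirna_rows = {}
    probe_map = {}
    for mid in mirna_ids:
        key = mirna_profile.get(mid)
        if mid == master_mirna:
            base = np.zeros(len(MIRNA_TIMEPOINTS))  # flat: not correlated
        elif key is not None:
            base = shapes[key][injury_idx]
        else:
            base = rng.normal(0, 1, size=len(MIRNA_TIMEPOINTS))
        level = 2.0 if mid == low_mirna else EXPR_BASE
        for suffix in ("p1", "p2"):
            mirna_rows[f"{mid}_{suffix}"] = (
                level + EXPR_SCALE * base
                + rng.normal(0, config.noise_sigma, size=len(base)))
        probe_map[mid] = (f"{mid}_p1", f"{mid}_p2")
    controls = [f"ctrl{i + 1}" for i in range(4)]
    for ctl in controls:
        mirna_rows[ctl] = np.full(len(MIRNA_TIMEPOINTS), CONTROL_LEVEL) \
            + rng.normal(0, config.noise_sigma, size=len(MIRNA_TIMEPOINTS))
    mirna_df = pd.DataFrame.from_dict(mirna_rows, orient="index",
                                      columns=MIRNA_TIMEPOINTS)
    mirna_df.index.name = "probeset"
    mirna_df.loc[sorted(mirna_df.index)].round(4).to_csv(
        out / "mirna_expression.tsv", sep="\t")
    pd.DataFrame([(m, a, b) for m, (a, b) in sorted(probe_map.items())],
                 columns=["mirna", "probe1", "probe2"]).to_csv(
        out / "mirna_probesets.tsv", sep="\t", index=False)
    (out / "mirna_controls.txt").write_text("\n".join(controls) + "\n")

    myelin = [m[0] for m in c_members if m]
    (out / "myelin_genes.txt").write_text("\n".join(myelin) + "\n")

    # ------------------------------------------------------------------
    # miRNA target lists (planted pairs in >=2 lists, decoys in exactly 1)
    # ------------------------------------------------------------------
    mirna_targets: dict[str, list[str]] = {}
    for mid in mirna_ids:
        key = mirna_profile.get(mid)
        if mid == master_mirna:
            mirna_targets[mid] = pick(m1, scaled(10))
            if scaled(10) > 0:
                truth.master_mirnas.add(mid)
        elif key in ("c1", "anti-c1"):
            # overlap with the ChIP TF's gene targets plants feedforward
            # loops (TF -> miRNA -> gene closed by TF -> gene)
            mirna_targets[mid] = pick(m1, scaled(4))
        elif key == "c2":
            mirna_targets[mid] = pick(m2[5:], scaled(4))
        else:
            mirna_targets[mid] = []
        for t in mirna_targets[mid]:
            truth.edges.add((mid, t, "-", "mirna_gene"))
    # one planted negative feedback loop: TF1 -> mirna1 -> TF1
    fb_mirna = intergenic_mirnas[0] if intergenic_mirnas else None
    if (fb_mirna and config.n_chip_tfs >= 1 and scaled(1) > 0
            and fb_mirna in chip_targets.get(tf_ids[0], [])):
        mirna_targets[fb_mirna] = mirna_targets[fb_mirna] + [tf_ids[0]]
        truth.edges.add((fb_mirna, tf_ids[0], "-", "mirna_gene"))

    lists: dict[str, set[tuple[str, str]]] = {"methodA": set(), "methodB": set(),
                                              "methodC": set()}
    method_names = sorted(lists)
    for i, (mid, targets) in enumerate(sorted(mirna_targets.items())):
        for j, t in enumerate(targets):
            chosen = [method_names[(i + j) % 3], method_names[(i + j + 1) % 3]]
            if (i + j) % 4 == 0:
                chosen = method_names  # some pairs in all three
            for m in chosen:
                lists[m].add((mid, t))
        # decoys: background-gene pairs in exactly one list
        for j in range(2):
            if not background_genes:
                break
            decoy = background_genes[(i * 2 + j) % len(background_genes)]
            lists[method_names[(i + j) % 3]].add((mid, decoy))
    for m, pairs in lists.items():
        pd.DataFrame(sorted(pairs), columns=["mirna", "gene"]).to_csv(
            out / f"targets_{m}.tsv", sep="\t", index=False)

    # ------------------------------------------------------------------
    # 3'UTRs and mature miRNA sequences with planted seed matches
    # ------------------------------------------------------------------
    mature = {mid: "".join("ACGT"[b] for b in rng.integers(0, 4, size=22))
              for mid in mirna_ids}
    utrs = {g: "".join("ACGT"[b] for b in rng.integers(0, 4, size=500))
            for g in gene_ids}
    for mid, targets in mirna_targets.items():
        seed_rc = _revcomp(mature[mid][1:8])
        for t in targets:
            u = utrs[t]
            utrs[t] = u[:100] + seed_rc + u[107:]
    iof.write_fasta({m: mature[m] for m in sorted(mature)},
                    out / "mirna_mature.fasta")
    iof.write_fasta({g: utrs[g] for g in sorted(utrs)}, out / "utrs.fasta")

    # ------------------------------------------------------------------
    # truth tables, pipeline config and manifest
    # ------------------------------------------------------------------
    pd.DataFrame(sorted(truth.edges),
                 columns=["regulator", "target", "sign", "edge_type"]).to_csv(
        out / "truth" / "edges.tsv", sep="\t", index=False)
    rows = [(g, cid, truth.cluster_class[cid])
            for cid in cluster_ids for g in sorted(truth.cluster_members[cid])]
    pd.DataFrame(rows, columns=["gene", "cluster", "class"]).to_csv(
        out / "truth" / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(truth.tss.items()), columns=["mirna", "tss"]).to_csv(
        out / "truth" / "tss.tsv", sep="\t", index=False)
    pd.DataFrame(sorted([("TF", t) for t in truth.master_tfs]
                        + [("miRNA", m) for m in truth.master_mirnas]),
                 columns=["type", "regulator"]).to_csv(
        out / "truth" / "masters.tsv", sep="\t", index=False)

    _write_pipeline_config(out, config, chip_tfs)

    files = sorted(str(p.relative_to(out)) for p in out.rglob("*")
                   if p.is_file() and p.name != "manifest.tsv")
    pd.DataFrame({"file": files}).to_csv(out / "manifest.tsv", sep="\t",
                                         index=False)
    return truth


def _edge_sign_truth(tf_key: str | None, target: str, truth: GroundTruth,
                     mirna_profile: dict, master: bool = False) -> str:
    """Planted sign: same-shape regulator/target pairs activate."""
    if master or tf_key is None:
        return "+"
    if target.startswith("mirna"):
        target_key = mirna_profile.get(target)
    else:
        target_key = None
        for cid, members in truth.cluster_members.items():
            if target in members:
                target_key = "c1" if truth.cluster_class[cid] == "MGC" else "c2"
    if target_key is None:
        return "+"
    flip = (tf_key.startswith("anti-") != str(target_key).startswith("anti-"))
    same_base = tf_key.removeprefix("anti-") == str(target_key).removeprefix("anti-")
    if not same_base:
        return "-"  # reciprocal shapes
    return "-" if flip else "+"


def _make_tree(species: list[str]) -> str:
    if len(species) >= 5:
        a, b, c, d, *rest = species
        inner = f"(({a}:1.0,{b}:1.0):1.0,({c}:1.0,{d}:1.0):1.0"
        for i, sp in enumerate(rest):
            inner += f",{sp}:{3.0 + i:.1f}"
        return inner + ");"
    tips = ",".join(f"{sp}:1.0" for sp in species)
    return f"({tips});"


def _write_pipeline_config(out: Path, config: ScenarioConfig,
                           chip_tfs: list[str]) -> None:
    lines = [
        f"seed = {config.seed}",
        "",
        "[paths]",
        'annotation = "annotation.tsv"',
        'genome = "genome.fasta"',
        'tracks = "tracks/tracks.yaml"',
        'pwms = "pwms.txt"',
        'tree = "tree.nwk"',
        'mrna_expression = "mrna_expression.tsv"',
        'mrna_presence = "mrna_presence.tsv"',
        'mirna_expression = "mirna_expression.tsv"',
        'mirna_probesets = "mirna_probesets.tsv"',
        'mirna_controls = "mirna_controls.txt"',
        'myelin_genes = "myelin_genes.txt"',
        'target_lists = ["targets_methodA.tsv", "targets_methodB.tsv", '
        '"targets_methodC.tsv"]',
        "",
        "[paths.peaks]",
    ]
    for tf in chip_tfs:
        lines.append(f'{tf} = "peaks/{tf}.bed"')
    lines += [
        "",
        "[cluster]",
        "k = 12",
        "alpha = 0.05",
        "merge_r = 0.85",
        "assign_r = 0.8",
        "r_cut = 0.8",
        f'injury_pre = {INJURY_PRE!r}'.replace("'", '"'),
        f'injury_post = {INJURY_POST!r}'.replace("'", '"'),
        "",
        "[cluster.timepoint_map]",
    ]
    for k, v in TIMEPOINT_MAP.items():
        lines.append(f'{k} = "{v}"')
    lines += [
        "",
        "[tfbs]",
        "n_perm = 999",
        "alpha = 0.005",
        "w_floor = 0.0",
        "",
        "[targets]",
        "min_methods = 2",
        "min_overlap_bp = 1",
        "",
        "[master]",
        "n_random = 9999",
        "alpha = 0.05",
        "",
        "[network]",
        "keep_isolated = false",
    ]
    (out / "scenario_config.toml").write_text("\n".join(lines) + "\n")


def score_recovery(inferred, truth: GroundTruth) -> dict:
    """Precision/recall of inferred edges against the planted edge set.

    Edges are matched on (regulator, target), ignoring sign; sign accuracy
    is reported over the matched edges. Per-edge-type and overall
    (micro-averaged) figures are returned; precision is NA when nothing
    was inferred.
    """
    truth_by_pair = {(r, t): s for r, t, s, _ in truth.edges}
    truth_type = {(r, t): et for r, t, _, et in truth.edges}
    inferred_pairs = {}
    for u, v, d in inferred.edges(data=True):
        ut = inferred.nodes[u].get("node_type", "mRNA")
        et = ("mirna_gene" if ut == "miRNA"
              else "tf_mirna" if inferred.nodes[v].get("node_type") == "miRNA"
              else "tf_gene")
        inferred_pairs[(u, v)] = (d.get("sign", "+"), et)

    types = sorted({et for _, _, _, et in truth.edges}
                   | {et for _, et in inferred_pairs.values()})
    out = {}
    for scope in types + ["overall"]:
        tp = [p for p in inferred_pairs if p in truth_by_pair
              and (scope == "overall" or truth_type[p] == scope)]
        n_inf = sum(1 for p, (_, et) in inferred_pairs.items()
                    if scope == "overall" or et == scope
                    or (p in truth_type and truth_type[p] == scope))
        n_truth = sum(1 for p, et in truth_type.items()
                      if scope == "overall" or et == scope)
        precision = len(tp) / n_inf if n_inf else float("nan")
        recall = len(tp) / n_truth if n_truth else float("nan")
        sign_ok = sum(1 for p in tp
                      if inferred_pairs[p][0] == truth_by_pair[p])
        out[scope] = {
            "precision": precision,
            "recall": recall,
            "n_inferred": n_inf,
            "n_truth": n_truth,
            "n_matched": len(tp),
            "sign_accuracy": sign_ok / len(tp) if tp else float("nan"),
        }
    return out
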