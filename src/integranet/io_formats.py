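"""Readers and writers for every external format the pipeline touches.

One internal coordinate convention is used throughout: 0-based, half-open
(BED-native), with strand one of ``+``, ``-`` or ``.`` (unstranded). Every
reader normalizes to this convention and every writer converts back to its
format's native one. Annotation TSVs are 1-based inclusive on disk, BED is
0-based half-open on disk.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A file did not conform to its declared format."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def oriented_strand(self) -> str:
        """Strand used for promoter arithmetic; '.' is treated as '+'."""
        if self.strand == ".":
            log.warning("unstranded interval treated as '+' for orientation")
            return "+"
        return self.strand


@dataclass(frozen=True)
class GeneRecord:
    interval: GenomicInterval
    tss: int
    gene_type: str  # {"coding", "TF", "other"}


@dataclass(frozen=True)
class MirnaRecord:
    interval: GenomicInterval  # the pre-miRNA hairpin
    host_gene: str | None = None


@dataclass
class GenomeAnnotation:
    """Genes, pre-miRNAs, their strands, TSSs and host-gene relations."""

    genes: dict[str, GeneRecord] = field(default_factory=dict)
    mirnas: dict[str, MirnaRecord] = field(default_factory=dict)
    tf_to_pwm_ids: dict[str, set[str]] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def tf_ids(self) -> set[str]:
        return {g for g, rec in self.genes.items() if rec.gene_type == "TF"}


@dataclass
class FeatureTrackSet:
    """Interval tracks backing TSS voting and conservation scoring."""

    tracks: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    alignment: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    premirna_conserved_species: dict[str, set[str]] = field(default_factory=dict)


TSS_FEATURES = ("transcript_EST", "CpG", "CAGE", "H3K4me3")


def tss_of(interval: GenomicInterval) -> int:
    """Transcription start of an interval: start on '+', end-1 on '-'."""
    return interval.start if interval.oriented_strand() == "+" else interval.end - 1


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file into intervals, preserving 0-based half-open coords.

    Column 6 supplies the strand when present; otherwise intervals are
    unstranded. Track/browser/comment lines are skipped.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: BED line has {len(fields)} columns, need >= 3"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Iterable[str] | None = None) -> None:
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t"
                     f"{iv.strand if iv.strand != '.' else '.'}\n")


# ---------------------------------------------------------------------------
# Annotation TSV (canonical) and GFF3 import (convenience)
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["id", "kind", "chrom", "start", "end", "strand", "host_gene"]
_KINDS = {"gene", "tf", "mirna"}


def read_annotation(path: str | Path) -> GenomeAnnotation:
    """Read the canonical annotation TSV (1-based inclusive coordinates).

    Columns: id, kind in {gene, tf, mirna}, chrom, start, end, strand and an
    optional host_gene column for intragenic miRNAs. Coordinates are converted
    to the internal 0-based half-open convention; host-gene ids must resolve.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(ANNOTATION_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing annotation columns {sorted(missing)}")
    ann = GenomeAnnotation()
    pending_hosts: list[tuple[str, str]] = []
    for row in df.itertuples(index=False):
        kind = row.kind
        if kind not in _KINDS:
            raise FormatError(f"{path}: unknown kind {kind!r} for {row.id}")
        start = int(row.start) - 1  # 1-based inclusive -> 0-based half-open
        end = int(row.end)
        iv = GenomicInterval(row.chrom, start, end, row.strand)
        if kind == "mirna":
            host = getattr(row, "host_gene", None)
            host = None if (host is None or (isinstance(host, float) and
                            math.isnan(host)) or host in ("", ".")) else host
            if host is not None:
                pending_hosts.append((row.id, host))
            ann.mirnas[row.id] = MirnaRecord(iv, host)
        else:
            gene_type = "TF" if kind == "tf" else "coding"
            ann.genes[row.id] = GeneRecord(iv, tss_of(iv), gene_type)
    for mid, host in pending_hosts:
        if host not in ann.genes:
            raise FormatError(f"{path}: miRNA {mid} names unknown host gene {host!r}")
        h, m = ann.genes[host].interval, ann.mirnas[mid].interval
        if not (h.overlaps(m) and h.strand == m.strand):
            raise FormatError(
                f"{path}: host {host} does not overlap {mid} on the same strand"
            )
    return ann


def write_annotation(ann: GenomeAnnotation, path: str | Path) -> None:
    rows = []
    for gid, rec in ann.genes.items():
        kind = "tf" if rec.gene_type == "TF" else "gene"
        iv = rec.interval
        rows.append((gid, kind, iv.chrom, iv.start + 1, iv.end, iv.strand, ""))
    for mid, rec in ann.mirnas.items():
        iv = rec.interval
        rows.append((mid, "mirna", iv.chrom, iv.start + 1, iv.end, iv.strand,
                     rec.host_gene or ""))
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def gff3_to_annotation_tsv(gff_path: str | Path, tsv_path: str | Path,
                           tf_ids: set[str] | None = None) -> None:
    """Convert a GFF3 file to the canonical annotation TSV.

    `gene` features become gene/tf rows (tf when the ID is in *tf_ids*),
    `miRNA_primary_transcript`/`pre_miRNA` features become mirna rows. Only
    the TSV is canonical; this is a convenience importer.
    """
    tf_ids = tf_ids or set()
    rows = []
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise FormatError(f"{gff_path}: GFF3 line with {len(f)} columns")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            fid = attrs.get("ID") or attrs.get("Name")
            if fid is None:
                continue
            if f[2] == "gene":
                kind = "tf" if fid in tf_ids else "gene"
                rows.append((fid, kind, f[0], f[3], f[4], f[6], ""))
            elif f[2] in ("miRNA_primary_transcript", "pre_miRNA", "miRNA"):
                rows.append((fid, "mirna", f[0], f[3], f[4], f[6],
                             attrs.get("host_gene", "")))
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PWMs (JASPAR matrix layout + log-base header)
# ---------------------------------------------------------------------------

@dataclass
class Pwm:
    """A position weight matrix of per-position log-odds scores.

    The matrix is stored in natural-log units regardless of the base declared
    in the source file; ``background`` is the base composition the log-odds
    are taken against.
    """

    id: str
    tf_id: str
    matrix: np.ndarray  # 4 x L, rows A,C,G,T, natural-log odds
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-6):
            raise ValueError("background frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


def read_pwms(path: str | Path) -> list[Pwm]:
    """Read PWMs from a JASPAR-style matrix file.

    Layout per motif::

        # log_base: e            (file-level header; 'e', '2' or '10')
        >PWM_ID TF_ID
        A [ 1.2  -0.5 ... ]
        C [ ... ]
        G [ ... ]
        T [ ... ]

    Scores are converted to natural-log units on read.
    """
    log_base = math.e
    pwms: list[Pwm] = []
    cur_id = cur_tf = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal rows, cur_id, cur_tf
        if cur_id is None:
            return
        if set(rows) != {"A", "C", "G", "T"}:
            raise FormatError(f"PWM {cur_id}: need exactly rows A, C, G, T")
        mat = np.array([rows[b] for b in "ACGT"], dtype=float)
        scale = math.log(log_base)  # to natural log
        pwms.append(Pwm(cur_id, cur_tf or cur_id, mat * scale))
        rows = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "log_base" in line:
                    token = line.split(":", 1)[1].strip()
                    log_base = math.e if token == "e" else float(token)
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                cur_id = parts[0]
                cur_tf = parts[1] if len(parts) > 1 else parts[0]
                continue
            base = line[0].upper()
            if base not in "ACGT":
                raise FormatError(f"{path}:{lineno}: unexpected PWM row {line!r}")
            body = line[1:].replace("[", " ").replace("]", " ")
            rows[base] = [float(x) for x in body.split()]
    flush()
    return pwms


def write_pwms(pwms: Iterable[Pwm], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# log_base: e\n")
        for p in pwms:
            fh.write(f">{p.id} {p.tf_id}\n")
            for base, row in zip("ACGT", p.matrix):
                vals = " ".join(f"{v:.6f}" for v in row)
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Newick, FASTA, expression TSV
# ---------------------------------------------------------------------------

def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Expression matrix: rows = features, columns = named timepoints."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise FormatError(f"{path}: expression values must be finite")
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def load_tracks(yaml_path: str | Path) -> tuple[FeatureTrackSet, str]:
    """Load a FeatureTrackSet from a YAML manifest.

    The manifest maps feature names and species ids to BED paths (relative
    to the manifest), points at a conserved-species TSV (mirna, comma-
    separated species) and names the reference species. Returns the track
    set and the reference species id.
    """
    import yaml

    yaml_path = Path(yaml_path)
    with open(yaml_path) as fh:
        spec = yaml.safe_load(fh)
    base = yaml_path.parent.parent if yaml_path.parent.name == "tracks" \
        else yaml_path.parent
    tracks = FeatureTrackSet()
    for feat, rel in (spec.get("features") or {}).items():
        if feat not in TSS_FEATURES:
            raise FormatError(f"{yaml_path}: unknown feature track {feat!r}")
        tracks.tracks[feat] = read_bed(base / rel)
    for sp, rel in (spec.get("alignment") or {}).items():
        tracks.alignment[sp] = read_bed(base / rel)
    cons = spec.get("conserved_species")
    if cons:
        df = pd.read_csv(base / cons, sep="\t", dtype=str)
        for row in df.itertuples(index=False):
            tracks.premirna_conserved_species[row.mirna] = set(
                row.species.split(","))
    return tracks, spec.get("reference", "")


# ---------------------------------------------------------------------------
# Network writers/readers
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ["regulator", "regulator_type", "target", "target_type",
                "sign", "evidence", "step"]
NODE_ATTRS = ("node_type", "role", "cluster_class")


def write_network(network: "nx.DiGraph", path: str | Path,
                  format: str = "edge_tsv") -> None:
    """Write a regulatory network as edge_tsv, graphml or sif.

    edge_tsv and graphml are lossless and round-trip through
    :func:`read_network`; SIF keeps only regulator, relation and target.
    """
    if format == "edge_tsv":
        rows = []
        for u, v, d in sorted(network.edges(data=True)):
            rows.append((u, network.nodes[u].get("node_type", ""),
                         v, network.nodes[v].get("node_type", ""),
                         d.get("sign", "+"), d.get("evidence", "predicted"),
                         d.get("step", "")))
        pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        g = nx.DiGraph()
        for n, d in network.nodes(data=True):
            g.add_node(n, **{k: str(d.get(k, "")) for k in NODE_ATTRS})
        for u, v, d in network.edges(data=True):
            g.add_edge(u, v, sign=d.get("sign", "+"),
                       evidence=d.get("evidence", "predicted"),
                       step=str(d.get("step", "")))
        nx.write_graphml(g, str(path))
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v, d in sorted(network.edges(data=True)):
                rel = "activates" if d.get("sign", "+") == "+" else "represses"
                fh.write(f"{u}\t{rel}\t{v}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "edge_tsv") -> "nx.DiGraph":
    g = nx.DiGraph()
    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        for row in df.itertuples(index=False):
            g.add_node(row.regulator, node_type=row.regulator_type)
            g.add_node(row.target, node_type=row.target_type)
            step = int(row.step) if str(row.step) not in ("", "nan") else None
            g.add_edge(row.regulator, row.target, sign=row.sign,
                       evidence=row.evidence, step=step)
    elif format == "graphml":
        raw = nx.read_graphml(str(path))
        for n, d in raw.nodes(data=True):
            g.add_node(n, **{k: d.get(k, "") for k in NODE_ATTRS})
        for u, v, d in raw.edges(data=True):
            step = int(d["step"]) if d.get("step") not in (None, "") else None
            g.add_edge(u, v, sign=d.get("sign", "+"),
                       evidence=d.get("evidence", "predicted"), step=step)
    else:
        raise ValueError(f"unknown network format {format!r}")
    return g
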