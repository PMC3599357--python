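"""TF target derivation from ChIP-Seq peaks and miRNA target consensus.

ChIP-Seq peaks falling inside the transcription-oriented promoter window of
a target (-10 kb..+5 kb of an annotated mRNA TSS, -5 kb..+1 kb of a
predicted miRNA TSS) yield experimentally supported TF->target edges.
miRNA->mRNA edges come from the consensus of independent target-prediction
lists (a pair must be predicted by at least 2 of 3 methods). A minimal
seed-match scanner (exact 3'UTR match to the reverse complement of miRNA
positions 2-8) backs fraction-of-targets summaries, and a Mann-Whitney test
checks that ChIP-supported targets score higher under the binding model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from .io_formats import GenomicInterval

log = logging.getLogger(__name__)

MRNA_WINDOW = (10_000, 5_000)   # upstream, downstream of annotated TSS
MIRNA_WINDOW = (5_000, 1_000)   # upstream, downstream of predicted TSS

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


@dataclass
class PeakSet:
    tf: str
    peaks: list[GenomicInterval]
    source: str = ""


@dataclass(frozen=True)
class TargetPairSet:
    method: str
    pairs: frozenset  # of (mirna, gene)


@dataclass(frozen=True)
class Edge:
    regulator: str
    target: str
    evidence: str  # {"chipseq", "predicted"}
    support: int = 1  # peak count or number of supporting methods


def promoter_window(tss: int, strand: str, upstream: int,
                    downstream: int) -> tuple[int, int]:
    """Transcription-oriented [tss-upstream, tss+downstream) as coordinates."""
    if strand == "+":
        return tss - upstream, tss + downstream
    return tss - downstream + 1, tss + upstream + 1


def peaks_to_targets(
    peaks: PeakSet,
    tss_table: dict[str, tuple[str, int, str]],
    upstream: int,
    downstream: int,
    min_overlap_bp: int = 1,
) -> list[Edge]:
    """TF->target edges from peaks overlapping promoter windows.

    *tss_table* maps target id to (chrom, tss, strand). A target is emitted
    when at least one peak overlaps its window by >= *min_overlap_bp*; the
    supporting peak count is recorded and edges are deduplicated.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("window extents must be non-negative")
    edges = []
    for target in sorted(tss_table):
        chrom, tss, strand = tss_table[target]
        lo, hi = promoter_window(tss, strand, upstream, downstream)
        lo = max(0, lo)
        n = 0
        for p in peaks.peaks:
            if p.chrom != chrom:
                continue
            overlap = min(p.end, hi) - max(p.start, lo)
            if overlap >= min_overlap_bp:
                n += 1
        if n > 0:
            edges.append(Edge(peaks.tf, target, "chipseq", n))
    return edges


def consensus_mirna_targets(sets: list[TargetPairSet],
                            min_methods: int = 2) -> list[Edge]:
    """miRNA->mRNA pairs predicted by at least *min_methods* of the lists."""
    if min_methods > len(sets):
        raise ValueError(
            f"min_methods={min_methods} exceeds number of sets ({len(sets)})")
    counts: dict[tuple[str, str], list[str]] = {}
    for s in sets:
        for pair in s.pairs:
            counts.setdefault(pair, []).append(s.method)
    return [Edge(mirna, gene, "predicted", len(methods))
            for (mirna, gene), methods in sorted(counts.items())
            if len(methods) >= min_methods]


def seed_of(mirna_seq: str) -> str:
    """Reverse complement (DNA) of miRNA positions 2-8, the 7-mer seed."""
    seed = mirna_seq[1:8].upper()
    if len(seed) < 7:
        raise ValueError("miRNA sequence shorter than 8 nt")
    return seed.translate(_COMPLEMENT)[::-1]


def seed_match_fraction(
    genes: set[str],
    mirnas: set[str],
    utrs: dict[str, str],
    mirna_seqs: dict[str, str],
) -> float:
    """Percentage of genes whose 3'UTR holds a seed match to any miRNA."""
    if not genes:
        raise ValueError("empty gene set")
    matches = {seed_of(mirna_seqs[m]) for m in mirnas if m in mirna_seqs}
    considered = matched = 0
    for g in sorted(genes):
        utr = utrs.get(g)
        if utr is None:
            log.warning("gene %s has no 3'UTR record; skipped", g)
            continue
        considered += 1
        utr = utr.upper().replace("U", "T")
        if any(seed in utr for seed in matches):
            matched += 1
    if considered == 0:
        return 0.0
    return 100.0 * matched / considered


def validate_vs_chipseq(
    scores: dict[str, float],
    chip_targets: set[str],
) -> tuple[float, float]:
    """One-sided Mann-Whitney test: do ChIP targets score higher?

    Returns (p, U). Tests whether the binding scores of *chip_targets* are
    stochastically greater than those of the remaining scored targets.
    """
    in_scores = [s for t, s in scores.items() if t in chip_targets]
    out_scores = [s for t, s in scores.items() if t not in chip_targets]
    if not in_scores or not out_scores:
        raise ValueError("need at least one target in each group")
    if len(set(in_scores + out_scores)) == 1:
        log.warning("all binding scores identical; p = 1")
        return 1.0, float(len(in_scores) * len(out_scores)) / 2.0
    u, p = stats.mannwhitneyu(in_scores, out_scores, alternative="greater")
    return float(p), float(u)
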