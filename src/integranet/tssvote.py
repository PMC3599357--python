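"""miRNA transcription-start-site prediction by feature voting (TSSvote).

Primary miRNA transcripts are rarely annotated, so the TSS of a pri-miRNA is
predicted by scoring 100-bp windows across a search range with five lines of
evidence for transcription initiation::

    score = 2*d_transcript/EST + d_CpG + d_CAGE + d_H3K4me3 + conservation

where each d_feature is 1 when at least one interval of that track overlaps
the window and 0 otherwise, and conservation is the number of species whose
alignment blocks overlap the window divided by the number of species in
which the pre-miRNA hairpin is conserved (the ratio may exceed 1; it is not
capped, and windows where it does are reported).

The search range runs from the nearest upstream gene end (intergenic
miRNAs) or the host gene's TSS (intragenic miRNAs) to the 5' end of the
pre-miRNA, in transcription orientation. The best-scoring window wins;
ties go to the window whose midpoint is closest to the pre-miRNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_formats import (FeatureTrackSet, GenomeAnnotation, GenomicInterval,
                         TSS_FEATURES)

log = logging.getLogger(__name__)

WINDOW = 100
UPSTREAM_CAP = 100_000
PROMOTER_UP = 5_000
PROMOTER_DOWN = 1_000
FEATURE_WEIGHTS = {"transcript_EST": 2.0, "CpG": 1.0, "CAGE": 1.0, "H3K4me3": 1.0}


@dataclass(frozen=True)
class TssSearchRange:
    mirna: str
    interval: GenomicInterval
    category: str  # {"intergenic", "intragenic"}


@dataclass(frozen=True)
class WindowScore:
    window: GenomicInterval
    deltas: dict
    conservation: float
    score: float


@dataclass(frozen=True)
class TssPrediction:
    mirna: str
    tss: int
    strand: str
    category: str
    promoter: GenomicInterval
    score: float
    n_tied_windows: int


def _premirna_5prime(iv: GenomicInterval) -> int:
    return iv.start if iv.oriented_strand() == "+" else iv.end - 1


def tss_search_range(mirna: str, annotation: GenomeAnnotation) -> TssSearchRange:
    """Compute the TSS search range of a miRNA.

    Intragenic (a same-strand gene spans the hairpin, or an annotated host):
    host TSS to pre-miRNA 5' end. Intergenic: previous gene's 3'-side end to
    the pre-miRNA 5' end, capped at 100 kb upstream when no gene precedes.
    """
    if mirna not in annotation.mirnas:
        raise KeyError(f"unknown miRNA {mirna!r}")
    rec = annotation.mirnas[mirna]
    pre = rec.interval
    strand = pre.oriented_strand()
    five = _premirna_5prime(pre)

    host = rec.host_gene
    if host is None:
        for gid, g in annotation.genes.items():
            gi = g.interval
            if (gi.chrom == pre.chrom and gi.strand == pre.strand
                    and gi.start <= pre.start and pre.end <= gi.end):
                host = gid
                break

    if host is not None:
        host_tss = annotation.genes[host].tss
        if strand == "+":
            if five <= host_tss:
                raise ValueError(
                    f"{mirna}: pre-miRNA 5' end upstream of host TSS")
            iv = GenomicInterval(pre.chrom, host_tss, pre.start, strand)
        else:
            if five >= host_tss:
                raise ValueError(
                    f"{mirna}: pre-miRNA 5' end upstream of host TSS")
            iv = GenomicInterval(pre.chrom, pre.end, host_tss + 1, strand)
        return TssSearchRange(mirna, iv, "intragenic")

    # intergenic: nearest gene on the upstream side (either strand)
    if strand == "+":
        bounds = [g.interval.end for g in annotation.genes.values()
                  if g.interval.chrom == pre.chrom and g.interval.end <= pre.start]
        lo = max(bounds) if bounds else max(0, pre.start - UPSTREAM_CAP)
        lo = max(lo, pre.start - UPSTREAM_CAP)
        iv = GenomicInterval(pre.chrom, lo, pre.start, strand)
    else:
        bounds = [g.interval.start for g in annotation.genes.values()
                  if g.interval.chrom == pre.chrom and g.interval.start >= pre.end]
        hi = min(bounds) if bounds else pre.end + UPSTREAM_CAP
        hi = min(hi, pre.end + UPSTREAM_CAP)
        iv = GenomicInterval(pre.chrom, pre.end, hi, strand)
    return TssSearchRange(mirna, iv, "intergenic")


def conservation_score(window: GenomicInterval, tracks: FeatureTrackSet,
                       mirna: str) -> float:
    """Aligned-species count in the window over pre-miRNA conserved species.

    The denominator has a floor of 1; the ratio may exceed 1 when more
    species align over the window than conserve the hairpin.
    """
    n_aligned = 0
    for blocks in tracks.alignment.values():
        if any(b.overlaps(window) for b in blocks):
            n_aligned += 1
    denom = max(1, len(tracks.premirna_conserved_species.get(mirna, set())))
    ratio = n_aligned / denom
    if ratio > 1:
        log.info("conservation ratio %.2f > 1 for %s window [%d,%d)",
                 ratio, mirna, window.start, window.end)
    return ratio


def _tile_windows(rng: TssSearchRange) -> list[GenomicInterval]:
    """Non-overlapping 100-bp windows from the pre-miRNA-proximal edge out.

    The final partial window (< 100 bp) at the distal edge is kept and
    scored over its actual length.
    """
    iv = rng.interval
    windows: list[GenomicInterval] = []
    if iv.oriented_strand() == "+":
        # proximal edge = iv.end
        hi = iv.end
        while hi > iv.start:
            lo = max(iv.start, hi - WINDOW)
            windows.append(GenomicInterval(iv.chrom, lo, hi, iv.strand))
            hi = lo
    else:
        lo = iv.start
        while lo < iv.end:
            hi = min(iv.end, lo + WINDOW)
            windows.append(GenomicInterval(iv.chrom, lo, hi, iv.strand))
            lo = hi
    return windows


def score_windows(rng: TssSearchRange, tracks: FeatureTrackSet,
                  mirna: str) -> list[WindowScore]:
    """Score every window in the search range, proximal first."""
    out: list[WindowScore] = []
    for w in _tile_windows(rng):
        deltas = {}
        for feat in TSS_FEATURES:
            ivs = tracks.tracks.get(feat, [])
            deltas[feat] = 1 if any(iv.overlaps(w) for iv in ivs) else 0
        cons = conservation_score(w, tracks, mirna)
        score = sum(FEATURE_WEIGHTS[f] * deltas[f] for f in TSS_FEATURES) + cons
        out.append(WindowScore(w, deltas, cons, score))
    return out


def predict_tss(mirna: str, annotation: GenomeAnnotation,
                tracks: FeatureTrackSet) -> TssPrediction:
    """Predict the pri-miRNA TSS as the best-scoring window's 5' boundary.

    Ties on score are broken by minimal distance from the window midpoint to
    the pre-miRNA 5' end, then by smaller start coordinate. An empty search
    range yields a zero-score prediction at the pre-miRNA 5' end.
    """
    pre = annotation.mirnas[mirna].interval
    strand = pre.oriented_strand()
    five = _premirna_5prime(pre)
    try:
        rng = tss_search_range(mirna, annotation)
        scored = score_windows(rng, tracks, mirna)
        category = rng.category
    except ValueError:
        raise
    if not scored:
        log.warning("%s: empty search range; TSS set to pre-miRNA 5' end", mirna)
        return TssPrediction(mirna, five, strand, "intergenic",
                             _promoter(pre.chrom, five, strand,
                                       annotation), 0.0, 0)

    best_score = max(ws.score for ws in scored)
    tied = [ws for ws in scored if ws.score == best_score]
    winner = min(tied, key=lambda ws: (abs(ws.window.midpoint() - five),
                                       ws.window.start))
    w = winner.window
    tss = w.start if strand == "+" else w.end - 1
    return TssPrediction(mirna, tss, strand, category,
                         _promoter(w.chrom, tss, strand, annotation),
                         best_score, len(tied))


def _promoter(chrom: str, tss: int, strand: str,
              annotation: GenomeAnnotation) -> GenomicInterval:
    """-5 kb .. +1 kb around a TSS in transcription orientation, clipped."""
    if strand == "+":
        lo, hi = tss - PROMOTER_UP, tss + PROMOTER_DOWN
    else:
        lo, hi = tss - PROMOTER_DOWN + 1, tss + PROMOTER_UP + 1
    lo = max(0, lo)
    chrom_len = annotation.chrom_lengths.get(chrom)
    if chrom_len is not None:
        hi = min(hi, chrom_len)
    return GenomicInterval(chrom, lo, hi, strand)


def mrna_promoter(chrom: str, tss: int, strand: str,
                  upstream: int = 10_000, downstream: int = 5_000,
                  chrom_len: int | None = None) -> GenomicInterval:
    """Core promoter window around an annotated mRNA TSS (-10 kb .. +5 kb)."""
    if strand == "+":
        lo, hi = tss - upstream, tss + downstream
    else:
        lo, hi = tss - downstream + 1, tss + upstream + 1
    lo = max(0, lo)
    if chrom_len is not None:
        hi = min(hi, chrom_len)
    return GenomicInterval(chrom, lo, hi, strand)


def benchmark_predictions(predictions: list[TssPrediction],
                          validated: dict[str, int],
                          distances: tuple[int, ...] = (500, 2500)) -> dict[int, float]:
    """Fraction of predictions within each distance of a validated TSS.

    *validated* maps miRNA id to an experimentally determined TSS position;
    miRNAs without a validated entry are ignored. This is the harness for
    benchmarking against a user-supplied validated-TSS table.
    """
    tested = [p for p in predictions if p.mirna in validated]
    out = {}
    for d in distances:
        if not tested:
            out[d] = float("nan")
            continue
        hit = sum(1 for p in tested if abs(p.tss - validated[p.mirna]) <= d)
        out[d] = hit / len(tested)
    return out
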