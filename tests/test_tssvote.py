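import numpy as np
import pytest

from integranet import tssvote as tv
from integranet.io_formats import (FeatureTrackSet, GenomeAnnotation,
                                   GenomicInterval, GeneRecord, MirnaRecord,
                                   TSS_FEATURES)


def _annotation(genes=(), mirnas=()):
    ann = GenomeAnnotation()
    for gid, chrom, start, end, strand in genes:
        iv = GenomicInterval(chrom, start, end, strand)
        tss = start if strand == "+" else end - 1
        ann.genes[gid] = GeneRecord(iv, tss, "coding")
    for mid, chrom, start, end, strand, host in mirnas:
        ann.mirnas[mid] = MirnaRecord(GenomicInterval(chrom, start, end,
                                                      strand), host)
    return ann


class TestSearchRange:
    def test_intergenic_plus_strand_bounded_by_upstream_gene_end(self):
        ann = _annotation(genes=[("g1", "chr1", 25_000, 30_000, "+")],
                          mirnas=[("m1", "chr1", 50_000, 50_080, "+", None)])
        rng = tv.tss_search_range("m1", ann)
        assert rng.category == "intergenic"
        assert (rng.interval.start, rng.interval.end) == (30_000, 50_000)

    def test_intragenic_from_host_tss(self):
        ann = _annotation(genes=[("h", "chr1", 10_000, 30_000, "+")],
                          mirnas=[("m1", "chr1", 18_000, 18_080, "+", "h")])
        rng = tv.tss_search_range("m1", ann)
        assert rng.category == "intragenic"
        assert (rng.interval.start, rng.interval.end) == (10_000, 18_000)

    def test_minus_strand_mirrors_arithmetic(self):
        # pre-miRNA 5' end at 39,999 (interval end 40,000), upstream gene
        # at higher coordinates starting at 60,000
        ann = _annotation(genes=[("g1", "chr1", 60_000, 65_000, "+")],
                          mirnas=[("m1", "chr1", 39_920, 40_000, "-", None)])
        rng = tv.tss_search_range("m1", ann)
        assert (rng.interval.start, rng.interval.end) == (40_000, 60_000)

    def test_no_upstream_gene_caps_at_100kb(self):
        ann = _annotation(mirnas=[("m1", "chr1", 250_000, 250_080, "+",
                                   None)])
        rng = tv.tss_search_range("m1", ann)
        assert rng.interval.start == 150_000

    def test_host_detected_by_same_strand_span(self):
        ann = _annotation(genes=[("h", "chr1", 10_000, 30_000, "+")],
                          mirnas=[("m1", "chr1", 18_000, 18_080, "+", None)])
        assert tv.tss_search_range("m1", ann).category == "intragenic"

    def test_opposite_strand_span_is_not_a_host(self):
        ann = _annotation(genes=[("h", "chr1", 10_000, 30_000, "-")],
                          mirnas=[("m1", "chr1", 18_000, 18_080, "+", None)])
        assert tv.tss_search_range("m1", ann).category == "intergenic"

    def test_premirna_upstream_of_host_tss_is_an_error(self):
        ann = _annotation(genes=[("h", "chr1", 10_000, 30_000, "-")],
                          mirnas=[("m1", "chr1", 28_000, 28_080, "-", "h")])
        # '-' host TSS is at 29,999; the pre-miRNA 5' end (28,079) is fine,
        # but a pre-miRNA at the very TSS edge is not
        tv.tss_search_range("m1", ann)
        ann2 = _annotation(genes=[("h", "chr1", 10_000, 28_040, "-")],
                           mirnas=[("m2", "chr1", 28_000, 28_080, "-", None)])
        ann2.mirnas["m2"] = MirnaRecord(ann2.mirnas["m2"].interval, "h")
        with pytest.raises(ValueError):
            tv.tss_search_range("m2", ann2)


class TestConservation:
    def _tracks(self, aligned, conserved):
        t = FeatureTrackSet()
        for i in range(aligned):
            t.alignment[f"S{i}"] = [GenomicInterval("chr1", 0, 1_000)]
        t.premirna_conserved_species["m1"] = {f"C{i}"
                                              for i in range(conserved)}
        return t

    def test_ratio_of_aligned_to_conserved(self):
        w = GenomicInterval("chr1", 100, 200)
        assert tv.conservation_score(w, self._tracks(5, 10), "m1") == 0.5

    def test_no_alignment_gives_zero(self):
        w = GenomicInterval("chr1", 100, 200)
        assert tv.conservation_score(w, self._tracks(0, 10), "m1") == 0.0

    def test_ratio_may_exceed_one(self):
        w = GenomicInterval("chr1", 100, 200)
        assert tv.conservation_score(w, self._tracks(8, 4), "m1") == 2.0

    def test_denominator_floor_of_one(self):
        w = GenomicInterval("chr1", 100, 200)
        assert tv.conservation_score(w, self._tracks(3, 0), "m1") == 3.0


class TestScoreWindows:
    def _setup(self, features, conservation_species=0):
        ann = _annotation(genes=[("g1", "chr1", 25_000, 30_000, "+")],
                          mirnas=[("m1", "chr1", 30_500, 30_580, "+", None)])
        rng = tv.tss_search_range("m1", ann)
        tracks = FeatureTrackSet()
        window = GenomicInterval("chr1", 30_400, 30_500)
        for f in features:
            tracks.tracks[f] = [GenomicInterval("chr1", 30_420, 30_460)]
        for i in range(conservation_species):
            tracks.alignment[f"S{i}"] = [window]
        tracks.premirna_conserved_species["m1"] = (
            {f"S{i}" for i in range(conservation_species)} or {"S0"})
        return rng, tracks

    def test_all_features_and_full_conservation_score_six(self):
        rng, tracks = self._setup(TSS_FEATURES, conservation_species=3)
        scores = tv.score_windows(rng, tracks, "m1")
        assert scores[0].score == 6.0  # 2 + 1 + 1 + 1 + 1.0

    def test_no_evidence_scores_zero(self):
        rng, tracks = self._setup(())
        assert all(w.score == 0.0 for w in tv.score_windows(rng, tracks,
                                                            "m1"))

    def test_transcript_weight_is_two(self):
        rng, tracks = self._setup(("transcript_EST",))
        scores = tv.score_windows(rng, tracks, "m1")
        assert scores[0].score == 2.0

    def test_removing_a_feature_drops_its_exact_weight(self):
        rng, full_tracks = self._setup(TSS_FEATURES, conservation_species=3)
        full = tv.score_windows(rng, full_tracks, "m1")[0].score
        for feat in TSS_FEATURES:
            rng2, tracks = self._setup(tuple(f for f in TSS_FEATURES
                                             if f != feat), 3)
            partial = tv.score_windows(rng2, tracks, "m1")[0].score
            assert full - partial == tv.FEATURE_WEIGHTS[feat]

    def test_windows_tile_from_proximal_edge(self):
        rng, tracks = self._setup(())
        windows = [w.window for w in tv.score_windows(rng, tracks, "m1")]
        assert windows[0].end == 30_500  # proximal to the pre-miRNA
        assert all(len(w) == 100 for w in windows[:-1])
        assert len(windows[-1]) <= 100


class TestPredictTss:
    def test_tie_broken_by_distance_to_premirna(self):
        ann = _annotation(genes=[("g1", "chr1", 15_000, 20_000, "+")],
                          mirnas=[("m1", "chr1", 30_000, 30_080, "+", None)])
        tracks = FeatureTrackSet()
        # identical evidence 200 bp away and 5 kb away
        near = GenomicInterval("chr1", 29_700, 29_800)
        far = GenomicInterval("chr1", 24_900, 25_000)
        tracks.tracks["CpG"] = [near, far]
        tracks.premirna_conserved_species["m1"] = {"S0"}
        pred = tv.predict_tss("m1", ann, tracks)
        assert pred.tss == 29_700
        assert pred.n_tied_windows == 2

    def test_single_window_wins_regardless_of_score(self):
        ann = _annotation(genes=[("g1", "chr1", 25_000, 29_950, "+")],
                          mirnas=[("m1", "chr1", 30_000, 30_080, "+", None)])
        tracks = FeatureTrackSet()
        tracks.premirna_conserved_species["m1"] = {"S0"}
        pred = tv.predict_tss("m1", ann, tracks)
        assert pred.tss == 29_950  # the lone (partial) window's 5' boundary
        assert pred.score == 0.0

    def test_promoter_extent_minus_5kb_plus_1kb(self):
        ann = _annotation(genes=[("g1", "chr1", 15_000, 20_000, "+")],
                          mirnas=[("m1", "chr1", 30_000, 30_080, "+", None)])
        tracks = FeatureTrackSet()
        tracks.tracks["CAGE"] = [GenomicInterval("chr1", 29_910, 29_950)]
        tracks.premirna_conserved_species["m1"] = {"S0"}
        pred = tv.predict_tss("m1", ann, tracks)
        assert pred.promoter.start == pred.tss - 5_000
        assert pred.promoter.end == pred.tss + 1_000

    def test_track_order_does_not_change_prediction(self):
        ann = _annotation(genes=[("g1", "chr1", 15_000, 20_000, "+")],
                          mirnas=[("m1", "chr1", 30_000, 30_080, "+", None)])
        tracks = FeatureTrackSet()
        ivs = [GenomicInterval("chr1", 29_700, 29_800),
               GenomicInterval("chr1", 24_900, 25_000),
               GenomicInterval("chr1", 27_300, 27_350)]
        tracks.tracks["CpG"] = ivs
        tracks.premirna_conserved_species["m1"] = {"S0"}
        a = tv.predict_tss("m1", ann, tracks)
        tracks.tracks["CpG"] = ivs[::-1]
        b = tv.predict_tss("m1", ann, tracks)
        assert a == b


def _brute_force_predict(mirna, ann, tracks):
    """Independent oracle: exhaustively score and rank every window."""
    rng = tv.tss_search_range(mirna, ann)
    iv = rng.interval
    pre = ann.mirnas[mirna].interval
    five = pre.start if pre.strand == "+" else pre.end - 1
    windows = []
    if iv.strand == "+":
        edges = list(range(iv.end, iv.start, -100))
        for hi in edges:
            windows.append((max(iv.start, hi - 100), hi))
    else:
        for lo in range(iv.start, iv.end, 100):
            windows.append((lo, min(iv.end, lo + 100)))
    best = None
    for lo, hi in windows:
        score = 0.0
        for feat, weight in tv.FEATURE_WEIGHTS.items():
            hit = any(t.chrom == iv.chrom and t.start < hi and lo < t.end
                      for t in tracks.tracks.get(feat, []))
            score += weight * hit
        aligned = sum(
            1 for blocks in tracks.alignment.values()
            if any(b.chrom == iv.chrom and b.start < hi and lo < b.end
                   for b in blocks))
        denom = max(1, len(tracks.premirna_conserved_species.get(mirna,
                                                                 set())))
        score += aligned / denom
        key = (-score, abs((lo + hi) / 2 - five), lo)
        if best is None or key < best[0]:
            best = (key, (lo, hi), score)
    tss = best[1][0] if iv.strand == "+" else best[1][1] - 1
    return tss, best[2]


class TestOracleEquivalence:
    def test_matches_exhaustive_argmax_on_random_loci(self):
        rng = np.random.default_rng(42)
        for trial in range(100):
            strand = "+" if rng.random() < 0.5 else "-"
            gene_start = int(rng.integers(12_000, 20_000))
            gap = int(rng.integers(2_000, min(20_000, gene_start - 6_000)))
            if strand == "+":
                genes = [("g", "chr1", gene_start, gene_start + 5_000, "+")]
                pre_start = gene_start + 5_000 + gap
                mirnas = [("m", "chr1", pre_start, pre_start + 80, "+",
                           None)]
                lo, hi = gene_start + 5_000, pre_start
            else:
                pre_end = gene_start - gap
                genes = [("g", "chr1", gene_start, gene_start + 5_000, "-")]
                mirnas = [("m", "chr1", pre_end - 80, pre_end, "-", None)]
                lo, hi = pre_end, gene_start
            ann = _annotation(genes=genes, mirnas=mirnas)
            tracks = FeatureTrackSet()
            for feat in TSS_FEATURES:
                n = int(rng.integers(0, 4))
                tracks.tracks[feat] = [
                    GenomicInterval("chr1", p, p + int(rng.integers(10, 200)))
                    for p in rng.integers(lo, hi, size=n)]
            for s in range(int(rng.integers(0, 4))):
                p = int(rng.integers(lo, hi))
                tracks.alignment[f"S{s}"] = [
                    GenomicInterval("chr1", p, p + int(rng.integers(50,
                                                                    500)))]
            tracks.premirna_conserved_species["m"] = {
                f"C{i}" for i in range(int(rng.integers(1, 6)))}
            pred = tv.predict_tss("m", ann, tracks)
            oracle_tss, oracle_score = _brute_force_predict("m", ann, tracks)
            assert pred.tss == oracle_tss, f"trial {trial}"
            assert pred.score == pytest.approx(oracle_score)


class TestPlantedRecovery:
    def test_all_predictions_fall_in_the_planted_window(self,
                                                        noisefree_scenario):
        from integranet import io_formats as iof
        base, truth = noisefree_scenario
        ann = iof.read_annotation(base / "annotation.tsv")
        tracks, _ = iof.load_tracks(base / "tracks" / "tracks.yaml")
        for mid, (lo, hi) in truth.tss_window.items():
            pred = tv.predict_tss(mid, ann, tracks)
            assert lo <= pred.tss < hi
            assert pred.tss == truth.tss[mid]
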