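# Methods

This note documents the models, parameters, numerical choices and
limitations of `integranet`. All coordinates are 0-based, half-open
(BED-native) internally; annotation TSVs are 1-based inclusive on disk and
converted on read. Strand "." is treated as "+" for promoter arithmetic,
with a logged warning.

## Coexpression clustering (IRGCs)

Expression profiles are z-scored per gene before k-means, because k-means
on raw intensities is dominated by absolute scale rather than shape. The
defaults are k = 12 clusters and a centroid-merge threshold of Pearson
r ≥ 0.85; both are config keys (`cluster.k`, `cluster.merge_r`). k must
comfortably exceed the number of biological clusters one expects to
survive filtering, since the merge step collapses redundant k-means
fragments.

A k-means cluster survives filtering when (a) it contains at least one
gene from the user-supplied myelination-gene list and (b) its member genes
are differentially expressed between the pre-injury and post-injury
timepoints. The differential test is a two-sample t-test on the per-gene
means over the pre- and post-injury columns; testing gene-level means
(rather than the centroid's few timepoint values) keeps the test
well-defined with a single pre-injury timepoint. Final membership is
re-derived from scratch: every expressed gene with Pearson r ≥ 0.8
(`cluster.assign_r`) to a merged centroid is assigned to its best-r
centroid, so memberships are disjoint by construction. Clusters whose
centroid falls at the first post-injury timepoint relative to the
pre-injury baseline are labelled MGC, the rest PGC; this automates a
labelling that is otherwise done by inspecting the profiles.

miRNA arrays carry each miRNA on two duplicate probesets plus control
probesets. A miRNA is dropped when its maximum over both duplicates and
all timepoints stays below the mean of the control probesets, or when one
duplicate exceeds the other at every timepoint with a one-sided exact
Mann–Whitney U test significant at 0.05 — one-sided because the criterion
is directional (one duplicate systematically higher). Surviving rows are
per-timepoint means of the duplicates. Note that with only 3 timepoints
the smallest attainable one-sided exact p is 1/C(6,3) = 0.05, so the
duplicate-disagreement filter cannot fire at the default alpha on a
3-timepoint design; it becomes active from 4 timepoints up.

Regulator calls use the same r cutoff of 0.8 (`cluster.r_cut`), matching
the membership cutoff. When the regulator platform samples different days
than the mRNA platform, `cluster.timepoint_map` aligns them (the default
scenario maps miRNA days 0/4/14 onto mRNA days 0/4/10); at least 3 mapped
points are required, and zero-variance profiles yield no call.

## miRNA TSS prediction (feature voting)

Each 100-bp window of the search range is scored

    score = 2·δ_transcript/EST + δ_CpG + δ_CAGE + δ_H3K4me3 + conservation

with δ_feature = 1 when at least one interval of that track overlaps the
window by ≥ 1 bp (the simplest testable overlap rule), and conservation =
(number of species whose alignment blocks overlap the window) / (number of
species conserving the pre-miRNA hairpin, floored at 1). The ratio is not
capped at 1; windows where it exceeds 1 are logged.

The search range runs from the host gene's TSS (intragenic miRNAs — a
same-strand gene spanning the hairpin, or an annotated host) or from the
nearest upstream gene boundary (intergenic) to the hairpin's 5' end, in
transcription orientation, capped at 100 kb when no upstream gene exists.
Window tiling is anchored at the pre-miRNA-proximal edge so the most
plausible proximal region is covered by full windows; a terminal partial
window is scored over its actual length. The best window wins; ties break
by minimal window-midpoint distance to the hairpin, then by smaller
coordinate for determinism. The reported TSS is the winning window's
transcription-oriented 5' boundary, and the promoter is −5 kb…+1 kb
around it (clipped at chromosome bounds). An empty search range yields a
zero-score prediction at the hairpin 5' end with a warning.

## Phylogenetically weighted binding model

PWMs are log-odds matrices (any log base in the file header; natural log
internally). Scanning is plain log-odds summation over both strands. The
"default" cutoff is the smallest score whose exceedance probability under
the background base composition is ≤ 10⁻³ per position per strand,
computed exactly by dynamic programming over the PWM score distribution
discretized at 0.01 score units — a self-contained, exact reimplementation
of default-cutoff log-odds scanning that avoids any external binary and is
overridable via `tfbs.cutoff`. Non-ACGT bases score −∞ in their columns
(never hits); spaces with > 10 % non-ACGT content are flagged.

A site is conserved in a species when its interval is fully covered by one
of that species' alignment blocks (partial cover does not count); the
reference species is always included. Its weight w_x is the branch-length
total of the minimal spanning subtree connecting the conserved species, so
shared branches are counted once and conservation in a distant species
weighs more than in a close relative. A reference-only site has w_x =
`tfbs.w_floor` (default 0, i.e. non-conserved sites contribute nothing; a
positive floor lets them contribute a baseline).

The binding score of a TF–target pair is Σ w_x·exp(s_x) with s_x in
natural-log units (when PWMs are supplied in bits the conversion happens
on read, and exp always applies to the natural-log value).

Significance uses a permutation null of our own design, since "site
permutation" admits several readings: every detected site of a PWM is
relocated uniformly at random over the concatenated search space of all
targets, keeping its (s_x, w_x) pair, and sites are reassigned to targets
by landing position. This null preserves both the number and the quality
distribution of sites, and raw_p = (1 + #{null ≥ observed})/(n_perm + 1)
is super-uniform by construction. Targets with observed score 0 get p = 1
directly. Defaults: `tfbs.n_perm = 999` (raw-p floor 0.001),
Bonferroni per TF over its PWMs, adjusted p ≤ 0.005 (`tfbs.alpha`).

The search space per mRNA is the −10 kb…+5 kb core promoter; when a
regulatory-potential BED is supplied (`paths.rp_track`), intervals scoring
> 0.1 within −100 kb…gene end are added as distal regions. miRNA search
spaces are the −5 kb…+1 kb predicted promoters. Computing the
regulatory-potential track itself is out of scope.

## ChIP integration, consensus targets, seed matches

A peak supports a TF→target edge when it overlaps the target's promoter
window by ≥ 1 bp (`targets.min_overlap_bp`); peaks must already be in the
working genome's coordinates (cross-species peak lift-over is out of
scope). When a pair is supported by both ChIP and prediction, the edge
keeps the ChIP label — experimental evidence takes precedence, and
prediction only fills in TFs lacking ChIP data. miRNA→mRNA edges need
agreement of ≥ 2 of the 3 supplied target lists. The seed-match utility
uses the exact 7-mer rule (3'UTR match to the reverse complement of miRNA
positions 2–8); 8-mer and 7mer-A1 variants are not counted.

## Master regulators

The R-score of a gene for a TF is its ascending rank of the binding score
divided by the number of scored genes, with average ranks on ties — a
deterministic concretization of rank-percentile scoring. The cluster
statistic is the mean member R; the null is `master.n_random = 9999`
same-size clusters drawn uniformly **without replacement** from the
universe (clusters are sets). Master TFs use Bonferroni over the
regulators tested at 0.05; master miRNAs use the one-sided hypergeometric
tail P(X ≥ k) with population = expressed genes targeted by at least one
miRNA, and deliberately no multiplicity correction — the two procedures
are asymmetric by design, and `master.correction` can override either.
The sampling universe is an explicit parameter (the pipeline uses
expressed genes) rather than a hard-coded genome-wide set.

## Network assembly and motifs

miRNA edges are always repressive. TF edge signs come from the Pearson
correlation between regulator and target profiles (the pipeline correlates
on the injury timepoints shared by both platforms); |r| < 0.3 or a missing
profile flags the sign low-confidence (defaulting to activation when no
profile exists). Feedforward loops are triples TF→gene, TF→miRNA→gene
with the gene typed mRNA; coherent iff the direct sign equals the product
of the indirect signs; categories I1/I2/C1/C2 by coherence × target class.
Loops whose target carries no cluster class are excluded from the census
and counted separately rather than forced into a class. The bias test is a
two-sided Fisher exact test on a 2×2 table counting **distinct** target
genes per cell — counting motifs would pseudo-replicate a gene that sits
in many loops — and motif-level counts are reported alongside. Feedback
loops are simple directed cycles up to length 3, canonicalized at their
lexicographically smallest node, signed by the product of edge signs.

## Synthetic scenarios

The default scenario is sized for fast, exhaustive testing: 2 chromosomes
× 1 Mb, 60 genes (8 TFs) on fixed 30-kb slots with alternating strands,
12 miRNAs (8 intergenic in gaps, 4 intragenic in host introns), 5 species
on a two-cherry-plus-outgroup tree, 7 mRNA timepoints (injury days
0/4/7/10 and development days 2/4/10) and 3 miRNA timepoints, expression
noise σ = 0.1 on z-shaped centroids (dip-and-recover "myelination" vs
spike-and-decay "proliferation"), ChIP peak false-negative and
false-positive rates of 0.05, and full TSS-feature completeness. The full
pipeline runs in a few seconds at this size. Planted structure: two
reciprocal 15-gene clusters; correlated/anti-correlated TF and miRNA
regulators; TSS evidence features in exactly one window per miRNA; PWM
consensus sites (five per planted TF–target pair, at per-TF-shifted
offsets so sites never overwrite each other) with alignment cover in four
of five species; a non-correlated master TF with sites across one
cluster; a non-correlated master miRNA with targets concentrated in one
cluster; target lists placing planted pairs in ≥ 2 of 3 methods and
decoys in exactly 1; duplicate miRNA probesets with controls and one
below-control decoy; overlapping TF/miRNA target sets that close
feedforward loops; and one negative feedback loop (TF1 → mirna1 ⊣ TF1).

What the generator does **not** emulate: realistic sequence composition
(background is i.i.d. uniform), probe-level microarray noise and
normalization artefacts, correlated noise across genes, alignment gaps,
or imprecise peak boundaries. Passing tests therefore demonstrate
correctness of the algorithms and their statistics under the stated
generative model, not performance on real genome-scale data; the
genome-scale figures of TSS-prediction accuracy or interaction counts
require external tracks and databases and are deliberately not
reproduced. A harness (`tssvote.benchmark_predictions`,
`integranet tss --validated`) is provided for benchmarking against a
user-supplied validated-TSS table.

## Determinism and numerical notes

One global seed drives everything; the pipeline derives per-module
sub-seeds (seed, seed+1, seed+2 for clustering, permutation, master
resampling) so modules cannot collide on a shared stream. Identical
config + seed gives byte-identical outputs (sorted iteration everywhere,
rounded fixed-format tables). Permutation and resampling p-values use the
(1 + exceedances)/(n + 1) estimator with a ≥-comparison cushioned by 1e-12
to make ties deterministic across platforms. Degenerate inputs are
handled explicitly: zero-variance profiles yield no correlation call,
empty site pools yield p = 1, empty search ranges yield a warned
zero-score TSS at the hairpin, degenerate 2×2 tables yield p = 1 with a
warning, and an empty cluster-filter result is a warned empty list, not
an error.

## Known limitations

- The permutation null and the R-score formula are this package's own
  concretizations of loosely specified procedures; both are documented
  above and config-exposed, but other choices are defensible.
- Edge signs for master regulators whose expression is uninformative are
  low-confidence by construction; the sign-accuracy figure reported by
  the acceptance script reflects this honestly.
- TSS prediction reports a single winner; close-scoring alternative
  windows are only visible through the tie count.
- The GFF3 importer handles the common single-line gene/miRNA case only;
  the annotation TSV is the canonical input.
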