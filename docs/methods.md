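# Methods

`circkit` is a downstream analysis toolkit for circular RNAs (circRNAs).
It starts where detection tools stop: given per-tool tables of predicted
back-splice junctions (BSJs), it harmonises them into one canonical record
set and carries that set through annotation, filtering, differential
expression, cross-species coordinate lifting, sequence extraction and
sequence-based functional screens.  This note documents the models,
conventions and numerical choices behind each stage, and what the
synthetic test data do and do not demonstrate.

## Canonical BSJ records

A circRNA is identified by its back-splice junction: the 3' end of a
downstream exon joined to the 5' start of an upstream exon.  Every
supported detector (MapSplice2, NCLscan, CircMarker, CircExplorer2,
KNIFE, UROBORUS) reports this junction differently, so each has a
table-driven dialect declaring column positions, the coordinate base
(0 or 1) and the end convention (inclusive or half-open).  None of the
tools publishes a frozen schema; the shipped dialects are best-effort
defaults and a documented `generic` dialect (chrom, strand, start, end,
gene, count) covers anything else.

Canonical coordinates are 1-based, inclusive, and stored in
*transcription order*: `startUpBSE` is the first transcribed base of the
upstream back-spliced exon, `endDownBSE` the last transcribed base of
the downstream one.  On the minus strand `startUpBSE >= endDownBSE`.
This matches GTF, the annotation currency of the rest of the pipeline,
and makes strand symmetry a mechanical property: every sequence
operation on a minus-strand record is the reverse complement of the
mirrored plus-strand operation.

Merging keys on (gene, strand, chrom, startUpBSE, endDownBSE) and
unions (tool, sample) counts.  Two conventions need a decision the
input formats force on us:

* CircMarker reports no gene symbol.  Gene-less records adopt the gene
  of a coordinate-identical gene-named record when that match is
  unique; otherwise they stay as gene `.` and can only be annotated by
  coordinate later.
* Identical coordinates under conflicting gene symbols are kept as two
  records with a warning; there is no principled automatic winner.

Antisense calls: a record whose strand contradicts the annotated strand
of its gene *while both BSJ coordinates sit on annotated exon
boundaries of that gene* is flagged antisense and excluded from
downstream stages by default (the flag is kept, so the exclusion is
reversible).  Strand conflicts off exon boundaries are flagged
`unannotated` instead — there is no evidence tying them to the gene at
all.

## Annotation

Exon structure comes from an Ensembl/GENCODE-style GTF (parsed with
`gffutils`).  A BSJ is matched by *exact* boundary coincidence: the
upstream coordinate must equal the transcribed start of exon *i* and
the downstream coordinate the transcribed end of exon *j >= i* of the
same transcript.  Exactness is the right default for annotation-based
detectors, whose coordinates are exon edges by construction; a
`tolerance` parameter (nt) exists for noisy inputs.  When several
transcripts match, the one with the most exons wins, ties broken by
genomic span and then transcript id — an arbitrary but deterministic
rule.  Requiring both coordinates to match the *same* transcript is
the stricter of the two possible readings and is intentional: flanking
introns are only well defined within one transcript.

Unmatched records carry their nearest-boundary distances and are
excluded from sequence-based stages.

## Count filtering

Multiple tools reporting the same junction in the same library largely
re-count the same BSJ-spanning reads, so the default cross-tool
collapse takes the per-sample **maximum** rather than the sum (sum and
single-tool modes are available).  The prevalence filter keeps a
circRNA iff at least one condition has `min_samples` samples with
`min_count` reads or more; the defaults (5 reads, 3 samples) are the
package's reference analysis settings.  The filter is monotone in both
thresholds and decided per condition, properties the test suite pins.

## Differential expression

A self-contained negative-binomial two-group pipeline in the
DESeq2/edgeR model family (`Var = mu + alpha mu^2`):

* **Size factors** — median of ratios to the per-row geometric mean,
  over zero-free rows only, rescaled to geometric mean 1.  With no
  zero-free row the estimator falls back to total-count scaling.
* **Dispersion** — per-circ method of moments on normalised counts,
  `alpha = max(0, (s2 - mu)/mu^2)` with the within-condition pooled
  variance, moderated toward the across-circ mean with weight
  `prior_df / (prior_df + resid_df)` on the prior (`prior_df = 20`).
  With the typical 3-vs-3 design a circ contributes 4 residual df, so
  ~83% of the weight falls on the shared prior.  This df-based
  moderation was chosen over a fixed small shrinkage weight after
  simulation: at n = 3/group a mostly-unshrunk MoM dispersion makes
  the Wald test badly anticonservative (type-I rate ≈ 0.11 at nominal
  0.05), while the moderated estimator sits at ≈ 0.055–0.065; the
  irreducible level of the same test with the *true* dispersion
  plugged in is ≈ 0.053.  The prior is the plain mean rather than a
  trimmed mean — trimming the heavily right-skewed MoM distribution
  biases the prior low and re-inflates the test.
* **Test** — log2FC = log2((mu_B + 0.5)/(mu_A + 0.5)) with the 0.5
  pseudocount in the point estimate and the variance plug-in only
  (never a likelihood); delta-method SE of the log mean,
  `Var(q_ij) = mu/sf_j + alpha mu^2`; two-sided normal p;
  Benjamini–Hochberg across tested circs.  A circRNA is significant at
  |log2FC| >= 1 and BH-adjusted p <= 0.05 by default.

Calibration and power are measured by simulation in the test suite:
1000 null circs (3 vs 3, dispersion 0.2) for the type-I rate, and 50
planted |log2FC| = 2 circs at mean 200 among 950 nulls for recovery.
The planted-effect simulation uses dispersion 0.1, a realistic value
for counts at that depth; at dispersion 0.2 no Wald-type test — not
even one given the true dispersion and means — exceeds ~75% sensitivity
under BH at these sample sizes, so that setting measures the ceiling of
the design, not the quality of the implementation.

Known limitation: the normal Wald p at n = 3/group is mildly liberal
(measured ≈ 0.06 at nominal 0.05) even with moderated dispersion; exact
small-sample NB tests are out of scope.

## Liftover

UCSC chain files (plain or gzip) are parsed with block-sum invariants
verified on load.  BSJ ends are lifted as exact points: chains covering
the position are tried in descending score order and the first chain
whose *aligned blocks* contain the position wins; positions falling
only in alignment gaps are unmapped.  There is no fractional-region
rescue — the unit of interest is the junction base itself.  A record
lifts iff both ends map to the same destination chromosome with the
same orientation flip; mismatches are reported as `split` or
`strand_conflict`, and the destination record is re-canonicalised to
transcription order under the (possibly flipped) destination strand.

## Random BSJ background

Enrichment screens need a null set: exon pairs from the same annotation
that are not observed circRNAs.  Sampling is uniform over transcripts,
then uniform over ordered exon index pairs i <= j; draws colliding with
the foreground or with earlier draws are rejected; generation is
deterministic given the seed and fails loudly (after n × 1000
attempts) when the annotation cannot supply enough distinct records.
Every accepted record sits on exact exon boundaries, so the background
flows through annotation, sequence extraction and the screens with zero
unmatched failures — a property the tests assert.

## Sequence extraction

All sequences are DNA (T not U) in transcript orientation; an RNA flag
converts T→U at FASTA-writing time only.  Soft-masked genome bases are
uppercased on load.

* `internal` — concatenated internal exon sequence, 5'→3' around the
  circle, flagged circular.
* `across_bsj` — last min(w, len) nt of the internal sequence joined to
  its first min(w, len) nt; w defaults to 11 per side, enough to cover
  a seed site on either side of the junction.
* flanks — `introns` (full flanking introns), `window` (the
  `intron_nt` intron bases adjacent to the BSJ joined to the `exon_nt`
  exon bases adjacent to the BSJ; defaults 200 + 10 nt, both anchored
  at the junction because that is where biogenesis-relevant RBP motifs
  act), `bse` (the full back-spliced exons).  Windows clip at feature
  boundaries with a warning.

## Motif screen

Motifs are IUPAC consensus strings (ATtRACT-style tables load
directly); position-wise degeneracy expansion, overlapping matches all
counted.  Circular sequences are extended by pattern length − 1 bases
so junction-spanning matches are found exactly once.  PWM scanning and
EM-style de novo discovery are out of scope; de novo screening is a
k-mer over-representation ranking instead.

Enrichment of a foreground set against a background set reports, per
motif, match rates per kilobase and their ratio (the fold), a Fisher
exact p on matched versus unmatched scan windows, and BH adjustment
across motifs.  Per-kilobase rates make differently sized sets
comparable; a zero background rate is reported as an infinite-fold
flag rather than a number.

## miRNA seed sites

The seed is mature positions 2–8 (the standard 7-mer; offset and
length are configurable).  A target window is scored by reversing it
and pairing position-wise against the seed (antiparallel duplex):
(A,T), (U,A), (G,C), (C,G) are Watson–Crick; (G,T), (U,G) are G:U
wobbles; anything else, including N, is a mismatch.  A site is
accepted at total >= 6 matches, >= 5 Watson–Crick, and at most one
wobble — the default stringency, all three thresholds configurable.
Scanning is junction-aware: windows start at every position of the
internal sequence extended by its first 6 nt, so the multiset of site
scores is invariant under rotation of the circle, and sites with start
position > len − 6 are flagged `spans_junction`.  Sites are counted
per start position without merging overlaps.  Only the sense strand is
scanned — the miRNA binds the transcript, not its complement.  An
optional expression filter keeps miRNAs with mean read count >= 10
over designated samples before scanning.

## Flank region annotation

GWAS-catalog-style SNPs (with an optional trait substring/regex
filter) and RepeatMasker-style repeats (0-based starts converted on
load) are assigned to the upstream/downstream flank of each circ by
>= 1 base overlap, inclusive boundaries, via interval trees.
"Complementary repeats" are operationalised as: one repeat in each of
the two flanking introns, both satisfying the family predicate
(default: Alu, by name prefix or family), on opposite strands.  This
is the configuration that lets the two intron arms base-pair and
promote back-splicing.  Sequence-level verification of
reverse-complementarity between the repeat copies is out of scope.

## Synthetic data

`circkit.fixtures.build_fixture` emits a fully consistent mini-dataset:
a ~47 kb two-chromosome genome, 12 genes (4–8 exons, 120–280 nt exons,
260–420 nt introns, two genes with a second, shorter transcript), 24
ground-truth circs (including a single-exon and a full-span case), all
six tool dialects with per-tool decoys (counts <= 4, so the prevalence
filter removes them), two antisense records on exact exon boundaries,
NB counts (dispersion 0.2, means 30–300) for 3 control + 3 disease
samples with six planted |log2FC| = 2 effects, eight mature miRNAs with
planted perfect seed sites (three interior, one split across the BSJ),
a five-motif database with one motif planted at exactly 4× foreground
density in generated foreground/background sets, GWAS SNPs and repeat
tables planted in flanking introns (an inverted Alu pair in exactly
half of the eligible circs), and identity/shift/gapped/inversion chain
files plus a cross-species chain covering only chr1.  A manifest JSON
records every planted truth; byte-identical output is guaranteed for a
given seed.

Eligibility for the repeat-pair fraction is restricted to circs whose
two flanking introns are disjoint from every other eligible circ's
introns; without that restriction a repeat planted for one circ can
leak into another circ's flank and the planted fraction stops being
exact.

What the fixture does **not** emulate: read-level noise and alignment
artifacts (counts are drawn, not aligned), realistic gene density,
overlapping genes, GC/repeat-matched backgrounds, isoform complexity
beyond one alternative transcript, and genuine evolutionary divergence
in the chains.  Passing tests therefore demonstrate correctness of the
bookkeeping, coordinate arithmetic, scanners and statistics under the
stated model — not detector accuracy on real sequencing data.

## Determinism

Every stochastic component takes one integer seed (config key `seed`);
tables are written with fixed column order and `%.6g` floats, JSON with
sorted keys, and no timestamps, so a pipeline run is byte-reproducible.
The acceptance script (`scripts/acceptance.py`) regenerates the
fixture, reruns the pipeline and the DE simulations from the given
seed, and reports recovery rates and calibration as JSON.
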