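# Methods

## Problem setting

`svharvest` detects large structural variants (deletions, tandem
duplications and multiplications, insertions, complex deletion+insertions,
inversions, and translocations, nominally >= 50 bp) in whole-genome
resequencing data of clonally propagated mutagenized strains — the setting
of TMP/UV forward-mutagenesis screens in *C. elegans*, where each strain
carries a handful of induced variants on an otherwise shared background.
The data model is short single-end reads (~120 bp) at modest depth
(15–20x), aligned to the reference; mate-pair or split-alignment evidence
from an aligner is not assumed.

## Detection model

**Split reads.** A read crossing a variant junction aligns partially: the
aligned portion anchors one side of the break and the soft-clipped tail,
realigned elsewhere, marks the partner side. Soft clips of at least
`min_clip_len` (default 15 bp) are realigned by exact-seed lookup (first
`seed_len` = 12 bases into a precomputed k-mer index) followed by ungapped
extension scored by identity over the full clip (`min_identity` = 0.95).
A clip with more than one equally best locus is discarded as ambiguous
rather than assigned — conservative by design. Realignment is deliberately
ungapped and deterministic: clips are 15–105 bp and the genome small enough
that a seeded exact scan is both fast and independently verifiable against
a brute-force full-genome scan (the test suite does exactly that).

**Novel sequence at junctions.** Insertions and deletion+insertions leave
a run of novel bases at the junction end of the clip. Offsets into the clip
are scanned and every realignable remainder is scored
`matches − 4·mismatches`; the best-scoring consistent interpretation wins.
This scoring matters: accepting the first offset that clears the identity
threshold lets an alignment absorb a few novel bases as mismatches and
shift the breakpoint by one or two positions. The remainder after trimming
must be at least 16 bases (`MIN_OFFSET_MATCH`): a bare 12-mer seed
exact-matches a random megabase-scale sequence with probability ~0.1 and
produced systematic false junctions in early testing, while 16 matching
bases are specific to ~5·10⁻⁷.

**Break-site classification.** With the anchor breakpoint, the clip side,
and the unique realignment locus, the junction pattern follows from the
table in `classify_pattern`: same contig and strand with the partner
downstream of a right-side anchor is a deletion (zero gap plus novel bases:
insertion; positive gap plus novel bases: deletion+insertion); partner
upstream or overlapping is a tandem duplication; opposite strand is an
inversion breakend; a different contig is a translocation. Both junctions
of an inversion normalize to the same (start, end) pair, so a complete
inversion appears as one cluster fed by left- and right-side clips;
clusters supported from only one side are flagged `breakend_only`.

**Clustering.** Per-read breakpoints of the same pattern merge when both
coordinates agree within `cluster_tolerance` (5 bp); cluster coordinates
are the modal per-read values with ties broken toward the smaller
coordinate (determinism); support counts distinct read ids, never
alignments. Clusters below `min_support` (3 reads) are dropped — at 15–20x
a real homozygous junction is typically crossed usably by 10–15 reads, so
3 distinct reads separates signal from stray realignment noise without
costing sensitivity.

**Copy number.** Read starts are binned (`bin_size` = 500 bp), normalized
to a genome-wide mean of 1, and divided by the same quantity from an
untreated control strain; bins whose control depth falls below 0.25 of the
mean are masked (unreliable denominator), and the denominator is floored at
`pseudo` = 0.05 against blow-ups. The ratio is the copy-state indicator:
~0 over homozygous deletions, ~0.5 heterozygous, ~2 over duplications, >= 3
over triplications. Candidate segments are maximal runs of >= `min_bins`
(2) bins within one band (`del_max` = 0.25, `dup_min` = 1.5,
`mult_min` = 2.5 — midpoints between integer copy states); no HMM or
circular binary segmentation is used because thresholding is the point of
the indicator. Segment means reported on calls are taken over bins fully
inside the event; partial edge bins dilute the signal and are used only
when no bin fits entirely.

**Integration.** Deletion evidence gains copy-number support when it
overlaps a deletion segment reciprocally at >= `reciprocal_overlap` (0.5);
because segments have bin resolution, the segment side of the test
tolerates one bin of slack per edge. Duplication junctions pair with
duplication/multiplication segments, and a duplication whose ratio mean
reaches `mult_min` is promoted to a multiplication even when its CN run
fragmented across the band boundary. Split-read-only calls are retained
and flagged; unmatched CN segments of >= 2 kb are emitted as imprecise
bin-resolution calls (excluded from size statistics — their breakpoints
are unknown).

**Variant frequency and zygosity.** Frequency is junction-supporting reads
over junction-supporting plus reference reads spanning the breakpoint with
>= `min_clip_len` aligned bases on each side. Calls at frequency >=
`hom_min` (0.8) are homozygous, in [0.25, 0.8) heterozygous, below 0.25
likely artifacts (`unknown`). For duplications/multiplications the
frequency criterion fails structurally: at a tandem junction,
reference-spanning reads exist even in homozygotes because the last copy
runs into downstream sequence, pinning the frequency near (c−1)/c. Their
zygosity therefore comes from the ratio mean (hom DUP ~2.0 vs het ~1.5,
threshold 1.75; MULT hom >= 2.5). For translocations the spanning count is
taken at the less-spanned of the two breakends — the insertion-site
junction is the informative one; an intact partner locus would drown the
signal.

**Background subtraction.** Calls of identical class whose breakpoints
match within tolerance across >= `min_strains` (2) independently derived
strains are ancestral genotype, not mutagen-induced: they move to a shared
background set and leave every strain's call list. Matching is
single-linkage over the pairwise within-tolerance graph, which makes the
operation symmetric in strain order and idempotent.

## Annotation

Variants are classified against gene models (GFF3; introns derived as gene
minus exons when not explicit) and regulatory regions (BED with a kind
column — a neutral dialect standing in for database-specific dumps, so no
external download is needed). A variant touching several feature kinds
receives one category by the precedence CDS > UTR > exon > intron >
pseudogene > intergenic; intergenic variants receive a regulatory
subcategory by the precedence enhancer > promoter > TSS > TF-binding site >
splice leader > other. The precedence order is this package's choice: a
variant disrupting any coding sequence is a coding mutation regardless of
what else it touches, and the ordering makes the assignment total and
deterministic. Per-strain summaries cover variant counts by class and
category, genes partially or completely deleted, chromosomes carrying
large variants, the deletion size distribution (median/IQR), and the R²
between per-window A/T fraction and variant count (windows default 100 kb;
a degenerate constant regressor is defined as R² = 0).

## Machine-learning candidate filter

Each candidate is an eight-feature vector: genome-wide absolute position
(cumulative contig offsets in declared order), log10 deletion and insertion
lengths (+1), copy-number ratio, control-minus-sample normalized depth
difference, variant frequency, total split reads, and strand bias
|fwd − rev| / (fwd + rev). Labels are 1 for PCR-confirmed candidates,
0 otherwise. Seven classical classifiers are wrapped behind one interface:
logistic regression (L2, C=1), decision tree (unlimited depth, min leaf 1),
k-nearest neighbours (k=5), random forest (100 trees), linear discriminant
analysis, Gaussian naive Bayes, and a linear SVM (C=1) — library-default
hyperparameters, exposed in the constructor. Features are z-scored with
training-set statistics only and missing values imputed with training-set
medians (no test-set leakage; the suite checks both). Training and test
sets are explicit disjoint inputs, mirroring the confirmed-set /
large-scale-set protocol, never an internal split.

## Mutation-number extrapolation

A forward-mutation reporter assay observes only its target sequence;
scaling the observed rate by genome size over target size extrapolates the
expected mutations per haploid genome: N = rate × G / T with
G = 100,272,607 bp, T = 21,477 bp for the *unc-22* twitching assay and
T = 89,840 bp for the 48-amplicon PCR assay. Rates are accepted as
percentages by default with an explicit flag for fractions, because the
×100 ambiguity is the only way to get this formula wrong. Deletion size
spectra are compared as <50 bp vs >= 50 bp counts with a two-sided Fisher
exact test (scipy's hypergeometric implementation, cross-checked against
full enumeration in the tests).

## Synthetic data generator

The simulator emulates the study's sequencing design at desk scale:
i.i.d. random genomes with a configurable AT fraction (default 0.66,
roughly the *C. elegans* average), engineered non-overlapping variants
applied to a haplotype pair (homozygous to both, heterozygous to one), and
uniform single-end 120 bp reads at 20x total depth with optional i.i.d.
substitution errors. Reads are emitted directly as emulated reference
alignments: a read inside one colinear block is a plain match, a read
crossing a junction anchors on its largest reference-mapped piece and
carries the remainder as soft clips — exactly what a clip-and-realign
caller sees after real alignment, with the advantage that the engineered
truth is exact by construction and no aligner binary is needed. Reads
entirely inside novel inserted sequence are unmappable and are not
emitted. All randomness flows from one seed.

The default engineered mix (50 variants) spans every class: 30 deletions
(10 heterozygous; sizes log-uniform 60–5000 bp, the spectrum this type of
mutagenesis produces), 4 duplications (2–4 kb) and 2 triplications
(2–3 kb) sized so the 500 bp copy-number track resolves them, 4 insertions
of 50–60 novel bases, 4 deletion+insertions (100–1000 bp deleted, 10–30
inserted), 4 inversions (300 bp–2 kb), and 2 translocated 500–1500 bp
segments copied from a different contig. Non-deletion classes are kept
homozygous by default, as in clonally propagated homozygous lines.
Inserted novel sequences are generated with terminal bases differing from
the adjoining reference bases, so engineered junctions carry no
microhomology and their breakpoint representation is unique — real
junctions with microhomology are detected too, but their breakpoints are
then only defined up to the homology length.

The labeled candidate generator for the classifier benchmark
(`make_ml_dataset`) is explicitly fictional: true candidates draw
frequency ~ Beta(8,2), cn_ratio ~ N(0.05, 0.05) truncated at 0,
split_total ~ Poisson(8)+3, strand_bias ~ Beta(2,2); false candidates
frequency ~ Beta(2,8), cn_ratio ~ N(0.9, 0.15), split_total ~ Poisson(2)+1,
strand_bias ~ 1−Beta(1,5); positions uniform, lengths log-normal, and
depth_diff = (1 − cn_ratio) + N(0, 0.1) to mirror its redundancy with the
ratio in real depth tracks. These distributions model the qualitative
separation of true homozygous deletions (low ratio, high frequency) from
alignment artifacts; they say nothing about absolute accuracies on real
sequencing data.

## What the synthetic tests do and do not show

Passing the round-trip tests shows that the detection logic is internally
correct: breakpoints exact on error-free reads, recall and zygosity high
at the study's depth, no calls from variant-free data. It does not show
performance on real data, where alignment artifacts, repeats,
homopolymer errors of semiconductor sequencing, coverage bias, and
microhomology-mediated breakpoint ambiguity all exist and are absent from
the generator by design (uniform coverage, i.i.d. errors, i.i.d. genomes).
The classifier benchmark likewise measures separability of the stated
generative model, not of real candidate sets.

## Problem sizes

Desk-scale defaults keep every check fast: the end-to-end benchmark uses a
1 Mb two-contig genome with 50 engineered variants at 20x (about 330k
simulated reads, a few seconds end to end); the copy-number band check
uses 100 replicates of a 60 kb genome with 5 kb homozygous and
heterozygous deletions; the classifier benchmark 500 training and 500 test
candidates. These sizes are the package's own reproducible study
conditions, chosen so the full suite runs in well under a minute per
component.

## Known limitations

- Ungapped realignment cannot place clips that span a second nearby
  junction or contain indel sequencing errors; such reads are silently
  unclassified (the support threshold absorbs this).
- Insertions are recoverable only while the novel run fits inside a clip
  with >= 16 realignable bases left over — with 120 bp reads this bounds
  detectable insertions at roughly 85 bp; larger insertions surface only
  as unpaired clip pile-ups.
- Imprecise CN-only calls have bin-resolution coordinates and no
  frequency, hence zygosity `unknown` unless the ratio decides it.
- A heterozygous multiplication (ratio ~2) is indistinguishable from a
  homozygous duplication by ratio alone and will be typed DUP.
- Background subtraction treats breakpoint coincidence within tolerance as
  identity; two distinct variants sharing breakpoints across strains are
  merged (vanishingly rare at genome scale).
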