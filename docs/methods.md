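# Methods

## Model

The primary object is the base-pair coverage curve: for a set of aligned
segments, the value at base *b* of a contig is the number of aligned
blocks containing *b*. Three alignment features shape the curve:

- **Soft clipping** (CIGAR `S`, and `H`): clipped bases never reached the
  reference and contribute nothing.
- **Spliced gaps** (`N`): the reference bases skipped by a spliced read
  contribute nothing to coverage; each gap is recorded as an exon-exon
  junction, keyed by the skipped interval.
- **Deletions** (`D`): treated as covered. A deletion is
  reference-consuming alignment, not splicing; keeping it covered keeps
  junction semantics (one junction per `N` gap) distinct from small
  indels.

Paired-end mates are independent segments: the per-sample read length is
understood as the sum of mate lengths, and no fragment-level
deduplication is performed. Secondary and supplementary alignments are
excluded by default (overridable); no mapping-quality filter is applied
by default. These are documented package choices — coverage-based
pipelines differ here and no single convention is universal.

All quantities derive from the curve:

- **AUC** (area under coverage): Σ over every base of every contig,
  annotation-blind. Equals mapped reads × read length exactly when no
  bases are clipped or skipped.
- **Coverage count** of a feature: Σ coverage over the feature's bases.
- **Disjoint exons**: each gene's (deduplicated) exon set is split into
  maximal windows lying in a constant subset of the exons. The gene count
  sums the disjoint exons, counting each exonic base once; exon counts
  are recomposed by summing each exon's member disjoint exons,
  double-counting shared bases across overlapping exons by construction.
  Both behaviours are exposed because downstream methods disagree on
  which they expect. Deduplication applies within a gene only: bases
  shared by two *genes* count in both genes.
- **Scaling**: `count / AUC × target` (target in reads, default 40
  million), or `count / (read length × mapped) × target`. The AUC form is
  implemented literally with a read-count target, matching the worked
  example (36/45 × 20 = 16); coverage *tracks* scale by `target_auc/auc`
  with `target_auc` defaulting to 40 million × 100 bases. Scaled counts
  are real-valued; rounding is optional, applied last, half away from
  zero (the convention is stated because "round to integer" alone is
  ambiguous at halves). The library default is no rounding; the CLI
  `scale` subcommand rounds by default, since its output typically feeds
  count-based DE tools.
- **Expressed regions**: maximal runs of bases with coverage strictly
  greater than the cutoff (strict inequality is the default and is
  switchable to ≥; the published region tables this mirrors show minimum
  region values strictly above the cutoff). `value`/`area` are computed
  from the unthresholded input track. Consecutive regions with gap ≤
  `max_cluster_gap` share a cluster; `cluster_length` is the genomic span
  from the cluster's first start to its last end. Detection emits
  width-1 regions; any minimum-width filter is a separate, explicit step
  (inclusive: "at least *w*" keeps width == *w*).
- **Region base classification**: exonic (inside the merged exonic union
  of all genes), else intronic (inside some gene's span), else
  intergenic. The three counts partition the region width.

## Coordinates and numerics

Internal coordinates are 1-based closed everywhere; BED/bedGraph I/O is
0-based half-open and SAM is 1-based, converted at the boundary. Coverage
is stored run-length encoded (values + run lengths); feature sums,
thresholding and AUC operate on runs without densifying, and the RLE
path is checked against dense per-base oracles in the tests. Raw count
matrices are integer by construction; scaled matrices are float64.
Feature order in every matrix is (contig, start, end, id) lexicographic,
and sorting ties elsewhere break by (start, end, input order), so
repeated runs are byte-identical (timestamps appear only in log lines).
Degenerate inputs are defined, not special-cased: empty segment lists
give all-zero coverage, empty interval lists disjoin to the empty list,
an empty junction set is a valid result. Zero AUC or a zero mapped×length
denominator makes scaling undefined and raises.

The low-expression filter keeps features whose row mean strictly exceeds
the threshold (default 0.5), matching the conventional pre-DE filter.
Gene-ID version suffixes are stripped at the first dot, keeping the
stable Ensembl part of Gencode-style IDs.

## The worked micro-example

The package embeds a 16-bp contig with one gene (two isoforms: exons
[1,5]+[13,15] and [1,8]+[13,15]) and 16 reads of length 3 producing 20
aligned blocks. The published form of this example fixes the block
(start, width) multiset but not the grouping into reads; the fixture
reconstructs a grouping consistent with every stated property: ten
full-length unspliced reads, four spliced reads (three across the
annotated introns [6,12] and [9,12], one across the unannotated gap
[9,9]), and two soft-clipped reads ([1,1] with two clipped bases, [3,4]
with one). This yields the coverage curve (3,3,5,4,4,2,2,3,1,3,3,1,4,4,
2,1), AUC 45 (48 read bases − 3 clipped), disjoint-exon counts
(19, 7, 10), gene count 36, and scaled gene count 16 at a 20-read target
— every worked number in the README is computed from this fixture at
run time.

## Simulator

`simulate_experiment` generates, from one integer seed, a compact genome
(by default one contig, 8 genes of 2–5 exons, exon widths 150–400 bp,
introns 100–1000 bp, intergenic gaps 500–3000 bp), 1–3 transcripts per
gene (extra transcripts take exon subsets, half of them with an extended
3′ exon end so that within-gene exons overlap and the disjoin is
exercised nontrivially), and per-sample reads: 100-bp single-end, 50–150
reads per gene, placed uniformly in transcript coordinates. A spliced
read is forced across a random exon-exon boundary of its transcript
(default fraction 0.2), an unspliced read sits inside a single exon;
optional soft clipping trims the leading bases of unspliced reads, and
optional intergenic reads fall in gaps outside every gene span. Defaults
are chosen as a small but representative bulk-RNA-seq-like setting that
a laptop executes in well under a second.

Ground truth is recorded constructively at generation time: per-gene
truth is each read's block overlap with the gene's exonic union (which
quantification must reproduce exactly, coverage being additive),
junction truth counts the generated spliced gaps, and per-sample AUC is
the total of aligned block bases. Per-sample random streams derive from
(seed, sample index), so adding samples never changes earlier ones, and
all emitted files are byte-identical across runs with the same seed.

The simulator emulates the geometry of spliced alignment, not the
sequencing process: there are no base errors, no GC or positional bias,
no fragment-length model, and no multi-mapping ambiguity. Passing the
exact-recovery tests therefore demonstrates that the counting arithmetic
is correct, not that the pipeline is robust to real-library noise.

## Problem sizes used in the checks

The bundled checks run the oracle-equivalence suites on 1,000 random
instances per operation (intervals on ≤500-bp contigs, coverage tracks
≤600 bp), and the conservation/recovery suites on simulated experiments
of 8–20 genes and 1–3 samples. These sizes already exercise every branch
of the interval and RLE arithmetic, which is size-independent; the
published large-cohort analyses (tens of millions of bases, dozens of
samples) differ only in scale, not in code path.

## Known limitations

- bigWig is not written; bedGraph (text) is the coverage interchange
  format, and tracks are read whole per contig rather than streamed.
- Gene counts double-count bases shared across distinct genes (only
  within-gene sharing is deduplicated).
- Junction annotation ignores strand; with unstranded data this is the
  only consistent choice, but on stranded annotation two opposite-strand
  introns with identical coordinates would be conflated.
- Statistical differentially-expressed-region calling (F-statistics,
  permutation) and downstream DE analysis are out of scope; the package
  stops at count matrices, scaled counts and region tables.
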