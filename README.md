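# covquant

Base-pair coverage quantification for RNA-seq.

Most RNA-seq pipelines summarize an experiment as *read* counts per gene.
`covquant` instead works at base-pair resolution: once reads have been
aligned (splice-aware, possibly soft-clipped), it computes the genome
coverage curve — at every base, the number of aligned read blocks
overlapping it — and derives everything else from that curve:

- **disjoint-exon / exon / gene coverage-count matrices.** A gene's exons
  can overlap (isoforms sharing sequence), so the gene's exons are first
  *disjoined* into windows of distinct exonic sequence. The coverage count
  of a feature is Σᵢ coverageᵢ over its bases; the gene count sums its
  disjoint exons, so each exonic base counts exactly once. Exon-level
  counts are recomposed by summing each exon's member disjoint exons
  (shared bases then deliberately count in every exon containing them).
- **exon-exon junction tables.** Spliced alignments (CIGAR `N`) skip a
  reference interval; junctions are keyed by that skipped interval and
  classified as annotated when it matches an intron implied by consecutive
  exons of some transcript.
- **library-size scaling.** Coverage counts scale to read counts at a
  target library size via the area under coverage,
  `scaled = count / AUC × target`, where AUC = Σ coverage over every base
  of the genome, annotation-blind. Without soft clipping AUC equals
  mapped reads × read length and the AUC formula coincides with
  `count / (read length × mapped) × target`; with clipping, AUC is the
  more precise denominator.
- **expressed regions.** Annotation-agnostic segmentation of a coverage
  track: maximal runs of bases with coverage strictly above a cutoff, each
  carrying its mean (`value`), sum (`area`) and a cluster id grouping
  regions separated by at most a maximum gap. Region × sample matrices
  and exonic/intronic/intergenic base classification follow.
- **a seeded simulator** that generates annotation and reads with known
  ground truth, so the whole chain can be verified for exact recovery.

Formats: SAM in (via pysam), GTF/GFF2 annotation, bedGraph coverage
tracks in/out, BED6/BED12, TSV matrices. All internal coordinates are
1-based closed; converters sit at the I/O boundaries.

## Worked example

A 16-bp contig, one gene with two isoforms (exons [1,5]+[13,15] and
[1,8]+[13,15]), and 16 aligned reads of length 3 — four spliced, two
soft-clipped — giving 20 aligned blocks:

```python
>>> import covquant as cq
>>> fx = cq.make_toy_fixture()
>>> cov = fx.coverage()["seq"]
>>> cov.to_dense().tolist()
[3, 3, 5, 4, 4, 2, 2, 3, 1, 3, 3, 1, 4, 4, 2, 1]
>>> cq.auc(cov)                       # 48 read bases - 3 clipped
45.0
>>> [(d.start, d.end) for d in fx.model.disjoint_exons["gene1"]]
[(1, 5), (6, 8), (13, 15)]
>>> [cq.feature_coverage_count(cov, d) for d in fx.model.disjoint_exons["gene1"]]
[19.0, 7.0, 10.0]
>>> cq.count_gene(cov, "gene1", fx.model)   # 19 + 7 + 10
36.0
>>> cq.scale_counts_auc(36, auc=45, target=20)
16.0
```

The scaled gene count (16) is below the target library size (20) because
4 read-equivalents of coverage fall outside exonic sequence — base 11,
for instance, has coverage 3 but lies in an intron, so it contributes to
the AUC but to no gene count. The same chain runs from the shell:

```sh
covquant count --sam toy.sam --annotation toy.gtf --level gene --out gene.tsv
covquant scale --counts gene.tsv --sample-info info.tsv --target 20 --out scaled.tsv
covquant coverage --sam toy.sam --out toy.bedgraph
covquant regions --bedgraph toy.bedgraph --genome genome.tsv --cutoff 2 \
    --max-cluster-gap 1 --out regions.bed
```

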