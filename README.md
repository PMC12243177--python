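# tiscaller

Detection of transgene (T-DNA) insertion sites in a host genome from
short-read sequencing alignments — RNA-seq, ChIP-seq input, or WGS.

*Agrobacterium*-mediated transformation integrates T-DNA more or less
randomly into plant (and fungal) genomes, and lines frequently carry
extra, unannotated insertions that confound downstream genetics.
`tiscaller` locates the insertion junctions directly from the alignments
a lab already has: it mines soft-clipped reads whose clipped segments
align to the supplied T-DNA/vector sequence, reconstructs the chimeric
junction each one spans, and scores every candidate insertion site
(TIS) with a five-category weighted evidence model before reporting
annotated, blacklist-filtered calls.

## Method

1. **Soft-clip mining.** Reads whose CIGAR carries an `S` operation are
   collected from each replicate's SAM/BAM. A read only qualifies if at
   least a fraction *r* of it is genome-aligned (*r* auto-selected by
   read length: 0.67 < 100 bp, 0.50 for 100–124 bp, 0.33 for ≥ 125 bp).
   PCR duplicates are collapsed per replicate; clips ≥ `l1` (18 bp)
   whose genomic portion is not poly(N)-dominated (< 0.8 N) become
   *cleaved reads*.
2. **T-DNA alignment.** Each cleaved read is aligned to the construct(s)
   on both strands, end-to-end first, then locally (exhaustive ungapped
   scan, ≤ `m` = 1 mismatch). Because integration proceeds through the
   left/right border repeats, hits within `d` = 200 bp of a border keep
   the mild length floor `l1` = 18 bp, while internal hits need
   `l2` = 30 bp.
3. **Junction reconstruction and scoring.** The genomic anchor of each
   surviving clip pins the junction to one base, with configuration
   R (REF–T-DNA) or L (T-DNA–REF) and construct orientation ±. Reads
   from all replicates are merged per junction; against the reference
   read (most balanced genome/T-DNA split) the supporters fall into
   groups: (1) different split ratio, (2) one substitution away,
   (3) identical but another replicate, (4) nearby junction,
   (5) discordant pairs (optional). The confidence score is the
   weighted supporter sum, default weights (700, 300, 300, 1, 1);
   a site passes at score ≥ 1000 — i.e. at least three independent
   chimeric reads, typically reference + G1 + one of G1–G3.
4. **Reporting.** Calls are blacklist-filtered, gene-annotated (GFF3),
   and written as TSV + BED6, alongside per-replicate cleaved FASTQs and
   RPKM bedGraph coverage tracks.

Evaluation against a truth set uses Sensitivity = TP/(TP+FN),
Precision = TP/(TP+FP), F1 = 2·S·P/(S+P).

## Worked example

The built-in simulator generates a complete synthetic study — genome,
expressed intervals, construct, planted insertions, reads, truth-derived
SAM — so the whole pipeline runs with no external data or aligner:

```sh
tiscaller simulate --seed 11 --insertions 2 -o demo/sim
tiscaller run --bam demo/sim/rep1.sam --bam demo/sim/rep2.sam \
              --tdna demo/sim/tdna.fa -o demo/out
tiscaller evaluate --calls demo/out/tis_calls.tsv \
                   --truth demo/sim/truth.tsv --tolerance 0
```

which prints

```
fixture with 2 insertion(s) in demo/sim
4 insertion site(s) called (4 candidates); report in demo/out
TP=4 FN=0 FP=0
sensitivity=1.000 precision=1.000 F1=1.000
```

The two planted insertions produce four junction calls — an R and an L
flank each — recovered at the exact base. `demo/out/tis_calls.tsv`:

```
chrom  junction  config  orientation  construct  t_junction  g1  g2  g3  g4  g5  score  replicates  genes  status
chr1   8855      R       +            tdna1      1           40  0   0   0   0   28000  rep1,rep2   .      pass
chr1   8856      L       +            tdna1      2000        44  0   0   0   0   30800  rep1,rep2   .      pass
chr1   57253     R       -            tdna1      2000        53  0   0   0   0   37100  rep1,rep2   .      pass
chr1   57254     L       -            tdna1      1           48  0   0   0   0   33600  rep1,rep2   .      pass
```

Read each row as: the junction base on the reference, whether reference
precedes (R) or follows (L) the T-DNA along the plus strand, the
construct's orientation and the construct coordinate at the breakpoint
(`t_junction` 1 / 2000 = the construct ends, as expected for untruncated
insertions), supporter counts per evidence group, and the weighted
score — here dominated by Group-1 reads, dozens of distinct
genome/T-DNA split ratios per flank.

The same stages are available as a library (`tiscaller.run_pipeline`,
`tiscaller.extract_soft_clips`, `tiscaller.align_clip_to_tdna`,
`tiscaller.score_candidate`, ...); see `docs/methods.md` for the model
details and parameter semantics.

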