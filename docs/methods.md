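# Methods

## Problem and model

A T-DNA insertion creates two genome/construct junctions. Any
sufficiently long read sequenced across a junction aligns to the
reference genome only partially; a local aligner (STAR, Bowtie2, BWA)
reports the non-reference remainder as a soft clip. `tiscaller` treats
those clipped segments as the primary signal: a clip that aligns to the
supplied construct sequence, at a plausible position within it, ties the
read's genomic anchor to a single junction base.

The evidence at one junction is deliberately redundant — fragments start
at many positions, replicates resample the same site, PCR and sequencing
errors perturb individual reads — and the scoring model quantifies that
redundancy rather than raw depth. One read (the *reference read*, the
member with the most balanced genome/construct split) defines the site;
every other read is assigned to exactly one group relative to it:

| group | relation to the reference read | default weight |
|-------|--------------------------------|----------------|
| G1 | same junction, different genome/T-DNA split ratio | 700 |
| G2 | same junction, sequence one substitution away | 300 |
| G3 | identical sequence, different biological replicate | 300 |
| G4 | junction within the clustering window but not identical | 1 |
| G5 | discordant pair: genomic mate near the junction, other mate on the construct | 1 |

Score = Σ gᵢ·wᵢ over supporters; the reference read contributes nothing.
The default threshold 1000 therefore requires, in practice, three
independent chimeric reads: reference + one G1 (700) + one more of
G1–G3 (≥ 300). G1 carries most weight because distinct split ratios are
distinct fragments — the strongest independence guarantee; G2/G3 are
weaker (an error away, or the same fragment length re-observed); G4/G5
are nearly tie-breakers, which is also why discordant-pair extraction is
optional and off by default. Supporters that fit no category — e.g. a
same-junction read ≥ 2 substitutions from the reference with the same
split ratio, or a residual same-replicate duplicate — are dropped, which
keeps classification a strict partition.

Calls with configuration R (REF–T-DNA) and L (T-DNA–REF) at the two
flanks of one physical insertion are reported as separate rows and can
be cross-referenced by adjacency; they are not merged into one score.

## Stage parameters

| parameter | default | meaning |
|-----------|---------|---------|
| `r` | auto | minimum genome-aligned fraction of a read: 0.67 (< 100 bp), 0.50 (100–124 bp), 0.33 (≥ 125 bp); max clip fraction is 1 − r |
| `l1` | 18 bp | minimum clip length; also minimum matched length for construct hits near a border (boundary inclusive) |
| `l2` | 30 bp | minimum matched length for construct hits far from the borders |
| `d` | 200 bp | border distance below which the mild `l1` floor applies ("near" is strictly < d) |
| `m` | 1 | mismatch budget for construct hits (more than one mismatch discarded) |
| `polyN_max` | 0.8 | records whose genome-aligned portion is ≥ 80 % N are excluded |
| `w` | 10 bp | junction clustering window (G4 capture radius) |
| weights | 700/300/300/1/1 | group weights, see above |
| threshold | 1000 | pass cutoff, compared with ≥ |
| `D` | 1000 bp | proximity for a discordant genomic mate |
| mapq floor | 0 (RNA-seq) / 30 (WGS) | minimum mapping quality of the genomic anchor |

Border positions default to the construct ends; full plasmids can
declare LB/RB coordinates (and intra-construct blacklist intervals, e.g.
endogenous gene fragments carried on the vector) in a metadata TSV.

Coordinates are 1-based closed internally (SAM convention); BED and
bedGraph outputs are 0-based half-open. The junction is the last aligned
reference base (R) or the first (L) — a single deterministic base, so
exact-coordinate evaluation is meaningful.

## The clipped-segment aligner

Clips are short (≤ ~130 bp) and constructs small (kb-scale), so the
aligner searches exhaustively instead of seeding: every diagonal
placement of the clip against the construct, on both strands, is scored
by Hamming distance. An end-to-end placement (whole clip, ≤ m
mismatches, no gaps) is preferred; otherwise the longest contiguous
sub-window with ≤ m mismatches that starts and ends on a match is taken
(a flanking mismatch can never extend an optimal local alignment). Ties
break by fewer mismatches, then smaller construct start, then the plus
strand; across multiple constructs the single global best is kept (ties
go to the lexicographically first construct id and are logged), so one
clip never seeds two sites. `N` matches nothing. Exhaustiveness makes
the search exact under this ordering, which the test suite verifies
against an independent brute-force scorer on a thousand random
instances.

Junction indels do occur in real integrations; an optional single-gap
mode allows one indel of ≤ 3 bp across the whole clip, costed as one
mismatch-equivalent (so with m = 1 no substitutions alongside). It is
off by default to keep the mismatch budget interpretable.

## Duplicate removal

The duplicate key is (replicate, chromosome, aligned span, clip side,
**full read sequence**). Using the full sequence rather than the clip
alone means two reads with the same span but different split ratios both
survive — necessary, since different split ratios are exactly the
Group-1 evidence. Identical reads in different replicates are both kept
(they are the Group-3 evidence). Deduplication is idempotent and
order-independent; the surviving record is the lexicographically
smallest read id of each class. For paired data, mates are treated as
independent single-end reads throughout clip extraction (pair identity
matters only to the discordant stage), and the key is per-mate.

## Synthetic data

The simulator emulates the transcriptional geometry the detector relies
on: a uniform-composition genome (default 100 kb) with disjoint
expressed intervals (default 10 × 2 kb), a random construct (default
2 kb, borders at its ends), and insertions planted mid-interval so
transcription runs across both junctions. Reads (50–151 bp, single or
paired, default 150 bp single) are sampled only from expressed intervals
of the *mutated* genome at a Poisson depth (default 50×), with i.i.d.
substitution errors (default 0). Alignments are derived from truth
rather than an external aligner: each read's projection onto the
original reference determines its position and CIGAR, and
junction-spanning reads receive their soft clip exactly at the
breakpoint. Reads entirely inside the construct are emitted as unmapped
records. Each replicate has its own RNG stream (`seed +
replicate_index`); all outputs are byte-deterministic given the seed.

What this does **not** emulate: splicing (and the multi-junction
artifacts mis-splicing creates at real insertions), indel sequencing
errors, quality-score variation, coverage bias along transcripts,
adapter contamination, fuzzy clip placement by a real aligner, or
chromosomal rearrangements between insertion sites. Passing the
round-trip tests therefore demonstrates the pipeline's bookkeeping —
coordinates, orientation handling, scoring, determinism — not robustness
to aligner idiosyncrasies; for that, the cleaved FASTQ output can be fed
to a real aligner via the adapter hook.

With the default study conditions (100-kb genome, two insertions — one
per orientation — 150-bp error-free single-end reads at 50×, two
replicates) every planted flank junction is recovered at the exact base
with no false positives. At 50-bp reads the r = 0.67 anchor requirement
leaves at most 16 bp of clip, below `l1` = 18, so junction reads cannot
qualify and sensitivity drops — the expected direction of the
read-length dependence.

## Numerical and design choices

- **Thread invariance.** Work is sharded per replicate alignment file;
  merged chimeric reads are canonically sorted before clustering, and
  clustering itself is deterministic (seeds chosen by split balance then
  read id), so TSV/BED outputs are byte-identical for any `--threads`.
- **Clustering.** Greedy: the most balanced unassigned read seeds a
  candidate and absorbs all unassigned reads within `w`; repeats until
  exhaustion. The window is applied per (chromosome, configuration).
- **Evaluation.** Greedy one-to-one nearest matching within a tolerance
  (default 100 bp; the simulator round-trip uses 0).
- **Blacklist semantics.** A call is removed when its junction base lies
  in a blacklist interval; a construct-internal hit is removed when its
  span *overlaps* an internal blacklist interval (the conservative
  reading for masking vector-carried endogenous fragments).
- **RPKM track.** value = reads_in_bin / ((bin/1000)·(total/10⁶)),
  binned at 100 bp by read start, zero bins omitted from the bedGraph.
- **BED scores** are capped at 1000 for format validity; true scores
  live in the TSV.
- **Degenerate inputs.** Zero parsable alignments produce an empty
  report and exit 0; an empty construct or unreadable
  blacklist/annotation is a configuration error; malformed CIGARs are
  skipped with a warning, never aborting the stream.
- **Problem sizes in tests.** The simulator fixtures use the default
  conditions above; aligner-equivalence checks use 1000 random
  instances with constructs ≤ 400 bp and clips ≤ 76 bp, where the
  brute-force oracle is fast.

## Known limitations

- Multi-junction artifacts from mis-splicing at a real insertion are
  reported as-is (several nearby calls), not merged.
- The per-species threshold choice (e.g. a stricter cutoff for
  high-background WGS collections) is exposed as configuration; no
  automatic calibration is attempted.
- The discordant stage requires mate information in the input; when
  mates were aligned independently it relies on shared read names.
- No splice-aware handling: a clip that is actually an exon of a
  distant gene can only be rejected by the construct alignment failing,
  not by a splice model.
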