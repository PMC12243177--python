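"""Soft-clip extraction from reference alignments.

Reads whose CIGAR carries an S operation are split into an aligned block
and one or two clipped segments.  Clips long enough to be informative are
re-packaged as "cleaved" reads and later aligned against the T-DNA
construct.  PCR duplicates are collapsed per replicate before cleaving.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator, Optional

import pysam

from .records import AlignmentRecord, CleavedRead, DiscordantCandidate, SoftClipRecord

log = logging.getLogger(__name__)

_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")
_MATCH_OPS = set("M=X")

#: minimum genome-aligned fraction of the read, keyed to read length;
#: the maximum clip fraction is 1 - r.
R_BY_READ_LENGTH = ((100, 0.67), (125, 0.50), (152, 0.33))


def r_for_read_length(read_len: int) -> float:
    """Default minimum genome-aligned fraction for a read length.

    0.67 below 100 bp, 0.50 for 100–124 bp, 0.33 for 125 bp and longer.
    Shorter reads must anchor a larger fraction to the genome because an
    18-bp clip is a bigger share of a 50-bp read.
    """
    for upper, r in R_BY_READ_LENGTH:
        if read_len < upper:
            return r
    return R_BY_READ_LENGTH[-1][1]


def records_from_sam(
    path: str, replicate_id: str, include_unmapped: bool = False
) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM/BAM file.

    Secondary/supplementary lines are always skipped; unmapped mates are
    included only on request (the discordant-pair stage needs them).
    """
    with pysam.AlignmentFile(path, check_sq=False) as af:
        for aln in af:
            if aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_unmapped and not include_unmapped:
                continue
            cigar = (
                [(length, "MIDNSHP=X"[op]) for op, length in aln.cigartuples]
                if aln.cigartuples
                else []
            )
            yield AlignmentRecord(
                read_id=aln.query_name,
                replicate_id=replicate_id,
                chrom=aln.reference_name or "*",
                pos=aln.reference_start + 1 if not aln.is_unmapped else 0,
                is_reverse=aln.is_reverse,
                cigar=cigar,
                seq=aln.query_sequence or "*",
                quals="".join(chr(q + 33) for q in aln.query_qualities)
                if aln.query_qualities is not None
                else "",
                mapq=aln.mapping_quality,
                is_paired=aln.is_paired,
                is_proper_pair=aln.is_proper_pair,
                mate_unmapped=aln.is_paired and aln.mate_is_unmapped,
                is_unmapped=aln.is_unmapped,
                mate_chrom=aln.next_reference_name if aln.is_paired else None,
                mate_pos=(aln.next_reference_start + 1)
                if aln.is_paired and not aln.mate_is_unmapped
                else None,
            )


def _cigar_is_valid(cigar: list[tuple[int, str]], seq: str) -> bool:
    if not cigar:
        return False
    if any(length <= 0 or op not in "MIDNSH=XP" for length, op in cigar):
        return False
    # S ops only at the ends (inside any flanking H)
    ops = [op for _, op in cigar]
    core = [op for op in ops if op != "H"]
    for i, op in enumerate(core):
        if op == "S" and i not in (0, len(core) - 1):
            return False
    query_len = sum(length for length, op in cigar if op in _QUERY_OPS)
    return query_len == len(seq)


def extract_soft_clips(
    alignments: Iterable[AlignmentRecord],
    r_min_match_fraction: Optional[float] = None,
    min_clip: int = 1,
    min_mapq: int = 0,
) -> list[SoftClipRecord]:
    """Collect one record per qualifying soft-clipped read end.

    A read clipped on both ends yields two records.  Records are dropped
    when the genome-matched query length is below ``r × read_len`` (r
    chosen by read length when not given explicitly), when the clip is
    shorter than ``min_clip``, or when mapq is below ``min_mapq``.
    Malformed CIGARs and missing sequences are skipped with a warning.
    """
    if r_min_match_fraction is not None and not (0 < r_min_match_fraction <= 1):
        raise ValueError("r_min_match_fraction must be in (0, 1]")

    out: list[SoftClipRecord] = []
    for rec in alignments:
        if rec.is_unmapped:
            continue
        if rec.seq == "*" or not rec.seq:
            log.warning("read %s has no sequence; skipped", rec.read_id)
            continue
        if not _cigar_is_valid(rec.cigar, rec.seq):
            log.warning("read %s has a malformed CIGAR %s; skipped", rec.read_id, rec.cigar)
            continue
        if rec.mapq < min_mapq:
            continue

        core = [(ln, op) for ln, op in rec.cigar if op != "H"]
        if not any(op == "S" for _, op in core):
            continue

        read_len = len(rec.seq)
        r = r_min_match_fraction if r_min_match_fraction is not None else r_for_read_length(read_len)
        genome_match_len = sum(ln for ln, op in core if op in _MATCH_OPS)
        if genome_match_len < r * read_len:
            continue

        left_clip = core[0][0] if core[0][1] == "S" else 0
        right_clip = core[-1][0] if len(core) > 1 and core[-1][1] == "S" else 0
        ref_span = sum(ln for ln, op in core if op in _REF_OPS)
        aligned_start = rec.pos
        aligned_end = rec.pos + ref_span - 1
        aligned_seq = rec.seq[left_clip : read_len - right_clip]
        quals = rec.quals if rec.quals else "I" * read_len

        for side, clip_len in (("left", left_clip), ("right", right_clip)):
            if clip_len < max(min_clip, 1):
                continue
            if side == "left":
                clip_seq, clip_quals = rec.seq[:clip_len], quals[:clip_len]
            else:
                clip_seq, clip_quals = rec.seq[read_len - clip_len :], quals[read_len - clip_len :]
            out.append(
                SoftClipRecord(
                    read_id=rec.read_id,
                    replicate_id=rec.replicate_id,
                    chrom=rec.chrom,
                    aligned_start=aligned_start,
                    aligned_end=aligned_end,
                    clip_side=side,
                    clip_seq=clip_seq,
                    clip_quals=clip_quals,
                    clip_len=clip_len,
                    read_len=read_len,
                    genome_match_len=genome_match_len,
                    aligned_seq=aligned_seq,
                    read_seq=rec.seq,
                    mapq=rec.mapq,
                )
            )
    return out


def deduplicate(records: Iterable[SoftClipRecord]) -> list[SoftClipRecord]:
    """Collapse PCR duplicates within each replicate.

    The duplicate key is (replicate, chrom, aligned span, clip side, full
    read sequence): using the full sequence keeps reads with distinct
    genome/T-DNA split ratios apart, which is Group-1 evidence downstream.
    Identical records in *different* replicates are both kept (Group-3
    evidence).  Order-independent and idempotent: the survivor is the
    lexicographically smallest read_id of each key class.
    """
    best: dict[tuple, SoftClipRecord] = {}
    for rec in records:
        key = (
            rec.replicate_id,
            rec.chrom,
            rec.aligned_start,
            rec.aligned_end,
            rec.clip_side,
            rec.read_seq,
        )
        cur = best.get(key)
        if cur is None or rec.read_id < cur.read_id:
            best[key] = rec
    return sorted(
        best.values(),
        key=lambda r: (r.replicate_id, r.chrom, r.aligned_start, r.aligned_end, r.clip_side, r.read_id),
    )


def n_fraction(seq: str) -> float:
    """Fraction of N (or n) bases; 0 for the empty string."""
    if not seq:
        return 0.0
    return (seq.count("N") + seq.count("n")) / len(seq)


def make_cleaved_reads(
    records: Iterable[SoftClipRecord],
    l1: int = 18,
    polyN_max: float = 0.8,
) -> list[CleavedRead]:
    """Turn soft-clip records into cleaved reads for T-DNA alignment.

    Keeps clips of length ≥ ``l1`` whose *genome-aligned* portion has an
    N-fraction strictly below ``polyN_max`` (records at or above the
    cutoff are excluded as poly(N) artifacts).  Clip qualities are
    carried over unchanged.
    """
    out = []
    for rec in records:
        if rec.clip_len < l1:
            continue
        if n_fraction(rec.aligned_seq) >= polyN_max:
            continue
        out.append(
            CleavedRead(
                read_id=f"{rec.read_id}/{'L' if rec.clip_side == 'left' else 'R'}",
                replicate_id=rec.replicate_id,
                clip_seq=rec.clip_seq,
                clip_quals=rec.clip_quals,
                provenance=rec,
            )
        )
    return out


def write_cleaved_fastq(cleaved: Iterable[CleavedRead], path: str) -> None:
    """Write cleaved reads as 4-line FASTQ (Phred+33)."""
    with open(path, "w") as fh:
        for cr in cleaved:
            fh.write(f"@{cr.read_id}\n{cr.clip_seq}\n+\n{cr.clip_quals}\n")


def extract_discordant_candidates(
    alignments: Iterable[AlignmentRecord],
    min_mapq: int = 30,
) -> list[DiscordantCandidate]:
    """Collect read pairs where exactly one mate aligned to the genome.

    The aligned mate must reach ``min_mapq``; the other mate must be
    unmapped (its sequence is retained for T-DNA alignment).  Single-end
    input yields an empty list.  This stage is optional and off by
    default in the pipeline: Group-5 evidence carries minimal weight.
    """
    by_pair: dict[tuple[str, str], list[AlignmentRecord]] = {}
    any_paired = False
    for rec in alignments:
        if rec.is_paired:
            any_paired = True
            by_pair.setdefault((rec.replicate_id, rec.read_id), []).append(rec)
    if not any_paired:
        log.info("no paired reads found; discordant extraction skipped")
        return []

    out: list[DiscordantCandidate] = []
    for (rep, pair_id), mates in sorted(by_pair.items()):
        mapped = [m for m in mates if not m.is_unmapped and m.mapq >= min_mapq]
        unmapped = [m for m in mates if m.is_unmapped]
        if len(mapped) != 1 or not unmapped:
            continue
        g, other = mapped[0], unmapped[0]
        if other.seq == "*" or not other.seq:
            continue
        ref_span = sum(ln for ln, op in g.cigar if op in _REF_OPS)
        out.append(
            DiscordantCandidate(
                pair_id=pair_id,
                replicate_id=rep,
                chrom=g.chrom,
                start=g.pos,
                end=g.pos + ref_span - 1,
                strand="-" if g.is_reverse else "+",
                other_mate_seq=other.seq,
                other_mate_quals=other.quals or "I" * len(other.seq),
            )
        )
    return out
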