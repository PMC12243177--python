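"""Synthetic fixtures: genome, construct, planted insertions, reads.

Generates a small uniform-composition reference genome with expressed
intervals, plants T-DNA insertions (optionally truncated and/or
reverse-oriented), and samples reads from the expressed regions of the
*mutated* genome.  Alignments are written against the *original*
reference with soft-clip CIGARs derived from the known breakpoints, so
every pipeline stage is testable without an external aligner.  Reads
overlapping an insertion junction carry the clip exactly at the
breakpoint; fuzziness enters only through the substitution error model.

All outputs are deterministic given the seed; each replicate draws from
its own RNG stream seeded as ``seed + replicate_index``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from .records import InsertionEvent, TdnaConstruct, TruthTable

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def simulate_reference_and_tdna(
    seed: int,
    genome_len: int = 100_000,
    n_expressed_intervals: int = 10,
    tdna_len: int = 2_000,
    interval_len: int = 2_000,
    chrom: str = "chr1",
) -> tuple[str, list[tuple[int, int]], TdnaConstruct]:
    """Random genome, disjoint expressed intervals, and a construct.

    Returns (genome sequence, expressed intervals as 1-based closed
    tuples, TdnaConstruct).  Intervals are placed one per equal-width
    slot with a random offset, so they never overlap.
    """
    if genome_len < 1_000:
        raise ValueError("genome_len must be at least 1 kb")
    if tdna_len < 500:
        raise ValueError("tdna_len must be at least 500 bp")
    slot = genome_len // n_expressed_intervals
    if interval_len > slot:
        raise ValueError(
            f"{n_expressed_intervals} intervals of {interval_len} bp do not fit "
            f"in a {genome_len} bp genome"
        )
    rng = np.random.default_rng(seed)
    genome = _random_dna(rng, genome_len)
    intervals = []
    for i in range(n_expressed_intervals):
        off = int(rng.integers(0, slot - interval_len + 1))
        start = i * slot + off + 1  # 1-based
        intervals.append((start, start + interval_len - 1))
    construct = TdnaConstruct(construct_id="tdna1", sequence=_random_dna(rng, tdna_len))
    return genome, intervals, construct


@dataclass
class _Segment:
    """One block of the mutated genome: ``source`` is 'genome' or 'tdna';
    ``src_start`` is the 1-based start in the source sequence."""

    mut_start: int  # 1-based
    length: int
    source: str
    src_start: int
    tdna_reversed: bool = False

    @property
    def mut_end(self) -> int:
        return self.mut_start + self.length - 1


def plant_insertions(
    genome: str,
    construct: TdnaConstruct,
    events: Sequence[InsertionEvent],
) -> tuple[str, TruthTable, list[_Segment]]:
    """Insert the (truncated, oriented) construct after each event position.

    Events must be sorted and non-overlapping.  Returns the mutated
    sequence, the truth table (R junction at ``position``, L at
    ``position + 1``, original coordinates), and the segment map used to
    project mutated coordinates back onto the reference/construct.
    """
    positions = [ev.position for ev in events]
    if positions != sorted(positions) or len(set(positions)) != len(positions):
        raise ValueError("insertion events must be sorted and non-overlapping")
    for ev in events:
        if not (1 <= ev.position < len(genome)):
            raise ValueError(f"insertion position {ev.position} outside genome")
        if ev.left_truncation + ev.right_truncation >= len(construct):
            raise ValueError("truncations remove the whole construct")

    parts: list[str] = []
    segments: list[_Segment] = []
    cursor = 1  # next genome base to copy (1-based)
    mut_pos = 1
    for ev in events:
        gseg_len = ev.position - cursor + 1
        parts.append(genome[cursor - 1 : ev.position])
        segments.append(_Segment(mut_pos, gseg_len, "genome", cursor))
        mut_pos += gseg_len
        ins = construct.sequence[
            ev.left_truncation : len(construct) - ev.right_truncation
        ]
        src_start = ev.left_truncation + 1
        if ev.orientation == "-":
            ins = _revcomp(ins)
        parts.append(ins)
        segments.append(
            _Segment(mut_pos, len(ins), "tdna", src_start, tdna_reversed=ev.orientation == "-")
        )
        mut_pos += len(ins)
        cursor = ev.position + 1
    parts.append(genome[cursor - 1 :])
    segments.append(_Segment(mut_pos, len(genome) - cursor + 1, "genome", cursor))
    mutated = "".join(parts)
    return mutated, TruthTable.from_events(list(events)), segments


def lift_intervals(
    intervals: Sequence[tuple[int, int]],
    events: Sequence[InsertionEvent],
    construct: TdnaConstruct,
) -> list[tuple[int, int]]:
    """Project original-coordinate intervals onto the mutated genome.

    An interval containing an insertion grows by the inserted length, so
    transcription runs across the junctions (the construct itself
    becomes part of the expressed window).
    """
    out = []
    for s, e in intervals:
        shift_s = 0
        grow = 0
        for ev in events:
            ins_len = len(construct) - ev.left_truncation - ev.right_truncation
            if ev.position < s:
                shift_s += ins_len
            elif s <= ev.position < e:
                grow += ins_len
        out.append((s + shift_s, e + shift_s + grow))
    return out


@dataclass
class SimRead:
    """A simulated read in mutated-genome coordinates, plus its projection
    onto the original reference (SAM fields)."""

    name: str
    seq: str  # reference-forward orientation, errors applied
    is_reverse: bool
    chrom: str
    pos: int  # 1-based on the ORIGINAL reference; 0 if unmapped
    cigar: str  # "*" if unmapped
    is_paired: bool = False
    mate_index: int = 0  # 1 or 2 when paired


def _project_read(
    mut_start: int, read_len: int, segments: Sequence[_Segment]
) -> tuple[int, str]:
    """SAM (pos, CIGAR) of a read sampled at ``mut_start`` on the mutated
    genome, projected onto the original reference.

    Reads fully inside the construct are unmapped (pos 0, CIGAR '*');
    reads crossing a junction get a soft clip covering the
    construct-derived portion.
    """
    mut_end = mut_start + read_len - 1
    touched = [
        seg for seg in segments if seg.mut_start <= mut_end and mut_start <= seg.mut_end
    ]
    genome_segs = [s for s in touched if s.source == "genome"]
    if not genome_segs:
        return 0, "*"
    if len(touched) > 2:
        # genome–tdna–genome (construct shorter than the read): treat the
        # aligner view as anchored on the longer genomic side
        touched = touched[:2] if touched[0].source == "genome" else touched[-2:]
    if len(touched) == 1:
        seg = touched[0]
        pos = seg.src_start + (mut_start - seg.mut_start)
        return pos, f"{read_len}M"
    first, second = touched[0], touched[1]
    first_len = first.mut_end - mut_start + 1
    second_len = read_len - first_len
    if first.source == "genome":
        pos = first.src_start + (mut_start - first.mut_start)
        return pos, f"{first_len}M{second_len}S"
    pos = second.src_start
    return pos, f"{first_len}S{second_len}M"


def simulate_reads(
    mutated: str,
    segments: Sequence[_Segment],
    expressed_intervals_mut: Sequence[tuple[int, int]],
    read_len: int = 150,
    layout: str = "single",
    depth: float = 50.0,
    error_rate: float = 0.0,
    n_replicates: int = 2,
    seed: int = 0,
    chrom: str = "chr1",
    fragment_len: Optional[int] = None,
) -> list[list[SimRead]]:
    """Sample reads from the expressed intervals of the mutated genome.

    ``depth`` is the mean per-base coverage inside expressed intervals;
    the read count per interval is Poisson.  Substitution errors are
    i.i.d. at ``error_rate``.  Returns one read list per replicate.
    """
    if not 50 <= read_len <= 151:
        raise ValueError("read_len must be within 50–151")
    if layout not in ("single", "paired"):
        raise ValueError("layout must be 'single' or 'paired'")
    frag = fragment_len or (2 * read_len + 50)

    replicates = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + rep)
        reads: list[SimRead] = []
        serial = 0
        for iv_start, iv_end in expressed_intervals_mut:
            iv_len = iv_end - iv_start + 1
            unit = read_len if layout == "single" else frag
            if iv_len < unit:
                continue
            n_units = rng.poisson(depth * iv_len / (read_len * (1 if layout == "single" else 2)))
            starts = rng.integers(iv_start, iv_end - unit + 2, size=n_units)
            for st in np.sort(starts):
                st = int(st)
                serial += 1
                if layout == "single":
                    rev = bool(rng.integers(0, 2))
                    name = f"rep{rep + 1}_read{serial}"
                    reads.append(
                        _make_read(name, st, read_len, rev, mutated, segments, rng,
                                   error_rate, chrom)
                    )
                else:
                    name = f"rep{rep + 1}_frag{serial}"
                    r1 = _make_read(name, st, read_len, False, mutated, segments, rng,
                                    error_rate, chrom)
                    r2 = _make_read(name, st + frag - read_len, read_len, True, mutated,
                                    segments, rng, error_rate, chrom)
                    r1.is_paired = r2.is_paired = True
                    r1.mate_index, r2.mate_index = 1, 2
                    reads.extend([r1, r2])
        replicates.append(reads)
    return replicates


def _make_read(
    name: str,
    mut_start: int,
    read_len: int,
    is_reverse: bool,
    mutated: str,
    segments: Sequence[_Segment],
    rng: np.random.Generator,
    error_rate: float,
    chrom: str,
) -> SimRead:
    seq = mutated[mut_start - 1 : mut_start - 1 + read_len]
    if error_rate > 0:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        hits = np.flatnonzero(rng.random(read_len) < error_rate)
        for i in hits:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = rng.choice(choices)
        seq = arr.tobytes().decode()
    pos, cigar = _project_read(mut_start, read_len, segments)
    return SimRead(name=name, seq=seq, is_reverse=is_reverse, chrom=chrom,
                   pos=pos, cigar=cigar)


def write_fasta(seq: str, path: str, name: str = "chr1") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


def write_bed(intervals: Sequence[tuple[int, int]], path: str, chrom: str = "chr1") -> None:
    """Write 1-based closed intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for s, e in intervals:
            fh.write(f"{chrom}\t{s - 1}\t{e}\n")


def write_truth_tsv(truth: TruthTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tjunction\tconfig\torientation\n")
        for j in truth.junctions:
            fh.write(f"{j.chrom}\t{j.junction}\t{j.config}\t{j.orientation}\n")


def read_truth_tsv(path: str) -> list[tuple[str, int, str, str]]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            chrom, junction, config, orientation = line.rstrip("\n").split("\t")
            out.append((chrom, int(junction), config, orientation))
    return out


def write_fastq(reads: Sequence[SimRead], path: str) -> None:
    """FASTQ in sequencing orientation (reverse-strand reads are
    reverse-complemented), constant Q40 qualities."""
    with open(path, "w") as fh:
        for r in reads:
            seq = _revcomp(r.seq) if r.is_reverse else r.seq
            name = r.name if not r.is_paired else f"{r.name}/{r.mate_index}"
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_sam(
    reads: Sequence[SimRead],
    path: str,
    chrom: str = "chr1",
    chrom_len: int = 0,
) -> None:
    """Truth-derived SAM against the original reference.

    Soft-clip CIGARs come straight from the planted breakpoints; reads
    entirely inside the construct are written as unmapped records so the
    discordant stage can see them.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": chrom, "LN": chrom_len or (max((r.pos for r in reads), default=1) + 1000)}],
    }
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            a.mapping_quality = 60
            if r.pos == 0:
                a.is_unmapped = True
                a.reference_id = -1
                a.reference_start = -1
            else:
                a.reference_id = 0
                a.reference_start = r.pos - 1
                a.cigarstring = r.cigar
                a.is_reverse = r.is_reverse
            if r.is_paired:
                a.is_paired = True
                a.is_read1 = r.mate_index == 1
                a.is_read2 = r.mate_index == 2
            out.write(a)


def make_fixture(
    out_dir: str,
    seed: int = 0,
    genome_len: int = 100_000,
    n_expressed_intervals: int = 10,
    tdna_len: int = 2_000,
    n_insertions: int = 2,
    read_len: int = 150,
    layout: str = "single",
    depth: float = 50.0,
    error_rate: float = 0.0,
    n_replicates: int = 2,
    orientations: Optional[Sequence[str]] = None,
    truncations: Optional[Sequence[tuple[int, int]]] = None,
) -> dict:
    """End-to-end fixture: genome + construct + insertions + reads on disk.

    Insertions are planted mid-interval (distinct intervals), so every
    junction lies inside an expressed window.  Returns a dict of paths
    plus the in-memory truth table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, intervals, construct = simulate_reference_and_tdna(
        seed, genome_len, n_expressed_intervals, tdna_len
    )
    if n_insertions > len(intervals):
        raise ValueError("more insertions than expressed intervals")
    orientations = orientations or ["+", "-"] * n_insertions
    truncations = truncations or [(0, 0)] * n_insertions
    events = []
    for i in range(n_insertions):
        s, e = intervals[i * (len(intervals) // max(n_insertions, 1))]
        events.append(
            InsertionEvent(
                chrom="chr1",
                position=(s + e) // 2,
                orientation=orientations[i],
                left_truncation=truncations[i][0],
                right_truncation=truncations[i][1],
            )
        )
    events.sort(key=lambda ev: ev.position)
    mutated, truth, segments = plant_insertions(genome, construct, events)
    intervals_mut = lift_intervals(intervals, events, construct)
    reps = simulate_reads(
        mutated, segments, intervals_mut, read_len=read_len, layout=layout,
        depth=depth, error_rate=error_rate, n_replicates=n_replicates, seed=seed,
    )

    genome_fa = out / "genome.fa"
    write_fasta(genome, str(genome_fa))
    tdna_fa = out / "tdna.fa"
    with open(tdna_fa, "w") as fh:
        fh.write(f">{construct.construct_id}\n{construct.sequence}\n")
    bed = out / "expressed.bed"
    write_bed(intervals, str(bed))
    truth_tsv = out / "truth.tsv"
    write_truth_tsv(truth, str(truth_tsv))
    sams, fastqs = [], []
    for i, reads in enumerate(reps, start=1):
        sam = out / f"rep{i}.sam"
        write_sam(reads, str(sam), chrom_len=len(genome))
        sams.append(str(sam))
        fq = out / f"rep{i}.fastq"
        write_fastq(reads, str(fq))
        fastqs.append(str(fq))
    return {
        "genome_fasta": str(genome_fa),
        "tdna_fasta": str(tdna_fa),
        "expressed_bed": str(bed),
        "truth_tsv": str(truth_tsv),
        "sam": sams,
        "fastq": fastqs,
        "truth": truth,
        "construct": construct,
        "events": events,
    }
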