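"""Domain records shared across the pipeline stages.

Coordinates are 1-based closed (SAM convention) everywhere in memory;
BED/bedGraph outputs are converted to 0-based half-open at write time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass
class AlignmentRecord:
    """One alignment line, decoupled from the pysam object so stages are
    testable without files.

    ``seq`` and ``quals`` are stored in reference orientation (as in SAM).
    ``cigar`` is an ordered list of ``(length, op)`` with op in MIDNSH=X.
    """

    read_id: str
    replicate_id: str
    chrom: str
    pos: int  # 1-based leftmost reference coordinate
    is_reverse: bool
    cigar: list[tuple[int, str]]
    seq: str
    quals: str
    mapq: int = 0
    is_paired: bool = False
    is_proper_pair: bool = False
    mate_unmapped: bool = False
    is_unmapped: bool = False
    mate_chrom: Optional[str] = None
    mate_pos: Optional[int] = None


@dataclass
class SoftClipRecord:
    """A single soft-clipped end of an aligned read.

    A read clipped on both ends yields two records.  ``aligned_start`` /
    ``aligned_end`` give the 1-based closed genomic span consumed on the
    reference by the aligned block.  ``aligned_seq`` is the query portion
    consumed by the genomic alignment (everything that is not a clip),
    used for the poly(N) screen; ``read_seq`` is the full read sequence,
    used as part of the duplicate key.
    """

    read_id: str
    replicate_id: str
    chrom: str
    aligned_start: int
    aligned_end: int
    clip_side: str  # "left" | "right"
    clip_seq: str
    clip_quals: str
    clip_len: int
    read_len: int
    genome_match_len: int  # query bases consumed by M/=/X
    aligned_seq: str
    read_seq: str
    mapq: int = 0


@dataclass
class CleavedRead:
    """The clipped portion of a soft-clipped read, re-packaged as a new
    sequencing record for alignment against the T-DNA construct."""

    read_id: str
    replicate_id: str
    clip_seq: str
    clip_quals: str
    provenance: SoftClipRecord


@dataclass
class DiscordantCandidate:
    """A read pair in which exactly one mate aligned confidently to the
    genome; the other mate's sequence is retained for T-DNA alignment."""

    pair_id: str
    replicate_id: str
    chrom: str
    start: int
    end: int
    strand: str  # strand of the genomic mate: "+" | "-"
    other_mate_seq: str
    other_mate_quals: str


@dataclass
class TdnaConstruct:
    """A T-DNA / vector sequence with border reference points.

    Integration proceeds through sequences near the left (LB) and right
    (RB) borders, so hits close to a border are treated leniently while
    internal hits face a stricter length threshold.  ``internal_blacklist``
    marks intra-construct intervals (1-based closed) such as endogenous
    gene fragments carried on the vector, whose hits are discarded.
    """

    construct_id: str
    sequence: str
    left_border_pos: int = 1
    right_border_pos: int = 0  # 0 -> defaults to len(sequence)
    internal_blacklist: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.right_border_pos == 0:
            self.right_border_pos = len(self.sequence)
        if not (1 <= self.left_border_pos < self.right_border_pos <= len(self.sequence)):
            raise ValueError(
                f"invalid border positions {self.left_border_pos}/{self.right_border_pos} "
                f"for construct {self.construct_id} of length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TdnaHit:
    """Best placement of a cleaved read on a construct."""

    read_id: str
    replicate_id: str
    construct_id: str
    t_start: int  # 1-based closed span on the construct
    t_end: int
    t_strand: str  # "+" | "-"
    mode: str  # "end2end" | "local"
    matched_len: int
    mismatches: int
    border_distance: int = -1  # filled by annotate_border_distance


@dataclass
class ChimericRead:
    """A reconstructed genome/T-DNA junction read.

    ``config`` encodes the order along the reference plus strand:
    R = REF–T-DNA (right clip), L = T-DNA–REF (left clip).
    ``orientation`` is the direction of the construct (as supplied)
    relative to the reference plus strand.
    """

    read_id: str
    replicate_id: str
    chrom: str
    junction: int
    config: str  # "R" | "L"
    orientation: str  # "+" | "-"
    construct_id: str
    t_junction: int
    genome_seg_len: int
    tdna_seg_len: int
    full_seq: str


@dataclass
class ScoringWeights:
    """Per-group weights of the five-category evidence model and the
    pass threshold for the weighted sum."""

    w1: int = 700
    w2: int = 300
    w3: int = 300
    w4: int = 1
    w5: int = 1
    threshold: int = 1000

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3, self.w4, self.w5) < 0:
            raise ValueError("weights must be non-negative")

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.w1, self.w2, self.w3, self.w4, self.w5)


@dataclass
class CandidateTIS:
    """A clustered candidate insertion junction with its evidence."""

    chrom: str
    junction: int
    config: str
    orientation: str
    construct_id: str
    t_junction: int
    reference_read: ChimericRead
    group_counts: tuple[int, int, int, int, int]  # g1..g5
    group_members: dict[int, list[ChimericRead]]
    replicates: frozenset[str]
    score: int = 0
    genes: list[str] = field(default_factory=list)
    status: str = "fail"  # "pass" | "fail"

    @property
    def n_chimeric_reads(self) -> int:
        """Reference + G1–G4 supporters (G5 pairs are not chimeric reads)."""
        return 1 + sum(self.group_counts[:4])


@dataclass
class EvaluationResult:
    """Confusion counts and derived metrics against a truth set."""

    TP: int
    FN: int
    FP: int

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else 0.0

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if (self.TP + self.FP) else 0.0

    @property
    def f1(self) -> float:
        s, p = self.sensitivity, self.precision
        return 2 * s * p / (s + p) if (s + p) else 0.0


@dataclass
class InsertionEvent:
    """A planted insertion: the construct goes between ``position`` and
    ``position + 1`` (1-based, original reference coordinates)."""

    chrom: str
    position: int
    orientation: str = "+"
    left_truncation: int = 0
    right_truncation: int = 0

    def __post_init__(self) -> None:
        if self.left_truncation < 0 or self.right_truncation < 0:
            raise ValueError("truncations must be non-negative")
        if self.orientation not in "+-":
            raise ValueError("orientation must be '+' or '-'")


@dataclass
class TruthJunction:
    """One expected flank junction of a planted insertion."""

    chrom: str
    junction: int
    config: str  # "R" | "L"
    orientation: str


@dataclass
class TruthTable:
    """Ground truth of planted insertions with the two expected flank
    junctions per event: R at ``position``, L at ``position + 1``."""

    events: list[InsertionEvent]
    junctions: list[TruthJunction]

    @classmethod
    def from_events(cls, events: list[InsertionEvent]) -> "TruthTable":
        junctions = []
        for ev in events:
            junctions.append(TruthJunction(ev.chrom, ev.position, "R", ev.orientation))
            junctions.append(TruthJunction(ev.chrom, ev.position + 1, "L", ev.orientation))
        return cls(events=list(events), junctions=junctions)
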