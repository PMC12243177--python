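"""Junction reconstruction, evidence classification, scoring and calling.

A retained cleaved read, together with the genomic alignment it came
from, pins a chimeric junction to a single base: the last aligned
reference base for a right clip (configuration R, REF–T-DNA along the
plus strand) or the first aligned base for a left clip (configuration L,
T-DNA–REF).  Junctions from all biological replicates are merged; at
each candidate site a reference read is chosen and the remaining
supporters fall into five evidence categories:

  G1  chimeric reads with a different genome/T-DNA split ratio
  G2  reads one base away from the reference sequence, same junction
  G3  reads identical to the reference but from another replicate
  G4  chimeric reads with a nearby but non-identical junction
  G5  discordant pairs (genomic mate near the junction, other mate on
      the construct) — optional

The candidate score is the weighted sum of the supporter counts
(defaults 700, 300, 300, 1, 1); the reference read itself contributes
nothing.  With the default threshold of 1000 a site needs at least three
independent chimeric reads — reference + G1 + one of G1–G3 — to pass.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .records import (
    CandidateTIS,
    ChimericRead,
    DiscordantCandidate,
    EvaluationResult,
    ScoringWeights,
    SoftClipRecord,
    TdnaConstruct,
    TdnaHit,
)
from .softclips import CleavedRead
from .tdna import align_clip_to_tdna, filter_hits

log = logging.getLogger(__name__)


def reconstruct_junction(record: SoftClipRecord, hit: TdnaHit) -> ChimericRead:
    """Restore the genomic context of a T-DNA-matched clip.

    The clip is stored in reference orientation, so a plus-strand hit
    means the construct runs co-directionally with the reference
    (orientation +).  The construct coordinate adjoining the breakpoint
    depends on which clip end touches the junction: for a right clip the
    clip *starts* at the junction, for a left clip it *ends* there.
    """
    if record.clip_side == "right":
        config = "R"
        junction = record.aligned_end
        t_junction = hit.t_start if hit.t_strand == "+" else hit.t_end
    else:
        config = "L"
        junction = record.aligned_start
        t_junction = hit.t_end if hit.t_strand == "+" else hit.t_start
    return ChimericRead(
        read_id=record.read_id,
        replicate_id=record.replicate_id,
        chrom=record.chrom,
        junction=junction,
        config=config,
        orientation=hit.t_strand,
        construct_id=hit.construct_id,
        t_junction=t_junction,
        genome_seg_len=record.genome_match_len,
        tdna_seg_len=hit.matched_len,
        full_seq=record.read_seq,
    )


def _hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))  # length mismatch: never distance 1
    return sum(x != y for x, y in zip(a, b))


def select_reference_and_classify(
    members: Sequence[ChimericRead], w: int = 10
) -> tuple[ChimericRead, tuple[int, int, int, int], dict[int, list[ChimericRead]]]:
    """Choose the reference read of a junction cluster and classify the rest.

    The reference is the member with the most balanced genome/T-DNA
    split — it maximizes min(genome_seg_len, tdna_seg_len) — with ties
    broken by lexicographic read_id.  Every other member is assigned to
    exactly one of G1–G4 by priority (G3, G2, G1, G4); residual exact
    duplicates within one replicate, and supporters matching no
    category, are dropped.
    """
    if not members:
        raise ValueError("empty member list")
    ref = min(members, key=lambda c: (-min(c.genome_seg_len, c.tdna_seg_len), c.read_id))
    groups: dict[int, list[ChimericRead]] = {1: [], 2: [], 3: [], 4: []}
    for c in members:
        if c is ref:
            continue
        if c.full_seq == ref.full_seq and c.replicate_id != ref.replicate_id:
            groups[3].append(c)
        elif c.junction == ref.junction and _hamming(c.full_seq, ref.full_seq) == 1:
            groups[2].append(c)
        elif c.junction == ref.junction and c.genome_seg_len != ref.genome_seg_len:
            groups[1].append(c)
        elif c.junction != ref.junction and abs(c.junction - ref.junction) <= w:
            groups[4].append(c)
        else:
            # residual duplicate in the same replicate, or an unclassifiable
            # same-junction read (>1 base away, same split ratio)
            log.debug("dropping unclassifiable supporter %s at %s:%d",
                      c.read_id, c.chrom, c.junction)
    counts = (len(groups[1]), len(groups[2]), len(groups[3]), len(groups[4]))
    return ref, counts, groups


def cluster_chimeric_reads(
    chimeras: Iterable[ChimericRead], w: int = 10
) -> list[CandidateTIS]:
    """Cluster merged chimeric reads into candidate insertion sites.

    Clustering is per (chrom, configuration): the strongest remaining
    read (most balanced split) seeds a candidate and pulls in every
    unassigned read whose junction lies within ``w`` bases; the process
    repeats until all reads are assigned.  Deterministic regardless of
    input order.
    """
    by_key: dict[tuple[str, str], list[ChimericRead]] = {}
    for c in chimeras:
        by_key.setdefault((c.chrom, c.config), []).append(c)

    candidates: list[CandidateTIS] = []
    for key in sorted(by_key):
        pool = sorted(
            by_key[key],
            key=lambda c: (-min(c.genome_seg_len, c.tdna_seg_len), c.read_id),
        )
        unassigned = list(pool)
        while unassigned:
            seed = unassigned[0]
            members = [c for c in unassigned if abs(c.junction - seed.junction) <= w]
            unassigned = [c for c in unassigned if abs(c.junction - seed.junction) > w]
            ref, counts, groups = select_reference_and_classify(members, w=w)
            replicates = frozenset(c.replicate_id for c in members)
            candidates.append(
                CandidateTIS(
                    chrom=ref.chrom,
                    junction=ref.junction,
                    config=ref.config,
                    orientation=ref.orientation,
                    construct_id=ref.construct_id,
                    t_junction=ref.t_junction,
                    reference_read=ref,
                    group_counts=(*counts, 0),
                    group_members={**{k: v for k, v in groups.items()}, 5: []},
                    replicates=replicates,
                )
            )
    candidates.sort(key=lambda c: (c.chrom, c.junction, c.config))
    return candidates


def attach_discordant_support(
    candidate: CandidateTIS,
    discordant: Sequence[DiscordantCandidate],
    constructs: Sequence[TdnaConstruct],
    D: int = 1000,
    l1: int = 18,
    l2: int = 30,
    d: int = 200,
    m: int = 1,
) -> CandidateTIS:
    """Count Group-5 discordant pairs supporting a candidate junction.

    A pair counts when its genomic mate lies within ``D`` bases of the
    junction on the same chromosome, points toward it (a plus-strand
    mate upstream, a minus-strand mate downstream), and its other mate
    passes the standard T-DNA hit filter.
    """
    from .tdna import annotate_border_distance

    construct_map = {c.construct_id: c for c in constructs}
    g5: list[ChimericRead] = []
    n5 = 0
    for dc in discordant:
        if dc.chrom != candidate.chrom:
            continue
        if dc.strand == "+":
            facing = dc.start <= candidate.junction and candidate.junction - dc.end <= D
        else:
            facing = dc.end >= candidate.junction and dc.start - candidate.junction <= D
        if not facing:
            continue
        if min(abs(dc.start - candidate.junction), abs(dc.end - candidate.junction)) > D:
            continue
        mate = CleavedRead(
            read_id=dc.pair_id,
            replicate_id=dc.replicate_id,
            clip_seq=dc.other_mate_seq,
            clip_quals=dc.other_mate_quals,
            provenance=None,  # type: ignore[arg-type]
        )
        best: Optional[TdnaHit] = None
        for construct in constructs:
            hit = align_clip_to_tdna(mate, construct, l1=l1, m=m)
            if hit is not None and (best is None or hit.matched_len > best.matched_len):
                best = hit
        if best is None:
            continue
        annotate_border_distance([best], construct_map)
        if filter_hits([best], d=d, l1=l1, l2=l2, m=m, construct_map=construct_map):
            n5 += 1
    counts = candidate.group_counts
    candidate.group_counts = (*counts[:4], n5)
    candidate.group_members[5] = g5
    return candidate


def score_candidate(
    group_counts: Sequence[int], weights: ScoringWeights = ScoringWeights()
) -> int:
    """Weighted sum of the five supporter-group counts.

    The reference read is not a supporter and contributes nothing.
    Integer arithmetic with the default weights (700, 300, 300, 1, 1).
    """
    if len(group_counts) != 5:
        raise ValueError("expected five group counts")
    if any(g < 0 for g in group_counts):
        raise ValueError("group counts must be non-negative")
    return sum(int(g) * int(wt) for g, wt in zip(group_counts, weights.as_tuple()))


def _bed_tree(bed_path: str) -> dict[str, IntervalTree]:
    """Load BED (0-based half-open) into per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def _gff_features(gff_path: str, feature_types: tuple[str, ...] = ("gene",)):
    """Per-chromosome interval trees of named GFF3 features (1-based closed)."""
    import gffutils

    db = gffutils.create_db(
        gff_path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    trees: dict[str, IntervalTree] = {}
    for ft in feature_types:
        for feat in db.features_of_type(ft):
            name = (
                feat.attributes.get("Name", [None])[0]
                or feat.attributes.get("ID", [feat.id])[0]
            )
            # store as 0-based half-open for the tree
            trees.setdefault(feat.seqid, IntervalTree()).addi(
                feat.start - 1, feat.end, name
            )
    return trees


def call_tis(
    candidates: Sequence[CandidateTIS],
    weights: ScoringWeights = ScoringWeights(),
    threshold: Optional[int] = None,
    blacklist: Optional[str] = None,
    annotation: Optional[str] = None,
) -> list[CandidateTIS]:
    """Score candidates, drop blacklisted junctions, annotate and call.

    A candidate passes when its score reaches the threshold (>=, so the
    minimal three-read configuration at exactly 1000 passes).  Junctions
    inside a blacklist interval are removed before reporting.  Passing
    calls carry every overlapping gene feature; output sorted by
    (chrom, junction).
    """
    thr = weights.threshold if threshold is None else threshold
    try:
        bl_trees = _bed_tree(blacklist) if blacklist else None
        gff_trees = _gff_features(annotation) if annotation else None
    except OSError as exc:
        raise RuntimeError(f"cannot read blacklist/annotation: {exc}") from exc

    out = []
    for cand in candidates:
        if bl_trees is not None:
            tree = bl_trees.get(cand.chrom)
            if tree is not None and tree.overlaps_point(cand.junction - 1):
                continue
        cand.score = score_candidate(cand.group_counts, weights)
        cand.status = "pass" if cand.score >= thr else "fail"
        if cand.status == "fail":
            log.debug("sub-threshold candidate %s:%d %s score=%d < %d",
                      cand.chrom, cand.junction, cand.config, cand.score, thr)
        if gff_trees is not None:
            tree = gff_trees.get(cand.chrom)
            if tree is not None:
                cand.genes = sorted(iv.data for iv in tree[cand.junction - 1])
        out.append(cand)
    out.sort(key=lambda c: (c.chrom, c.junction, c.config))
    return out


def evaluate_calls(
    calls: Sequence[tuple[str, int]],
    truth: Sequence[tuple[str, int]],
    match_tolerance: int = 100,
) -> EvaluationResult:
    """Confusion counts of called junctions against an annotated truth set.

    A call matches a truth entry on the same chromosome within
    ``match_tolerance`` bases; matching is one-to-one, greedy by
    distance.  TP = annotated and identified; FN = annotated, missed;
    FP = identified but not annotated.
    """
    pairs = []
    for ci, (c_chrom, c_pos) in enumerate(calls):
        for ti, (t_chrom, t_pos) in enumerate(truth):
            if c_chrom == t_chrom and abs(c_pos - t_pos) <= match_tolerance:
                pairs.append((abs(c_pos - t_pos), ci, ti))
    pairs.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        tp += 1
    return EvaluationResult(TP=tp, FN=len(truth) - tp, FP=len(calls) - tp)
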