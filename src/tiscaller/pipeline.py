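"""End-to-end pipeline: alignments in, insertion-site calls out.

Stages: soft-clip extraction → duplicate removal → cleaved-read
generation → T-DNA alignment and filtering → junction reconstruction →
replicate merge, classification, scoring → threshold / blacklist /
annotation.  Work is sharded per replicate; the merge step sorts
canonically, so the outputs are byte-identical for any thread count.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pysam

from .calling import (
    attach_discordant_support,
    call_tis,
    cluster_chimeric_reads,
    evaluate_calls,
    reconstruct_junction,
)
from .records import CandidateTIS, ChimericRead, ScoringWeights, TdnaConstruct
from .softclips import (
    deduplicate,
    extract_discordant_candidates,
    extract_soft_clips,
    make_cleaved_reads,
    records_from_sam,
    write_cleaved_fastq,
)
from .tdna import align_to_constructs, annotate_border_distance, filter_hits, load_constructs

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of one run; defaults mirror the tool's printed defaults."""

    alignments: list[str] = field(default_factory=list)  # one SAM/BAM per replicate
    tdna_fasta: str = ""
    tdna_metadata: Optional[str] = None
    l1: int = 18
    l2: int = 30
    d: int = 200
    m: int = 1
    r: Optional[float] = None  # None = auto by read length
    w: int = 10
    weights: ScoringWeights = field(default_factory=ScoringWeights)
    threshold: Optional[int] = None  # None = weights.threshold
    polyN_max: float = 0.8
    discordant: bool = False
    D: int = 1000
    blacklist: Optional[str] = None
    gff: Optional[str] = None
    mode: str = "rnaseq"  # "rnaseq" | "wgs"
    min_mapq: Optional[int] = None  # None = 0 (rnaseq) / 30 (wgs)
    discordant_min_mapq: int = 30
    threads: int = 1
    allow_single_gap: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("rnaseq", "wgs"):
            raise ValueError("mode must be 'rnaseq' or 'wgs'")
        thr = self.weights.threshold if self.threshold is None else self.threshold
        if thr <= 0:
            raise ValueError("threshold must be positive")

    @property
    def effective_min_mapq(self) -> int:
        if self.min_mapq is not None:
            return self.min_mapq
        return 30 if self.mode == "wgs" else 0


def _process_replicate(
    path: str,
    replicate_id: str,
    constructs: Sequence[TdnaConstruct],
    config: PipelineConfig,
    out_dir: Optional[Path],
) -> tuple[list[ChimericRead], list]:
    """readcore + tdnamap + junction reconstruction for one replicate."""
    records = list(
        records_from_sam(path, replicate_id, include_unmapped=config.discordant)
    )
    clips = extract_soft_clips(
        (r for r in records if not r.is_unmapped),
        r_min_match_fraction=config.r,
        min_clip=1,
        min_mapq=config.effective_min_mapq,
    )
    clips = deduplicate(clips)
    cleaved = make_cleaved_reads(clips, l1=config.l1, polyN_max=config.polyN_max)
    if out_dir is not None:
        write_cleaved_fastq(cleaved, str(out_dir / f"{replicate_id}.cleaved.fastq"))

    construct_map = {c.construct_id: c for c in constructs}
    chimeras: list[ChimericRead] = []
    for cr in cleaved:
        hit = align_to_constructs(
            cr, constructs, l1=config.l1, m=config.m,
            allow_single_gap=config.allow_single_gap,
        )
        if hit is None:
            continue
        annotate_border_distance([hit], construct_map)
        if not filter_hits([hit], d=config.d, l1=config.l1, l2=config.l2,
                           m=config.m, construct_map=construct_map):
            continue
        chimeras.append(reconstruct_junction(cr.provenance, hit))

    discordant = (
        extract_discordant_candidates(records, min_mapq=config.discordant_min_mapq)
        if config.discordant
        else []
    )
    return chimeras, discordant


def run_pipeline(config: PipelineConfig, out_dir: Optional[str] = None) -> list[CandidateTIS]:
    """Execute the full pipeline; optionally write the report bundle.

    Returns all scored candidates (status pass/fail); the report files
    are a TSV of candidates, a BED6 of passing calls, per-replicate
    cleaved FASTQs, and an RPKM bedGraph per replicate.
    """
    if not config.tdna_fasta:
        raise ValueError("a T-DNA FASTA is required")
    if not config.alignments:
        raise ValueError("at least one replicate alignment is required")
    constructs = load_constructs(config.tdna_fasta, config.tdna_metadata)

    out_path = Path(out_dir) if out_dir else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    shards = [
        (path, f"rep{i + 1}") for i, path in enumerate(config.alignments)
    ]
    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            results = list(
                pool.map(
                    lambda s: _process_replicate(s[0], s[1], constructs, config, out_path),
                    shards,
                )
            )
    else:
        results = [
            _process_replicate(p, rid, constructs, config, out_path) for p, rid in shards
        ]

    chimeras = sorted(
        (c for res in results for c in res[0]),
        key=lambda c: (c.chrom, c.junction, c.config, c.replicate_id, c.read_id),
    )
    discordant = sorted(
        (d for res in results for d in res[1]),
        key=lambda d: (d.replicate_id, d.pair_id),
    )
    if not chimeras:
        log.warning("no chimeric junction reads found; empty report")

    candidates = cluster_chimeric_reads(chimeras, w=config.w)
    if config.discordant and discordant:
        for cand in candidates:
            attach_discordant_support(
                cand, discordant, constructs, D=config.D,
                l1=config.l1, l2=config.l2, d=config.d, m=config.m,
            )
    calls = call_tis(
        candidates,
        weights=config.weights,
        threshold=config.threshold,
        blacklist=config.blacklist,
        annotation=config.gff,
    )

    if out_path is not None:
        write_report(calls, out_path)
        for path, rid in shards:
            track = coverage_track_from_sam(path)
            write_bedgraph(track, str(out_path / f"{rid}.rpkm.bedgraph"))
    return calls


TSV_COLUMNS = [
    "chrom", "junction", "config", "orientation", "construct", "t_junction",
    "g1", "g2", "g3", "g4", "g5", "score", "replicates", "genes", "status",
]


def write_report(calls: Sequence[CandidateTIS], out_dir: Path) -> None:
    """TSV of every candidate plus BED6 of the passing calls.

    BED scores are capped at 1000 for format validity; the true score is
    in the TSV.
    """
    tsv = out_dir / "tis_calls.tsv"
    with open(tsv, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        c.chrom, c.junction, c.config, c.orientation, c.construct_id,
                        c.t_junction, *c.group_counts, c.score,
                        ",".join(sorted(c.replicates)),
                        ",".join(c.genes) if c.genes else ".",
                        c.status,
                    ]
                )
                + "\n"
            )
    bed = out_dir / "tis_calls.bed"
    with open(bed, "w") as fh:
        for c in calls:
            if c.status != "pass":
                continue
            name = f"{c.construct_id}:{c.config}:{c.orientation}"
            strand = c.orientation
            fh.write(
                f"{c.chrom}\t{c.junction - 1}\t{c.junction}\t{name}"
                f"\t{min(c.score, 1000)}\t{strand}\n"
            )


def coverage_track_from_sam(
    path: str, bin_width: int = 100
) -> dict[str, "CoverageTrack"]:
    """Per-chromosome RPKM coverage from a SAM/BAM file."""
    counts: dict[str, dict[int, int]] = {}
    lengths: dict[str, int] = {}
    total = 0
    with pysam.AlignmentFile(path, check_sq=False) as af:
        for sq in af.header.get("SQ", []):
            lengths[sq["SN"]] = sq["LN"]
        for aln in af:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            total += 1
            b = aln.reference_start // bin_width
            counts.setdefault(aln.reference_name, {}).setdefault(b, 0)
            counts[aln.reference_name][b] += 1
    tracks = {}
    for chrom, length in lengths.items():
        tracks[chrom] = coverage_track(
            counts.get(chrom, {}), length, bin_width, total
        )
    return tracks


@dataclass
class CoverageTrack:
    chrom_len: int
    bin_width: int
    values: list[float]
    chrom: str = "chr1"


def coverage_track(
    bin_counts: dict[int, int], chrom_len: int, bin_width: int, total_mapped: int
) -> CoverageTrack:
    """RPKM per bin: reads / ((bin_width/1000) × (total_mapped/1e6)).

    An empty library yields an empty (all-zero) track with a warning.
    """
    n_bins = (chrom_len + bin_width - 1) // bin_width
    if total_mapped <= 0:
        log.warning("total_mapped is zero; coverage track is empty")
        return CoverageTrack(chrom_len, bin_width, [0.0] * n_bins)
    denom = (bin_width / 1000.0) * (total_mapped / 1e6)
    values = [bin_counts.get(i, 0) / denom for i in range(n_bins)]
    return CoverageTrack(chrom_len, bin_width, values)


def write_bedgraph(tracks: dict[str, CoverageTrack], path: str) -> None:
    """bedGraph (0-based half-open), zero bins skipped."""
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            t = tracks[chrom]
            for i, v in enumerate(t.values):
                if v == 0:
                    continue
                start = i * t.bin_width
                end = min(start + t.bin_width, t.chrom_len)
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.4f}\n")


def evaluate_from_files(
    calls_tsv: str, truth_tsv: str, match_tolerance: int = 100
):
    """Evaluate a TSV report against a truth TSV (chrom, junction cols)."""
    calls = []
    with open(calls_tsv) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ic, ij = header.index("chrom"), header.index("junction")
        istatus = header.index("status") if "status" in header else None
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if istatus is not None and parts[istatus] != "pass":
                continue
            calls.append((parts[ic], int(parts[ij])))
    truth = []
    with open(truth_tsv) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ic, ij = header.index("chrom"), header.index("junction")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            truth.append((parts[ic], int(parts[ij])))
    return evaluate_calls(calls, truth, match_tolerance=match_tolerance)
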