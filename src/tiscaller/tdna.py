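"""Alignment of cleaved reads to T-DNA constructs and hit filtering.

The aligner is an exhaustive ungapped scan: every placement of the clip
against the construct, on both strands, is scored by Hamming distance
along the diagonal.  End-to-end placements (the whole clip, at most ``m``
mismatches) are preferred; otherwise the longest contiguous sub-window
with at most ``m`` mismatches is taken (local mode).  Ties are broken by
fewer mismatches, then smaller construct start, then the plus strand.
Being exhaustive, the search is exact under that ordering — there is no
seed length or heuristic to miss a hit.

An optional single-gap mode additionally allows one indel of up to 3 bp
(costed as one mismatch-equivalent) spanning the whole clip, to absorb
the small junction indels occasionally created during integration.  It
is off by default.
"""

from __future__ import annotations

import csv
import logging
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .records import CleavedRead, TdnaConstruct, TdnaHit

log = logging.getLogger(__name__)

_SENTINEL = 255


def load_constructs(
    fasta_path: str, metadata_tsv: Optional[str] = None
) -> list[TdnaConstruct]:
    """Load T-DNA constructs from FASTA, with optional border metadata.

    The metadata TSV has columns: construct_id, lb_pos, rb_pos, blacklist
    (semicolon-separated ``start-end`` 1-based closed intervals; may be
    empty).  Constructs without metadata use their ends as borders.
    """
    meta: dict[str, tuple[int, int, list[tuple[int, int]]]] = {}
    if metadata_tsv:
        with open(metadata_tsv) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                cid, lb, rb = row[0], int(row[1]), int(row[2])
                bl = []
                if len(row) > 3 and row[3]:
                    for part in row[3].split(";"):
                        s, e = part.split("-")
                        bl.append((int(s), int(e)))
                meta[cid] = (lb, rb, bl)

    constructs = []
    for rec in SeqIO.parse(fasta_path, "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"construct {rec.id} has an empty sequence")
        lb, rb, bl = meta.get(rec.id, (1, len(seq), []))
        constructs.append(
            TdnaConstruct(rec.id, seq, left_border_pos=lb, right_border_pos=rb, internal_blacklist=bl)
        )
    if not constructs:
        raise ValueError(f"no sequences found in {fasta_path}")
    return constructs


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _diagonal_mismatches(t_arr: np.ndarray, c_arr: np.ndarray) -> np.ndarray:
    """Mismatch matrix over all diagonals.

    Row ``o`` (0..L+n-2) aligns clip index ``i`` to construct index
    ``o + i - (n - 1)``; out-of-construct cells are marked sentinel
    mismatches.  N never matches anything.
    """
    n = len(c_arr)
    pad = np.full(len(t_arr) + 2 * (n - 1), _SENTINEL, dtype=np.uint8)
    pad[n - 1 : n - 1 + len(t_arr)] = t_arr
    windows = np.lib.stride_tricks.sliding_window_view(pad, n)
    mism = windows != c_arr
    # N in either sequence is always a mismatch
    mism |= windows == ord("N")
    mism |= c_arr == ord("N")
    return mism


def _best_on_strand(
    t_arr: np.ndarray, clip: str, l1: int, m: int
) -> Optional[tuple[int, int, int, int, str]]:
    """Best ungapped placement of ``clip`` on one strand of the construct.

    Returns (matched_len, mismatches, t_start, t_end, mode) with t
    coordinates 1-based closed, or None.
    """
    n = len(clip)
    L = len(t_arr)
    if n == 0 or L == 0:
        return None
    c_arr = _encode(clip)
    mism = _diagonal_mismatches(t_arr, c_arr)
    offsets = np.arange(mism.shape[0]) - (n - 1)  # construct index of clip[0]

    # --- end-to-end: whole clip inside the construct, <= m mismatches
    full = (offsets >= 0) & (offsets <= L - n)
    best_e2e = None
    if full.any():
        totals = mism[full].sum(axis=1)
        idx = np.flatnonzero(totals <= m)
        if idx.size:
            cand_off = offsets[full][idx]
            cand_mm = totals[idx]
            order = np.lexsort((cand_off, cand_mm))  # fewest mm, then smallest start
            o, mm = int(cand_off[order[0]]), int(cand_mm[order[0]])
            best_e2e = (n, mm, o + 1, o + n, "end2end")
    if best_e2e is not None:
        return best_e2e

    # --- local: longest sub-window with <= m mismatches, length >= l1
    # prefilter: a qualifying window needs >= l1 - m matching positions
    row_matches = (~mism).sum(axis=1)
    best = None  # (matched_len, mm, t_start, t_end)
    for row in np.flatnonzero(row_matches >= max(l1 - m, 1)):
        off = int(offsets[row])
        lo = max(0, -off)  # first clip index on the construct
        hi = min(n, L - off)  # one past the last
        if hi - lo < l1:
            continue
        v = mism[row, lo:hi]
        # sliding window over mismatch positions: longest run with <= m
        mpos = np.flatnonzero(v)
        span = _longest_window(hi - lo, mpos, m)
        if span is None:
            continue
        start, end, mm = span  # clip-relative within [lo, hi)
        length = end - start
        if length < l1:
            continue
        t_start = off + lo + start + 1
        cand = (length, mm, t_start)
        if best is None or (cand[0], -cand[1], -cand[2]) > (best[0], -best[1], -best[2]):
            best = cand
    if best is None:
        return None
    length, mm, t_start = best
    return (length, mm, t_start, t_start + length - 1, "local")


def _longest_window(n: int, mismatch_pos: np.ndarray, m: int) -> Optional[tuple[int, int, int]]:
    """Longest window [start, end) with <= m mismatches that starts and
    ends on a match (a flanking mismatch never extends a local alignment).

    Enumerates every contiguous run of 0..m included mismatches with its
    maximal match-bounded extent.  Prefers the leftmost among equally
    long windows.  Returns (start, end, mismatches) or None.
    """
    if n <= 0:
        return None
    mp = [int(p) for p in mismatch_pos]
    k = len(mp)
    pos = set(mp)
    bounds = [-1] + mp + [n]  # sentinels: virtual mismatches just outside

    best: Optional[tuple[int, int, int]] = None  # (start, end, mm)
    # subset of included mismatches = mp[i..j-1]  (size t = j - i, 0 <= t <= m)
    for t in range(0, m + 1):
        for i in range(0, k - t + 1):
            s = bounds[i] + 1  # just after the previous excluded mismatch
            e = bounds[i + t + 1]  # up to the next excluded mismatch
            # boundary collision: window would start/end on an included
            # mismatch; that case is covered by a smaller subset
            if s in pos or (e - 1) in pos:
                continue
            if e <= s:
                continue
            cand = (s, e, t)
            if best is None or (e - s, -s) > (best[1] - best[0], -best[0]):
                best = cand
    return best


def _best_single_gap(
    t_arr: np.ndarray, clip: str, m: int, max_gap: int
) -> Optional[tuple[int, int, int, int, str]]:
    """End-to-end placement with exactly one indel of 1..max_gap bases.

    The gap costs one mismatch-equivalent, so with the default budget
    m=1 no substitutions are allowed alongside it.
    """
    n = len(clip)
    L = len(t_arr)
    if n < 2 or L == 0:
        return None
    c_arr = _encode(clip)
    mism = _diagonal_mismatches(t_arr, c_arr).astype(np.int32)
    n_rows = mism.shape[0]
    pref = np.cumsum(mism, axis=1)  # pref[o, k] = mismatches in clip[:k+1] at row o
    zeros = np.zeros((n_rows, 1), dtype=np.int32)
    P = np.hstack([zeros, pref])  # P[o, k] = mismatches in clip[:k]
    offsets = np.arange(n_rows) - (n - 1)

    best = None  # (q_aligned, cost, t_start, t_end)
    for g in range(1, max_gap + 1):
        for kind in ("del_in_clip", "ins_in_clip"):
            # prefix clip[:k] at row o; suffix clip[k:] (del) or
            # clip[k+g:] (ins) at row o2 = o ± g
            shift = g if kind == "del_in_clip" else -g
            for o in range(n_rows):
                o2 = o + shift
                if not (0 <= o2 < n_rows):
                    continue
                off1 = int(offsets[o])
                t_end = int(offsets[o2]) + n
                if off1 < 0 or t_end > L:
                    continue
                if kind == "del_in_clip":
                    ks = np.arange(1, n)
                    cost = P[o, ks] + (P[o2, n] - P[o2, ks]) + 1
                    q_aligned = n
                else:
                    ks = np.arange(1, n - g)
                    if ks.size == 0:
                        continue
                    cost = P[o, ks] + (P[o2, n] - P[o2, ks + g]) + 1
                    q_aligned = n - g
                ok = np.flatnonzero(cost <= m)  # the gap itself costs 1
                if ok.size == 0:
                    continue
                c = int(cost[ok].min())
                cand = (q_aligned, c, off1 + 1, t_end)
                if best is None or (cand[0], -cand[1], -cand[2]) > (
                    best[0],
                    -best[1],
                    -best[2],
                ):
                    best = cand
    if best is None:
        return None
    q_aligned, cost, t_start, t_end = best
    return (q_aligned, cost, t_start, t_end, "local")


def align_clip_to_tdna(
    cleaved: CleavedRead,
    construct: TdnaConstruct,
    l1: int = 18,
    m: int = 1,
    allow_single_gap: bool = False,
    max_gap: int = 3,
) -> Optional[TdnaHit]:
    """Best placement of a cleaved read on one construct, or None.

    Both strands are searched; end-to-end placements are preferred over
    local ones; best = maximal matched length, then fewer mismatches,
    then smaller construct start, then the plus strand.  Returns None
    when no placement reaches ``l1`` matched bases within ``m``
    mismatches.
    """
    if not construct.sequence:
        raise ValueError(f"construct {construct.construct_id} has an empty sequence")
    t_arr = _encode(construct.sequence)
    results = []  # (is_local, -matched_len, mismatches, t_start, strand_rank, payload)
    for strand, clip in (("+", cleaved.clip_seq), ("-", _revcomp(cleaved.clip_seq))):
        found = [_best_on_strand(t_arr, clip, l1=l1, m=m)]
        if allow_single_gap:
            found.append(_best_single_gap(t_arr, clip, m=m, max_gap=max_gap))
        for hit in found:
            if hit is None:
                continue
            matched_len, mm, t_start, t_end, mode = hit
            if matched_len < l1 or mm > m:
                continue
            results.append(
                (mode == "local", -matched_len, mm, t_start, 0 if strand == "+" else 1,
                 (matched_len, mm, t_start, t_end, mode, strand))
            )
    if not results:
        return None
    results.sort()
    matched_len, mm, t_start, t_end, mode, strand = results[0][-1]
    return TdnaHit(
        read_id=cleaved.read_id,
        replicate_id=cleaved.replicate_id,
        construct_id=construct.construct_id,
        t_start=t_start,
        t_end=t_end,
        t_strand=strand,
        mode=mode,
        matched_len=matched_len,
        mismatches=mm,
    )


def align_to_constructs(
    cleaved: CleavedRead,
    constructs: Sequence[TdnaConstruct],
    l1: int = 18,
    m: int = 1,
    allow_single_gap: bool = False,
) -> Optional[TdnaHit]:
    """Align one cleaved read to every construct, keep the global best.

    A clip aligning equally well to two constructs keeps the
    lexicographically first construct (the tie is logged), so one clip
    never seeds two insertion sites.
    """
    best: Optional[TdnaHit] = None
    tied_with: Optional[str] = None
    for construct in sorted(constructs, key=lambda c: c.construct_id):
        hit = align_clip_to_tdna(cleaved, construct, l1=l1, m=m, allow_single_gap=allow_single_gap)
        if hit is None:
            continue
        if best is None:
            best = hit
            continue
        key_new = (hit.mode == "local", -hit.matched_len, hit.mismatches)
        key_old = (best.mode == "local", -best.matched_len, best.mismatches)
        if key_new < key_old:
            best, tied_with = hit, None
        elif key_new == key_old:
            tied_with = hit.construct_id
    if best is not None and tied_with is not None:
        log.debug(
            "read %s aligns equally well to constructs %s and %s; keeping %s",
            cleaved.read_id, best.construct_id, tied_with, best.construct_id,
        )
    return best


def border_distance(span: tuple[int, int], construct: TdnaConstruct) -> int:
    """Distance in bp from a construct span to the nearer border.

    Zero when the span covers the border position.  Raises on spans
    outside the construct.
    """
    t_start, t_end = span
    if not (1 <= t_start <= t_end <= len(construct)):
        raise ValueError(f"span {span} outside construct of length {len(construct)}")
    dists = []
    for b in (construct.left_border_pos, construct.right_border_pos):
        dists.append(max(t_start - b, b - t_end, 0))
    return min(dists)


def annotate_border_distance(hits: Iterable[TdnaHit], construct_map: dict[str, TdnaConstruct]) -> None:
    for hit in hits:
        hit.border_distance = border_distance((hit.t_start, hit.t_end), construct_map[hit.construct_id])


def filter_hits(
    hits: Sequence[TdnaHit],
    d: int = 200,
    l1: int = 18,
    l2: int = 30,
    m: int = 1,
    construct_map: Optional[dict[str, TdnaConstruct]] = None,
) -> list[TdnaHit]:
    """Border-distance–dependent hit filter.

    Hits within ``d`` bp of a border face the mild length floor ``l1``;
    hits further inside the construct face the stricter ``l2`` (spurious
    internal matches are a major false-positive source, while genuine
    junction reads concentrate near the borders).  More than ``m``
    mismatches is always discarded, as is any hit overlapping the
    construct's internal blacklist.  Pure predicate: stable order,
    idempotent.
    """
    out = []
    for hit in hits:
        if hit.border_distance < 0:
            raise ValueError(f"hit {hit.read_id} lacks a border distance")
        if hit.mismatches > m:
            continue
        floor = l1 if hit.border_distance < d else l2
        if hit.matched_len < floor:
            continue
        if construct_map is not None:
            bl = construct_map[hit.construct_id].internal_blacklist
            if any(hit.t_start <= e and s <= hit.t_end for s, e in bl):
                continue
        out.append(hit)
    return out
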