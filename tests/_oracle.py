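"""Definition-level brute-force oracle for the clipped-segment aligner.

Enumerates every clip sub-window (local windows must start and end on a
match) against every diagonal placement on both strands, scoring by
Hamming distance, and applies the tie-break: end-to-end preferred, then
maximal matched length, fewer mismatches, smaller construct start, plus
strand.  Written from the definition — windows × diagonals — so it is
structurally independent of the package aligner, which scans diagonals
and enumerates mismatch runs.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _mismatch_matrix(clip: str, construct: str) -> np.ndarray:
    c = np.frombuffer(clip.encode(), dtype=np.uint8)
    t = np.frombuffer(construct.encode(), dtype=np.uint8)
    mm = c[:, None] != t[None, :]
    mm |= c[:, None] == ord("N")
    mm |= t[None, :] == ord("N")
    return mm


def oracle_align(
    construct: str, clip: str, l1: int = 18, m: int = 1
) -> Optional[tuple[int, int, int, int, str, str]]:
    """Best placement as (matched_len, mismatches, t_start, t_end, mode,
    strand), 1-based closed construct coordinates, or None."""
    candidates = []  # (is_local, -len, mm, t_start, strand_rank, payload)
    L = len(construct)
    for rank, (strand, c) in enumerate((("+", clip), ("-", _revcomp(clip)))):
        n = len(c)
        if n == 0 or L == 0:
            continue
        mm_mat = _mismatch_matrix(c, construct)
        # diagonal prefix sums: Q[i, j] = mismatches of clip[..i] vs
        # construct[..j] along the diagonal ending at (i, j)
        Q = np.zeros((n + 1, L + 1), dtype=np.int32)
        for i in range(n):
            Q[i + 1, 1:] = Q[i, :-1] + mm_mat[i]

        # end-to-end: whole clip at every offset
        if n <= L:
            for o in range(L - n + 1):
                total = int(Q[n, o + n])
                if total <= m:
                    candidates.append(
                        (0, -n, total, o + 1, rank, (n, total, o + 1, o + n, "end2end", strand))
                    )
        # local: every window [s, e) of the clip, start and end on a match
        for s in range(n):
            for e in range(s + l1, n + 1):
                length = e - s
                ks = np.arange(-s, L - e + 1)
                if ks.size == 0:
                    continue
                mm_vec = Q[e, ks + e] - Q[s, ks + s]
                start_ok = ~mm_mat[s, ks + s]
                end_ok = ~mm_mat[e - 1, ks + e - 1]
                good = np.flatnonzero((mm_vec <= m) & start_ok & end_ok)
                for gi in good:
                    k = int(ks[gi])
                    mmv = int(mm_vec[gi])
                    t_start = k + s + 1
                    candidates.append(
                        (1, -length, mmv, t_start, rank,
                         (length, mmv, t_start, t_start + length - 1, "local", strand))
                    )
    if not candidates:
        return None
    candidates.sort(key=lambda x: x[:5])
    best = candidates[0]
    if best[0] == 1 and -best[1] < l1:
        return None
    return best[5]
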