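"""Minimal per-site visualization: coverage around a called junction.

Plot generation is optional and excluded from the pipeline's determinism
guarantees; the data behind it (bedGraph + TSV) are the canonical
outputs.
"""

from __future__ import annotations

from .pipeline import CoverageTrack
from .records import CandidateTIS


def plot_tis_coverage(
    call: CandidateTIS,
    track: CoverageTrack,
    path: str,
    flank: int = 5_000,
) -> None:
    """Coverage bars around one insertion-site call, junction marked.

    The marker direction encodes the construct orientation.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bw = track.bin_width
    lo = max(0, (call.junction - flank) // bw)
    hi = min(len(track.values), (call.junction + flank) // bw + 1)
    xs = [i * bw for i in range(lo, hi)]
    ys = track.values[lo:hi]

    fig, ax = plt.subplots(figsize=(8, 2.5))
    ax.bar(xs, ys, width=bw, align="edge", color="#777777", linewidth=0)
    ax.axvline(call.junction, color="crimson", lw=1)
    marker = ">" if call.orientation == "+" else "<"
    ax.plot([call.junction], [max(ys) * 1.05 if ys else 1], marker=marker,
            color="crimson", markersize=8, clip_on=False)
    ax.set_xlabel(f"{call.chrom} position (bp)")
    ax.set_ylabel("RPKM")
    ax.set_title(
        f"{call.chrom}:{call.junction} {call.config}:{call.orientation} "
        f"score={call.score}", fontsize=9,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
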