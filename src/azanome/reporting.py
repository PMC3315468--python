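"""Figure-style reports: single-molecule lollipop diagrams as SVG and text.

The text rendering is a loss-free table (one row per clone, one symbol per
annotated site) that round-trips back to the call table; the SVG rendering
draws the conventional diagram: open/filled circles for unmethylated/
methylated CpG sites, teal-filled circles for enzyme-accessible GpC sites,
pink shading over protected runs longer than one nucleosome core, a TSS
arrow and the promoter window.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import FancyArrow, Rectangle

from .footprint import NDR_MIN_SPAN_BP, NDRWindow, segment_clone
from .nome_core import CloneCallSet, SiteAnnotation

_HCG_SYMBOL = {"methylated": "M", "unmethylated": "U", "missing": "."}
_GCH_SYMBOL = {"accessible": "A", "inaccessible": "I", "missing": "."}
_HCG_CALL = {v: k for k, v in _HCG_SYMBOL.items()}
_GCH_CALL = {v: k for k, v in _GCH_SYMBOL.items()}


def lollipop_text(
    callsets: Sequence[CloneCallSet], annotation: SiteAnnotation, region_id: str
) -> str:
    """Plain-text lollipop table: clone_id, strand, HCG string, GCH string."""
    if not callsets:
        raise ValueError("empty call table")
    lines = [
        f"# region={region_id}",
        f"# hcg_sites={','.join(map(str, annotation.hcg_sites))}",
        f"# gch_sites={','.join(map(str, annotation.gch_sites))}",
        "clone_id\tstrand\thcg\tgch",
    ]
    for cs in callsets:
        hcg = "".join(_HCG_SYMBOL[c] for c in cs.hcg_calls)
        gch = "".join(_GCH_SYMBOL[c] for c in cs.gch_calls)
        lines.append(f"{cs.clone_id}\t{cs.strand}\t{hcg}\t{gch}")
    return "\n".join(lines) + "\n"


def parse_lollipop_text(text: str) -> list[CloneCallSet]:
    """Invert :func:`lollipop_text` (QC fields are not representable and come
    back as passed with rate NaN)."""
    callsets = []
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("clone_id"):
            continue
        clone_id, strand, hcg, gch = line.split("\t")
        callsets.append(
            CloneCallSet(
                clone_id,
                strand,  # type: ignore[arg-type]
                tuple(_HCG_CALL[s] for s in hcg),
                tuple(_GCH_CALL[s] for s in gch),
                float("nan"),
                True,
            )
        )
    return callsets


def render_lollipop(
    callsets: Sequence[CloneCallSet],
    annotation: SiteAnnotation,
    region_id: str,
    tss: int,
    window: NDRWindow | None = None,
    out_svg=None,
) -> plt.Figure:
    """Draw the lollipop diagram; optionally write a timestamp-free SVG."""
    if not callsets:
        raise ValueError("empty call table")
    fig, ax = plt.subplots(
        figsize=(10, 0.28 * len(callsets) + 1.2), constrained_layout=True
    )
    for row, cs in enumerate(callsets):
        y = len(callsets) - 1 - row
        for seg in segment_clone(cs, annotation):
            if seg.state == "protected" and seg.span >= NDR_MIN_SPAN_BP:
                ax.add_patch(
                    Rectangle(
                        (seg.start, y - 0.4), seg.span, 0.8,
                        facecolor="#f4b6c2", edgecolor="none", zorder=1,
                    )
                )
        for p, c in zip(annotation.hcg_sites, cs.hcg_calls):
            if c == "missing":
                continue
            filled = c == "methylated"
            ax.plot(
                p, y, "o", markersize=5, zorder=3,
                markerfacecolor="black" if filled else "white",
                markeredgecolor="black",
            )
        for p, c in zip(annotation.gch_sites, cs.gch_calls):
            if c == "missing":
                continue
            accessible = c == "accessible"
            ax.plot(
                p, y, "s", markersize=4, zorder=3,
                markerfacecolor="teal" if accessible else "white",
                markeredgecolor="teal",
            )
    if window is not None:
        ax.add_patch(
            Rectangle(
                (window.start, -0.9), window.width, 0.35,
                facecolor="green", edgecolor="none",
            )
        )
    ax.add_patch(
        FancyArrow(
            tss, len(callsets) + 0.1, 40, 0, width=0.05,
            head_width=0.3, head_length=12, color="black",
        )
    )
    ax.set_xlim(-5, max(annotation.gch_sites + annotation.hcg_sites) + 10)
    ax.set_ylim(-1.2, len(callsets) + 0.8)
    ax.set_yticks([])
    ax.set_xlabel(f"{region_id} position (bp)")
    if out_svg is not None:
        fig.savefig(out_svg, format="svg", metadata={"Date": None})
    return fig


__all__ = ["lollipop_text", "parse_lollipop_text", "render_lollipop"]
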