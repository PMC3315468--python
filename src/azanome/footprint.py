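"""Footprint segmentation and nucleosome-depleted-region statistics.

A clone's GCH accessibility calls are collapsed into maximal runs of
consecutive same-state sites.  Each run becomes a half-open bp segment: the
outermost observed sites bound the analysed span (no extrapolation past
them), interior boundaries between opposite-state neighbours are placed at
their midpoint, and a segment's span is the width of its interval.  For a run
that touches a clone boundary this reduces to the site-based rule
``last − first + 2`` (both GpC dinucleotides included).

A clone carries a nucleosome-depleted region (NDR) when an accessible
segment longer than 146 bp — i.e. at least one nucleosome core — overlaps
the promoter window.  Population fractions come with exact (Clopper–Pearson)
binomial confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

from scipy.stats import binomtest

from .nome_core import CloneCallSet, SiteAnnotation

log = logging.getLogger(__name__)

#: Strict lower bound on NDR span, per one nucleosome core footprint.
NDR_MIN_SPAN_BP = 147


@dataclass(frozen=True)
class FootprintSegment:
    state: Literal["accessible", "protected"]
    start: int
    end: int
    n_sites: int
    first_site: int
    last_site: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def span(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class NDRWindow:
    """Half-open bp interval around a TSS (or −1 nucleosome) used for NDR calls."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FractionStat:
    """k-of-n clone fraction with an exact binomial 95% CI."""

    k: int
    n: int
    fraction: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_counts(cls, k: int, n: int, confidence: float = 0.95) -> "FractionStat":
        if not 0 <= k <= n or n == 0:
            raise ValueError(f"invalid counts k={k}, n={n}")
        ci = binomtest(k, n).proportion_ci(confidence_level=confidence, method="exact")
        return cls(k, n, k / n, ci.low, ci.high)


def segment_clone(
    callset: CloneCallSet, annotation: SiteAnnotation
) -> list[FootprintSegment]:
    """Collapse one clone's GCH calls into alternating accessible/protected
    segments.

    Missing calls are uninformative: they neither break a run nor contribute
    sites.  Two or more consecutive missing sites trigger a low-density
    warning but no split.  Returns an empty list (with a warning) when every
    call is missing.
    """
    sites = annotation.gch_sites
    if len(callset.gch_calls) != len(sites):
        raise ValueError("gch_calls not aligned to annotation.gch_sites")
    informative = [
        (p, c) for p, c in zip(sites, callset.gch_calls) if c != "missing"
    ]
    if not informative:
        log.warning("clone %s: all GCH calls missing", callset.clone_id)
        return []
    run_missing = 0
    for c in callset.gch_calls:
        if c == "missing":
            run_missing += 1
            if run_missing == 2:
                log.warning(
                    "clone %s: >=2 consecutive missing GCH calls (low density)",
                    callset.clone_id,
                )
        else:
            run_missing = 0

    state = {"accessible": "accessible", "inaccessible": "protected"}
    runs: list[tuple[str, list[int]]] = []
    for p, c in informative:
        s = state[c]
        if runs and runs[-1][0] == s:
            runs[-1][1].append(p)
        else:
            runs.append((s, [p]))

    # Segment boundaries: outermost sites bound the span; interior boundaries
    # at the midpoint between adjacent opposite-state sites.
    bounds = [informative[0][0]]
    for (_, left), (_, right) in zip(runs, runs[1:]):
        bounds.append((left[-1] + right[0]) // 2 + 1)
    bounds.append(informative[-1][0] + 2)

    return [
        FootprintSegment(
            state=s,
            start=bounds[i],
            end=bounds[i + 1],
            n_sites=len(ps),
            first_site=ps[0],
            last_site=ps[-1],
        )
        for i, (s, ps) in enumerate(runs)
    ]


def call_ndr(
    segments: Sequence[FootprintSegment],
    window: NDRWindow,
    min_span_bp: int = NDR_MIN_SPAN_BP,
) -> bool:
    """True iff an accessible segment of span >= ``min_span_bp`` (i.e. strictly
    longer than one nucleosome core at the default) overlaps the window."""
    return any(
        seg.state == "accessible"
        and seg.span >= min_span_bp
        and seg.overlaps(window.start, window.end)
        for seg in segments
    )


def ndr_fraction(
    callsets: Sequence[CloneCallSet],
    annotation: SiteAnnotation,
    window: NDRWindow,
    min_span_bp: int = NDR_MIN_SPAN_BP,
) -> FractionStat:
    """Fraction of clones carrying an NDR over the window."""
    if not callsets:
        raise ValueError("no clones supplied")
    k = sum(
        call_ndr(segment_clone(cs, annotation), window, min_span_bp)
        for cs in callsets
    )
    return FractionStat.from_counts(k, len(callsets))


def window_depletion_fraction(
    callsets: Sequence[CloneCallSet],
    annotation: SiteAnnotation,
    window: NDRWindow,
    min_span_bp: int = NDR_MIN_SPAN_BP,
) -> FractionStat:
    """Fraction of clones whose window is fully nucleosome-free.

    A clone qualifies when every informative GCH call inside the window is
    accessible and no protected segment of span >= ``min_span_bp`` intrudes
    into the window (segment extent measured over its own sites).
    """
    if not callsets:
        raise ValueError("no clones supplied")
    in_window = [
        i for i, p in enumerate(annotation.gch_sites) if window.start <= p < window.end
    ]
    if not in_window:
        raise ValueError(
            f"window [{window.start},{window.end}) contains no GCH sites"
        )
    k = 0
    for cs in callsets:
        calls = [cs.gch_calls[i] for i in in_window]
        if any(c == "inaccessible" for c in calls):
            continue
        if all(c == "missing" for c in calls):
            continue
        segments = segment_clone(cs, annotation)
        intruding = any(
            seg.state == "protected"
            and seg.span >= min_span_bp
            and seg.first_site < window.end
            and window.start < seg.last_site + 2
            for seg in segments
        )
        if not intruding:
            k += 1
    return FractionStat.from_counts(k, len(callsets))


def segments_to_bed(
    segments_by_clone: dict[str, Sequence[FootprintSegment]], region_id: str
) -> str:
    """Region-relative BED: name=state, score=span."""
    lines = []
    for clone_id, segs in segments_by_clone.items():
        for seg in segs:
            lines.append(
                f"{region_id}\t{seg.start}\t{seg.end}\t"
                f"{clone_id}:{seg.state}\t{seg.span}\t."
            )
    return "\n".join(lines) + ("\n" if lines else "")


__all__ = [
    "NDR_MIN_SPAN_BP",
    "FootprintSegment",
    "NDRWindow",
    "FractionStat",
    "segment_clone",
    "call_ndr",
    "ndr_fraction",
    "window_depletion_fraction",
    "segments_to_bed",
]
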