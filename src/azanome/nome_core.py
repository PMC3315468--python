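"""Amplicon annotation and single-clone bisulfite calling for dual-enzyme footprinting.

NOMe-seq reads report two signals on the same molecule: endogenous CpG
methylation (HCG trinucleotides, i.e. CpG cytosines not preceded by G) and
exogenous GpC-methyltransferase accessibility (GCH trinucleotides, i.e. GpC
cytosines not followed by G).  GCG contexts are ambiguous — a retained
cytosine there could reflect either endogenous CpG methylation or enzyme
action — and are excluded from both readouts.

Coordinates are 0-based top-strand positions throughout; a site's position is
the top-strand index of its cytosine.  Bottom-strand reads are handled in the
reference frame as their PCR top-strand image: a bottom-strand cytosine sits
opposite a reference G, so bisulfite conversion appears as G→A.  For a CpG at
top position ``p`` the bottom-strand readout base is ``p+1``; for a GpC whose
top cytosine is at ``p`` the bottom-strand readout base is ``p-1``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

log = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")

# H = "not G" in the IUPAC sense used for trinucleotide contexts.
_H = frozenset("ACT")

Strand = Literal["top", "bottom"]

MethCall = Literal["methylated", "unmethylated", "missing"]
AccessCall = Literal["accessible", "inaccessible", "missing"]


class StrandInferenceError(ValueError):
    """Read is incompatible with both bisulfite conversion models."""


@dataclass(frozen=True)
class AmpliconReference:
    """One amplicon: top-strand sequence, TSS, and optional selection primers.

    ``primer_cpg_positions`` lists the CpG cytosines covered by
    methylation-specific PCR primers; strand selection retains only clones
    unmethylated at every one of them.
    """

    region_id: str
    sequence: str
    tss: int
    primer_cpg_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        bad = [i for i, b in enumerate(self.sequence) if b not in _VALID_BASES]
        if bad:
            raise ValueError(
                f"non-ACGT character at position {bad[0]} in region {self.region_id}"
            )
        if not 0 <= self.tss < len(self.sequence):
            raise ValueError(f"tss {self.tss} outside [0, {len(self.sequence)})")
        cpgs = set(self.cpg_positions())
        extra = set(self.primer_cpg_positions) - cpgs
        if extra:
            raise ValueError(f"primer positions {sorted(extra)} are not CpG cytosines")

    def __len__(self) -> int:
        return len(self.sequence)

    def cpg_positions(self) -> tuple[int, ...]:
        """Top-strand indices of every CpG cytosine (any context)."""
        s = self.sequence
        return tuple(i for i in range(len(s) - 1) if s[i] == "C" and s[i + 1] == "G")


@dataclass(frozen=True)
class SiteAnnotation:
    """Partition of CpG/GpC cytosines into HCG, GCH and excluded contexts."""

    hcg_sites: tuple[int, ...]
    gch_sites: tuple[int, ...]
    excluded_gcg: tuple[int, ...]

    def __post_init__(self) -> None:
        sets = [set(self.hcg_sites), set(self.gch_sites), set(self.excluded_gcg)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("HCG/GCH/excluded site lists must be pairwise disjoint")

    @property
    def n_sites(self) -> int:
        return len(self.hcg_sites) + len(self.gch_sites) + len(self.excluded_gcg)


@dataclass
class CloneCallSet:
    """Per-site calls for one sequenced bisulfite clone."""

    clone_id: str
    strand: Strand
    hcg_calls: tuple[MethCall, ...]
    gch_calls: tuple[AccessCall, ...]
    conversion_rate_observed: float
    passed_qc: bool
    qc_indeterminate: bool = False


def annotate_sites(reference: AmpliconReference) -> SiteAnnotation:
    """Scan the top strand and classify every CpG/GpC cytosine.

    HCG: CpG cytosine whose preceding base is A/C/T.  GCH: GpC cytosine whose
    following base is A/C/T.  GCG trinucleotides — and sites whose flanking
    context is truncated by the region edge — go to ``excluded_gcg``.
    """
    s = reference.sequence
    hcg: list[int] = []
    gch: list[int] = []
    excluded: list[int] = []
    for i, b in enumerate(s):
        if b != "C":
            continue
        is_cpg = i + 1 < len(s) and s[i + 1] == "G"
        is_gpc = i - 1 >= 0 and s[i - 1] == "G"
        if not (is_cpg or is_gpc):
            continue
        if is_cpg and is_gpc:  # GCG: ambiguous by construction
            excluded.append(i)
        elif is_cpg:
            if i == 0:  # no preceding base: context truncated
                excluded.append(i)
            elif s[i - 1] in _H:
                hcg.append(i)
            else:  # preceded by G but next base checked above; unreachable
                excluded.append(i)
        else:  # GpC only
            if i + 1 >= len(s):
                excluded.append(i)
            elif s[i + 1] in _H:
                gch.append(i)
            else:
                excluded.append(i)
    return SiteAnnotation(tuple(hcg), tuple(gch), tuple(excluded))


def _mismatches_top(read: str, ref: str) -> int:
    """Mismatch count under the top-strand conversion model (C→{C,T})."""
    n = 0
    for r, q in zip(ref, read):
        if r == "C":
            n += q not in ("C", "T")
        else:
            n += q != r
    return n


def _mismatches_bottom(read: str, ref: str) -> int:
    """Mismatch count under the bottom-strand image model (G→{G,A})."""
    n = 0
    for r, q in zip(ref, read):
        if r == "G":
            n += q not in ("G", "A")
        else:
            n += q != r
    return n


def infer_bisulfite_strand(
    read: str, reference: AmpliconReference, max_mismatch_frac: float = 0.10
) -> Strand:
    """Decide which strand a converted read came from.

    Compares the read against both conversion images of the reference and
    returns the better-fitting strand; ties break toward "top" with a warning.
    A read exceeding ``max_mismatch_frac`` under both models is rejected.
    """
    ref = reference.sequence
    if len(read) != len(ref):
        raise ValueError(
            f"read length {len(read)} != reference length {len(ref)} "
            f"for region {reference.region_id}"
        )
    m_top = _mismatches_top(read, ref)
    m_bot = _mismatches_bottom(read, ref)
    limit = max_mismatch_frac * len(ref)
    if m_top > limit and m_bot > limit:
        raise StrandInferenceError(
            f"read fits neither strand model (mismatch fractions "
            f"top={m_top / len(ref):.3f}, bottom={m_bot / len(ref):.3f}, "
            f"limit {max_mismatch_frac})"
        )
    if m_top == m_bot:
        warnings.warn(
            "strand inference tie; defaulting to top", stacklevel=2
        )
        return "top"
    return "top" if m_top < m_bot else "bottom"


def _readout_index(site: int, strand: Strand, kind: str) -> int:
    """Reference-frame base index carrying the call for a site on a strand."""
    if strand == "top":
        return site
    return site + 1 if kind == "hcg" else site - 1


def call_clone(
    read: str,
    reference: AmpliconReference,
    annotation: SiteAnnotation,
    qc_min_conversion: float = 0.95,
    strand: Strand | None = None,
    clone_id: str = "clone",
) -> CloneCallSet:
    """Call methylation and accessibility at every annotated site of one read.

    A retained cytosine (C on top reads, G on bottom-image reads) at a site
    means methylated (HCG) or accessible (GCH); the converted base means
    unmethylated/inaccessible; anything else is a missing call.  The observed
    conversion rate is computed over strand cytosines outside all HCG/GCH/GCG
    contexts, which should be fully converted in a successful reaction.
    """
    if strand is None:
        strand = infer_bisulfite_strand(read, reference)
    ref = reference.sequence
    if len(read) != len(ref):
        raise ValueError("read/reference length mismatch")

    retained, converted = ("C", "T") if strand == "top" else ("G", "A")

    def _call(site: int, kind: str, states: tuple[str, str]) -> str:
        idx = _readout_index(site, strand, kind)
        if not 0 <= idx < len(read):
            return "missing"
        b = read[idx]
        if b == retained:
            return states[0]
        if b == converted:
            return states[1]
        return "missing"

    hcg_calls = tuple(
        _call(p, "hcg", ("methylated", "unmethylated")) for p in annotation.hcg_sites
    )
    gch_calls = tuple(
        _call(p, "gch", ("accessible", "inaccessible")) for p in annotation.gch_sites
    )

    # Conversion QC: strand cytosines outside every annotated context.
    context = _context_positions(annotation, strand)
    cyt = retained if strand == "top" else "G"  # ref base carrying a strand cytosine
    informative = converted_n = 0
    for i, b in enumerate(ref):
        if b != cyt or i in context:
            continue
        # Skip CpG/GpC strand cytosines not in the annotation lists
        # (there are none by the partition invariant, but stay safe).
        q = read[i]
        if q == converted:
            informative += 1
            converted_n += 1
        elif q == retained:
            informative += 1

    if informative == 0:
        log.warning("clone %s: no informative non-context cytosines", clone_id)
        return CloneCallSet(
            clone_id, strand, hcg_calls, gch_calls, float("nan"), False, True
        )
    rate = converted_n / informative
    return CloneCallSet(
        clone_id, strand, hcg_calls, gch_calls, rate, rate >= qc_min_conversion
    )


def _context_positions(annotation: SiteAnnotation, strand: Strand) -> set[int]:
    """Reference-frame positions occupied by annotated-site readouts."""
    pos: set[int] = set()
    for p in annotation.hcg_sites:
        pos.add(_readout_index(p, strand, "hcg"))
    for p in annotation.gch_sites:
        pos.add(_readout_index(p, strand, "gch"))
    for p in annotation.excluded_gcg:
        # A GCG cytosine is both a CpG and a GpC; mask both strand readouts.
        pos.add(p if strand == "top" else p + 1)
        if strand == "bottom":
            pos.add(p - 1)
    return pos


def filter_demethylated_strands(
    callsets: Sequence[CloneCallSet],
    reference: AmpliconReference,
    annotation: SiteAnnotation | None = None,
) -> list[CloneCallSet]:
    """Emulate methylation-specific primers: keep clones unmethylated at every
    primer CpG.

    Clones with a methylated or missing call at any primer position are
    dropped; order is preserved, so the operation is idempotent.
    """
    if not reference.primer_cpg_positions:
        raise ValueError(f"region {reference.region_id} has no primer CpG positions")
    if annotation is None:
        annotation = annotate_sites(reference)
    site_index = {p: i for i, p in enumerate(annotation.hcg_sites)}
    missing = [p for p in reference.primer_cpg_positions if p not in site_index]
    if missing:
        raise ValueError(
            f"primer CpG positions {missing} are not HCG sites of the annotation"
        )
    idx = [site_index[p] for p in reference.primer_cpg_positions]
    return [
        cs for cs in callsets if all(cs.hcg_calls[i] == "unmethylated" for i in idx)
    ]


__all__ = [
    "AmpliconReference",
    "SiteAnnotation",
    "CloneCallSet",
    "Strand",
    "StrandInferenceError",
    "annotate_sites",
    "infer_bisulfite_strand",
    "call_clone",
    "filter_demethylated_strands",
]
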