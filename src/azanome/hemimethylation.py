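"""Hpa II digestion modeling and duplex-class (U/H/F) deconvolution.

Hpa II cuts its CCGG target only when the internal CpG is unmethylated on
**both** strands; hemimethylated and fully methylated duplexes resist
digestion.  Combined with a strand-level methylation readout (Ms-SNuPE after
bisulfite conversion) this gives two measurements at one CCGG site:

* ``m0`` — methylated-strand fraction in the undigested sample,
* ``m1`` — the same fraction after digestion.

Writing the duplex-class fractions U (both strands unmethylated),
H (exactly one methylated) and F (both methylated), with U + H + F = 1, and
noting that PCR reads both strands of a surviving duplex:

    m0 = F + H/2                      (all duplexes present)
    m1 = (F + H/2) / (F + H)          (only H and F survive digestion)

Inverting:

    H = 2 * m0 * (1/m1 - 1)
    F = m0 * (2 - 1/m1)
    U = 1 - H - F

Feasible measurements require m1 >= 1/2 (survivors are at least half
methylated, since every surviving duplex carries >= 1 methylated strand) and
m0 <= m1 (digestion removes only unmethylated material).  The forward model
is shipped (``forward_model``) so the inversion can be verified directly.

The cut rule is modeled as complete digestion ("an excess" of enzyme); a
``digestion_efficiency`` parameter below 1 leaves a random fraction of
cuttable molecules intact for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nome_core import (
    AmpliconReference,
    CloneCallSet,
    SiteAnnotation,
    call_clone,
    filter_demethylated_strands,
)
from .synthetic_data import (
    DuplexMolecule,
    SimulationConfig,
    bisulfite_reads,
    find_ccgg_internal_cpgs,
)


@dataclass(frozen=True)
class SnupeMeasurement:
    """Strand-methylation fractions at one CCGG-internal CpG."""

    m_undigested: float  # m0
    m_digested: float  # m1

    def __post_init__(self) -> None:
        for name in ("m_undigested", "m_digested"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class HemiEstimate:
    """Deconvolved duplex-class fractions; U + H + F = 1 to within 1e-9."""

    U: float
    H: float
    F: float
    residual: float = 0.0

    def __post_init__(self) -> None:
        for name in "UHF":
            v = getattr(self, name)
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.U + self.H + self.F - 1.0) > 1e-9:
            raise ValueError("U + H + F must equal 1")


class InfeasibleMeasurementError(ValueError):
    """Measurement violates the digestion model's mass balance."""


def classify_duplex(top_meth: bool, bottom_meth: bool) -> str:
    """U/H/F state of one CpG site on a duplex."""
    if top_meth and bottom_meth:
        return "F"
    if top_meth or bottom_meth:
        return "H"
    return "U"


def forward_model(U: float, H: float, F: float) -> SnupeMeasurement:
    """Expected (m0, m1) for a duplex mixture; requires H + F > 0."""
    total = U + H + F
    if abs(total - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if H + F <= 0:
        raise ValueError("m1 undefined when no duplex survives digestion")
    m0 = F + H / 2.0
    m1 = (F + H / 2.0) / (F + H)
    return SnupeMeasurement(m0, m1)


def deconvolve_uhf(
    meas: SnupeMeasurement, tolerance: float = 1e-6
) -> HemiEstimate:
    """Invert the digestion + strand-readout model to (U, H, F).

    Violations of the [0, 1] bounds within ``tolerance`` are clamped (and
    reported via ``residual``); larger violations raise
    :class:`InfeasibleMeasurementError`.
    """
    m0, m1 = meas.m_undigested, meas.m_digested
    if m1 == 0:
        raise InfeasibleMeasurementError("m_digested = 0: inversion undefined")
    if m1 < 0.5 - tolerance:
        raise InfeasibleMeasurementError(
            f"m_digested={m1} < 1/2: survivors cannot be less than half methylated"
        )
    if m0 > m1 + tolerance:
        raise InfeasibleMeasurementError(
            f"m_undigested={m0} > m_digested={m1}: digestion cannot lower "
            "the methylated fraction"
        )
    H = 2.0 * m0 * (1.0 / m1 - 1.0)
    F = m0 * (2.0 - 1.0 / m1)
    U = 1.0 - H - F
    residual = max(
        0.0,
        *(-v for v in (U, H, F)),
        *(v - 1.0 for v in (U, H, F)),
    )
    if residual > tolerance:
        raise InfeasibleMeasurementError(
            f"inconsistent measurement: class fraction out of [0,1] by {residual:.3g}"
        )
    U, H, F = (min(1.0, max(0.0, v)) for v in (U, H, F))
    # Re-balance the clamp so the simplex constraint holds exactly.
    s = U + H + F
    U, H, F = U / s, H / s, F / s
    return HemiEstimate(U, H, F, residual)


def measure_snupe(
    molecules: Sequence[DuplexMolecule], site: int
) -> float:
    """Methylated-strand fraction at one CpG site across a molecule pool."""
    if not molecules:
        raise ValueError("empty molecule pool")
    idx = molecules[0].cpg_positions.index(site)
    meth = sum(int(m.top_meth[idx]) + int(m.bottom_meth[idx]) for m in molecules)
    return meth / (2 * len(molecules))


def digest_hpaii(
    molecules: Sequence[DuplexMolecule],
    ccgg_internal_cpg_positions: Sequence[int],
    reference: AmpliconReference | None = None,
    digestion_efficiency: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[DuplexMolecule]:
    """Return the molecules surviving Hpa II digestion, unchanged.

    A molecule is destroyed iff at least one listed site is unmethylated on
    both strands (the enzyme cuts anywhere along the amplicon).  When a
    reference is supplied, each listed position is checked to be the internal
    CpG of a CCGG motif.  ``digestion_efficiency`` < 1 lets a matching
    fraction of cuttable molecules escape (requires ``rng``).
    """
    if reference is not None:
        valid = set(find_ccgg_internal_cpgs(reference))
        bad = [p for p in ccgg_internal_cpg_positions if p not in valid]
        if bad:
            raise ValueError(
                f"positions {bad} are not internal CpGs of CCGG motifs in "
                f"region {reference.region_id}"
            )
    if not molecules:
        return []
    pos_index = {p: i for i, p in enumerate(molecules[0].cpg_positions)}
    missing = [p for p in ccgg_internal_cpg_positions if p not in pos_index]
    if missing:
        raise ValueError(f"positions {missing} are not annotated CpG sites")
    idx = [pos_index[p] for p in ccgg_internal_cpg_positions]
    if digestion_efficiency < 1.0 and rng is None:
        raise ValueError("partial digestion requires an rng")
    survivors = []
    for mol in molecules:
        cuttable = any(
            not mol.top_meth[i] and not mol.bottom_meth[i] for i in idx
        )
        if cuttable and (
            digestion_efficiency >= 1.0 or rng.random() < digestion_efficiency
        ):
            continue
        survivors.append(mol)
    return survivors


def select_hemimethylated_strands(
    molecules: Sequence[DuplexMolecule],
    gch_flags: Mapping[str, tuple[np.ndarray, np.ndarray]],
    reference: AmpliconReference,
    annotation: SiteAnnotation,
    ccgg_positions: Sequence[int],
    config: SimulationConfig,
    n_clones: int,
    qc_min_conversion: float = 0.95,
    seed: int | None = None,
) -> tuple[list[CloneCallSet], pd.DataFrame]:
    """Hpa II pre-digestion + demethylation-selective amplification.

    Pipeline: digest → bisulfite clone reads → per-clone calling →
    retain clones unmethylated at every primer CpG.  Because digestion
    destroys symmetrically demethylated duplexes, the surviving demethylated
    strands derive from hemimethylated duplexes, so their footprints report
    the chromatin state of hemimethylated DNA.  Returns the retained
    callsets and the matching truth-table rows.
    """
    survivors = digest_hpaii(molecules, ccgg_positions, reference)
    if not survivors:
        return [], pd.DataFrame()
    n_clones = min(n_clones, 2 * len(survivors))
    records, truth = bisulfite_reads(
        survivors, gch_flags, reference, annotation, config, n_clones, seed=seed
    )
    callsets = [
        call_clone(read, reference, annotation, qc_min_conversion, clone_id=cid)
        for cid, read in records
    ]
    callsets = [cs for cs in callsets if cs.passed_qc]
    kept = filter_demethylated_strands(callsets, reference, annotation)
    kept_ids = {cs.clone_id for cs in kept}
    return kept, truth[truth["clone_id"].isin(kept_ids)].reset_index(drop=True)


__all__ = [
    "SnupeMeasurement",
    "HemiEstimate",
    "InfeasibleMeasurementError",
    "classify_duplex",
    "forward_model",
    "deconvolve_uhf",
    "measure_snupe",
    "digest_hpaii",
    "select_hemimethylated_strands",
]
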