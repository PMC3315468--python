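"""Synthetic molecule- and matrix-level data with retained ground truth.

The generator emulates the biology a DNMT-inhibitor time course produces:

* Duplex CpG methylation evolving by **semiconservative replication**.  Each
  daughter duplex keeps one parental strand; the newly synthesised strand is
  unmethylated at every CpG when the division happened under drug inhibition
  (the analog was incorporated and trapped the methyltransferase), otherwise
  maintenance methylation copies the parental pattern, with optional per-site
  de novo remethylation after drug washout.
* **Nucleosome remodeling conditional on symmetric demethylation**: only
  duplexes unmethylated on both strands at every promoter-window CpG can
  acquire a nucleosome-depleted region (probability ``p_ndr``, attenuated by
  ``srcap_kd_factor`` when the remodeler-knockdown flag is set).  All other
  molecules are tiled with 147-bp nucleosome cores.
* **GpC methyltransferase** action on accessible (linker/NDR) DNA, bisulfite
  conversion with configurable failure rates, and clone FASTA output in the
  reference frame (bottom strands as their PCR G→A image).
* **Array matrices**: bimodal promoter beta values with planted demethylation
  and log2 expression with planted reactivation, attenuated under the
  knockdown condition.

Every stage is reproducible bit-for-bit under a fixed seed and returns the
ground truth needed to audit the downstream calls.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .footprint import NDRWindow
from .nome_core import AmpliconReference, SiteAnnotation, annotate_sites

NUCLEOSOME_BP = 147


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the replication/remodeling simulation.

    Defaults are illustrative of a 24 h drug pulse followed by washout in a
    line dividing about once per day; the drug-era incorporation probability
    and the remodeling probability are population-level effect sizes, not
    fitted kinetic constants.
    """

    n_molecules: int = 500
    days: tuple[int, ...] = (0, 1, 2, 3, 5)
    divisions_per_day: float = 1.0
    incorporation_prob: float = 0.9
    remethylation_prob: float = 0.0
    washout_day: int = 2
    p_ndr: float = 0.4
    srcap_kd_factor: float = 0.5
    srcap_kd: bool = False
    conversion_rate: float = 0.995
    inappropriate_conversion: float = 0.002
    mcvipi_efficiency: float = 0.99
    linker_bp: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "incorporation_prob": self.incorporation_prob,
            "remethylation_prob": self.remethylation_prob,
            "p_ndr": self.p_ndr,
            "srcap_kd_factor": self.srcap_kd_factor,
            "conversion_rate": self.conversion_rate,
            "inappropriate_conversion": self.inappropriate_conversion,
            "mcvipi_efficiency": self.mcvipi_efficiency,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.divisions_per_day <= 0:
            raise ValueError("divisions_per_day must be positive")
        if any(d < 0 for d in self.days):
            raise ValueError("negative day index")
        if list(self.days) != sorted(self.days):
            raise ValueError("days must be sorted ascending")


@dataclass
class DuplexMolecule:
    """One DNA duplex: per-CpG strand methylation plus a bp occupancy track."""

    region_id: str
    cpg_positions: tuple[int, ...]
    top_meth: np.ndarray
    bottom_meth: np.ndarray
    occupancy: tuple[tuple[int, int], ...] = ()
    molecule_id: str = ""
    has_ndr: bool = False

    def __post_init__(self) -> None:
        if len(self.top_meth) != len(self.cpg_positions) or len(
            self.bottom_meth
        ) != len(self.cpg_positions):
            raise ValueError("strand vectors not aligned to cpg_positions")


def duplex_class(mol: DuplexMolecule) -> str:
    """U/H/F over all CpGs; "M" for mixed (partially methylated) strands."""
    t_all, t_any = bool(mol.top_meth.all()), bool(mol.top_meth.any())
    b_all, b_any = bool(mol.bottom_meth.all()), bool(mol.bottom_meth.any())
    if not t_any and not b_any:
        return "U"
    if t_all and b_all:
        return "F"
    if (t_all and not b_any) or (b_all and not t_any):
        return "H"
    return "M"


def class_fractions(molecules: Sequence[DuplexMolecule]) -> dict[str, float]:
    counts = {"U": 0, "H": 0, "F": 0, "M": 0}
    for m in molecules:
        counts[duplex_class(m)] += 1
    n = len(molecules)
    return {k: v / n for k, v in counts.items()}


# ---------------------------------------------------------------------------
# Example amplicon: a synthetic CpG-island promoter with evenly spaced HCG and
# GCH readouts and a single Hpa II (CCGG) site just upstream of the TSS.

# Each tile also carries one plain C (top) and one plain G (bottom cytosine)
# outside any CpG/GpC context, providing conversion-QC readouts per strand.
_HCG_TILE = "ATTACGTCAG"  # one HCG at tile offset 4
_GCH_TILE = "TTAGCATCAG"  # one GCH at tile offset 4
_CCGG_TILE = "ATACCGGTTA"  # one Hpa II site; internal CpG (HCG) at offset 4


def example_amplicon(
    region_id: str = "PROM1", n_tiles: int = 60, tss_tile: int = 30
) -> AmpliconReference:
    """Deterministic synthetic promoter amplicon.

    Alternating 10-bp tiles carry one HCG or one GCH site each (so sites fall
    every 20 bp per readout); the tile preceding the TSS carries the CCGG
    site.  Primer CpGs are the first and last HCG sites, mimicking
    methylation-specific primers at the amplicon ends.
    """
    tiles = []
    for i in range(n_tiles):
        if i == tss_tile - 2:
            tiles.append(_CCGG_TILE)
        elif i % 2 == 0:
            tiles.append(_HCG_TILE)
        else:
            tiles.append(_GCH_TILE)
    seq = "".join(tiles)
    ref = AmpliconReference(region_id, seq, tss=tss_tile * 10)
    ann = annotate_sites(ref)
    return replace(
        ref, primer_cpg_positions=(ann.hcg_sites[0], ann.hcg_sites[-1])
    )


def find_ccgg_internal_cpgs(reference: AmpliconReference) -> tuple[int, ...]:
    """Top-strand positions of the internal CpG cytosine of every CCGG motif."""
    s = reference.sequence
    return tuple(
        i + 1 for i in range(len(s) - 3) if s[i : i + 4] == "CCGG"
    )


# ---------------------------------------------------------------------------
# Replication time course


def simulate_timecourse(
    config: SimulationConfig, region: AmpliconReference
) -> dict[int, list[DuplexMolecule]]:
    """Evolve a fully methylated population through drug-era divisions.

    Day 0 molecules are fully methylated at every CpG.  Divisions occur at
    times ``i / divisions_per_day``; a division at or before ``washout_day``
    is drug-inhibited with probability ``incorporation_prob`` independently
    per daughter strand.  After washout, maintenance methylation copies the
    parental strand, plus per-site de novo remethylation at
    ``remethylation_prob``.  Population size is held at ``n_molecules`` by
    uniform subsampling.  Returns a snapshot per requested day.
    """
    cpgs = region.cpg_positions()
    if not cpgs:
        raise ValueError(f"region {region.region_id} has no CpG sites")
    if any(d < 0 for d in config.days):
        raise ValueError("negative day index")
    rng = np.random.default_rng([config.seed, 101])
    n, m = config.n_molecules, len(cpgs)
    top = np.ones((n, m), dtype=bool)
    bottom = np.ones((n, m), dtype=bool)

    eps = 1e-9
    snapshots: dict[int, list[DuplexMolecule]] = {}

    def take(day: int) -> None:
        snapshots[day] = [
            DuplexMolecule(
                region.region_id,
                cpgs,
                top[i].copy(),
                bottom[i].copy(),
                molecule_id=f"{region.region_id}_d{day}_m{i:05d}",
            )
            for i in range(n)
        ]

    divs_done = 0
    for day in config.days:
        target = int(np.floor(day * config.divisions_per_day + eps))
        while divs_done < target:
            t = (divs_done + 1) / config.divisions_per_day
            drug_era = t <= config.washout_day + eps
            new_from_top = _new_strand(top, drug_era, config, rng)
            new_from_bottom = _new_strand(bottom, drug_era, config, rng)
            # Daughter A keeps the parental top strand; B keeps the bottom.
            top2 = np.concatenate([top, new_from_bottom])
            bottom2 = np.concatenate([new_from_top, bottom])
            keep = rng.choice(2 * n, size=n, replace=False)
            keep.sort()
            top, bottom = top2[keep], bottom2[keep]
            divs_done += 1
        take(day)
    return snapshots


def _new_strand(
    parental: np.ndarray, drug_era: bool, config: SimulationConfig, rng
) -> np.ndarray:
    """Synthesise complementary strands for each parental strand (vectorised)."""
    n, m = parental.shape
    if drug_era:
        inhibited = rng.random(n) < config.incorporation_prob
    else:
        inhibited = np.zeros(n, dtype=bool)
    new = parental.copy()  # maintenance: copy parental pattern
    if not drug_era and config.remethylation_prob > 0:
        denovo = rng.random((n, m)) < config.remethylation_prob
        new |= denovo
    new[inhibited] = False  # analog incorporated: no methylation transferred
    return new


# ---------------------------------------------------------------------------
# Nucleosome remodeling


def _tile_occupancy(
    length: int, phase: int, linker_bp: int, exclude: tuple[int, int] | None = None
) -> tuple[tuple[int, int], ...]:
    """147-bp cores at a fixed period, truncated at region edges; cores
    overlapping ``exclude`` are dropped entirely."""
    period = NUCLEOSOME_BP + linker_bp
    start = phase - period  # allow a truncated core at the left edge
    out = []
    while start < length:
        s, e = max(start, 0), min(start + NUCLEOSOME_BP, length)
        if e > s:
            if exclude is None or not (s < exclude[1] and exclude[0] < e):
                out.append((s, e))
        start += period
    return tuple(out)


def apply_remodeling(
    molecules: Sequence[DuplexMolecule],
    config: SimulationConfig,
    window: NDRWindow,
    region_length: int | None = None,
) -> list[DuplexMolecule]:
    """Assign occupancy: an NDR gap for symmetrically demethylated promoters,
    full nucleosome tiling otherwise.

    A molecule whose windowed CpGs are all unmethylated on both strands
    receives, with probability ``p_ndr`` (times ``srcap_kd_factor`` under the
    knockdown flag), an occupancy gap covering the window; every other
    molecule is tiled with nucleosome cores at a uniformly random phase.
    """
    if not molecules:
        return []
    cpgs = molecules[0].cpg_positions
    length = region_length if region_length is not None else max(cpgs) + 2
    if window.start < 0 or window.end > length:
        raise ValueError(
            f"window [{window.start},{window.end}) outside region [0,{length})"
        )
    win_idx = [
        i for i, p in enumerate(cpgs) if window.start <= p < window.end
    ]
    rng = np.random.default_rng([config.seed, 202])
    p_gap = config.p_ndr * (config.srcap_kd_factor if config.srcap_kd else 1.0)
    period = NUCLEOSOME_BP + config.linker_bp
    out = []
    for mol in molecules:
        symmetric_unmeth = not (
            mol.top_meth[win_idx].any() or mol.bottom_meth[win_idx].any()
        ) if win_idx else False
        phase = int(rng.integers(period))
        gets_gap = symmetric_unmeth and rng.random() < p_gap
        if gets_gap:
            occ = _tile_occupancy(
                length, phase, config.linker_bp, exclude=(window.start, window.end)
            )
        else:
            occ = _tile_occupancy(length, phase, config.linker_bp)
        out.append(
            replace(mol, occupancy=occ, has_ndr=gets_gap)
        )
    return out


# ---------------------------------------------------------------------------
# GpC methyltransferase treatment


def apply_mcvipi(
    molecule: DuplexMolecule,
    annotation: SiteAnnotation,
    efficiency: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Mark accessible GCH sites as enzyme-methylated, per strand.

    A GCH site covered by any nucleosome core is never marked; uncovered
    sites are marked independently per strand with probability
    ``efficiency``.  Returns (top_flags, bottom_flags) aligned to
    ``annotation.gch_sites``.
    """
    sites = np.asarray(annotation.gch_sites)
    covered = np.zeros(len(sites), dtype=bool)
    for s, e in molecule.occupancy:
        covered |= (sites >= s) & (sites < e)
    accessible = ~covered
    top = accessible & (rng.random(len(sites)) < efficiency)
    bottom = accessible & (rng.random(len(sites)) < efficiency)
    return top, bottom


def treat_pool_with_mcvipi(
    molecules: Sequence[DuplexMolecule],
    annotation: SiteAnnotation,
    config: SimulationConfig,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Apply the enzyme to every molecule under a seed-derived stream."""
    rng = np.random.default_rng([config.seed, 303])
    return {
        mol.molecule_id: apply_mcvipi(mol, annotation, config.mcvipi_efficiency, rng)
        for mol in molecules
    }


# ---------------------------------------------------------------------------
# Bisulfite clone reads


def _top_read(
    mol: DuplexMolecule,
    gch_top: np.ndarray,
    reference: AmpliconReference,
    annotation: SiteAnnotation,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> str:
    seq = list(reference.sequence)
    cpg_index = {p: i for i, p in enumerate(mol.cpg_positions)}
    gch_index = {p: i for i, p in enumerate(annotation.gch_sites)}
    for i, b in enumerate(seq):
        if b != "C":
            continue
        meth = False
        if i in cpg_index:
            meth = bool(mol.top_meth[cpg_index[i]])
        if i in gch_index:
            meth = meth or bool(gch_top[gch_index[i]])
        p_convert = config.inappropriate_conversion if meth else config.conversion_rate
        if rng.random() < p_convert:
            seq[i] = "T"
    return "".join(seq)


def _bottom_read(
    mol: DuplexMolecule,
    gch_bottom: np.ndarray,
    reference: AmpliconReference,
    annotation: SiteAnnotation,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> str:
    """Bottom strand as its PCR top-strand image: converted Cs appear as G→A."""
    seq = list(reference.sequence)
    cpg_index = {p: i for i, p in enumerate(mol.cpg_positions)}
    gch_index = {p: i for i, p in enumerate(annotation.gch_sites)}
    for q, b in enumerate(seq):
        if b != "G":
            continue
        meth = False
        if q - 1 in cpg_index:  # bottom CpG cytosine opposite the top G
            meth = bool(mol.bottom_meth[cpg_index[q - 1]])
        if q + 1 in gch_index:  # bottom GpC cytosine opposite the top G
            meth = meth or bool(gch_bottom[gch_index[q + 1]])
        p_convert = config.inappropriate_conversion if meth else config.conversion_rate
        if rng.random() < p_convert:
            seq[q] = "A"
    return "".join(seq)


def bisulfite_reads(
    molecules: Sequence[DuplexMolecule],
    gch_flags: Mapping[str, tuple[np.ndarray, np.ndarray]],
    reference: AmpliconReference,
    annotation: SiteAnnotation,
    config: SimulationConfig,
    n_clones: int,
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Sample strands and emit converted clone reads plus the truth table.

    Each (molecule, strand) pair is sampled at most once.  Returns a list of
    ``(clone_id, read)`` records and a truth table with one row per clone:
    molecule id, strand, duplex class, NDR status, per-site HCG/GCH truth
    strings and the occupancy intervals.
    """
    if n_clones <= 0:
        raise ValueError("n_clones must be positive")
    if n_clones > 2 * len(molecules):
        raise ValueError(
            f"n_clones={n_clones} exceeds 2 x {len(molecules)} available strands"
        )
    rng = np.random.default_rng(
        [config.seed if seed is None else seed, 404]
    )
    pairs = [(i, s) for i in range(len(molecules)) for s in ("top", "bottom")]
    pick = rng.choice(len(pairs), size=n_clones, replace=False)
    pick.sort()

    cpg_index = {p: i for i, p in enumerate(molecules[0].cpg_positions)}
    hcg_idx = [cpg_index[p] for p in annotation.hcg_sites]

    records: list[tuple[str, str]] = []
    truth_rows = []
    for k, j in enumerate(pick):
        mol_i, strand = pairs[j]
        mol = molecules[mol_i]
        gch_top, gch_bottom = gch_flags[mol.molecule_id]
        clone_id = f"{reference.region_id}_c{k:04d}"
        if strand == "top":
            read = _top_read(mol, gch_top, reference, annotation, config, rng)
            strand_meth = mol.top_meth
            strand_gch = gch_top
        else:
            read = _bottom_read(mol, gch_bottom, reference, annotation, config, rng)
            strand_meth = mol.bottom_meth
            strand_gch = gch_bottom
        records.append((clone_id, read))
        truth_rows.append(
            {
                "clone_id": clone_id,
                "molecule_id": mol.molecule_id,
                "strand": strand,
                "duplex_class": duplex_class(mol),
                "has_ndr": mol.has_ndr,
                "hcg_truth": "".join(
                    "M" if strand_meth[i] else "U" for i in hcg_idx
                ),
                "gch_truth": "".join("A" if f else "I" for f in strand_gch),
                "occupancy": ";".join(f"{s}-{e}" for s, e in mol.occupancy),
            }
        )
    return records, pd.DataFrame(truth_rows)


def write_clones_fasta(
    records: Iterable[tuple[str, str]], path, seed: int
) -> None:
    """Clone reads as FASTA; the seed is recorded in every header."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seq_write
    from Bio.SeqRecord import SeqRecord

    seqs = [
        SeqRecord(Seq(read), id=clone_id, description=f"seed={seed}")
        for clone_id, read in records
    ]
    seq_write(seqs, str(path), "fasta")


def write_table(df: pd.DataFrame, path, seed: int, index: bool = False) -> None:
    """TSV with a seed-recording comment header."""
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


# ---------------------------------------------------------------------------
# Array-scale matrices


@dataclass
class ArrayData:
    """Beta-value and expression matrices for the four conditions plus truth."""

    betas: pd.DataFrame  # index probe_id; columns: gene + 4 beta columns
    expr: pd.DataFrame  # index transcript_id; columns: gene + replicate columns
    samples: pd.DataFrame  # sample -> (sirna, treatment)
    truth: dict


BETA_CONDITIONS = ("NC_PBS", "NC_Aza", "KD_PBS", "KD_Aza")


def generate_array_data(
    n_probes: int = 5000,
    n_genes_planted_demeth: int = 250,
    n_genes_planted_reactivated: int = 44,
    kd_attenuation: float = 0.5,
    seed: int = 0,
    effect_log2: float = 2.0,
    beta_noise_sd: float = 0.01,
    expr_sd: float = 0.5,
    n_reps: int = 4,
) -> ArrayData:
    """Promoter beta values and log2 expression with planted effects.

    Control betas are a bimodal mixture concentrated below 0.2 and above 0.8.
    Planted demethylated genes have all their probes start above 0.8 and drop
    by at least 0.25 under treatment (in both siRNA conditions — knockdown of
    the remodeler barely touches methylation).  Planted reactivated genes — a
    subset of the demethylated ones — gain ``effect_log2`` under treatment in
    the control-siRNA condition and ``kd_attenuation`` times that under
    knockdown.
    """
    if not 0.0 <= kd_attenuation <= 1.0:
        raise ValueError(f"kd_attenuation={kd_attenuation} outside [0, 1]")
    n_genes = n_probes // 2
    if n_genes_planted_demeth > n_genes:
        raise ValueError("more planted demethylated genes than genes")
    if n_genes_planted_reactivated > n_genes_planted_demeth:
        raise ValueError("reactivated genes must be a subset of demethylated genes")

    rng = np.random.default_rng([seed, 505])
    probes = [f"cg{i:06d}" for i in range(n_probes)]
    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    probe_gene = [genes[min(i // 2, n_genes - 1)] for i in range(n_probes)]

    demeth_genes = sorted(
        rng.choice(n_genes, size=n_genes_planted_demeth, replace=False)
    )
    demeth_gene_set = {genes[i] for i in demeth_genes}
    demeth_probe_mask = np.array(
        [g in demeth_gene_set for g in probe_gene]
    )
    react_genes = sorted(
        rng.choice(demeth_genes, size=n_genes_planted_reactivated, replace=False)
    )
    react_gene_set = {genes[i] for i in react_genes}

    # Control betas: bimodal mixture; planted probes forced hypermethylated.
    lo = rng.beta(2, 20, size=n_probes)
    hi = rng.beta(20, 2, size=n_probes)
    pick_hi = rng.random(n_probes) < 0.5
    beta_ctrl = np.where(pick_hi, hi, lo)
    beta_ctrl[demeth_probe_mask] = 0.82 + 0.16 * rng.random(demeth_probe_mask.sum())

    def noisy(x: np.ndarray) -> np.ndarray:
        return np.clip(x + rng.normal(0, beta_noise_sd, size=x.shape), 0.0, 1.0)

    drops_nc = 0.30 + 0.40 * rng.random(demeth_probe_mask.sum())
    drops_kd = 0.30 + 0.40 * rng.random(demeth_probe_mask.sum())
    nc_pbs = noisy(beta_ctrl)
    kd_pbs = noisy(beta_ctrl)
    nc_aza = beta_ctrl.copy()
    nc_aza[demeth_probe_mask] -= drops_nc
    nc_aza = noisy(nc_aza)
    kd_aza = beta_ctrl.copy()
    kd_aza[demeth_probe_mask] -= drops_kd
    kd_aza = noisy(kd_aza)

    betas = pd.DataFrame(
        {
            "gene": probe_gene,
            "NC_PBS": nc_pbs,
            "NC_Aza": nc_aza,
            "KD_PBS": kd_pbs,
            "KD_Aza": kd_aza,
        },
        index=pd.Index(probes, name="probe_id"),
    )

    # Expression: one transcript per gene, a second for every third
    # reactivated gene (reactivated genes are often probed by >1 transcript).
    transcripts: list[str] = []
    tx_gene: list[str] = []
    for i, g in enumerate(genes):
        transcripts.append(f"TX{i:05d}_1")
        tx_gene.append(g)
    for k, gi in enumerate(react_genes):
        if k % 3 == 0:
            transcripts.append(f"TX{gi:05d}_2")
            tx_gene.append(genes[gi])
    react_tx_mask = np.array([g in react_gene_set for g in tx_gene])

    baseline = rng.normal(8.0, 1.0, size=len(transcripts))
    cols = {}
    sample_rows = []
    for sirna in ("NC", "KD"):
        for treat in ("PBS", "Aza"):
            shift = np.zeros(len(transcripts))
            if treat == "Aza":
                eff = effect_log2 * (kd_attenuation if sirna == "KD" else 1.0)
                shift[react_tx_mask] = eff
            for r in range(1, n_reps + 1):
                name = f"{sirna}_{treat}_r{r}"
                cols[name] = baseline + shift + rng.normal(
                    0, expr_sd, size=len(transcripts)
                )
                sample_rows.append(
                    {"sample": name, "sirna": sirna, "treatment": treat}
                )
    expr = pd.DataFrame(
        {"gene": tx_gene, **cols}, index=pd.Index(transcripts, name="transcript_id")
    )
    samples = pd.DataFrame(sample_rows).set_index("sample")

    truth = {
        "demeth_genes": sorted(demeth_gene_set),
        "demeth_probes": [p for p, m in zip(probes, demeth_probe_mask) if m],
        "react_genes": sorted(react_gene_set),
        "react_transcripts": [
            t for t, m in zip(transcripts, react_tx_mask) if m
        ],
        "effect_log2": effect_log2,
        "kd_attenuation": kd_attenuation,
    }
    return ArrayData(betas, expr, samples, truth)


__all__ = [
    "NUCLEOSOME_BP",
    "BETA_CONDITIONS",
    "SimulationConfig",
    "DuplexMolecule",
    "ArrayData",
    "duplex_class",
    "class_fractions",
    "example_amplicon",
    "find_ccgg_internal_cpgs",
    "simulate_timecourse",
    "apply_remodeling",
    "apply_mcvipi",
    "treat_pool_with_mcvipi",
    "bisulfite_reads",
    "write_clones_fasta",
    "write_table",
    "generate_array_data",
]
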