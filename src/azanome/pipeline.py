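"""End-to-end orchestration: simulate → call → footprint → hemi → arrays.

Each stage is a plain function over the library types; ``run_pipeline``
chains them for one seed, writes every artifact as a text table and records
a manifest (inputs, seed, per-stage output hashes).  Reruns with the same
seed reproduce every artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import array_stats, footprint, hemimethylation, nome_core, synthetic_data
from .footprint import NDRWindow
from .nome_core import AmpliconReference, CloneCallSet, SiteAnnotation
from .synthetic_data import SimulationConfig

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters for one reproducible pipeline run."""

    out_dir: Path
    seed: int = 0
    analysis_day: int = 2
    n_clones: int = 300
    qc_min_conversion: float = 0.95
    min_span_bp: int = footprint.NDR_MIN_SPAN_BP
    delta_beta: float = 0.25
    q_cutoff: float = 0.05
    n_perm: int = 1000
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        self.simulation = replace(self.simulation, seed=self.seed)
        if self.analysis_day not in self.simulation.days:
            raise ValueError(
                f"analysis_day {self.analysis_day} not in simulated days "
                f"{self.simulation.days}"
            )


def default_window(reference: AmpliconReference, half_width: int = 100) -> NDRWindow:
    """TSS-centred promoter window [tss-100, tss+100)."""
    return NDRWindow(
        reference.tss - half_width, reference.tss + half_width,
        label=f"TSS±{half_width}",
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def callsets_to_table(
    callsets: Sequence[CloneCallSet], annotation: SiteAnnotation
) -> pd.DataFrame:
    """One row per clone, one column per site, symbols {M,U,A,I,·}."""
    hcg_sym = {"methylated": "M", "unmethylated": "U", "missing": "·"}
    gch_sym = {"accessible": "A", "inaccessible": "I", "missing": "·"}
    cols = sorted(annotation.hcg_sites + annotation.gch_sites)
    rows = []
    for cs in callsets:
        by_pos = {
            p: hcg_sym[c] for p, c in zip(annotation.hcg_sites, cs.hcg_calls)
        }
        by_pos.update(
            {p: gch_sym[c] for p, c in zip(annotation.gch_sites, cs.gch_calls)}
        )
        row = {"clone_id": cs.clone_id, "strand": cs.strand}
        row.update({str(p): by_pos[p] for p in cols})
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_stage(cfg: RunConfig, region: AmpliconReference) -> dict:
    """Replication time course; returns snapshots and the class-kinetics table."""
    snaps = synthetic_data.simulate_timecourse(cfg.simulation, region)
    rows = []
    for day, pool in snaps.items():
        fr = synthetic_data.class_fractions(pool)
        rows.append({"day": day, **fr})
    table = pd.DataFrame(rows)
    return {"snapshots": snaps, "class_table": table}


def nome_stage(
    cfg: RunConfig,
    region: AmpliconReference,
    annotation: SiteAnnotation,
    window: NDRWindow,
    molecules,
    srcap_kd: bool = False,
) -> dict:
    """Remodel, treat with the GpC enzyme, emit clone reads, call clones."""
    sim = replace(cfg.simulation, srcap_kd=srcap_kd)
    remodeled = synthetic_data.apply_remodeling(
        molecules, sim, window, region_length=len(region)
    )
    flags = synthetic_data.treat_pool_with_mcvipi(remodeled, annotation, sim)
    records, truth = synthetic_data.bisulfite_reads(
        remodeled, flags, region, annotation, sim, cfg.n_clones
    )
    callsets = [
        nome_core.call_clone(
            read, region, annotation, cfg.qc_min_conversion, clone_id=cid
        )
        for cid, read in records
    ]
    n_fail = sum(not cs.passed_qc for cs in callsets)
    if n_fail:
        log.warning("%d/%d clones failed conversion QC", n_fail, len(callsets))
    passed = [cs for cs in callsets if cs.passed_qc]
    return {
        "molecules": remodeled,
        "gch_flags": flags,
        "records": records,
        "truth": truth,
        "callsets": passed,
        "n_qc_fail": n_fail,
    }


def footprint_stage(
    cfg: RunConfig,
    callsets: Sequence[CloneCallSet],
    annotation: SiteAnnotation,
    window: NDRWindow,
    region: AmpliconReference,
    condition: str,
) -> dict:
    ndr = footprint.ndr_fraction(callsets, annotation, window, cfg.min_span_bp)
    depletion = footprint.window_depletion_fraction(
        callsets, annotation, window, cfg.min_span_bp
    )
    segments = {
        cs.clone_id: footprint.segment_clone(cs, annotation) for cs in callsets
    }
    summary = pd.DataFrame(
        [
            {
                "region": region.region_id,
                "condition": condition,
                "statistic": name,
                "k": st.k,
                "n": st.n,
                "fraction": st.fraction,
                "ci_low": st.ci_low,
                "ci_high": st.ci_high,
            }
            for name, st in (("ndr", ndr), ("window_depletion", depletion))
        ]
    )
    return {"ndr": ndr, "depletion": depletion, "segments": segments, "summary": summary}


def hemi_stage(cfg: RunConfig, region: AmpliconReference, snapshots: dict) -> dict:
    """Forward Hpa II measurement + U/H/F deconvolution per simulated day."""
    site = synthetic_data.find_ccgg_internal_cpgs(region)[0]
    rows = []
    for day, pool in snapshots.items():
        m0 = hemimethylation.measure_snupe(pool, site)
        survivors = hemimethylation.digest_hpaii(pool, [site], region)
        idx = pool[0].cpg_positions.index(site)
        true = {
            "U": np.mean(
                [not m.top_meth[idx] and not m.bottom_meth[idx] for m in pool]
            ),
            "H": np.mean(
                [bool(m.top_meth[idx]) != bool(m.bottom_meth[idx]) for m in pool]
            ),
            "F": np.mean(
                [bool(m.top_meth[idx]) and bool(m.bottom_meth[idx]) for m in pool]
            ),
        }
        if not survivors:
            rows.append(
                {"day": day, "m0": m0, "m1": float("nan"),
                 "U": float("nan"), "H": float("nan"), "F": float("nan"),
                 "true_U": true["U"], "true_H": true["H"], "true_F": true["F"],
                 "estimated": False}
            )
            continue
        m1 = hemimethylation.measure_snupe(survivors, site)
        est = hemimethylation.deconvolve_uhf(
            hemimethylation.SnupeMeasurement(m0, m1)
        )
        rows.append(
            {
                "day": day, "m0": m0, "m1": m1,
                "U": est.U, "H": est.H, "F": est.F,
                "true_U": true["U"], "true_H": true["H"], "true_F": true["F"],
                "estimated": True,
            }
        )
    return {"site": site, "table": pd.DataFrame(rows)}


def arrays_stage(cfg: RunConfig, kd_attenuation: float = 0.5) -> dict:
    """Array-scale analysis: demethylation calls, SAM, overlap, reactivation."""
    data = synthetic_data.generate_array_data(
        kd_attenuation=kd_attenuation, seed=cfg.seed
    )
    betas, expr = data.betas, data.expr
    gene_map = betas["gene"]
    demeth_nc = array_stats.call_demethylated(
        betas["NC_PBS"], betas["NC_Aza"], gene_map, delta=cfg.delta_beta
    )
    demeth_kd = array_stats.call_demethylated(
        betas["KD_PBS"], betas["KD_Aza"], gene_map, delta=cfg.delta_beta
    )

    def _sam(sirna: str) -> array_stats.SamResult:
        cols = [
            s for s in data.samples.index if data.samples.loc[s, "sirna"] == sirna
        ]
        labels = [data.samples.loc[s, "treatment"] for s in cols]
        return array_stats.sam_two_class(
            expr[cols], labels, n_perm=cfg.n_perm, q_cutoff=cfg.q_cutoff,
            seed=cfg.seed, group_order=("PBS", "Aza"),
        )

    sam_nc, sam_kd = _sam("NC"), _sam("KD")
    tx_gene = expr["gene"]
    up_genes_nc = {
        tx_gene[t] for t in sam_nc.significant if sam_nc.scores[t] > 0
    }
    up_genes_kd = {
        tx_gene[t] for t in sam_kd.significant if sam_kd.scores[t] > 0
    }
    overlap = (
        array_stats.overlap_fraction(up_genes_nc, up_genes_kd, "A")
        if up_genes_nc
        else {"fraction": float("nan")}
    )

    # Reactivated-and-demethylated genes: per-gene log2 fold change by siRNA.
    react_demeth = sorted(up_genes_nc & set(demeth_nc.genes))

    def _gene_fc(sirna: str) -> pd.Series:
        cols_t = data.samples.query(
            "sirna == @sirna and treatment == 'Aza'"
        ).index
        cols_c = data.samples.query(
            "sirna == @sirna and treatment == 'PBS'"
        ).index
        fc = expr[list(cols_t)].mean(axis=1) - expr[list(cols_c)].mean(axis=1)
        return fc.groupby(tx_gene).mean().loc[react_demeth]

    comparison = (
        array_stats.reactivation_comparison(_gene_fc("NC"), _gene_fc("KD"))
        if len(react_demeth) >= 5
        else None
    )
    cluster_order = None
    if react_demeth:
        probes = betas.index[betas["gene"].isin(react_demeth)]
        sub = betas.loc[probes, list(synthetic_data.BETA_CONDITIONS)]
        if len(sub) >= 2:
            cluster_order, _ = array_stats.cluster_rows(sub)
    return {
        "data": data,
        "demeth_nc": demeth_nc,
        "demeth_kd": demeth_kd,
        "sam_nc": sam_nc,
        "sam_kd": sam_kd,
        "up_genes_nc": up_genes_nc,
        "up_genes_kd": up_genes_kd,
        "overlap": overlap,
        "react_demeth_genes": react_demeth,
        "reactivation": comparison,
        "cluster_order": cluster_order,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in dependency order and write a run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "outputs": {}}
    seed = cfg.seed
    region = synthetic_data.example_amplicon()
    annotation = nome_core.annotate_sites(region)
    window = default_window(region)

    def _write_table(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        synthetic_data.write_table(df, path, seed, index=index)
        manifest["outputs"][name] = _sha256(path)

    # 1. simulate
    sim = simulate_stage(cfg, region)
    _write_table(sim["class_table"], "timecourse_classes.tsv")
    manifest["stages"]["simulate"] = "complete"

    # 2. nome (NC and KD conditions at the analysis day)
    pool = sim["snapshots"][cfg.analysis_day]
    nome = {}
    for label, kd in (("NC", False), ("KD", True)):
        res = nome_stage(cfg, region, annotation, window, pool, srcap_kd=kd)
        nome[label] = res
        fasta = out / f"clones_{label}.fasta"
        synthetic_data.write_clones_fasta(res["records"], fasta, seed)
        manifest["outputs"][fasta.name] = _sha256(fasta)
        _write_table(res["truth"], f"clone_truth_{label}.tsv")
        _write_table(
            callsets_to_table(res["callsets"], annotation),
            f"clone_calls_{label}.tsv",
        )
    manifest["stages"]["nome"] = "complete"

    # 3. footprint (demethylated-strand selection per condition)
    summaries = []
    for label in ("NC", "KD"):
        selected = nome_core.filter_demethylated_strands(
            nome[label]["callsets"], region, annotation
        )
        if selected:
            fp = footprint_stage(
                cfg, selected, annotation, window, region, label
            )
            summaries.append(fp["summary"])
            bed = out / f"segments_{label}.bed"
            bed.write_text(
                footprint.segments_to_bed(fp["segments"], region.region_id)
            )
            manifest["outputs"][bed.name] = _sha256(bed)
    if summaries:
        _write_table(pd.concat(summaries, ignore_index=True), "footprint_summary.tsv")
    manifest["stages"]["footprint"] = "complete"

    # 4. hemimethylation
    hemi = hemi_stage(cfg, region, sim["snapshots"])
    _write_table(hemi["table"], "hemimethylation.tsv")
    manifest["stages"]["hemi"] = "complete"

    # 5. arrays
    arr = arrays_stage(cfg)
    _write_table(
        pd.DataFrame({"probe_id": arr["demeth_nc"].probes}), "demethylated_probes_NC.tsv"
    )
    summary = {
        "demethylated_probes_NC": len(arr["demeth_nc"].probes),
        "demethylated_genes_NC": len(arr["demeth_nc"].genes),
        "demethylated_probes_KD": len(arr["demeth_kd"].probes),
        "demethylated_genes_KD": len(arr["demeth_kd"].genes),
        "upregulated_genes_NC": len(arr["up_genes_nc"]),
        "upregulated_transcripts_NC": len(arr["sam_nc"].significant),
        "upregulated_genes_KD": len(arr["up_genes_kd"]),
        "upregulated_transcripts_KD": len(arr["sam_kd"].significant),
        "overlap_fraction": arr["overlap"]["fraction"],
        "reactivated_demethylated_genes": len(arr["react_demeth_genes"]),
    }
    if arr["reactivation"] is not None:
        summary["reactivation_median_difference"] = arr[
            "reactivation"
        ].median_difference
        summary["reactivation_p_value"] = arr["reactivation"].p_value
    path = out / "array_summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    manifest["outputs"][path.name] = _sha256(path)
    manifest["stages"]["arrays"] = "complete"

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


__all__ = [
    "RunConfig",
    "default_window",
    "callsets_to_table",
    "simulate_stage",
    "nome_stage",
    "footprint_stage",
    "hemi_stage",
    "arrays_stage",
    "run_pipeline",
]
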