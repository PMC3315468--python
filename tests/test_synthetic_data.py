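"""Replication kinetics, remodeling rules, enzyme treatment, read chemistry."""

from dataclasses import replace

import numpy as np
import pytest

from azanome.footprint import NDRWindow
from azanome.nome_core import annotate_sites
from azanome.synthetic_data import (
    DuplexMolecule,
    SimulationConfig,
    apply_mcvipi,
    apply_remodeling,
    bisulfite_reads,
    class_fractions,
    duplex_class,
    generate_array_data,
    simulate_timecourse,
    treat_pool_with_mcvipi,
)


def _mol(region, top, bottom, occupancy=(), mol_id="m0"):
    cpgs = region.cpg_positions()
    return DuplexMolecule(
        region.region_id,
        cpgs,
        np.full(len(cpgs), top, dtype=bool),
        np.full(len(cpgs), bottom, dtype=bool),
        occupancy,
        molecule_id=mol_id,
    )


# ---------------------------------------------------------------------------
# Replication time course


def _enumeration_oracle(k):
    """Exact duplex-class distribution after k fully inhibited divisions.

    Tracks (top, bottom) strand methylation states with population weights;
    each division replaces a duplex by two equal-weight daughters, each
    keeping one parental strand and gaining an unmethylated strand.
    """
    pop = {(True, True): 1.0}
    for _ in range(k):
        nxt = {}
        for (t, b), w in pop.items():
            for child in [(t, False), (False, b)]:
                nxt[child] = nxt.get(child, 0.0) + w / 2
        pop = nxt
    frac = {"U": 0.0, "H": 0.0, "F": 0.0}
    for (t, b), w in pop.items():
        key = "F" if t and b else ("U" if not (t or b) else "H")
        frac[key] += w
    return frac


@pytest.mark.parametrize("k", [1, 2, 3, 4])
def test_full_inhibition_matches_enumeration(region, k):
    """Semiconservative dilution: hemi fraction 2^(1-k), no fully methylated."""
    oracle = _enumeration_oracle(k)
    assert oracle["H"] == pytest.approx(2.0 ** (1 - k))
    assert oracle["F"] == 0.0 if k >= 1 else 1.0
    n = 10_000
    cfg = SimulationConfig(
        n_molecules=n,
        days=tuple(range(k + 1)),
        incorporation_prob=1.0,
        remethylation_prob=0.0,
        washout_day=10,
        seed=3,
    )
    frac = class_fractions(simulate_timecourse(cfg, region)[k])
    for key in "UHF":
        p = oracle[key]
        # resampling across generations inflates variance mildly beyond the
        # final binomial draw; 3 SD plus the accumulated bottleneck term
        sd = np.sqrt(max(p * (1 - p), 0.25 / 4) / n) * np.sqrt(1 + k / 2)
        assert abs(frac[key] - p) <= 3 * sd, (key, frac[key], p)


def test_no_inhibition_stays_fully_methylated(region):
    cfg = SimulationConfig(
        n_molecules=200, days=(0, 1, 2, 3), incorporation_prob=0.0, seed=1
    )
    snaps = simulate_timecourse(cfg, region)
    for day, pool in snaps.items():
        assert class_fractions(pool)["F"] == 1.0


def test_one_division_full_inhibition_all_hemi(region):
    cfg = SimulationConfig(
        n_molecules=200, days=(0, 1), incorporation_prob=1.0, seed=1
    )
    assert class_fractions(simulate_timecourse(cfg, region)[1])["H"] == 1.0


def test_class_fractions_sum_to_one_every_day(region):
    cfg = SimulationConfig(n_molecules=400, days=(0, 1, 2, 3, 5), seed=9)
    for pool in simulate_timecourse(cfg, region).values():
        fr = class_fractions(pool)
        assert fr["U"] + fr["H"] + fr["F"] + fr["M"] == pytest.approx(1.0)


def test_timecourse_reproducible_and_rejects_bad_input(region):
    cfg = SimulationConfig(n_molecules=50, days=(0, 2), seed=42)
    a = simulate_timecourse(cfg, region)
    b = simulate_timecourse(cfg, region)
    for day in a:
        for ma, mb in zip(a[day], b[day]):
            assert np.array_equal(ma.top_meth, mb.top_meth)
            assert np.array_equal(ma.bottom_meth, mb.bottom_meth)
    with pytest.raises(ValueError, match="negative day"):
        SimulationConfig(days=(-1, 0))
    from azanome.nome_core import AmpliconReference

    no_cpg = AmpliconReference("x", "ATTATTATTA", 2)
    with pytest.raises(ValueError, match="no CpG"):
        simulate_timecourse(cfg, no_cpg)


def test_remethylation_restores_methylation_after_washout(region):
    """Post-washout de novo remethylation acts on newly synthesised strands:
    every division converts half the hemi duplexes back to fully methylated,
    while retained unmethylated parental strands keep the rest hemi."""
    cfg = SimulationConfig(
        n_molecules=2000,
        days=(0, 1, 5),
        incorporation_prob=1.0,
        remethylation_prob=1.0,
        washout_day=1,
        seed=2,
    )
    frac = class_fractions(simulate_timecourse(cfg, region)[5])
    # after the drug-era division all duplexes are hemi; 4 post-washout
    # divisions leave 2^-4 of them hemi, the rest fully remethylated
    assert frac["F"] == pytest.approx(1 - 2.0**-4, abs=0.02)
    assert frac["H"] == pytest.approx(2.0**-4, abs=0.02)
    assert frac["U"] == 0.0


# ---------------------------------------------------------------------------
# Remodeling


def test_remodeling_branches(region, window):
    cfg = SimulationConfig(p_ndr=1.0, srcap_kd_factor=1.0, linker_bp=0, seed=0)
    full = _mol(region, True, True)
    hemi = _mol(region, True, False)
    sym = _mol(region, False, False)
    out = apply_remodeling(
        [full, hemi, sym], cfg, window, region_length=len(region)
    )
    # methylated and hemimethylated duplexes: no gap, window occupied
    for mol in out[:2]:
        assert not mol.has_ndr
        covered = np.zeros(len(region), dtype=bool)
        for s, e in mol.occupancy:
            covered[s:e] = True
        assert covered[window.start : window.end].all()
    # symmetrically demethylated duplex at p_ndr=1: gap covering the window
    assert out[2].has_ndr
    for s, e in out[2].occupancy:
        assert e <= window.start or s >= window.end


def test_ndr_gaps_only_on_symmetric_unmethylated(region, window):
    cfg = SimulationConfig(n_molecules=500, days=(0, 2), p_ndr=0.7, seed=5)
    pool = simulate_timecourse(cfg, region)[2]
    out = apply_remodeling(pool, cfg, window, region_length=len(region))
    for mol in out:
        if mol.has_ndr:
            assert duplex_class(mol) == "U"
            for s, e in mol.occupancy:
                assert e <= window.start or s >= window.end
        # occupancy intervals are disjoint and in range
        ivals = sorted(mol.occupancy)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            assert e1 <= s2
        assert all(0 <= s < e <= len(region) for s, e in ivals)


def test_srcap_kd_attenuates_gap_probability(region, window):
    cfg = SimulationConfig(
        n_molecules=4000, days=(0, 1, 2), incorporation_prob=1.0,
        p_ndr=0.5, srcap_kd_factor=0.5, seed=8,
    )
    pool = simulate_timecourse(cfg, region)[2]
    nc = apply_remodeling(pool, cfg, window, region_length=len(region))
    kd = apply_remodeling(
        pool, replace(cfg, srcap_kd=True), window, region_length=len(region)
    )
    n_u = sum(duplex_class(m) == "U" for m in pool)
    f_nc = sum(m.has_ndr for m in nc) / n_u
    f_kd = sum(m.has_ndr for m in kd) / n_u
    assert f_nc == pytest.approx(0.5, abs=0.05)
    assert f_kd / f_nc == pytest.approx(0.5, abs=0.12)


def test_remodeling_rejects_window_outside_region(region):
    cfg = SimulationConfig(seed=0)
    mol = _mol(region, True, True)
    with pytest.raises(ValueError, match="outside"):
        apply_remodeling([mol], cfg, NDRWindow(0, 10_000), region_length=len(region))


# ---------------------------------------------------------------------------
# GpC methyltransferase


def test_mcvipi_full_efficiency_no_occupancy(region, annotation, rng):
    mol = _mol(region, True, True)
    top, bottom = apply_mcvipi(mol, annotation, 1.0, rng)
    assert top.all() and bottom.all()


def test_mcvipi_fully_occupied_never_marked(region, annotation, rng):
    mol = _mol(region, True, True, occupancy=((0, len(region)),))
    top, bottom = apply_mcvipi(mol, annotation, 1.0, rng)
    assert not top.any() and not bottom.any()


def test_mcvipi_efficiency_is_binomial(region, annotation, rng):
    """Across many accessible draws the marked fraction tracks efficiency."""
    mol = _mol(region, True, True)
    eff, draws = 0.9, []
    for _ in range(40):
        top, bottom = apply_mcvipi(mol, annotation, eff, rng)
        draws.extend([top.mean(), bottom.mean()])
    n = 80 * len(annotation.gch_sites)
    assert np.mean(draws) == pytest.approx(eff, abs=3 * np.sqrt(eff * (1 - eff) / n))


# ---------------------------------------------------------------------------
# Bisulfite reads


def test_unmethylated_strand_fully_converts(region, annotation):
    cfg = SimulationConfig(
        conversion_rate=1.0, inappropriate_conversion=0.0, seed=0
    )
    mol = _mol(region, False, False)
    flags = {
        "m0": (
            np.zeros(len(annotation.gch_sites), bool),
            np.zeros(len(annotation.gch_sites), bool),
        )
    }
    records, truth = bisulfite_reads(
        [mol], flags, region, annotation, cfg, 2, seed=1
    )
    by_strand = dict(zip(truth["strand"], [r for _, r in records]))
    assert "C" not in by_strand["top"]
    assert "G" not in by_strand["bottom"]


def test_methylated_cpgs_resist_conversion(region, annotation):
    cfg = SimulationConfig(
        conversion_rate=1.0, inappropriate_conversion=0.0, seed=0
    )
    mol = _mol(region, True, True)
    flags = {
        "m0": (
            np.zeros(len(annotation.gch_sites), bool),
            np.zeros(len(annotation.gch_sites), bool),
        )
    }
    records, truth = bisulfite_reads(
        [mol], flags, region, annotation, cfg, 2, seed=1
    )
    by_strand = dict(zip(truth["strand"], [r for _, r in records]))
    top = by_strand["top"]
    cpgs = set(region.cpg_positions())
    for i, b in enumerate(region.sequence):
        if b == "C":
            assert top[i] == ("C" if i in cpgs else "T")


def test_bisulfite_rejects_bad_clone_counts(region, annotation, config):
    mol = _mol(region, True, True)
    flags = {"m0": (np.zeros(30, bool), np.zeros(30, bool))}
    with pytest.raises(ValueError, match="positive"):
        bisulfite_reads([mol], flags, region, annotation, config, 0)
    with pytest.raises(ValueError, match="exceeds"):
        bisulfite_reads([mol], flags, region, annotation, config, 3)


def test_reads_reproducible_under_seed(region, annotation, window):
    cfg = SimulationConfig(n_molecules=40, days=(0, 2), seed=21)
    pool = simulate_timecourse(cfg, region)[2]
    pool = apply_remodeling(pool, cfg, window, region_length=len(region))
    flags = treat_pool_with_mcvipi(pool, annotate_sites(region), cfg)
    a = bisulfite_reads(pool, flags, region, annotate_sites(region), cfg, 30)
    b = bisulfite_reads(pool, flags, region, annotate_sites(region), cfg, 30)
    assert a[0] == b[0]
    assert a[1].equals(b[1])


# ---------------------------------------------------------------------------
# Array generator


def test_array_kd_attenuation_one_matches_nc_in_expectation():
    data = generate_array_data(
        n_probes=1000, n_genes_planted_demeth=50,
        n_genes_planted_reactivated=20, kd_attenuation=1.0, seed=4,
    )
    react = data.truth["react_transcripts"]
    nc = data.expr.loc[react, [c for c in data.expr if c.startswith("NC_Aza")]]
    kd = data.expr.loc[react, [c for c in data.expr if c.startswith("KD_Aza")]]
    # same planted shift: mean difference within noise of zero
    se = 0.5 * np.sqrt(2 / nc.size)
    assert abs(nc.values.mean() - kd.values.mean()) < 4 * se


def test_array_planted_demethylation_exact_when_noise_free():
    from azanome.array_stats import call_demethylated

    data = generate_array_data(
        n_probes=2000, n_genes_planted_demeth=25,
        n_genes_planted_reactivated=10, kd_attenuation=0.5,
        beta_noise_sd=0.0, seed=6,
    )
    call = call_demethylated(
        data.betas["NC_PBS"], data.betas["NC_Aza"], data.betas["gene"]
    )
    assert sorted(call.probes) == sorted(data.truth["demeth_probes"])
    assert sorted(call.genes) == sorted(data.truth["demeth_genes"])


def test_array_generator_validates_inputs():
    with pytest.raises(ValueError, match="kd_attenuation"):
        generate_array_data(kd_attenuation=1.5)
    with pytest.raises(ValueError, match="planted"):
        generate_array_data(n_probes=10, n_genes_planted_demeth=50)
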