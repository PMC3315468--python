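"""Hpa II digestion rules and U/H/F deconvolution."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from azanome.hemimethylation import (
    InfeasibleMeasurementError,
    SnupeMeasurement,
    classify_duplex,
    deconvolve_uhf,
    digest_hpaii,
    forward_model,
    measure_snupe,
    select_hemimethylated_strands,
)
from azanome.synthetic_data import (
    DuplexMolecule,
    SimulationConfig,
    apply_remodeling,
    find_ccgg_internal_cpgs,
    simulate_timecourse,
    treat_pool_with_mcvipi,
)


@pytest.mark.parametrize(
    "top,bottom,expected",
    [(False, False, "U"), (True, False, "H"), (False, True, "H"), (True, True, "F")],
)
def test_classify_duplex(top, bottom, expected):
    assert classify_duplex(top, bottom) == expected


def _site_mol(region, states, mol_id="m"):
    """Molecule with given (top, bottom) state at each CCGG internal CpG and
    fully methylated elsewhere."""
    cpgs = region.cpg_positions()
    sites = find_ccgg_internal_cpgs(region)
    top = np.ones(len(cpgs), bool)
    bottom = np.ones(len(cpgs), bool)
    for site, (t, b) in zip(sites, states):
        i = cpgs.index(site)
        top[i], bottom[i] = t, b
    return DuplexMolecule(region.region_id, cpgs, top, bottom, molecule_id=mol_id)


def test_digestion_rule_exhaustive(region):
    """Only duplexes unmethylated on both strands at >=1 CCGG site are cut,
    over every duplex state at every combination of listed sites."""
    site = find_ccgg_internal_cpgs(region)[0]
    states = [(False, False), (True, False), (False, True), (True, True)]
    for st_ in states:
        mol = _site_mol(region, [st_])
        survivors = digest_hpaii([mol], [site], region)
        destroyed = st_ == (False, False)
        assert (len(survivors) == 0) is destroyed
        if survivors:
            assert survivors[0] is mol  # unchanged, same object


def test_digestion_multiple_sites_cut_anywhere():
    """With several CCGG sites a single fully unmethylated one destroys the
    molecule; enumerated exhaustively over 3-site state configurations."""
    from azanome.nome_core import AmpliconReference

    seq = "TTAACCGGTTAACCGGTTAACCGGTTAA"
    region = AmpliconReference("multi", seq, 0)
    sites = find_ccgg_internal_cpgs(region)
    assert len(sites) == 3
    states = [(False, False), (True, False), (False, True), (True, True)]
    for combo in itertools.product(states, repeat=3):
        mol = _site_mol(region, combo)
        survivors = digest_hpaii([mol], sites, region)
        should_cut = any(s == (False, False) for s in combo)
        assert (len(survivors) == 0) is should_cut


def test_digestion_rejects_non_ccgg_position(region):
    not_ccgg = region.cpg_positions()[0]
    mol = _site_mol(region, [(True, True)])
    with pytest.raises(ValueError, match="CCGG"):
        digest_hpaii([mol], [not_ccgg], region)


@pytest.mark.parametrize(
    "m0,m1,expected",
    [
        (1.0, 1.0, (0.0, 0.0, 1.0)),
        (0.5, 0.5, (0.0, 1.0, 0.0)),
        (0.4, 2.0 / 3.0, (0.4, 0.4, 0.2)),
    ],
)
def test_deconvolution_examples(m0, m1, expected):
    est = deconvolve_uhf(SnupeMeasurement(m0, m1))
    assert (est.U, est.H, est.F) == pytest.approx(expected, abs=1e-12)


def test_deconvolution_grid_identity():
    """forward-model -> deconvolve recovers every simplex point to 1e-9."""
    step = 0.05
    grid = np.arange(0.0, 1.0 + 1e-12, step)
    checked = 0
    for u in grid:
        for h in grid:
            f = 1.0 - u - h
            if f < -1e-12 or h + f <= 0:
                continue
            f = max(f, 0.0)
            meas = forward_model(u, h, f)
            assert meas.m_digested >= 0.5 - 1e-12
            est = deconvolve_uhf(meas)
            assert abs(est.U - u) < 1e-9
            assert abs(est.H - h) < 1e-9
            assert abs(est.F - f) < 1e-9
            checked += 1
    assert checked > 200


@given(
    st.tuples(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)
    ).filter(lambda t: sum(t) > 0 and t[1] + t[2] > 1e-6)
)
@settings(max_examples=200, deadline=None)
def test_deconvolution_identity_property(raw):
    total = sum(raw)
    u, h, f = (v / total for v in raw)
    est = deconvolve_uhf(forward_model(u, h, f))
    assert est.U == pytest.approx(u, abs=1e-8)
    assert est.H == pytest.approx(h, abs=1e-8)
    assert est.F == pytest.approx(f, abs=1e-8)


def test_deconvolution_rejects_infeasible():
    with pytest.raises(InfeasibleMeasurementError, match="1/2"):
        deconvolve_uhf(SnupeMeasurement(0.2, 0.4))
    with pytest.raises(InfeasibleMeasurementError):
        deconvolve_uhf(SnupeMeasurement(0.9, 0.0))
    with pytest.raises(InfeasibleMeasurementError, match="lower"):
        deconvolve_uhf(SnupeMeasurement(0.9, 0.6))


def test_digest_survivors_are_subset_unchanged(region):
    cfg = SimulationConfig(n_molecules=300, days=(0, 2), seed=17)
    pool = simulate_timecourse(cfg, region)[2]
    site = find_ccgg_internal_cpgs(region)[0]
    survivors = digest_hpaii(pool, [site], region)
    ids = {m.molecule_id for m in pool}
    assert all(m.molecule_id in ids for m in survivors)
    assert len(survivors) <= len(pool)
    idx = pool[0].cpg_positions.index(site)
    for m in survivors:
        assert m.top_meth[idx] or m.bottom_meth[idx]


def test_pool_measurement_deconvolution_is_exact(region):
    """On a finite pool the digestion+readout inversion is exact, because the
    model equations hold identically for empirical fractions."""
    cfg = SimulationConfig(n_molecules=500, days=(0, 1, 2), seed=23)
    pool = simulate_timecourse(cfg, region)[2]
    site = find_ccgg_internal_cpgs(region)[0]
    idx = pool[0].cpg_positions.index(site)
    m0 = measure_snupe(pool, site)
    survivors = digest_hpaii(pool, [site], region)
    m1 = measure_snupe(survivors, site)
    est = deconvolve_uhf(SnupeMeasurement(m0, m1))
    u = np.mean([not m.top_meth[idx] and not m.bottom_meth[idx] for m in pool])
    h = np.mean([bool(m.top_meth[idx]) != bool(m.bottom_meth[idx]) for m in pool])
    assert est.U == pytest.approx(u, abs=1e-9)
    assert est.H == pytest.approx(h, abs=1e-9)


def test_selected_strands_are_all_hemimethylated(region, annotation, window):
    """Hpa II pre-digestion + demethylation-selective primers leave only
    strands from hemimethylated duplexes."""
    cfg = SimulationConfig(
        n_molecules=400, days=(0, 1, 2), seed=31,
        conversion_rate=1.0, inappropriate_conversion=0.0, mcvipi_efficiency=1.0,
    )
    pool = simulate_timecourse(cfg, region)[2]
    pool = apply_remodeling(pool, cfg, window, region_length=len(region))
    flags = treat_pool_with_mcvipi(pool, annotation, cfg)
    sites = find_ccgg_internal_cpgs(region)
    callsets, truth = select_hemimethylated_strands(
        pool, flags, region, annotation, sites, cfg, n_clones=200
    )
    assert len(callsets) > 0
    assert set(truth["duplex_class"]) == {"H"}


def test_pure_pools(region, annotation, window):
    """All-symmetric-unmethylated input -> empty output; all-hemimethylated
    input -> every unmethylated strand retained."""
    cfg = SimulationConfig(
        seed=3, conversion_rate=1.0, inappropriate_conversion=0.0,
        mcvipi_efficiency=1.0,
    )
    cpgs = region.cpg_positions()
    n = len(cpgs)
    gch_n = len(annotation.gch_sites)

    def mols(top, bottom, count):
        out = [
            DuplexMolecule(
                region.region_id, cpgs,
                np.full(n, top, bool), np.full(n, bottom, bool),
                molecule_id=f"p{i}",
            )
            for i in range(count)
        ]
        flags = {
            m.molecule_id: (np.ones(gch_n, bool), np.ones(gch_n, bool))
            for m in out
        }
        return out, flags

    sites = find_ccgg_internal_cpgs(region)
    sym, flags = mols(False, False, 20)
    callsets, truth = select_hemimethylated_strands(
        sym, flags, region, annotation, sites, cfg, n_clones=40
    )
    assert callsets == [] and truth.empty

    hemi, flags = mols(True, False, 20)
    callsets, truth = select_hemimethylated_strands(
        hemi, flags, region, annotation, sites, cfg, n_clones=40
    )
    # every sampled bottom (unmethylated) strand retained, top strands dropped
    assert all(cs.strand == "bottom" for cs in callsets)
    assert len(callsets) == 20
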