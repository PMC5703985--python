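"""Propensity, coordination-number, geometry, pH and quartet statistics."""

import numpy as np
import pytest

from metalsites.geometry import GeometryAssignment
from metalsites.pdb_io import parse_structure
from metalsites.propensity import (
    PH_BINS,
    cn_distribution,
    compute_propensities,
    extract_quartets,
    geometry_distribution,
    ph_bin_label,
    stratify_by_ph,
    table_to_tsv,
)
from metalsites.site_extraction import DEFAULT_METALS, build_sites
from metalsites.synthetic import ProteinLigand, SiteSpec, generate_structure


def _site(spec, pdb_id="PRP1", seed=0):
    text, _ = generate_structure(spec, seed=seed, pdb_id=pdb_id)
    model = parse_structure(text, pdb_id)
    (site,) = build_sites(model, DEFAULT_METALS)
    return site, model


def test_chelation_counted_per_atom_not_per_residue():
    spec = SiteSpec(
        "ZN",
        (ProteinLigand("ASP", ("OD1", "OD2")), ProteinLigand("HIS", ("NE2",))),
        "tri",
    )
    site, _ = _site(spec)
    by_atom = compute_propensities([site], "by_atom")
    assert by_atom.fractions("ZN") == {"D": 2 / 3, "H": 1 / 3}
    by_res = compute_propensities([site], "by_residue")
    assert by_res.fractions("ZN") == {"D": 1 / 2, "H": 1 / 2}


def test_modes_coincide_without_chelation(small_corpus):
    _, models, _ = small_corpus
    sites = []
    for model in models.values():
        sites.extend(build_sites(model, DEFAULT_METALS))
    mono = [
        s for s in sites
        if all(n == 1 for n in s.residue_multiset().values())
    ]
    assert mono  # the palette contains monodentate-only designs
    a = compute_propensities(mono, "by_atom")
    r = compute_propensities(mono, "by_residue")
    assert a.as_dict() == r.as_dict()


def test_unknown_mode_rejected():
    with pytest.raises(ValueError):
        compute_propensities([], "by_bond")


def test_empty_input_gives_empty_tables():
    assert compute_propensities([], "by_atom").metals() == []
    assert cn_distribution([]).metals() == []
    assert extract_quartets([]).metals() == []


def test_cn_distribution_counts_waters():
    spec = SiteSpec(
        "MN",
        (ProteinLigand("ASP", ("OD1",)), ProteinLigand("ASP", ("OD1",)),
         ProteinLigand("GLU", ("OE1",))),
        "oct",
        include_waters=3,
    )
    site, _ = _site(spec)
    cn = cn_distribution([site])
    assert cn.fractions("MN") == {6: 1.0}


def test_irregular_sites_stay_in_cn_pool_but_not_geometry_pool():
    spec = SiteSpec("CO", (ProteinLigand("HIS", ("NE2",)),) * 2, "oct", include_waters=4)
    sites = [_site(spec, pdb_id=f"CO{i:02d}", seed=i)[0] for i in range(4)]
    assignments = [
        (sites[0], GeometryAssignment(sites[0].site_id, 6, "oct", 0.02, 0.01, "regular")),
        (sites[1], GeometryAssignment(sites[1].site_id, 6, "oct", 0.05, 0.02, "regular")),
        (sites[2], GeometryAssignment(sites[2].site_id, 6, "oct", 0.9, 0.43, "distorted")),
        (sites[3], GeometryAssignment(sites[3].site_id, 6, None, 1.9, 0.9, "irregular")),
    ]
    geo = geometry_distribution(assignments)
    assert geo.denominator("CO") == 3
    assert cn_distribution(sites).denominator("CO") == 4


@pytest.mark.parametrize(
    "ph,label",
    [(4.0, "acidic"), (6.0, "acidic"), (6.01, "mild_acidic"), (6.99, "mild_acidic"),
     (7.0, "neutral"), (7.99, "neutral"), (8.0, "basic"), (12.0, "basic")],
)
def test_ph_bin_boundaries(ph, label):
    assert ph_bin_label(ph) == label


def test_ph_bins_partition_ph_bearing_sites(small_corpus):
    _, models, manifest = small_corpus
    from metalsites.pipeline import RunConfig, scan_corpus

    result = scan_corpus(models, RunConfig(inputs=("x",)))
    sites = result.surviving_sites
    tables = stratify_by_ph(sites, models)
    assert set(tables) == set(PH_BINS)
    n_with_ph = sum(1 for s in sites if models[s.structure_id].ph is not None)
    n_binned = sum(
        cn.denominator(m) for _, cn in tables.values() for m in cn.metals()
    )
    assert n_binned == n_with_ph
    bins = {label: sum(cn.denominator(m) for m in cn.metals())
            for label, (_, cn) in tables.items()}
    assert bins == manifest.expected_ph_bins()


def test_sites_without_ph_only_skip_ph_analysis():
    spec = SiteSpec("ZN", (ProteinLigand("CYS", ("SG",)),) * 4, "tet", ph=None)
    site, model = _site(spec)
    tables = stratify_by_ph([site], {model.pdb_id: model})
    assert all(cn.metals() == [] for _, cn in tables.values())
    assert compute_propensities([site], "by_atom").fractions("ZN") == {"C": 1.0}


def test_quartet_requires_exactly_four_distinct_residues():
    quartet = SiteSpec(
        "CD",
        (ProteinLigand("HIS", ("NE2",)), ProteinLigand("ASP", ("OD1",)),
         ProteinLigand("ASP", ("OD1", "OD2")), ProteinLigand("GLU", ("OE1",))),
        "spy",
    )
    site, _ = _site(quartet)
    profile = extract_quartets([site])
    assert profile.fractions("CD") == {"DDEH": 1.0}

    trio = SiteSpec(
        "CD",
        (ProteinLigand("HIS", ("NE2",)), ProteinLigand("ASP", ("OD1", "OD2")),
         ProteinLigand("GLU", ("OE1", "OE2"))),
        "spy",
    )
    site3, _ = _site(trio, pdb_id="TRIO")  # 3 residues, 5 atoms
    assert extract_quartets([site3]).metals() == []


def test_cysteine_quartets_flagged():
    spec = SiteSpec(
        "ZN",
        (ProteinLigand("CYS", ("SG",)), ProteinLigand("CYS", ("SG",)),
         ProteinLigand("CYS", ("SG",)), ProteinLigand("HIS", ("NE2",))),
        "tet",
    )
    site, _ = _site(spec)
    profile = extract_quartets([site])
    assert profile.cysteine_keys("ZN") == ["CCCH"]


def test_all_fraction_tables_normalise(small_corpus):
    _, models, _ = small_corpus
    from metalsites.pipeline import RunConfig, compute_tables, scan_corpus

    cfg = RunConfig(inputs=("x",))
    result = scan_corpus(models, cfg)
    compute_tables(result, cfg)
    for name in ("propensity_by_atom", "propensity_by_residue", "cn", "geometry", "quartets"):
        table = result.tables[name]
        for metal in table.metals():
            assert sum(table.fractions(metal).values()) == pytest.approx(1.0, abs=1e-9)


def test_tsv_serialisation_round_figures(small_corpus):
    _, models, _ = small_corpus
    sites = []
    for model in models.values():
        sites.extend(build_sites(model, DEFAULT_METALS))
    tsv = table_to_tsv(compute_propensities(sites, "by_atom"), "residue")
    header, *rows = tsv.strip().splitlines()
    assert header == "metal\tresidue\tcount\tfraction"
    assert all(len(r.split("\t")) == 4 for r in rows)
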