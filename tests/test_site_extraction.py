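"""Site construction from LINK records, the filtration cascade, and dedup."""

import numpy as np
import pytest

from metalsites.pdb_io import AtomRecord, LinkEndpoint, LinkRecord, StructureModel, parse_structure
from metalsites.site_extraction import (
    DDDD_FILTER,
    DDDD_METALS,
    DEFAULT_METALS,
    STANDARD_FILTER,
    FilterConfig,
    apply_filters,
    build_sites,
    dedup_equivalent_sites,
)
from metalsites.synthetic import ProteinLigand, SiteSpec, generate_structure


def _model_from_spec(spec, seed=0, pdb_id="TST1", **kw):
    text, _ = generate_structure(spec, seed=seed, pdb_id=pdb_id, **kw)
    return parse_structure(text, pdb_id)


def test_build_site_classifies_ligands_and_counts():
    spec = SiteSpec(
        "ZN",
        (ProteinLigand("HIS", ("NE2",)), ProteinLigand("ASP", ("OD1", "OD2"))),
        "tet",
        include_waters=1,
    )
    model = _model_from_spec(spec)
    (site,) = build_sites(model, DEFAULT_METALS)
    assert site.coordination_number == 4
    assert site.n_protein_atoms == 3
    multiset = {key[1]: n for key, n in site.residue_multiset().items()}
    assert multiset == {"HIS": 1, "ASP": 2}
    classes = sorted(lig.ligand_class for lig in site.ligands)
    assert classes == ["protein", "protein", "protein", "water"]
    for lig in site.ligands:
        assert lig.bond_length == pytest.approx(2.1, abs=0.01)


def test_metal_without_links_yields_no_site(zn_cchh_model):
    import dataclasses

    stripped = dataclasses.replace(zn_cchh_model, links=[])
    assert build_sites(stripped, DEFAULT_METALS) == []


def test_ferrous_and_ferric_attributed_by_component_and_label():
    fe2 = _model_from_spec(
        SiteSpec("FE2", (ProteinLigand("GLU", ("OE1",)), ProteinLigand("GLU", ("OE2",))), "ben"),
        pdb_id="FE2X",
    )
    fe3 = _model_from_spec(
        SiteSpec("FE3", (ProteinLigand("HIS", ("NE2",)), ProteinLigand("HIS", ("ND1",))), "ben"),
        pdb_id="FE3X",
    )
    (s2,) = build_sites(fe2, DEFAULT_METALS)
    (s3,) = build_sites(fe3, DEFAULT_METALS)
    assert s2.species.label == "FE2" and s2.metal.residue_name == "FE2"
    assert s3.species.label == "FE3" and s3.metal.residue_name == "FE"


def _sites_and_models(*specs_ids):
    sites, models = [], {}
    for spec, pdb_id in specs_ids:
        model = _model_from_spec(spec, pdb_id=pdb_id)
        models[pdb_id] = model
        sites.extend(build_sites(model, DDDD_METALS))
    return sites, models


def test_low_protein_ligation_dropped_at_protein_stage():
    spec = SiteSpec("ZN", (ProteinLigand("ASP", ("OD1",)),), "tet", include_waters=3)
    sites, models = _sites_and_models((spec, "LOWP"))
    surviving, report = apply_filters(sites, models, STANDARD_FILTER)
    assert surviving == []
    stages = {s["stage"]: s for s in report.stages}
    assert stages["protein_atoms"]["dropped_ids"] == [sites[0].site_id]


def test_non_water_coligand_dropped():
    spec = SiteSpec(
        "ZN",
        (ProteinLigand("CYS", ("SG",)), ProteinLigand("CYS", ("SG",)),
         ProteinLigand("HIS", ("NE2",))),
        "tet",
        decoy_ligand=("GOL", "O1", "O"),
    )
    sites, models = _sites_and_models((spec, "DECY"))
    surviving, report = apply_filters(sites, models, STANDARD_FILTER)
    assert surviving == []
    assert {s["stage"]: s["surviving"] for s in report.stages}["coligand"] == 0


def test_resolution_cut_is_preset_dependent():
    spec = SiteSpec(
        "MN",
        (ProteinLigand("ASP", ("OD1",)), ProteinLigand("ASP", ("OD1",)),
         ProteinLigand("GLU", ("OE1",))),
        "oct",
        include_waters=3,
        resolution=2.4,
    )
    sites, models = _sites_and_models((spec, "LRES"))
    standard_surviving, _ = apply_filters(sites, models, STANDARD_FILTER)
    assert standard_surviving == []
    dddd_surviving, report = apply_filters(sites, models, DDDD_FILTER)
    assert len(dddd_surviving) == 1  # no resolution limit, and Asp is ligated
    assert "resolution" not in {s["stage"] for s in report.stages}


def test_dddd_variant_requires_asp():
    no_asp = SiteSpec(
        "ZN",
        (ProteinLigand("HIS", ("NE2",)), ProteinLigand("HIS", ("ND1",)),
         ProteinLigand("GLU", ("OE1",)), ProteinLigand("GLU", ("OE1",))),
        "tet",
    )
    sites, models = _sites_and_models((no_asp, "NASP"))
    surviving, report = apply_filters(sites, models, DDDD_FILTER)
    assert surviving == []
    assert {s["stage"]: s["surviving"] for s in report.stages}["link_component"] == 0


def test_filter_counts_non_increasing_and_order_stable(small_corpus):
    _, models, _ = small_corpus
    sites = []
    for pdb_id in sorted(models):
        sites.extend(dedup_equivalent_sites(build_sites(models[pdb_id], DEFAULT_METALS)))
    surviving, report = apply_filters(sites, models, STANDARD_FILTER)
    counts = report.counts()
    for stage, n_in, n_out in counts:
        assert n_out <= n_in
    assert counts[-1][2] == len(surviving)
    # permuting the input permutes but does not change the surviving set
    rng = np.random.default_rng(0)
    shuffled = [sites[i] for i in rng.permutation(len(sites))]
    surviving2, _ = apply_filters(shuffled, models, STANDARD_FILTER)
    assert {s.site_id for s in surviving2} == {s.site_id for s in surviving}


def test_homodimer_keeps_one_representative_site(zn_cchh_spec):
    model = _model_from_spec(zn_cchh_spec, pdb_id="DIM1", symmetric_copies=2)
    sites = build_sites(model, DEFAULT_METALS)
    assert len(sites) == 2
    kept = dedup_equivalent_sites(sites)
    assert len(kept) == 1
    assert kept[0].metal.chain == "A"  # lexicographically first representative


def test_distinct_sites_in_one_chain_both_retained():
    # two Zn ions with different residue multisets, built by hand
    model = StructureModel("TWOS")
    def atom(serial, name, resname, chain, resnum, xyz, element, kind):
        model.atoms.append(
            AtomRecord(serial, name, "", resname, chain, resnum, "", *xyz, element, kind)
        )
    def link(m_name, m_res, m_num, name, resname, resnum):
        model.links.append(
            LinkRecord(
                LinkEndpoint(m_name, "", m_res, "A", m_num, ""),
                LinkEndpoint(name, "", resname, "A", resnum, ""),
            )
        )
    atom(1, "SG", "CYS", "A", 5, (2.1, 0, 0), "S", "ATOM")
    atom(2, "SG", "CYS", "A", 9, (-2.1, 0, 0), "S", "ATOM")
    atom(3, "NE2", "HIS", "A", 20, (22.1, 0, 0), "N", "ATOM")
    atom(4, "OD1", "ASP", "A", 24, (17.9, 0, 0), "O", "ATOM")
    atom(5, "ZN", "ZN", "A", 101, (0, 0, 0), "ZN", "HETATM")
    atom(6, "ZN", "ZN", "A", 102, (20, 0, 0), "ZN", "HETATM")
    link("ZN", "ZN", 101, "SG", "CYS", 5)
    link("ZN", "ZN", 101, "SG", "CYS", 9)
    link("ZN", "ZN", 102, "NE2", "HIS", 20)
    link("ZN", "ZN", 102, "OD1", "ASP", 24)
    sites = build_sites(model, DEFAULT_METALS)
    assert len(sites) == 2
    assert len(dedup_equivalent_sites(sites)) == 2


def test_many_planted_duplicate_pairs_collapse_exactly():
    """100 distinct sites, each planted twice, dedup to exactly 100."""
    model = StructureModel("BIGD")
    serial = 1
    for k in range(100):
        base = 10 * k
        for copy, chain in enumerate("AB"):
            x = 100.0 * k + 50.0 * copy
            model.atoms.append(
                AtomRecord(serial, "NE2", "", "HIS", chain, base + 1, "", x + 2.1, 0, 0, "N", "ATOM")
            )
            serial += 1
            model.atoms.append(
                AtomRecord(serial, "OD1", "", "ASP", chain, base + 3 + k, "", x - 2.1, 0, 0, "O", "ATOM")
            )
            serial += 1
            model.atoms.append(
                AtomRecord(serial, "ZN", "", "ZN", chain, 5000 + base + copy, "", x, 0, 0, "ZN", "HETATM")
            )
            serial += 1
            metal = LinkEndpoint("ZN", "", "ZN", chain, 5000 + base + copy, "")
            model.links.append(
                LinkRecord(metal, LinkEndpoint("NE2", "", "HIS", chain, base + 1, ""))
            )
            model.links.append(
                LinkRecord(metal, LinkEndpoint("OD1", "", "ASP", chain, base + 3 + k, ""))
            )
    sites = build_sites(model, DEFAULT_METALS)
    assert len(sites) == 200
    assert len(dedup_equivalent_sites(sites)) == 100


def test_contradictory_config_allowed_but_validated():
    with pytest.raises(ValueError):
        FilterConfig(require_protein_atoms_min=-1)
    cfg = FilterConfig(require_protein_atoms_min=0)  # logged, not fatal
    assert cfg.require_protein_atoms_min == 0
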