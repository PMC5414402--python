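"""Site characterizer: metal finding, sphere building, QBA recovery,
denticity, disorder grouping, occupancy conventions, report serialization."""

import json

import numpy as np
import pytest

from metalsites import (MetalSite, RefinementStats, SiteConfig, build_site,
                        characterize, check_occupancy_consistency,
                        detect_alternate_positions, find_metal_atoms,
                        generate_structure, implied_third_side)
from metalsites.synth import SiteSpec
from metalsites.structure import Atom, SpaceGroup, Structure, UnitCell


def bare_metal_pair(sep, occ1=0.25, occ2=0.15):
    cell = UnitCell(40, 40, 40)
    a = Atom(1, "RE", "Re", "RRE", "X", 1, "", [10.0, 10.0, 10.0], occ1, 30.0)
    b = Atom(2, "RE", "Re", "RRE", "X", 2, "", [10.0 + sep, 10.0, 10.0], occ2, 30.0)
    s = Structure([a, b], cell, SpaceGroup.from_name("P 1"))
    return s, [MetalSite(metal=a), MetalSite(metal=b)]


class TestFindMetals:
    def test_no_metals_empty(self):
        s = Structure([Atom(1, "CA", "C", "ALA", "A", 1, "", [0, 0, 0])])
        assert find_metal_atoms(s, {"RE"}) == []

    def test_planted_metals_found_sorted(self, clean_structure):
        s, gt = clean_structure
        metals = find_metal_atoms(s, {"RE"}, 0.0)
        assert len(metals) == 7  # 5 single sites + a disorder pair
        assert metals == sorted(metals, key=lambda a: (a.chain, a.resseq))

    def test_occupancy_floor(self, clean_structure):
        s, _ = clean_structure
        assert len(find_metal_atoms(s, {"RE"}, 0.5)) < 7


class TestBuildSite:
    def test_isolated_metal_empty_contacts(self):
        cell = UnitCell(40, 40, 40)
        m = Atom(1, "RE", "Re", "RRE", "X", 1, "", [20.0, 20.0, 20.0], 0.8, 25.0)
        s = Structure([m], cell, SpaceGroup.from_name("P 1"))
        site = build_site(s, m)
        assert site.contacts == [] and site.qbas == []

    def test_planted_anisobidentate_qba_recovered(self):
        spec = SiteSpec("asp_anisobidentate", d1=2.15, d2=3.30)
        s, gt = generate_structure([spec], noise_sigma=0.0, seed=0)
        rep = characterize(s)
        (site,) = rep.sites
        q = [q for q in site.qbas
             if {q.arm_a.name, q.arm_b.name} == {"OD1", "OD2"}][0]
        # law-of-cosines oracle from the carboxylate O...O separation
        expected = gt.sites[0].qba
        oo = implied_third_side(2.15, 3.30, expected)
        assert oo == pytest.approx(2.20, abs=1e-9)
        assert q.angle == pytest.approx(expected, abs=1e-9)
        assert 41.0 <= q.angle <= 42.0

    def test_esds_propagated_when_stats_given(self, clean_structure):
        s, _ = clean_structure
        stats = RefinementStats(r_free=0.2, dmin=1.3, completeness=0.999,
                                n_reflections=60000)
        rep = characterize(s, stats=stats)
        assert rep.dpi is not None and 0.0 < rep.dpi < 0.2
        contact_esds = [h.esd for site in rep.sites for h in site.contacts]
        assert contact_esds and all(e > 0 for e in contact_esds)
        qba_esds = [q.esd for site in rep.sites for q in site.qbas]
        assert qba_esds and all(e > 0 for e in qba_esds)

    def test_altloc_partner_of_other_conformer_skipped(self):
        cell = UnitCell(30, 30, 30)
        m = Atom(1, "RE", "Re", "RRE", "X", 1, "A", [10.0, 10, 10], 0.5, 25.0)
        o_same = Atom(2, "OD1", "O", "ASP", "A", 5, "A", [12.2, 10, 10], 0.5, 20.0)
        o_other = Atom(3, "OD1", "O", "ASP", "A", 5, "B", [10, 12.2, 10], 0.5, 20.0)
        s = Structure([m, o_same, o_other], cell, SpaceGroup.from_name("P 1"))
        site = build_site(s, m)
        partners = [(h.partner.name, h.partner.altloc) for h in site.contacts]
        assert ("OD1", "A") in partners and ("OD1", "B") not in partners

    def test_implausible_contact_flagged_not_dropped(self):
        cell = UnitCell(30, 30, 30)
        m = Atom(1, "RE", "Re", "RRE", "X", 1, "", [10.0, 10, 10], 0.4, 25.0)
        n = Atom(2, "NH1", "N", "ARG", "A", 61, "", [10.8, 10, 10], 1.0, 40.0)
        s = Structure([m, n], cell, SpaceGroup.from_name("P 1"))
        site = build_site(s, m)
        (hit,) = site.contacts
        assert "implausible_distance" in hit.flags


class TestDenticity:
    def test_planted_labels_recovered(self, clean_structure):
        s, gt = clean_structure
        rep = characterize(s)
        by_id = {site.site_id: site for site in rep.sites}
        for p in gt.sites:
            if p.denticity is None:
                continue
            site = by_id[f"{p.residue_key}:RE"]
            assert list(site.denticity.values()) == [p.denticity], p.template

    def test_chelate_vs_anisobidentate_regimes(self):
        chel = SiteSpec("chelate_OO", d1=2.15, d2=2.15, qba=59.6)
        s, _ = generate_structure([chel], noise_sigma=0.0, seed=1)
        rep = characterize(s)
        assert list(rep.sites[0].denticity.values()) == ["bidentate_chelate"]
        aniso = SiteSpec("asp_anisobidentate", d1=2.15, d2=3.30)
        s, _ = generate_structure([aniso], noise_sigma=0.0, seed=1)
        rep = characterize(s)
        assert list(rep.sites[0].denticity.values()) == ["anisobidentate"]

    def test_vicinity_site_label(self):
        s, _ = generate_structure([SiteSpec("glu_vicinity", d2=3.30)],
                                  noise_sigma=0.0, seed=2)
        rep = characterize(s)
        assert list(rep.sites[0].denticity.values()) == ["nonbinding_vicinity"]


class TestDisorder:
    def test_short_pair_grouped_as_alternate_positions(self):
        s, sites = bare_metal_pair(1.5)
        groups = detect_alternate_positions(sites)
        assert len(groups) == 1
        g = groups[0]
        assert g["occupancy_sum"] == pytest.approx(0.4)
        assert not g["occupancy_exceeds_one"]
        assert sites[0].disorder_group == sites[1].disorder_group == 0

    def test_mid_range_pair_flagged_metal_metal(self):
        s, sites = bare_metal_pair(3.0)
        groups = detect_alternate_positions(sites)
        assert groups == []
        assert any("possible_metal_metal" in f for f in sites[0].flags)

    def test_vdw_range_pair_flagged_proximity(self):
        s, sites = bare_metal_pair(3.8)
        groups = detect_alternate_positions(sites)
        assert groups == []
        assert any("vdw_proximity" in f for f in sites[0].flags)

    def test_occupancy_sum_over_one_flagged(self):
        s, sites = bare_metal_pair(1.2, occ1=0.7, occ2=0.6)
        groups = detect_alternate_positions(sites)
        assert groups[0]["occupancy_exceeds_one"]

    def test_transitive_grouping_shares_element(self):
        cell = UnitCell(40, 40, 40)
        atoms = [Atom(i + 1, "RE", "Re", "RRE", "X", i + 1, "",
                      [10.0 + 1.0 * i, 10, 10], 0.2, 30.0) for i in range(3)]
        s = Structure(atoms, cell, SpaceGroup.from_name("P 1"))
        sites = [MetalSite(metal=a) for a in atoms]
        groups = detect_alternate_positions(sites)
        assert len(groups) == 1 and len(groups[0]["members"]) == 3


class TestOccupancyConsistency:
    def test_matching_ligand_occupancies_clean(self, clean_structure):
        s, gt = clean_structure
        rep = characterize(s)
        his = [site for site in rep.sites
               if any(k.startswith("HIS") for k in site.denticity)][0]
        assert his.occupancy_flags == []

    def test_zero_occupancy_convention_reported_not_flagged(self, clean_structure):
        s, gt = clean_structure
        rep = characterize(s)
        planted = [p for p in gt.sites if p.zero_occupancy_ligands][0]
        site = {x.site_id: x for x in rep.sites}[f"{planted.residue_key}:RE"]
        assert site.zero_occupancy_ligands  # reported as chemically present
        assert not any("occupancy" in f and "0.00" in f
                       for f in site.occupancy_flags)

    def test_mismatched_ligand_occupancy_flagged(self):
        cell = UnitCell(30, 30, 30)
        m = Atom(1, "RE", "Re", "RRE", "X", 1, "", [10.0, 10, 10], 0.83, 25.0)
        c = Atom(2, "C1", "C", "RRE", "X", 1, "", [11.9, 10, 10], 0.50, 25.0)
        s = Structure([m, c], cell, SpaceGroup.from_name("P 1"))
        site = build_site(s, m)
        check_occupancy_consistency(site, s, tol=0.05)
        assert any("0.50" in f for f in site.occupancy_flags)


class TestCharacterize:
    def test_empty_structure_empty_report(self):
        s = Structure([], UnitCell(20, 20, 20), SpaceGroup.from_name("P 1"))
        rep = characterize(s)
        assert rep.sites == [] and rep.summary["n_sites"] == 0

    def test_deterministic_byte_identical(self, clean_structure):
        s, _ = clean_structure
        r1 = characterize(s).to_json()
        r2 = characterize(s).to_json()
        assert r1 == r2

    def test_report_serializes_to_json_and_tsv(self, clean_structure):
        s, _ = clean_structure
        rep = characterize(s)
        doc = json.loads(rep.to_json())
        assert doc["summary"]["n_sites"] == 7
        assert doc["settings"]["radius"] == 4.5
        df = rep.to_dataframe()
        assert {"site", "partner", "distance", "class"} <= set(df.columns)
        assert len(df) > 10
        tsv = rep.to_tsv()
        assert tsv.startswith("site\t")

    def test_summary_counts_residue_types(self, clean_structure):
        s, _ = clean_structure
        rep = characterize(s)
        assert {"HIS", "ASP", "GLU"} <= set(rep.summary["residue_types"])
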