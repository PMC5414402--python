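"""Metal-site characterization pipeline.

Finds metal atoms in a refined structure, builds symmetry-expanded
coordination spheres, classifies every contact against small-molecule
reference ranges, measures quasi bite angles (QBA) with DPI-propagated
esds, assigns per-residue denticity, groups fractionally disordered metal
positions, and checks occupancy conventions, assembling everything into a
serializable report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .structure import Atom, Structure
from .geometry import (ContactHit, QBAMeasurement, angle, neighbor_search)
from .precision import (RefinementStats, cruickshank_dpi, atom_sigma,
                        distance_esd, angle_esd, format_with_esd)
from .references import (ContactClass, ClassifyConfig, ReferenceSet,
                         classify_distance, load_references, vdw_sum)

__all__ = [
    "SiteConfig", "MetalSite", "SiteReport", "find_metal_atoms", "build_site",
    "classify_denticity", "detect_alternate_positions",
    "check_occupancy_consistency", "characterize",
]

DONOR_ELEMENTS = frozenset({"N", "O", "S"})


@dataclass
class SiteConfig:
    """Pipeline settings with the defaults used throughout the analysis."""

    metal_elements: tuple[str, ...] = ("RE",)
    min_occupancy: float = 0.0
    radius: float = 4.5
    use_symmetry: bool = True
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    chelate_qba_threshold: float = 52.0  # deg; separates anisobidentate (<=47)
    #                                      from kappa2 chelation (>=59.4)
    occupancy_tol: float = 0.05
    disorder_occupancy_tol: float = 0.05
    implausible_distance: float = 1.2    # A; shorter than any covalent bond
    dpi_variant: str = "rfree"

    def as_dict(self) -> dict:
        d = asdict(self)
        d["metal_elements"] = list(self.metal_elements)
        return d


def _residue_key(a: Atom) -> str:
    return f"{a.resname}{a.resseq}{a.chain}"


def _image_key(hit: ContactHit) -> tuple:
    return (hit.partner.chain, hit.partner.resseq, hit.partner.resname,
            hit.symop.triplet(), hit.shift)


@dataclass
class MetalSite:
    """One metal atom with its classified contact sphere."""

    metal: Atom
    contacts: list[ContactHit] = field(default_factory=list)       # protein
    ligand_contacts: list[ContactHit] = field(default_factory=list)  # complex/waters
    metal_contacts: list[ContactHit] = field(default_factory=list)
    qbas: list[QBAMeasurement] = field(default_factory=list)
    denticity: dict[str, str] = field(default_factory=dict)
    occupancy_flags: list[str] = field(default_factory=list)
    zero_occupancy_ligands: list[str] = field(default_factory=list)
    disorder_group: int | None = None
    flags: list[str] = field(default_factory=list)
    evidence_sigma: float | None = None
    cutoffs_echo: dict = field(default_factory=dict)

    @property
    def site_id(self) -> str:
        alt = f".{self.metal.altloc}" if self.metal.altloc else ""
        return f"{_residue_key(self.metal)}:{self.metal.name}{alt}"

    def all_classified(self) -> list[ContactHit]:
        return self.contacts + self.ligand_contacts

    def to_dict(self) -> dict:
        def hit_dict(h: ContactHit) -> dict:
            d = {
                "partner": f"{_residue_key(h.partner)}:{h.partner.name}",
                "partner_element": h.partner.element,
                "symop": h.symop.triplet(),
                "shift": list(h.shift),
                "distance": round(h.distance, 3),
                "class": h.contact_class,
                "flags": h.flags,
            }
            if h.esd is not None and h.esd > 0:
                d["esd"] = round(h.esd, 3)
                d["formatted"] = format_with_esd(h.distance, h.esd)
            return d

        def qba_dict(q: QBAMeasurement) -> dict:
            d = {
                "arm_a": f"{_residue_key(q.arm_a)}:{q.arm_a.name}",
                "arm_b": f"{_residue_key(q.arm_b)}:{q.arm_b.name}",
                "angle": round(q.angle, 1),
            }
            if q.esd is not None and q.esd > 0:
                d["esd"] = round(q.esd, 1)
                d["formatted"] = format_with_esd(q.angle, q.esd)
            return d

        return {
            "site_id": self.site_id,
            "metal": {"element": self.metal.element,
                      "occupancy": self.metal.occupancy,
                      "b_iso": self.metal.b_iso,
                      "xyz": [round(float(x), 3) for x in self.metal.xyz]},
            "contacts": [hit_dict(h) for h in self.contacts],
            "ligand_contacts": [hit_dict(h) for h in self.ligand_contacts],
            "metal_contacts": [hit_dict(h) for h in self.metal_contacts],
            "qbas": [qba_dict(q) for q in self.qbas],
            "denticity": self.denticity,
            "occupancy_flags": self.occupancy_flags,
            "zero_occupancy_ligands": self.zero_occupancy_ligands,
            "disorder_group": self.disorder_group,
            "flags": self.flags,
            "evidence_sigma": (round(self.evidence_sigma, 2)
                               if self.evidence_sigma is not None else None),
            "cutoffs": self.cutoffs_echo,
        }


@dataclass
class SiteReport:
    label: str
    sites: list[MetalSite]
    settings: dict
    dpi: float | None = None
    b_avg: float | None = None
    disorder_groups: list[dict] = field(default_factory=list)
    cell: tuple[float, ...] | None = None

    @property
    def summary(self) -> dict:
        by_restype: dict[str, int] = {}
        by_denticity: dict[str, int] = {}
        for site in self.sites:
            for reskey, label in site.denticity.items():
                restype = "".join(c for c in reskey if c.isalpha())[:3]
                by_restype[restype] = by_restype.get(restype, 0) + 1
                by_denticity[label] = by_denticity.get(label, 0) + 1
        return {"n_sites": len(self.sites),
                "residue_types": dict(sorted(by_restype.items())),
                "denticity": dict(sorted(by_denticity.items()))}

    def to_dict(self) -> dict:
        return {
            "structure": self.label,
            "cell": self.cell,
            "dpi": self.dpi,
            "b_avg": self.b_avg,
            "summary": self.summary,
            "sites": [s.to_dict() for s in self.sites],
            "disorder_groups": self.disorder_groups,
            "settings": self.settings,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=False)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per classified contact (protein + ligand sphere)."""
        rows = []
        for site in self.sites:
            for kind, hits in (("protein", site.contacts),
                               ("ligand", site.ligand_contacts),
                               ("metal", site.metal_contacts)):
                for h in hits:
                    rows.append({
                        "site": site.site_id,
                        "metal_occupancy": site.metal.occupancy,
                        "sphere": kind,
                        "partner": f"{_residue_key(h.partner)}:{h.partner.name}",
                        "element": h.partner.element,
                        "symop": h.symop.triplet(),
                        "shift": "{},{},{}".format(*h.shift),
                        "distance": round(h.distance, 3),
                        "esd": round(h.esd, 3) if h.esd else None,
                        "formatted": (format_with_esd(h.distance, h.esd)
                                      if h.esd else f"{h.distance:.3f}"),
                        "class": h.contact_class,
                        "flags": ";".join(h.flags),
                    })
        cols = ["site", "metal_occupancy", "sphere", "partner", "element",
                "symop", "shift", "distance", "esd", "formatted", "class",
                "flags"]
        return pd.DataFrame(rows, columns=cols)

    def to_tsv(self) -> str:
        return self.to_dataframe().to_csv(sep="\t", index=False)


def find_metal_atoms(s: Structure, elements: set[str] | tuple[str, ...],
                     min_occupancy: float = 0.0) -> list[Atom]:
    """Metal atoms of the requested elements at or above an occupancy floor."""
    if not elements:
        raise ValueError("no metal elements requested")
    wanted = {e.upper() for e in elements}
    found = [a for a in s.atoms
             if a.element.upper() in wanted and a.occupancy >= min_occupancy]
    found.sort(key=lambda a: (a.chain, a.resseq, a.name, a.altloc))
    return found


def build_site(s: Structure, metal: Atom, refset: ReferenceSet | None = None,
               dpi: float | None = None,
               config: SiteConfig | None = None,
               b_avg: float | None = None) -> MetalSite:
    """Build and classify the contact sphere of one metal atom.

    Contacts are split into the protein sphere, the metal's own ligand
    sphere (atoms of the same residue group, e.g. carbonyls, plus waters)
    and other metal atoms.  QBAs are measured for every donor pair of a
    residue image that has at least one coordination/semi contact.
    """
    cfg = config or SiteConfig()
    refset = refset or load_references()
    if b_avg is None:
        heavies = s.heavy_atoms()
        b_avg = float(np.mean([a.b_iso for a in heavies])) if heavies else None

    use_sym = cfg.use_symmetry and s.cell is not None and s.spacegroup is not None
    hits = neighbor_search(s, metal, cfg.radius, use_symmetry=use_sym)

    def sigma_of(a: Atom) -> float:
        if dpi is None or b_avg is None or b_avg <= 0:
            return 0.0
        return atom_sigma(dpi, max(a.b_iso, 1e-3), b_avg)

    site = MetalSite(metal=metal)
    metal_elements = {e.upper() for e in cfg.metal_elements}
    sigma_m = sigma_of(metal)
    for h in hits:
        p = h.partner
        if p.is_hydrogen:
            continue
        if (metal.altloc and p.altloc and p.altloc != metal.altloc):
            continue  # never measure across altlocs
        esd = distance_esd(sigma_m, sigma_of(p)) if dpi is not None else None
        h.esd = esd
        if p.element.upper() in metal_elements:
            h.contact_class = None
            if h.is_direct:
                site.metal_contacts.append(h)
            continue
        cls, cutoffs = classify_distance(h.distance, esd or 0.0,
                                         metal.element, p.element,
                                         refset, cfg.classify)
        h.contact_class = cls.value
        site.cutoffs_echo.setdefault(
            f"{metal.element.upper()}-{p.element.upper()}", cutoffs)
        if h.distance < cfg.implausible_distance:
            h.flags.append("implausible_distance")
        same_group = (p.chain == metal.chain and p.resseq == metal.resseq
                      and p.resname == metal.resname)
        if same_group or p.is_water:
            site.ligand_contacts.append(h)
        else:
            site.contacts.append(h)

    # QBA per residue image with at least one coordination/semi donor contact
    groups: dict[tuple, list[ContactHit]] = {}
    for h in site.contacts:
        groups.setdefault(_image_key(h), []).append(h)
    for key, ghits in sorted(groups.items()):
        donors = [h for h in ghits if h.partner.element.upper() in DONOR_ELEMENTS]
        engaged = any(h.contact_class in (ContactClass.coordination_bond.value,
                                          ContactClass.semi_coordination.value)
                      for h in donors)
        if not engaged:
            continue
        donors.sort(key=lambda h: h.distance)
        for i in range(len(donors)):
            for j in range(i + 1, len(donors)):
                a, b = donors[i], donors[j]
                try:
                    qba = angle(a.position, metal.xyz, b.position)
                except ValueError:
                    continue
                esd_q = None
                if dpi is not None:
                    try:
                        esd_q = angle_esd(
                            np.vstack([a.position, metal.xyz, b.position]),
                            [sigma_of(a.partner), sigma_m, sigma_of(b.partner)])
                    except ValueError:
                        esd_q = None
                site.qbas.append(QBAMeasurement(
                    vertex=metal, arm_a=a.partner, arm_b=b.partner,
                    angle=qba, esd=esd_q))
    return site


def classify_denticity(site: MetalSite, refset: ReferenceSet | None = None,
                       config: SiteConfig | None = None) -> MetalSite:
    """Assign a per-residue denticity label from classified donor contacts.

    Labels: ``monodentate`` (one bond, no engaged second donor),
    ``anisobidentate`` (one bond plus a semi/vdW second donor at a QBA below
    the chelate threshold), ``bidentate_chelate`` (two bonds at a chelate-like
    QBA), ``tridentate`` and ``nonbinding_vicinity`` (no bond, only longer
    approaches).
    """
    cfg = config or SiteConfig()
    groups: dict[tuple, list[ContactHit]] = {}
    for h in site.contacts:
        if h.partner.element.upper() in DONOR_ELEMENTS:
            groups.setdefault(_image_key(h), []).append(h)

    def qba_between(a: Atom, b: Atom) -> float | None:
        for q in site.qbas:
            pair = {(q.arm_a.chain, q.arm_a.resseq, q.arm_a.name, q.arm_a.altloc),
                    (q.arm_b.chain, q.arm_b.resseq, q.arm_b.name, q.arm_b.altloc)}
            if pair == {(a.chain, a.resseq, a.name, a.altloc),
                        (b.chain, b.resseq, b.name, b.altloc)}:
                return q.angle
        return None

    site.denticity = {}
    for key, ghits in sorted(groups.items()):
        reskey = f"{key[2]}{key[1]}{key[0]}"
        coord = [h for h in ghits
                 if h.contact_class == ContactClass.coordination_bond.value]
        secondary = [h for h in ghits
                     if h.contact_class in (ContactClass.semi_coordination.value,
                                            ContactClass.vdw_contact.value)]
        if len(coord) == 0:
            if secondary or any(
                    h.contact_class == ContactClass.borderline_vdw.value
                    for h in ghits):
                site.denticity[reskey] = "nonbinding_vicinity"
            continue
        if len(coord) >= 3:
            site.denticity[reskey] = "tridentate"
            continue
        if len(coord) == 2:
            q = qba_between(coord[0].partner, coord[1].partner)
            if q is not None and q >= cfg.chelate_qba_threshold:
                site.denticity[reskey] = "bidentate_chelate"
            else:
                site.denticity[reskey] = "anisobidentate"
            continue
        # exactly one coordination bond
        label = "monodentate"
        for h in secondary:
            q = qba_between(coord[0].partner, h.partner)
            if q is not None and q < cfg.chelate_qba_threshold:
                label = "anisobidentate"
                break
        site.denticity[reskey] = label
    return site


def detect_alternate_positions(sites: list[MetalSite],
                               refset: ReferenceSet | None = None,
                               config: SiteConfig | None = None) -> list[dict]:
    """Group metal positions that are mutually too close to coexist.

    Same-element pairs separated by less than the all-oxidation-state
    small-molecule minimum are treated as fractionally disordered alternate
    positions of one metal; pairs inside the reference metal-metal range are
    flagged as possible M-M interactions; pairs under the vdW sum as vdW
    proximity.  Groups are transitive closures of the alternate-position
    relation; each group's occupancy sum is checked against 1.
    """
    cfg = config or SiteConfig()
    refset = refset or load_references()
    n = len(sites)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for site in sites:
        site.disorder_group = None
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sites[i].metal, sites[j].metal
            if a.element.upper() != b.element.upper():
                continue
            sep = float(np.linalg.norm(a.xyz - b.xyz))
            mm_ranges = refset.metal_metal(a.element)
            if mm_ranges:
                mm_min = min(r.min for r in mm_ranges)
                mm_max = max(r.max for r in mm_ranges)
            else:  # fall back to twice the covalent radius
                cov = 2.0 * refset.radii.covalent_radius(a.element)
                mm_min, mm_max = 0.8 * cov, 1.2 * cov
            vdw = vdw_sum(a.element, b.element, refset.radii)
            if sep >= cfg.radius and sep >= vdw:
                continue
            tag = f"{sites[i].site_id}<->{sites[j].site_id} {sep:.2f}A"
            if sep < mm_min:
                union(i, j)
            elif sep <= mm_max:
                for k in (i, j):
                    sites[k].flags.append(f"possible_metal_metal_interaction:{tag}")
            elif sep < vdw:
                for k in (i, j):
                    sites[k].flags.append(f"vdw_proximity:{tag}")

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out: list[dict] = []
    gid = 0
    for members in groups.values():
        if len(members) < 2:
            continue
        occ_sum = sum(sites[i].metal.occupancy for i in members)
        for i in members:
            sites[i].disorder_group = gid
        entry = {
            "group": gid,
            "members": [sites[i].site_id for i in members],
            "element": sites[members[0]].metal.element,
            "occupancy_sum": round(occ_sum, 3),
            "occupancy_exceeds_one": bool(
                occ_sum > 1.0 + cfg.disorder_occupancy_tol),
            "separations": [
                round(float(np.linalg.norm(
                    sites[i].metal.xyz - sites[j].metal.xyz)), 3)
                for ii, i in enumerate(members) for j in members[ii + 1:]],
        }
        out.append(entry)
        gid += 1
    return out


def check_occupancy_consistency(site: MetalSite, s: Structure,
                                tol: float = 0.05) -> MetalSite:
    """Check the convention that complex ligand atoms share the metal's
    occupancy, with zero occupancy reserved for chemically-present but
    weakly-visible ligands."""
    site.occupancy_flags = []
    site.zero_occupancy_ligands = []
    m_occ = site.metal.occupancy
    for h in site.ligand_contacts:
        p = h.partner
        label = f"{_residue_key(p)}:{p.name}"
        if p.occupancy == 0.0:
            site.zero_occupancy_ligands.append(label)
        elif abs(p.occupancy - m_occ) > tol:
            site.occupancy_flags.append(
                f"{label} occupancy {p.occupancy:.2f} differs from metal "
                f"{m_occ:.2f}")
    return site


def characterize(s: Structure, config: SiteConfig | None = None,
                 refset: ReferenceSet | None = None,
                 stats: RefinementStats | None = None) -> SiteReport:
    """Run the full pipeline on a structure; a pure function of its inputs."""
    cfg = config or SiteConfig()
    refset = refset or load_references()
    dpi = None
    if stats is not None:
        if stats.n_atoms is None:
            stats.n_atoms = len(s.heavy_atoms())
        dpi = cruickshank_dpi(stats, cfg.dpi_variant).dpi
    heavies = s.heavy_atoms()
    b_avg = float(np.mean([a.b_iso for a in heavies])) if heavies else None
    metals = find_metal_atoms(s, cfg.metal_elements, cfg.min_occupancy)
    sites = []
    for m in metals:
        site = build_site(s, m, refset=refset, dpi=dpi, config=cfg, b_avg=b_avg)
        classify_denticity(site, refset, cfg)
        check_occupancy_consistency(site, s, cfg.occupancy_tol)
        if not site.contacts and not site.metal_contacts:
            site.flags.append("nonbinding_entity")
        elif not any(
                h.contact_class in (ContactClass.coordination_bond.value,
                                    ContactClass.semi_coordination.value)
                for h in site.contacts):
            site.flags.append("no_protein_coordination")
        sites.append(site)
    disorder = detect_alternate_positions(sites, refset, cfg)
    return SiteReport(label=s.label, sites=sites, settings=cfg.as_dict(),
                      dpi=dpi, b_avg=b_avg, disorder_groups=disorder,
                      cell=s.cell.parameters if s.cell else None)
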