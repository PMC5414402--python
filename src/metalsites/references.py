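"""Shipped reference data and contact classification.

The default data file carries a snapshot of small-molecule (CSD-derived)
bond-distance and bite-angle ranges for fac-[Re(CO)3]+ chemistry, Re...Re
separation statistics, and a van der Waals radii set anchored so that the
pairwise sums match the values used in the protein analysis (Re+O 3.67 A,
Re+N 3.70 A, Re+Re 4.30 A).

Contact classes form a tiered scale of decreasing "bondedness":

    coordination_bond > semi_coordination > vdw_contact
                      > borderline_vdw > nonbonded

A ``coordination_bond`` is a distance within (reference max + margin) of the
small-molecule bond range; ``semi_coordination`` covers long, chemically
meaningful approaches up to a configurable cutoff (default 2.9 A);
``vdw_contact`` is anything shorter than the van der Waals sum; and
``borderline_vdw`` marks distances at or beyond the vdW sum that are still
indistinguishable from it within 3 esd.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

__all__ = [
    "RadiiTable", "ReferenceRange", "ReferenceSet", "ContactClass",
    "ClassifyConfig", "load_references", "vdw_sum", "classify_distance",
    "zscore",
]


class ContactClass(str, Enum):
    coordination_bond = "coordination_bond"
    semi_coordination = "semi_coordination"
    vdw_contact = "vdw_contact"
    borderline_vdw = "borderline_vdw"
    nonbonded = "nonbonded"

    @property
    def rank(self) -> int:
        """Bondedness rank: higher = more bonded."""
        order = ["nonbonded", "borderline_vdw", "vdw_contact",
                 "semi_coordination", "coordination_bond"]
        return order.index(self.value)


@dataclass
class RadiiTable:
    vdw: dict[str, float]
    covalent: dict[str, float]
    source: str = ""

    def vdw_radius(self, element: str) -> float:
        key = element.upper()
        if key not in self.vdw:
            raise KeyError(f"no van der Waals radius for element {element!r}")
        return self.vdw[key]

    def covalent_radius(self, element: str) -> float:
        key = element.upper()
        if key not in self.covalent:
            raise KeyError(f"no covalent radius for element {element!r}")
        return self.covalent[key]

    def knows(self, element: str) -> bool:
        return element.upper() in self.vdw


@dataclass
class ReferenceRange:
    id: str
    descriptor: str
    metal: str
    partner: str
    kind: str  # distance | angle | metal_metal
    min: float
    max: float
    mean: float | None = None
    sd: float | None = None
    n: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.min > self.max:
            raise ValueError(f"range {self.id}: min > max")
        if self.sd is not None and self.sd < 0:
            raise ValueError(f"range {self.id}: negative sd")

    def contains(self, value: float) -> bool:
        return self.min <= value <= self.max


@dataclass
class ReferenceSet:
    radii: RadiiTable
    ranges: dict[str, ReferenceRange] = field(default_factory=dict)
    version: str = ""

    def by_pair(self, metal: str, partner: str,
                kind: str = "distance") -> list[ReferenceRange]:
        m, p = metal.upper(), partner.upper()
        return [r for r in self.ranges.values()
                if r.kind == kind and r.metal == m and r.partner == p]

    def metal_metal(self, element: str) -> list[ReferenceRange]:
        return self.by_pair(element, element, kind="metal_metal")

    def __getitem__(self, range_id: str) -> ReferenceRange:
        return self.ranges[range_id]


def _parse_refset(data: dict) -> ReferenceSet:
    radii_block = data.get("radii", {})
    radii = RadiiTable(
        vdw={k.upper(): float(v) for k, v in radii_block.get("vdw", {}).items()},
        covalent={k.upper(): float(v)
                  for k, v in radii_block.get("covalent", {}).items()},
        source=radii_block.get("source", ""),
    )
    ranges: dict[str, ReferenceRange] = {}
    for entry in data.get("ranges", []):
        try:
            rr = ReferenceRange(
                id=entry["id"], descriptor=entry.get("descriptor", ""),
                metal=entry["metal"].upper(), partner=entry["partner"].upper(),
                kind=entry.get("kind", "distance"),
                min=float(entry["min"]), max=float(entry["max"]),
                mean=entry.get("mean"), sd=entry.get("sd"), n=entry.get("n"),
                provenance=entry.get("provenance", ""),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(
                f"malformed reference entry {entry.get('id', '<no id>')!r}: {exc}"
            ) from exc
        ranges[rr.id] = rr
    return ReferenceSet(radii=radii, ranges=ranges,
                        version=str(data.get("version", "")))


def load_references(path: str | Path | None = None) -> ReferenceSet:
    """Load the default embedded reference set, merging a user file over it.

    A user file may override the radii tables wholesale and add or replace
    ranges by ``id``; an empty override leaves the defaults untouched.
    """
    default_text = (resources.files("metalsites") / "data" /
                    "references.json").read_text()
    data = json.loads(default_text)
    refset = _parse_refset(data)
    if path is not None:
        try:
            user = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed reference file {path}: {exc}") from exc
        if not isinstance(user, dict):
            raise ValueError(f"reference file {path} must be a JSON object")
        if "radii" in user:
            block = user["radii"]
            refset.radii.vdw.update(
                {k.upper(): float(v) for k, v in block.get("vdw", {}).items()})
            refset.radii.covalent.update(
                {k.upper(): float(v)
                 for k, v in block.get("covalent", {}).items()})
        for entry in user.get("ranges", []):
            sub = _parse_refset({"ranges": [entry]})
            refset.ranges.update(sub.ranges)
    return refset


def vdw_sum(e1: str, e2: str, radii: RadiiTable) -> float:
    """Sum of van der Waals radii of two elements, Angstroms."""
    return radii.vdw_radius(e1) + radii.vdw_radius(e2)


@dataclass
class ClassifyConfig:
    """Tunable cutoffs for contact classification (Angstroms)."""

    bond_margin: float = 0.45       # added to the tightest reference max
    fallback_bond_margin: float = 0.4   # added to covalent sum when no reference
    semi_cutoff: float = 2.9
    borderline_n_sigma: float = 3.0

    def bond_cutoff(self, metal: str, partner: str,
                    refset: ReferenceSet) -> float:
        matches = refset.by_pair(metal, partner, kind="distance")
        if matches:
            return min(r.max for r in matches) + self.bond_margin
        cov = (refset.radii.covalent_radius(metal)
               + refset.radii.covalent_radius(partner))
        return cov + self.fallback_bond_margin


def classify_distance(d: float, esd: float, metal: str, partner: str,
                      refset: ReferenceSet,
                      config: ClassifyConfig | None = None
                      ) -> tuple[ContactClass, dict]:
    """Classify a metal-partner distance on the tiered contact scale.

    Returns ``(ContactClass, cutoffs)`` where the second element echoes the
    numeric cutoffs used, for transparent reporting.
    """
    if d <= 0:
        raise ValueError("distance must be positive")
    cfg = config or ClassifyConfig()
    bond = cfg.bond_cutoff(metal, partner, refset)
    semi = max(cfg.semi_cutoff, bond)
    vdw = vdw_sum(metal, partner, refset.radii)
    cutoffs = {"bond_cutoff": round(bond, 4), "semi_cutoff": round(semi, 4),
               "vdw_sum": round(vdw, 4),
               "borderline_n_sigma": cfg.borderline_n_sigma}
    if d <= bond:
        cls = ContactClass.coordination_bond
    elif d <= semi:
        cls = ContactClass.semi_coordination
    elif d < vdw:
        cls = ContactClass.vdw_contact
    elif d - cfg.borderline_n_sigma * esd < vdw:
        cls = ContactClass.borderline_vdw
    else:
        cls = ContactClass.nonbonded
    return cls, cutoffs


def zscore(d: float, range_: ReferenceRange) -> float:
    """Standard score of a value against a reference range's mean/sd."""
    if range_.mean is None or range_.sd is None or range_.sd <= 0:
        raise ValueError(
            f"range {range_.id} has no mean/sd; use min/max containment instead")
    return (d - range_.mean) / range_.sd
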