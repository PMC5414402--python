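"""Synthetic crystal structures and maps with fully known planted geometry.

The generator emulates the binding modes seen for fac-[Re(CO)3]+ on a
protein surface: monodentate imidazole coordination, anisobidentate
carboxylate binding (one short Re-O bond plus a ~3.0-3.5 A second-oxygen
contact at a QBA near 41 deg), kappa2-O,O' chelation (~59.6 deg bite),
van-der-Waals-range vicinity sites, fractionally disordered metal pairs and
nonbinding entities.  Every planted quantity is recorded in a ground-truth
object that regenerates bit-identically from (specs, seed), so every
pipeline stage can be tested by construct-and-recover.

Scaffold realism is deliberately minimal — a short poly-alanine-like chain
plus the spec'd donor residues — because the downstream analysis consumes
only geometry, occupancies and B factors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .structure import Atom, SpaceGroup, Structure, UnitCell
from .geometry import implied_third_side
from .density import DensityMap, peak_height

__all__ = ["SiteSpec", "PlantedSite", "GroundTruth", "generate_structure",
           "generate_map", "DEFAULT_SITE_SPECS"]

TEMPLATES = ("his_monodentate", "asp_anisobidentate", "chelate_OO",
             "glu_vicinity", "disorder_pair", "nonbinding")

# carboxylate O...O separation used when a QBA is derived rather than given
_CARBOXYLATE_OO = 2.20
_CO_C = 1.92   # Re-C(carbonyl)
_CO_O = 3.07   # Re...O(carbonyl)
_AQUA = 2.19   # Re-OH2


@dataclass
class SiteSpec:
    """Requested geometry for one planted metal site."""

    template: str
    metal: str = "RE"
    d1: float | None = None      # primary metal-donor distance, A
    d2: float | None = None      # secondary donor distance, A
    qba: float | None = None     # quasi bite angle, deg (derived if None)
    occupancy: float = 0.80
    occupancy2: float | None = None   # second metal of a disorder pair
    separation: float | None = None   # metal-metal separation (disorder pair)
    b_iso: float = 25.0
    zero_occupancy_co: bool = False   # plant one chemically-present CO at occ 0

    def __post_init__(self) -> None:
        if self.template not in TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must be in (0, 1]")
        for d in (self.d1, self.d2, self.separation):
            if d is not None and not 0.8 < d < 6.0:
                raise ValueError(f"distance {d} outside the sane range (0.8, 6)")


@dataclass
class PlantedSite:
    index: int
    template: str
    residue_key: str
    metal_serial: int
    metal_xyz: tuple[float, float, float]
    occupancy: float
    donors: list[dict] = field(default_factory=list)  # {atom, residue, distance}
    qba: float | None = None
    denticity: str | None = None
    disorder_group: int | None = None
    map_height: float | None = None
    zero_occupancy_ligands: list[str] = field(default_factory=list)


@dataclass
class GroundTruth:
    seed: int
    noise_sigma: float
    sites: list[PlantedSite] = field(default_factory=list)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent)


DEFAULT_SITE_SPECS: tuple[SiteSpec, ...] = (
    SiteSpec("his_monodentate", d1=2.20, occupancy=0.83),
    SiteSpec("asp_anisobidentate", d1=2.15, d2=3.30, occupancy=0.42,
             zero_occupancy_co=True),
    SiteSpec("chelate_OO", d1=2.15, d2=2.15, qba=59.6, occupancy=0.60),
    SiteSpec("glu_vicinity", d2=3.30, occupancy=0.30),
    SiteSpec("disorder_pair", separation=1.5, occupancy=0.25, occupancy2=0.15),
    SiteSpec("nonbinding", occupancy=0.40),
)


def _resolve_qba(spec: SiteSpec, d1: float, d2: float) -> float:
    """QBA for a carboxylate site; derived from the O...O separation when
    not requested explicitly."""
    if spec.qba is not None:
        return spec.qba
    oo = _CARBOXYLATE_OO
    if not abs(d1 - d2) < oo < d1 + d2:
        raise ValueError(
            f"infeasible site geometry: law of cosines admits no triangle "
            f"with sides d1={d1}, d2={d2} and O...O={oo}")
    cosv = (d1 * d1 + d2 * d2 - oo * oo) / (2.0 * d1 * d2)
    return float(np.degrees(np.arccos(cosv)))


class _Builder:
    def __init__(self) -> None:
        self.atoms: list[Atom] = []
        self._serial = 0

    def add(self, name: str, element: str, resname: str, chain: str,
            resseq: int, xyz: np.ndarray, occ: float, b: float,
            altloc: str = "") -> Atom:
        self._serial += 1
        a = Atom(self._serial, name, element, resname, chain, resseq,
                 altloc, np.asarray(xyz, float), occ, b)
        self.atoms.append(a)
        return a


def _add_fac_carbonyls(b: _Builder, anchor: np.ndarray, resseq: int,
                       occ: float, b_iso: float,
                       zero_occ_axis: int | None = None) -> list[str]:
    """Three facial carbonyls along -x, -y, -z from the metal."""
    zero_names = []
    for k, axis in enumerate(np.eye(3)):
        c_occ = occ
        names = (f"C{k + 1}", f"O{k + 1}")
        if zero_occ_axis is not None and k == zero_occ_axis:
            c_occ = 0.0
            zero_names.extend(names)
        b.add(names[0], "C", "RRE", "X", resseq, anchor - _CO_C * axis,
              c_occ, b_iso)
        b.add(names[1], "O", "RRE", "X", resseq, anchor - _CO_O * axis,
              c_occ, b_iso)
    return zero_names


def _imidazole_ring(b: _Builder, metal: np.ndarray, d1: float, resseq: int,
                    b_iso: float) -> None:
    """Approximate imidazole with NE2 exactly at d1 from the metal, ring
    extending away along +x so ND1 stays outside the vdW sum."""
    r = 1.16  # ring circumradius
    center = metal + np.array([d1 + r, 0.0, 0.0])
    ring = {"NE2": 180.0, "CD2": 108.0, "CG": 36.0, "ND1": -36.0, "CE1": -108.0}
    for name, ang in ring.items():
        el = name[0]
        pos = center + r * np.array([np.cos(np.radians(ang)),
                                     np.sin(np.radians(ang)), 0.0])
        b.add(name, el, "HIS", "A", resseq, pos, 1.0, b_iso)
    b.add("CB", "C", "HIS", "A", resseq,
          center + 2.6 * np.array([np.cos(np.radians(36)),
                                   np.sin(np.radians(36)), 0.0]), 1.0, b_iso)


def _carboxylate(b: _Builder, metal: np.ndarray, d1: float, d2: float,
                 qba: float, resname: str, names: tuple[str, str, str, str],
                 resseq: int, b_iso: float) -> None:
    """Carboxylate with one O exactly at d1 along +x and the second at d2 at
    the requested angle, in the xy plane."""
    o1 = metal + np.array([d1, 0.0, 0.0])
    th = np.radians(qba)
    o2 = metal + d2 * np.array([np.cos(th), np.sin(th), 0.0])
    mid = 0.5 * (o1 + o2)
    oo = np.linalg.norm(o2 - o1)
    away = mid - metal
    away = away / np.linalg.norm(away)
    h2 = max(1.25 ** 2 - (oo / 2.0) ** 2, 0.04)
    cg = mid + np.sqrt(h2) * away
    cb = mid + (np.sqrt(h2) + 1.5) * away
    n_o1, n_o2, n_c, n_cb = names
    b.add(n_o1, "O", resname, "A", resseq, o1, 1.0, b_iso)
    b.add(n_o2, "O", resname, "A", resseq, o2, 1.0, b_iso)
    b.add(n_c, "C", resname, "A", resseq, cg, 1.0, b_iso)
    b.add(n_cb, "C", resname, "A", resseq, cb, 1.0, b_iso)


def _scaffold(b: _Builder, origin: np.ndarray, b_iso: float = 20.0) -> None:
    """Short poly-alanine-like chain; geometry is schematic."""
    backbone = {"N": ("N", np.array([0.0, 0.0, 0.0])),
                "CA": ("C", np.array([1.2, 0.8, 0.0])),
                "C": ("C", np.array([2.4, 0.0, 0.3])),
                "O": ("O", np.array([2.6, -1.1, 0.6])),
                "CB": ("C", np.array([1.2, 1.8, 1.1]))}
    for i in range(6):
        base = origin + np.array([3.4 * i, 0.6 * (i % 2), 0.4 * i])
        for name, (el, off) in backbone.items():
            b.add(name, el, "ALA", "S", 100 + i, base + off, 1.0, b_iso)


def _anchors(n: int, cell: UnitCell) -> list[np.ndarray]:
    """Deterministic well-separated site anchors inside the cell."""
    out = []
    for i in range(n):
        col, row = i % 2, i // 2
        out.append(np.array([10.0, 12.0 + 16.0 * row, 12.0 + 16.0 * col]))
    span = max((a.max() for a in out), default=0.0)
    if out and (span > min(cell.a, cell.b, cell.c) * 2):  # generous guard
        raise ValueError("too many sites for the default anchor layout")
    return out


def generate_structure(specs: list[SiteSpec] | tuple[SiteSpec, ...] = DEFAULT_SITE_SPECS,
                       cell: UnitCell | None = None,
                       spacegroup: str = "P 21 21 21",
                       noise_sigma: float = 0.0,
                       seed: int = 0) -> tuple[Structure, GroundTruth]:
    """Build a crystal structure with planted metal sites.

    Deterministic given ``seed``: coordinates receive i.i.d. Gaussian noise
    of ``noise_sigma`` per component; the ground truth records pre-noise
    geometry.  Site anchors are laid out so that no two sites (or their
    symmetry images, for the default cell) approach within 6 A.
    """
    cell = cell or UnitCell(40.0, 80.0, 80.0)
    rng = np.random.default_rng(seed)
    b = _Builder()
    gt = GroundTruth(seed=seed, noise_sigma=noise_sigma)
    anchors = _anchors(len(specs), cell)
    for i in range(len(anchors)):
        for j in range(i + 1, len(anchors)):
            if np.linalg.norm(anchors[i] - anchors[j]) < 6.0:
                raise ValueError("site anchors closer than 6 A")

    resseq_metal = 200
    resseq_protein = 10
    group_id = 0
    for idx, spec in enumerate(specs):
        anchor = anchors[idx]
        planted = PlantedSite(index=idx, template=spec.template,
                              residue_key="", metal_serial=0,
                              metal_xyz=tuple(anchor), occupancy=spec.occupancy)
        if spec.template == "his_monodentate":
            d1 = spec.d1 or 2.20
            m = b.add("RE", "Re", "RRE", "X", resseq_metal, anchor,
                      spec.occupancy, spec.b_iso * 1.2)
            zero = _add_fac_carbonyls(b, anchor, resseq_metal, spec.occupancy,
                                      spec.b_iso,
                                      0 if spec.zero_occupancy_co else None)
            for k, ax in ((0, np.array([0, 1.0, 0])), (1, np.array([0, 0, 1.0]))):
                b.add("O", "O", "HOH", "W", 300 + idx * 4 + k,
                      anchor + _AQUA * ax, spec.occupancy, spec.b_iso)
            _imidazole_ring(b, anchor, d1, resseq_protein, spec.b_iso)
            planted.donors = [{"atom": "NE2",
                               "residue": f"HIS{resseq_protein}A",
                               "distance": d1}]
            planted.denticity = "monodentate"
            planted.zero_occupancy_ligands = zero
        elif spec.template == "asp_anisobidentate":
            d1 = spec.d1 or 2.15
            d2 = spec.d2 or 3.30
            qba = _resolve_qba(spec, d1, d2)
            m = b.add("RE", "Re", "RRE", "X", resseq_metal, anchor,
                      spec.occupancy, spec.b_iso * 1.2)
            zero = _add_fac_carbonyls(b, anchor, resseq_metal, spec.occupancy,
                                      spec.b_iso,
                                      0 if spec.zero_occupancy_co else None)
            _carboxylate(b, anchor, d1, d2, qba, "ASP",
                         ("OD1", "OD2", "CG", "CB"), resseq_protein, spec.b_iso)
            planted.donors = [
                {"atom": "OD1", "residue": f"ASP{resseq_protein}A",
                 "distance": d1},
                {"atom": "OD2", "residue": f"ASP{resseq_protein}A",
                 "distance": d2}]
            planted.qba = qba
            planted.denticity = "anisobidentate"
            planted.zero_occupancy_ligands = zero
        elif spec.template == "chelate_OO":
            d1 = spec.d1 or 2.15
            d2 = spec.d2 or d1
            qba = spec.qba or 59.6
            m = b.add("RE", "Re", "RRE", "X", resseq_metal, anchor,
                      spec.occupancy, spec.b_iso * 1.2)
            _add_fac_carbonyls(b, anchor, resseq_metal, spec.occupancy,
                               spec.b_iso)
            _carboxylate(b, anchor, d1, d2, qba, "GLU",
                         ("OE1", "OE2", "CD", "CG"), resseq_protein, spec.b_iso)
            planted.donors = [
                {"atom": "OE1", "residue": f"GLU{resseq_protein}A",
                 "distance": d1},
                {"atom": "OE2", "residue": f"GLU{resseq_protein}A",
                 "distance": d2}]
            planted.qba = qba
            planted.denticity = "bidentate_chelate"
        elif spec.template == "glu_vicinity":
            d2 = spec.d2 or 3.30
            m = b.add("RE", "Re", "RRE", "X", resseq_metal, anchor,
                      spec.occupancy, spec.b_iso * 1.2)
            oe2 = anchor + np.array([d2, 0.0, 0.0])
            oe1 = oe2 + np.array([1.6, 1.5, 0.0])  # away from the metal
            b.add("OE2", "O", "GLU", "A", resseq_protein, oe2, 1.0, spec.b_iso)
            b.add("OE1", "O", "GLU", "A", resseq_protein, oe1, 1.0, spec.b_iso)
            b.add("CD", "C", "GLU", "A", resseq_protein,
                  oe2 + np.array([0.8, 1.0, 0.0]), 1.0, spec.b_iso)
            planted.donors = [{"atom": "OE2",
                               "residue": f"GLU{resseq_protein}A",
                               "distance": d2}]
            planted.denticity = "nonbinding_vicinity"
        elif spec.template == "disorder_pair":
            sep = spec.separation or 1.5
            occ2 = spec.occupancy2 if spec.occupancy2 is not None else 0.15
            m = b.add("RE", "Re", "RRE", "X", resseq_metal, anchor,
                      spec.occupancy, spec.b_iso * 1.2)
            b.add("RE", "Re", "RRE", "X", resseq_metal + 1,
                  anchor + np.array([sep, 0.0, 0.0]), occ2, spec.b_iso * 1.2)
            planted.disorder_group = group_id
            planted.donors = []
            group_id += 1
            resseq_metal += 1  # consumed an extra residue number
        elif spec.template == "nonbinding":
            m = b.add("RE", "Re", "RRE", "X", resseq_metal, anchor,
                      spec.occupancy, spec.b_iso * 1.2)
            _add_fac_carbonyls(b, anchor, resseq_metal, spec.occupancy,
                               spec.b_iso)
            b.add("CB", "C", "ALA", "A", resseq_protein,
                  anchor + np.array([5.5, 0.0, 0.0]), 1.0, spec.b_iso)
            planted.denticity = None
        planted.residue_key = f"RRE{m.resseq}X" if spec.template != "disorder_pair" \
            else f"RRE{m.resseq}X"
        planted.metal_serial = m.serial
        planted.metal_xyz = tuple(float(x) for x in m.xyz)
        gt.sites.append(planted)
        resseq_metal += 2
        resseq_protein += 2

    _scaffold(b, np.array([24.0, 58.0, 58.0]))

    if noise_sigma > 0:
        noise = rng.normal(0.0, noise_sigma, size=(len(b.atoms), 3))
        for a, dx in zip(b.atoms, noise):
            a.xyz = a.xyz + dx

    s = Structure(atoms=b.atoms, cell=cell,
                  spacegroup=SpaceGroup.from_name(spacegroup),
                  source={"label": f"synthetic-seed{seed}", "format": "memory"})
    s.validate()
    return s, gt


def generate_map(s: Structure, peak_sigma_heights: list[float],
                 grid_spacing: float = 0.6, noise_rms: float = 1.0,
                 seed: int = 0, metals: tuple[str, ...] = ("RE",),
                 peak_width: float = 0.5) -> DensityMap:
    """Synthetic anomalous-style map: Gaussian peaks at the metal positions
    over white background noise.

    Requested heights are in map-sigma units of the *final* map.  Because the
    background noise at a peak voxel shifts any a-priori amplitude by about
    one sigma, each amplitude is calibrated against the realized map (two
    fixed-point passes with the default local-max estimator), so the planted
    heights are achieved rather than merely expected.
    """
    if s.cell is None:
        raise ValueError("structure has no unit cell")
    metal_atoms = [a for a in s.atoms if a.element.upper() in
                   {m.upper() for m in metals}]
    if len(peak_sigma_heights) != len(metal_atoms):
        raise ValueError(
            f"need one height per metal atom ({len(metal_atoms)}), got "
            f"{len(peak_sigma_heights)}")
    cell = s.cell
    dims = tuple(max(int(np.ceil(L / grid_spacing)), 2)
                 for L in (cell.a, cell.b, cell.c))
    rng = np.random.default_rng(seed)
    noise = (rng.normal(0.0, noise_rms, size=dims).astype(np.float32)
             if noise_rms > 0 else np.zeros(dims, dtype=np.float32))

    # precompute each peak's local grid footprint out to 4 widths
    fx = [np.arange(n) / n for n in dims]
    peaks = []
    for a, h in zip(metal_atoms, peak_sigma_heights):
        if not h:
            peaks.append(None)
            continue
        frac = cell.fractionalize(a.xyz) % 1.0
        idx_c = np.round(frac * dims).astype(int)
        half = np.ceil(4.0 * peak_width / grid_spacing).astype(int)
        rng_idx = [np.arange(idx_c[k] - half, idx_c[k] + half + 1) % dims[k]
                   for k in range(3)]
        grid_frac = np.stack(np.meshgrid(
            *[(np.arange(idx_c[k] - half, idx_c[k] + half + 1)) / dims[k]
              for k in range(3)], indexing="ij"), axis=-1)
        xyz = cell.orthogonalize(grid_frac.reshape(-1, 3))
        d2 = ((xyz - cell.orthogonalize(frac)) ** 2).sum(axis=1)
        shape = tuple(len(r) for r in rng_idx)
        profile = np.exp(-d2 / (2.0 * peak_width ** 2)).reshape(shape)
        peaks.append((np.ix_(*rng_idx), profile.astype(np.float32)))

    amps = [float(h or 0.0) * (noise_rms if noise_rms > 0 else 1.0)
            for h in peak_sigma_heights]
    sg_name = s.spacegroup.name if s.spacegroup else "P 1"

    def compose() -> DensityMap:
        values = noise.copy()
        for amp, pk in zip(amps, peaks):
            if pk is None:
                continue
            ix, profile = pk
            values[ix] += np.float32(amp) * profile
        return DensityMap(values=values, cell=cell, spacegroup=sg_name,
                          source=f"synthetic-map-seed{seed}")

    for _ in range(2):
        dmap = compose()
        if dmap.sigma <= 0:
            return dmap  # constant map (no peaks, no noise)
        for k, (a, h) in enumerate(zip(metal_atoms, peak_sigma_heights)):
            if not h or peaks[k] is None:
                continue
            measured = peak_height(dmap, a.xyz, mode="local_max", radius=0.75)
            if measured > 0.1:
                amps[k] *= float(h) / measured
    return compose()
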