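"""Crystal-structure data model: atoms, unit cells, symmetry operators, file I/O.

Coordinates are orthogonal Angstroms everywhere in the public API; fractional
coordinates appear only inside symmetry operations.  PDB and mmCIF files are
read and written through :mod:`gemmi`; the in-memory model is the package's
own lightweight types so that downstream geometry code stays independent of
any particular I/O library.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom", "UnitCell", "SymOp", "SpaceGroup", "Structure",
    "read_structure", "write_structure", "parse_symop", "apply_symop",
    "spacegroup_ops", "STANDARD_RESIDUES",
]

# Heavy-atom standard residues (amino acids + water); used for ATOM/HETATM
# assignment on writing, and for protein/ligand partitioning downstream.
STANDARD_RESIDUES = frozenset("""
ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL
MSE HOH WAT
""".split())

_KNOWN_ELEMENTS = frozenset("""
H HE LI BE B C N O F NE NA MG AL SI P S CL AR K CA SC TI V CR MN FE CO NI CU ZN
GA GE AS SE BR KR RB SR Y ZR NB MO TC RU RH PD AG CD IN SN SB TE I XE CS BA
LA CE PR ND PM SM EU GD TB DY HO ER TM YB LU HF TA W RE OS IR PT AU HG TL PB BI
""".split())


@dataclass
class Atom:
    """One atom record of a refined model."""

    serial: int
    name: str
    element: str
    resname: str
    chain: str
    resseq: int
    altloc: str = ""
    xyz: np.ndarray = field(default_factory=lambda: np.zeros(3))
    occupancy: float = 1.0
    b_iso: float = 20.0
    anisou: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chain, self.resseq, self.name, self.altloc)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def is_water(self) -> bool:
        return self.resname in ("HOH", "WAT")

    def copy(self) -> "Atom":
        return Atom(self.serial, self.name, self.element, self.resname,
                    self.chain, self.resseq, self.altloc, self.xyz.copy(),
                    self.occupancy, self.b_iso, self.anisou)


class UnitCell:
    """Unit cell with orthogonalization / fractionalization transforms.

    Uses the standard PDB convention: *a* along x, *b* in the xy plane.
    """

    def __init__(self, a: float, b: float, c: float,
                 alpha: float = 90.0, beta: float = 90.0, gamma: float = 90.0):
        if min(a, b, c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (alpha, beta, gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180)")
        self.a, self.b, self.c = float(a), float(b), float(c)
        self.alpha, self.beta, self.gamma = float(alpha), float(beta), float(gamma)
        ca, cb, cg = (np.cos(np.radians(x)) for x in (alpha, beta, gamma))
        sg = np.sin(np.radians(gamma))
        v = np.sqrt(max(1.0 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg, 0.0))
        if v <= 0:
            raise ValueError("degenerate unit cell")
        self._orth = np.array([
            [a, b * cg, c * cb],
            [0.0, b * sg, c * (ca - cb * cg) / sg],
            [0.0, 0.0, c * v / sg],
        ])
        self._frac = np.linalg.inv(self._orth)

    @property
    def parameters(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self._orth)))

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        """Fractional -> orthogonal Angstrom coordinates (vector or N x 3)."""
        return np.asarray(frac, dtype=float) @ self._orth.T

    def fractionalize(self, xyz: np.ndarray) -> np.ndarray:
        """Orthogonal Angstrom -> fractional coordinates (vector or N x 3)."""
        return np.asarray(xyz, dtype=float) @ self._frac.T

    def is_close(self, other: "UnitCell", rtol: float = 0.01) -> bool:
        return bool(np.allclose(self.parameters, other.parameters, rtol=rtol))

    def __repr__(self) -> str:
        return ("UnitCell(a=%.3f, b=%.3f, c=%.3f, alpha=%.2f, beta=%.2f, "
                "gamma=%.2f)" % self.parameters)


_TERM_RE = re.compile(r"[+-][^+-]+")


def _parse_component(comp: str) -> tuple[np.ndarray, Fraction]:
    row = np.zeros(3)
    trans = Fraction(0)
    s = comp.strip().replace(" ", "").replace("*", "")
    if not s:
        raise ValueError("empty symmetry-operator component")
    if s[0] not in "+-":
        s = "+" + s
    consumed = 0
    for m in _TERM_RE.finditer(s):
        consumed += len(m.group(0))
        term = m.group(0)
        sign = 1 if term[0] == "+" else -1
        body = term[1:]
        if not body:
            raise ValueError(f"malformed symmetry term {term!r}")
        axis = None
        if body[-1] in "xyzXYZ":
            axis = "xyz".index(body[-1].lower())
            body_coef = body[:-1]
            if body_coef == "":
                coef = Fraction(1)
            else:
                try:
                    coef = Fraction(body_coef)
                except ValueError as exc:
                    raise ValueError(f"malformed symmetry term {term!r}") from exc
            row[axis] += sign * float(coef)
        elif "/" in body or body.replace(".", "", 1).isdigit():
            try:
                trans += sign * Fraction(body)
            except (ValueError, ZeroDivisionError) as exc:
                raise ValueError(f"malformed symmetry term {term!r}") from exc
        else:
            raise ValueError(f"malformed symmetry term {term!r}")
    if consumed != len(s):
        raise ValueError(f"malformed symmetry component {comp!r}")
    return row, trans


@dataclass(frozen=True)
class SymOp:
    """Space-group operator in fractional space: x' = R x + t."""

    rotation: tuple[tuple[float, ...], ...]
    translation: tuple[float, ...]

    @property
    def R(self) -> np.ndarray:
        return np.array(self.rotation)

    @property
    def t(self) -> np.ndarray:
        return np.array(self.translation)

    @classmethod
    def from_arrays(cls, rotation: np.ndarray, translation: np.ndarray) -> "SymOp":
        det = np.linalg.det(rotation)
        if not np.isclose(abs(det), 1.0):
            raise ValueError(f"symmetry rotation has |det| = {abs(det):g}, not 1")
        return cls(tuple(map(tuple, np.asarray(rotation, float))),
                   tuple(np.asarray(translation, float)))

    @property
    def is_identity(self) -> bool:
        return (np.allclose(self.R, np.eye(3))
                and np.allclose(np.mod(self.t, 1.0), 0.0))

    def apply(self, frac: np.ndarray) -> np.ndarray:
        frac = np.asarray(frac, dtype=float)
        return frac @ self.R.T + self.t

    def compose(self, other: "SymOp") -> "SymOp":
        """self after other: (R1 R2) x + (R1 t2 + t1)."""
        return SymOp.from_arrays(self.R @ other.R, self.R @ other.t + self.t)

    def triplet(self) -> str:
        comps = []
        for i in range(3):
            parts = []
            for j, letter in enumerate("xyz"):
                c = Fraction(self.rotation[i][j]).limit_denominator(12)
                if c == 0:
                    continue
                sign = "-" if c < 0 else ("+" if parts else "")
                mag = abs(c)
                coef = "" if mag == 1 else f"{mag}"
                parts.append(f"{sign}{coef}{letter}")
            t = Fraction(self.translation[i]).limit_denominator(24)
            if t != 0:
                sign = "-" if t < 0 else "+"
                parts.append(f"{sign}{abs(t)}")
            comps.append("".join(parts) if parts else "0")
        return ",".join(comps)

    def same_modulo_lattice(self, other: "SymOp", tol: float = 1e-9) -> bool:
        dt = np.mod(self.t - other.t + 0.5, 1.0) - 0.5
        return bool(np.allclose(self.R, other.R, atol=tol)
                    and np.allclose(dt, 0.0, atol=tol))


def parse_symop(triplet: str) -> SymOp:
    """Parse an xyz-triplet like ``"-X,-Y+1/2,Z"`` into a :class:`SymOp`."""
    comps = triplet.split(",")
    if len(comps) != 3:
        raise ValueError(f"symmetry triplet needs 3 components: {triplet!r}")
    rows, trans = zip(*(_parse_component(c) for c in comps))
    return SymOp.from_arrays(np.vstack(rows), np.array([float(t) for t in trans]))


def apply_symop(op: SymOp, frac: np.ndarray) -> np.ndarray:
    """Apply ``op`` to fractional coordinates."""
    return op.apply(frac)


# Operator tables for the space groups of lysozyme crystal forms used here.
_EMBEDDED_GROUPS: dict[str, tuple[str, ...]] = {
    "P1": ("x,y,z",),
    "P212121": (
        "x,y,z", "-x+1/2,-y,z+1/2", "x+1/2,-y+1/2,-z", "-x,y+1/2,-z+1/2",
    ),
    "P43212": (
        "x,y,z", "-y+1/2,x+1/2,z+3/4", "-x,-y,z+1/2", "y+1/2,-x+1/2,z+1/4",
        "x+1/2,-y+1/2,-z+1/4", "-y,-x,-z+1/2", "-x+1/2,y+1/2,-z+3/4", "y,x,-z",
    ),
}


def _normalize_sg_name(name: str) -> str:
    return re.sub(r"[\s_()]", "", name).upper().replace("₁", "1").replace(
        "₂", "2").replace("₃", "3").replace("₄", "4")


def spacegroup_ops(name: str) -> list[SymOp]:
    """Symmetry operators for a Hermann-Mauguin space-group name.

    The groups used by the tetragonal/orthorhombic/triclinic lysozyme forms
    are embedded; anything else is resolved through gemmi's tables.
    """
    key = _normalize_sg_name(name)
    if key in _EMBEDDED_GROUPS:
        return [parse_symop(t) for t in _EMBEDDED_GROUPS[key]]
    sg = gemmi.find_spacegroup_by_name(name)
    if sg is None:
        raise ValueError(f"unknown space group {name!r}")
    return [parse_symop(op.triplet()) for op in sg.operations()]


@dataclass
class SpaceGroup:
    name: str
    ops: list[SymOp] = field(default_factory=list)

    @classmethod
    def from_name(cls, name: str) -> "SpaceGroup":
        return cls(name=name, ops=spacegroup_ops(name))

    @property
    def order(self) -> int:
        return len(self.ops)


@dataclass
class Structure:
    """Atoms plus unit cell, space group and provenance."""

    atoms: list[Atom]
    cell: UnitCell | None = None
    spacegroup: SpaceGroup | None = None
    source: dict = field(default_factory=dict)

    def validate(self) -> None:
        seen: set[tuple] = set()
        for a in self.atoms:
            if a.key in seen:
                raise ValueError(f"duplicate atom identifier {a.key}")
            seen.add(a.key)

    @property
    def label(self) -> str:
        return str(self.source.get("label", self.source.get("path", "structure")))

    def coords(self, atoms: Sequence[Atom] | None = None) -> np.ndarray:
        sel = self.atoms if atoms is None else atoms
        if not sel:
            return np.zeros((0, 3))
        return np.vstack([a.xyz for a in sel])

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def select(self, **fields) -> list[Atom]:
        out = []
        for a in self.atoms:
            if all(getattr(a, k) == v for k, v in fields.items()):
                out.append(a)
        return out

    def copy(self) -> "Structure":
        cell = UnitCell(*self.cell.parameters) if self.cell else None
        sg = SpaceGroup(self.spacegroup.name, list(self.spacegroup.ops)) \
            if self.spacegroup else None
        return Structure([a.copy() for a in self.atoms], cell, sg,
                         dict(self.source))


def _infer_element(name: str, resname: str) -> str:
    stripped = re.sub(r"[^A-Za-z]", "", name).upper()
    if len(stripped) >= 2 and stripped[:2] in _KNOWN_ELEMENTS:
        # two-letter match only when plausible (metals, halogens); organic
        # names like "CA" (alpha carbon) must resolve to C for protein residues
        if resname in STANDARD_RESIDUES and stripped[0] in ("C", "N", "O", "S", "H"):
            return stripped[0]
        return stripped[:2].capitalize()
    if stripped and stripped[0] in _KNOWN_ELEMENTS:
        return stripped[0]
    raise ValueError(f"cannot infer element from atom name {name!r}")


def _atom_from_gemmi(g_atom: gemmi.Atom, res: gemmi.Residue,
                     chain: gemmi.Chain) -> Atom:
    el = g_atom.element.name
    if not el or el == "X":
        warnings.warn(f"unknown element for atom {g_atom.name!r}; "
                      "inferring from atom name")
        el = _infer_element(g_atom.name, res.name)
    altloc = g_atom.altloc if g_atom.altloc not in ("\x00",) else ""
    aniso = None
    if g_atom.aniso.nonzero():
        u = g_atom.aniso
        aniso = (u.u11, u.u22, u.u33, u.u12, u.u13, u.u23)
    return Atom(
        serial=g_atom.serial, name=g_atom.name, element=el,
        resname=res.name, chain=chain.name, resseq=res.seqid.num,
        altloc=altloc, xyz=np.array([g_atom.pos.x, g_atom.pos.y, g_atom.pos.z]),
        occupancy=float(g_atom.occ), b_iso=float(g_atom.b_iso), anisou=aniso,
    )


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or (minimal) mmCIF model file.

    All atom records are kept, including metals, waters and alternate
    locations.  A missing space group falls back to P1 with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    st.merge_chain_parts()
    atoms: list[Atom] = []
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    model = st[0]
    for chain in model:
        for res in chain:
            for g_atom in res:
                atoms.append(_atom_from_gemmi(g_atom, res, chain))
    cell = None
    if st.cell.a > 1.0 and not (st.cell.a == st.cell.b == st.cell.c == 1.0):
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                        st.cell.alpha, st.cell.beta, st.cell.gamma)
    sg_name = st.spacegroup_hm or ""
    if not sg_name.strip():
        warnings.warn(f"{path.name}: no space group record; assuming P1")
        sg_name = "P 1"
    spacegroup = SpaceGroup.from_name(sg_name)
    fmt_label = "pdb" if path.suffix.lower() in (".pdb", ".ent") else (
        "mmcif" if "cif" in path.suffix.lower() else format)
    return Structure(atoms=atoms, cell=cell, spacegroup=spacegroup,
                     source={"path": str(path), "format": fmt_label,
                             "label": path.stem})


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.label
    if s.cell is not None:
        st.cell = gemmi.UnitCell(*s.cell.parameters)
    if s.spacegroup is not None:
        st.spacegroup_hm = s.spacegroup.name
    model = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    res_map: dict[tuple, gemmi.Residue] = {}
    for a in s.atoms:
        ch = chain_map.get(a.chain)
        if ch is None:
            ch = gemmi.Chain(a.chain)
            chain_map[a.chain] = ch
        rkey = (a.chain, a.resseq, a.resname)
        res = res_map.get(rkey)
        if res is None:
            res = gemmi.Residue()
            res.name = a.resname
            res.seqid = gemmi.SeqId(a.resseq, " ")
            res.het_flag = "A" if a.resname in STANDARD_RESIDUES else "H"
            ch.add_residue(res)
            res_map[rkey] = res
            res = ch[-1]
            res_map[rkey] = res
        ga = gemmi.Atom()
        ga.name = a.name
        ga.element = gemmi.Element(a.element)
        ga.pos = gemmi.Position(*a.xyz)
        ga.occ = a.occupancy
        ga.b_iso = a.b_iso
        ga.serial = a.serial
        if a.altloc:
            ga.altloc = a.altloc
        if a.anisou is not None:
            u11, u22, u33, u12, u13, u23 = a.anisou
            ga.aniso = gemmi.SMat33f(u11, u22, u33, u12, u13, u23)
        res.add_atom(ga)
    for ch in chain_map.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure, path: str | Path, format: str = "pdb") -> Path:
    """Write a structure as PDB or minimal mmCIF; returns the path written."""
    path = Path(path)
    if format == "pdb":
        for a in s.atoms:
            if len(a.name) > 4:
                raise ValueError(
                    f"atom name {a.name!r} exceeds 4 characters (PDB limit)")
        st = _to_gemmi(s)
        st.write_pdb(str(path))
    elif format == "mmcif":
        st = _to_gemmi(s)
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
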