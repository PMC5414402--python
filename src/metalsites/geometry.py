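"""Distances, angles, quasi bite angles, symmetry-expanded contact search,
and rigid-body (Kabsch) superposition.

The quasi bite angle (QBA) is the angle at the metal between two candidate
donor atoms of the same residue.  For a chelating carboxylate it approaches
the small-molecule bite angle (~59-60 deg for kappa2-O,O'); for monodentate
binding with a proximal second donor it is much smaller (~34-47 deg), so the
QBA separates the two binding regimes even at protein resolution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .structure import Atom, Structure, SymOp

__all__ = [
    "ContactHit", "QBAMeasurement", "distance", "angle",
    "implied_third_side", "neighbor_search", "kabsch_superpose",
]


def distance(p: np.ndarray, q: np.ndarray) -> float:
    """Euclidean distance between two points in Angstroms."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(p - q))


def angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    """Angle a-vertex-b in degrees, in [0, 180]."""
    va = np.asarray(a, dtype=float) - np.asarray(vertex, dtype=float)
    vb = np.asarray(b, dtype=float) - np.asarray(vertex, dtype=float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-length arm in angle computation")
    cosv = np.dot(va, vb) / (na * nb)
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def implied_third_side(d1: float, d2: float, theta: float) -> float:
    """Law-of-cosines third side for arm lengths d1, d2 and included angle.

    Inverse of :func:`angle` on the constructed triangle; used to cross-check
    measured QBAs against donor-donor separations.
    """
    if d1 <= 0 or d2 <= 0:
        raise ValueError("arm lengths must be positive")
    if not 0.0 < theta < 180.0:
        raise ValueError("angle must lie in (0, 180) degrees")
    th = np.radians(theta)
    return float(np.sqrt(d1 * d1 + d2 * d2 - 2.0 * d1 * d2 * np.cos(th)))


@dataclass
class ContactHit:
    """A neighbor of a center atom, possibly a symmetry/lattice image."""

    center: Atom
    partner: Atom
    symop: SymOp
    shift: tuple[int, int, int]
    distance: float
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    # filled by the site characterizer:
    contact_class: str | None = None
    esd: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def is_direct(self) -> bool:
        return self.symop.is_identity and self.shift == (0, 0, 0)


@dataclass
class QBAMeasurement:
    """Quasi bite angle at a metal vertex between two same-residue donors."""

    vertex: Atom
    arm_a: Atom
    arm_b: Atom
    angle: float
    esd: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle <= 180.0:
            raise ValueError("QBA outside [0, 180]")


def neighbor_search(s: Structure, center: Atom, radius: float,
                    use_symmetry: bool = True) -> list[ContactHit]:
    """All atoms (and their symmetry/lattice images) within ``radius`` of
    ``center``.

    With ``use_symmetry`` the search covers every space-group operator
    combined with lattice translations in {-1,0,1}^3, which is exhaustive as
    long as the radius is below half the shortest cell edge (asserted).
    The center atom itself and its own images at zero distance are excluded;
    a non-identity image of the center at finite distance is a genuine
    packing contact and is kept.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    hits: list[ContactHit] = []
    c_xyz = center.xyz
    atoms = s.atoms
    if not atoms:
        return hits
    coords = s.coords(atoms)

    if not use_symmetry:
        d = np.linalg.norm(coords - c_xyz, axis=1)
        identity = SymOp.from_arrays(np.eye(3), np.zeros(3))
        for i in np.nonzero(d <= radius)[0]:
            a = atoms[int(i)]
            if a is center:
                continue
            hits.append(ContactHit(center, a, identity, (0, 0, 0),
                                   float(d[i]), coords[int(i)].copy()))
        hits.sort(key=lambda h: h.distance)
        return hits

    if s.cell is None:
        raise ValueError("symmetry-expanded search requires a unit cell")
    if s.spacegroup is None or not s.spacegroup.ops:
        raise ValueError("symmetry-expanded search requires space-group operators")
    min_edge = min(s.cell.a, s.cell.b, s.cell.c)
    if radius >= 0.5 * min_edge:
        raise ValueError(
            f"radius {radius} exceeds half the shortest cell edge "
            f"({min_edge / 2:.2f} A); +-1 lattice translations would not cover it")

    frac = s.cell.fractionalize(coords)
    shifts = [np.array(t, dtype=float)
              for t in itertools.product((-1, 0, 1), repeat=3)]
    for op in s.spacegroup.ops:
        f_op = op.apply(frac)
        for shift in shifts:
            xyz = s.cell.orthogonalize(f_op + shift)
            d = np.linalg.norm(xyz - c_xyz, axis=1)
            for i in np.nonzero(d <= radius)[0]:
                i = int(i)
                a = atoms[i]
                if a is center and d[i] < 1e-6:
                    continue  # self or an image on a special position
                hits.append(ContactHit(center, a, op,
                                       tuple(int(x) for x in shift),
                                       float(d[i]), xyz[i].copy()))
    hits.sort(key=lambda h: (h.distance, h.partner.serial))
    return hits


def _proper_axis_relabelings() -> list[np.ndarray]:
    """The 24 proper rotations that permute and flip coordinate axes."""
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3))
            for i, p in enumerate(perm):
                m[i, p] = signs[i]
            if np.isclose(np.linalg.det(m), 1.0):
                mats.append(m)
    return mats


def _kabsch(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    P = mov - mov_c
    Q = ref - ref_c
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mov_c
    diff = (mov @ R.T + t) - ref
    rmsd = float(np.sqrt((diff * diff).sum() / len(ref)))
    return R, t, rmsd


def kabsch_superpose(ref_coords: np.ndarray, mov_coords: np.ndarray,
                     try_axis_relabeling: bool = False
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of matched coordinate sets.

    Returns ``(rotation, translation, rmsd)`` with ``rotation`` proper.
    With ``try_axis_relabeling`` the fit is additionally minimized over the
    24 proper axis permutation/sign conventions — needed when two models of
    the same crystal were indexed with the cell axes in different orders.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate lists must be matched N x 3 arrays")
    if len(ref) < 3:
        raise ValueError("superposition needs at least 3 matched points")
    for pts in (ref, mov):
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise ValueError("collinear point set; superposition is degenerate")
    candidates = [np.eye(3)]
    if try_axis_relabeling:
        candidates = _proper_axis_relabelings()
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for M in candidates:
        R, t, rmsd = _kabsch(ref, mov @ M.T)
        R_full = R @ M
        if best is None or rmsd < best[2]:
            best = (R_full, t, rmsd)
    assert best is not None
    return best
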