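import itertools

import numpy as np
import pytest

from metalsites import load_references, generate_structure
from metalsites.structure import Atom, SpaceGroup, Structure, UnitCell


@pytest.fixture(scope="session")
def refset():
    return load_references()


@pytest.fixture(scope="session")
def clean_structure():
    """Noise-free default synthetic structure with its ground truth."""
    return generate_structure(noise_sigma=0.0, seed=7)


def random_crystal(rng, spacegroup="P 1", n_atoms=30, cell_params=None):
    """Random atoms in a random (or given) cell; helper for oracle tests."""
    if cell_params is None:
        if spacegroup == "P 1":
            abc = rng.uniform(14.0, 25.0, 3)
            angles = rng.uniform(75.0, 105.0, 3)
            cell_params = (*abc, *angles)
        elif spacegroup == "P 43 21 2":
            a = rng.uniform(16.0, 26.0)
            cell_params = (a, a, rng.uniform(14.0, 22.0), 90, 90, 90)
        else:
            cell_params = (*rng.uniform(16.0, 30.0, 3), 90, 90, 90)
    cell = UnitCell(*cell_params)
    atoms = []
    for i, f in enumerate(rng.random((n_atoms, 3))):
        atoms.append(Atom(i + 1, f"C{i}", "C", "ALA", "A", i + 1, "",
                          cell.orthogonalize(f), 1.0, 20.0))
    return Structure(atoms, cell, SpaceGroup.from_name(spacegroup))


def brute_force_neighbors(s, center, radius):
    """Exhaustive 3x3x3 supercell expansion over all symmetry operators.

    Independent loop-based oracle for the vectorized neighbor search.
    Returns a set of (partner serial, operator index, lattice shift,
    distance rounded to 1e-9).
    """
    hits = set()
    frac_all = [s.cell.fractionalize(a.xyz) for a in s.atoms]
    for op_i, op in enumerate(s.spacegroup.ops):
        for shift in itertools.product((-1, 0, 1), repeat=3):
            for a, f in zip(s.atoms, frac_all):
                xyz = s.cell.orthogonalize(op.apply(f) + np.array(shift))
                d = float(np.linalg.norm(xyz - center.xyz))
                if d <= radius:
                    if a is center and d < 1e-6:
                        continue
                    hits.add((a.serial, op_i, shift, round(d, 9)))
    return hits
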