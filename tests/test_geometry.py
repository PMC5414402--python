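"""Geometry engine: distances, angles, QBA triangle identities, symmetry
neighbor search against a brute-force oracle, Kabsch superposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metalsites import (angle, distance, implied_third_side, kabsch_superpose,
                        neighbor_search)
from metalsites.structure import Atom, SpaceGroup, Structure, UnitCell

from conftest import brute_force_neighbors, random_crystal


class TestDistanceAngle:
    def test_basic_identities(self):
        assert distance([1, 2, 3], [1, 2, 3]) == 0.0
        assert distance([0, 0, 0], [3, 4, 0]) == 5.0
        assert angle([1, 0, 0], [0, 0, 0], [-1, 0, 0]) == pytest.approx(180.0)
        assert angle([1, 0, 0], [0, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_zero_arm_rejected(self):
        with pytest.raises(ValueError):
            angle([0, 0, 0], [0, 0, 0], [1, 0, 0])

    def test_equilateral_third_side(self):
        assert implied_third_side(1, 1, 60) == pytest.approx(1.0)

    def test_aspartate_dimer_reference_geometry(self):
        # carboxylate with Re-O1 2.149, Re...O2 3.35 at a 41.5 deg QBA has a
        # ~2.25 A O1...O2 separation, matching a carboxylate bite
        assert implied_third_side(2.149, 3.35, 41.5) == pytest.approx(2.25, abs=0.005)

    @given(st.floats(0.5, 5.0), st.floats(0.5, 5.0), st.floats(1.0, 179.0))
    @settings(max_examples=300, deadline=None)
    def test_angle_third_side_mutually_inverse(self, d1, d2, theta):
        side = implied_third_side(d1, d2, theta)
        a = np.array([d1, 0.0, 0.0])
        b = d2 * np.array([np.cos(np.radians(theta)),
                           np.sin(np.radians(theta)), 0.0])
        assert np.isclose(np.linalg.norm(a - b), side, rtol=0, atol=1e-9)
        assert np.isclose(angle(a, [0, 0, 0], b), theta, atol=1e-9)


class TestNeighborSearch:
    @pytest.mark.parametrize("sg", ["P 1", "P 21 21 21", "P 43 21 2"])
    def test_matches_brute_force_supercell(self, sg):
        rng = np.random.default_rng(11)
        for trial in range(3):
            s = random_crystal(rng, sg, n_atoms=25)
            ops = {op.triplet(): i for i, op in enumerate(s.spacegroup.ops)}
            center = s.atoms[int(rng.integers(len(s.atoms)))]
            radius = float(rng.uniform(4.0, 6.5))
            mine = {(h.partner.serial, ops[h.symop.triplet()], h.shift,
                     round(h.distance, 9))
                    for h in neighbor_search(s, center, radius)}
            assert mine == brute_force_neighbors(s, center, radius)

    def test_hit_distance_consistent_with_position(self):
        rng = np.random.default_rng(5)
        s = random_crystal(rng, "P 21 21 21", n_atoms=20)
        for h in neighbor_search(s, s.atoms[0], 6.0):
            assert np.isclose(np.linalg.norm(h.position - h.center.xyz),
                              h.distance, atol=1e-9)

    def test_p1_lattice_image_across_cell_edge(self):
        cell = UnitCell(10.0, 30.0, 30.0)
        a = Atom(1, "C1", "C", "ALA", "A", 1, "", [0.5, 15.0, 15.0])
        b = Atom(2, "C2", "C", "ALA", "A", 2, "", [9.8, 15.0, 15.0])
        s = Structure([a, b], cell, SpaceGroup.from_name("P 1"))
        hits = neighbor_search(s, a, 2.0)
        assert len(hits) == 1
        h = hits[0]
        assert h.partner is b and h.shift == (-1, 0, 0)
        assert h.distance == pytest.approx(0.7, abs=1e-9)

    def test_radius_guard_against_half_cell(self):
        rng = np.random.default_rng(0)
        s = random_crystal(rng, "P 1", cell_params=(10, 30, 30, 90, 90, 90))
        with pytest.raises(ValueError, match="half the shortest cell edge"):
            neighbor_search(s, s.atoms[0], 5.0)

    def test_requires_cell_for_symmetry(self):
        a = Atom(1, "C1", "C", "ALA", "A", 1, "", [0, 0, 0])
        s = Structure([a, Atom(2, "C2", "C", "ALA", "A", 2, "", [1, 0, 0])])
        with pytest.raises(ValueError, match="cell"):
            neighbor_search(s, a, 3.0, use_symmetry=True)
        hits = neighbor_search(s, a, 3.0, use_symmetry=False)
        assert len(hits) == 1 and hits[0].distance == 1.0


class TestKabsch:
    def test_self_superposition_zero(self):
        pts = np.random.default_rng(1).random((12, 3)) * 20
        R, t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd < 1e-9
        assert np.allclose(R, np.eye(3), atol=1e-9)

    def test_known_rotation_recovery(self):
        rng = np.random.default_rng(2)
        pts = rng.random((15, 3)) * 15
        theta = 0.7
        R0 = np.array([[np.cos(theta), -np.sin(theta), 0],
                       [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        mov = pts @ R0.T + np.array([3.0, -1.0, 2.0])
        R, t, rmsd = kabsch_superpose(pts, mov)
        assert rmsd < 1e-9
        # the recovered transform must undo the applied one
        assert np.allclose(R @ R0, np.eye(3), atol=1e-9)

    def test_axis_relabeled_copy_recovered(self):
        rng = np.random.default_rng(3)
        pts = rng.random((20, 3)) * 10
        M = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]], dtype=float)
        _, _, rmsd = kabsch_superpose(pts, pts @ M.T,
                                      try_axis_relabeling=True)
        assert rmsd < 1e-9

    def test_noise_rmsd_matches_expectation(self):
        rng = np.random.default_rng(4)
        pts = rng.random((400, 3)) * 30
        sigma = 0.1
        mov = pts + rng.normal(0, sigma, pts.shape)
        _, _, rmsd = kabsch_superpose(pts, mov)
        # per-atom 3-D displacement rmsd ~ sigma*sqrt(3), lightly reduced by
        # the 6 fitted rigid-body parameters
        assert rmsd == pytest.approx(sigma * np.sqrt(3), rel=0.10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestRigidMotionInvariance:
    def test_qba_invariant_under_rigid_motion(self, clean_structure):
        from metalsites import characterize
        s, _ = clean_structure
        rep1 = characterize(s)
        s2 = s.copy()
        theta = 0.4
        R = np.array([[1, 0, 0],
                      [0, np.cos(theta), -np.sin(theta)],
                      [0, np.sin(theta), np.cos(theta)]])
        for a in s2.atoms:
            a.xyz = R @ a.xyz + np.array([1.0, 2.0, -1.0])
        # symmetry off: a rigid motion breaks lattice registration but must
        # not change any internal angle
        from metalsites import SiteConfig
        cfg = SiteConfig(use_symmetry=False)
        rep1 = characterize(s, cfg)
        rep2 = characterize(s2, cfg)
        q1 = sorted(round(q.angle, 9) for site in rep1.sites for q in site.qbas)
        q2 = sorted(round(q.angle, 9) for site in rep2.sites for q in site.qbas)
        assert np.allclose(q1, q2, atol=1e-9)
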