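"""SASA, contact area, hydrogen bonds, RDF and stacking detection."""

import numpy as np
import pytest

from cdnakit.contacts import (
    ContactConfig,
    contact_area,
    detect_stacking,
    hydrogen_bonds,
    min_heavy_distance,
    rdf,
    sasa,
)
from cdnakit.core import AtomRecord
from cdnakit.geometry import rotation_about


def _atom(serial, pos, element="C", radius=0.17, name=None):
    return AtomRecord(serial, name or element, element, 1, "UNK", "A", pos,
                      vdw_radius=radius)


def _two_sphere_oracle(r1, r2, d, probe):
    """Closed-form SASA of two overlapping probe-extended spheres."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * np.pi * (R1**2 + R2**2)
    h1 = R1 - (R1**2 + d**2 - R2**2) / (2 * d)
    h2 = R2 - (R2**2 + d**2 - R1**2) / (2 * d)
    return 4 * np.pi * (R1**2 + R2**2) - 2 * np.pi * (R1 * h1 + R2 * h2)


class TestSASA:
    def test_single_atom_matches_analytic_sphere(self):
        total, per_atom = sasa([_atom(1, [0, 0, 0])])
        expect = 4 * np.pi * 0.31**2
        assert total == pytest.approx(expect, rel=1e-3)
        assert per_atom.sum() == pytest.approx(total)

    def test_disjoint_atoms_additive(self):
        a, b = _atom(1, [0, 0, 0]), _atom(2, [10, 0, 0])
        total, _ = sasa([a, b])
        single, _ = sasa([a])
        assert total == pytest.approx(2 * single, rel=1e-9)

    @pytest.mark.parametrize("d", [0.30, 0.40, 0.55])
    def test_two_sphere_overlap_matches_cap_formula(self, d):
        atoms = [_atom(1, [0, 0, 0]), _atom(2, [d, 0, 0])]
        total, _ = sasa(atoms)
        assert total == pytest.approx(
            _two_sphere_oracle(0.17, 0.17, d, 0.14), rel=0.02
        )

    def test_point_count_convergence_on_cd(self, cd0):
        coarse, _ = sasa(cd0.structure, ContactConfig(sasa_points=960))
        fine, _ = sasa(cd0.structure, ContactConfig(sasa_points=3840))
        assert abs(coarse - fine) / fine < 0.01

    def test_deterministic(self, cd0):
        t1, _ = sasa(cd0.structure)
        t2, _ = sasa(cd0.structure)
        assert t1 == t2

    def test_zero_radius_rejected(self):
        bad = _atom(1, [0, 0, 0])
        bad.vdw_radius = 0.0  # corrupted after construction
        with pytest.raises(ValueError):
            sasa([bad])


class TestContactArea:
    def test_zero_when_out_of_probe_reach(self):
        a = [_atom(1, [0, 0, 0])]
        b = [_atom(2, [0.17 + 0.17 + 2 * 0.14 + 0.01, 0, 0])]
        assert contact_area(a, b) == 0.0

    def test_positive_and_symmetric_in_contact(self):
        a = [_atom(1, [0, 0, 0])]
        b = [_atom(2, [0.35, 0, 0])]
        ab = contact_area(a, b)
        ba = contact_area(b, a)
        assert ab > 0
        assert ab == pytest.approx(ba, rel=1e-9)

    def test_monotone_decay_with_separation(self, cd0, duplex20):
        """A flake stacked over a terminal bp buries less area as it lifts."""
        from cdnakit.na_synth import PoseSpec, place_cd_pose

        areas = []
        for sep in (0.34, 0.5, 0.7, 1.0):
            posed = place_cd_pose(duplex20, cd0, PoseSpec("terminal_stack",
                                                          separation=sep))
            serials = set(posed.annotations["cd_serials"])
            cd = [a for a in posed.atoms if a.serial in serials]
            na = [a for a in posed.atoms if a.serial not in serials]
            areas.append(contact_area(cd, na))
        assert areas[0] > 0
        assert all(b < a for a, b in zip(areas, areas[1:]))

    def test_bound_poses_bury_area_unbound_does_not(self, cd_plus, duplex20):
        from cdnakit.na_synth import PoseSpec, place_cd_pose

        def buried(mode):
            posed = place_cd_pose(duplex20, cd_plus, PoseSpec(mode))
            serials = set(posed.annotations["cd_serials"])
            cd = [a for a in posed.atoms if a.serial in serials]
            na = [a for a in posed.atoms if a.serial not in serials]
            return contact_area(cd, na)

        assert buried("minor_groove") > 1.0
        assert buried("terminal_stack") > 1.0
        assert buried("unbound") == 0.0

    def test_shared_atoms_rejected(self):
        a = [_atom(1, [0, 0, 0])]
        with pytest.raises(ValueError):
            contact_area(a, a)

    def test_rigid_motion_invariance(self, cd0, duplex20):
        from cdnakit.na_synth import PoseSpec, place_cd_pose

        posed = place_cd_pose(duplex20, cd0, PoseSpec("terminal_stack"))
        serials = set(posed.annotations["cd_serials"])
        cd = [a for a in posed.atoms if a.serial in serials]
        na = [a for a in posed.atoms if a.serial not in serials]
        before = contact_area(cd, na)
        R = rotation_about([1, 1, 0], 61.0)
        moved = posed.copy()
        moved.set_coordinates(posed.coordinates() @ R.T + [3.0, 0.0, -1.0])
        cd2 = [a for a in moved.atoms if a.serial in serials]
        na2 = [a for a in moved.atoms if a.serial not in serials]
        # the Fibonacci point set is fixed in space, so rotation invariance
        # holds to sampling resolution, not machine precision
        assert contact_area(cd2, na2) == pytest.approx(before, rel=0.02)


class TestHydrogenBonds:
    def _dha(self, d_da, angle):
        d = _atom(1, [0, 0, 0], "N", 0.155)
        h = _atom(2, [0.10, 0, 0], "H", 0.11)
        # place acceptor so that D-H...A has the requested angle at H
        direction = rotation_about([0, 0, 1], 180.0 - angle) @ np.array([1.0, 0, 0])
        # choose |HA| so that |DA| = d_da
        from scipy.optimize import brentq

        def da(t):
            return np.linalg.norm(h.position + t * direction) - d_da

        t = brentq(da, 1e-4, 1.0)
        a = _atom(3, h.position + t * direction, "O", 0.152)
        return [(d, h)], [a]

    def test_linear_short_bond_counts(self):
        donors, acceptors = self._dha(0.29, 180.0)
        assert len(hydrogen_bonds(donors, acceptors)) == 1

    def test_long_distance_rejected(self):
        donors, acceptors = self._dha(0.40, 180.0)
        assert hydrogen_bonds(donors, acceptors) == []

    def test_bent_geometry_rejected(self):
        donors, acceptors = self._dha(0.29, 120.0)
        assert hydrogen_bonds(donors, acceptors) == []

    def test_donor_without_hydrogen_skipped(self):
        d = _atom(1, [0, 0, 0], "N", 0.155)
        not_h = _atom(2, [0.1, 0, 0], "C")
        a = _atom(3, [0.29, 0, 0], "O", 0.152)
        with pytest.warns(UserWarning):
            assert hydrogen_bonds([(d, not_h)], [a]) == []


class TestRDF:
    def test_uniform_points_give_flat_g(self):
        rng = np.random.default_rng(5)
        # uniform points in a sphere around a single central reference
        n = 30000
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= rng.uniform(0, 1, size=(n, 1)) ** (1 / 3) * 2.0
        table = rdf(np.zeros((1, 3)), pts, bin_width=0.1, r_max=2.0)
        mid = table[(table.r > 0.7) & (table.r < 1.8)]
        assert np.allclose(mid.g, 1.0, atol=0.1)

    def test_fixed_pair_occupies_single_bin(self):
        table = rdf(np.zeros((1, 3)), np.array([[0.5, 0, 0]]),
                    bin_width=0.1, r_max=1.0)
        occupied = table[table["count"] > 0]
        assert len(occupied) == 1
        assert occupied.r.iloc[0] == pytest.approx(0.55, abs=0.051)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rdf(np.zeros((0, 3)), np.zeros((3, 3)), 0.1, 1.0)

    def test_bad_binning_rejected(self):
        with pytest.raises(ValueError):
            rdf(np.zeros((1, 3)), np.zeros((1, 3)), 0.5, 0.4)


def _hex_ring(z=0.0, offset=(0.0, 0.0), normal_tilt=0.0, radius=0.14):
    ring = []
    for k in range(6):
        ang = np.radians(60 * k)
        p = np.array([radius * np.cos(ang) + offset[0],
                      radius * np.sin(ang) + offset[1], z])
        if normal_tilt:
            p = rotation_about([1, 0, 0], normal_tilt) @ p
        ring.append(_atom(k + 1, p))
    return ring


class TestStacking:
    def test_parallel_rings_at_stacking_distance(self):
        g = detect_stacking(_hex_ring(0.0), _hex_ring(0.34))
        assert g.stacked
        assert g.separation == pytest.approx(0.34, abs=1e-9)
        assert g.offset == pytest.approx(0.0, abs=1e-9)

    def test_t_shaped_rejected_by_angle_gate(self):
        tilted = [_atom(k + 1, rotation_about([1, 0, 0], 90.0) @ a.position
                        + np.array([0, 0, 0.34]))
                  for k, a in enumerate(_hex_ring())]
        g = detect_stacking(_hex_ring(0.0), tilted)
        assert not g.stacked and g.angle > 60

    def test_distance_gate(self):
        assert not detect_stacking(_hex_ring(0.0), _hex_ring(0.60)).stacked

    def test_lateral_offset_gate(self):
        g = detect_stacking(_hex_ring(0.0), _hex_ring(0.34, offset=(0.3, 0.0)))
        assert not g.stacked and g.offset == pytest.approx(0.3, abs=1e-9)

    def test_collinear_ring_rejected(self):
        line = [_atom(k + 1, [0.1 * k, 0, 0]) for k in range(5)]
        with pytest.raises(ValueError):
            detect_stacking(line, _hex_ring(0.34))


def test_min_heavy_distance_ignores_hydrogens():
    a = [_atom(1, [0, 0, 0], "C"), _atom(2, [0.4, 0, 0], "H", 0.11)]
    b = [_atom(3, [1.0, 0, 0], "O", 0.152)]
    assert min_heavy_distance(a, b) == pytest.approx(1.0)
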