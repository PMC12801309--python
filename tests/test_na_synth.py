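"""Synthetic duplexes, superhelix, CD poses and noisy trajectories."""

import numpy as np
import pytest

from cdnakit.contacts import contact_area, detect_stacking
from cdnakit.core import select
from cdnakit.helix import assign_base_frames
from cdnakit.na_synth import (
    DuplexSpec,
    PoseSpec,
    SuperhelixSpec,
    SynthTrajectorySpec,
    build_duplex,
    build_superhelix_dna,
    build_two_tetrad_mock,
    place_cd_pose,
    synthesize_trajectory,
)


class TestDuplex:
    def test_counts_and_chains(self):
        d = build_duplex(DuplexSpec("CG" * 10))
        chains = {a.chain_id for a in d.atoms}
        assert chains == {"A", "B"}
        assert len({(a.chain_id, a.residue_index) for a in d.atoms}) == 40
        assert len(d.annotations["pairing"]) == 20

    def test_watson_crick_complement(self):
        d = build_duplex(DuplexSpec("ACGT"))
        names = {}
        for chain, resi, resn in d.residues():
            names[(chain, resi)] = resn
        # strand B runs antiparallel: B:1 pairs A:4
        assert [names[("A", i)] for i in range(1, 5)] == ["DA", "DC", "DG", "DT"]
        assert [names[("B", i)] for i in range(1, 5)] == ["DA", "DC", "DG", "DT"]

    def test_sequence_validation(self):
        with pytest.raises(ValueError):
            build_duplex(DuplexSpec("ACGU"))  # U in B-DNA
        with pytest.raises(ValueError):
            build_duplex(DuplexSpec("ACGT", form="A-RNA"))  # T in RNA
        with pytest.raises(ValueError):
            build_duplex(DuplexSpec("ACGX"))

    def test_a_rna_defaults(self):
        d = build_duplex(DuplexSpec("ACGU", form="A-RNA"))
        assert d.annotations["twist"] == pytest.approx(32.7)
        assert d.annotations["rise"] == pytest.approx(0.281)

    def test_overhang_is_annotated_unpaired(self, duplex20_overhang):
        assert duplex20_overhang.annotations["unpaired"] == [("A", 21)]
        res = duplex20_overhang.residue_atoms("A", 21)
        assert res and all("unpaired" in a.tags for a in res)


class TestSuperhelix:
    def test_bp_origins_on_parametric_curve(self):
        spec = SuperhelixSpec(n_bp=60, turns=0.8)
        sh = build_superhelix_dna(spec)
        frames = assign_base_frames(sh)
        lookup = {(f.chain_id, f.residue_index): f for f in frames}
        from cdnakit.helix import bp_frame

        total = 2 * np.pi * spec.turns
        for i, (a, b) in enumerate(sh.annotations["pairing"]):
            _, _, om = bp_frame(lookup[tuple(a)], lookup[tuple(b)])
            th = total * i / (spec.n_bp - 1)
            expect = np.array([
                spec.radius * np.cos(th), spec.radius * np.sin(th),
                -spec.pitch * th / (2 * np.pi),
            ])
            assert np.linalg.norm(om - expect) < 0.05

    def test_left_handedness(self):
        sh = build_superhelix_dna(SuperhelixSpec(n_bp=40, turns=0.5))
        frames = assign_base_frames(sh)
        lookup = {(f.chain_id, f.residue_index): f for f in frames}
        from cdnakit.helix import bp_frame

        oms = np.array([
            bp_frame(lookup[tuple(a)], lookup[tuple(b)])[2]
            for a, b in sh.annotations["pairing"]
        ])
        # z decreases while the azimuth advances counterclockwise
        assert oms[-1, 2] < oms[0, 2]

    def test_zero_turns_degenerate_straight(self):
        sh = build_superhelix_dna(SuperhelixSpec(n_bp=30, turns=0.0))
        assert sh.annotations["superhelix"]["degenerate_straight"]
        frames = assign_base_frames(sh)
        z = np.array([f.origin for f in frames if f.chain_id == "A"])[:, :2]
        assert np.abs(z).max() < 1e-9

    def test_invalid_pitch(self):
        with pytest.raises(ValueError):
            SuperhelixSpec(pitch=-1.0)


class TestPoses:
    def test_terminal_stack_separation(self, cd0, duplex20):
        posed = place_cd_pose(duplex20, cd0, PoseSpec("terminal_stack"))
        serials = set(posed.annotations["cd_serials"])
        layer_of = posed.annotations["cd_layer_of_atom"]
        bottom_layer = min(
            (a for a in posed.atoms if a.serial in serials and a.element == "C"),
            key=lambda a: layer_of[a.serial],
        )
        bottom = [a for a in posed.atoms if a.serial in serials
                  and a.element == "C"
                  and layer_of[a.serial] == layer_of[bottom_layer.serial]]
        from cdnakit.templates import RING_NAMES
        from cdnakit.helix import base_letter

        i = len(duplex20.annotations["pairing"]) - 1
        keys = [tuple(k) for k in duplex20.annotations["pairing"][i]]
        rings = []
        for chain, resi in keys:
            for a in posed.residue_atoms(chain, resi):
                letter = base_letter(a.residue_name)
                if letter and a.name in RING_NAMES[letter]:
                    rings.append(a)
        geom = detect_stacking(bottom, rings)
        assert geom.separation == pytest.approx(0.34, abs=0.005)

    def test_unbound_pose_has_zero_contact_area(self, cd0, duplex20):
        posed = place_cd_pose(duplex20, cd0, PoseSpec("unbound"))
        serials = set(posed.annotations["cd_serials"])
        cd = [a for a in posed.atoms if a.serial in serials]
        na = [a for a in posed.atoms if a.serial not in serials]
        assert contact_area(cd, na) == 0.0

    def test_no_severe_steric_overlap_in_any_mode(self, cd_plus, duplex20,
                                                  duplex20_overhang, tetrad_mock):
        from scipy.spatial.distance import cdist

        for mode, na in [
            ("minor_groove", duplex20), ("major_groove", duplex20),
            ("backbone", duplex20), ("terminal_stack", duplex20),
            ("unpaired_stack", duplex20_overhang),
            ("tetrad_stack", tetrad_mock), ("unbound", duplex20),
        ]:
            posed = place_cd_pose(na, cd_plus, PoseSpec(mode))
            serials = set(posed.annotations["cd_serials"])
            xyz_cd = np.array([a.position for a in posed.atoms
                               if a.serial in serials])
            r_cd = np.array([a.vdw_radius for a in posed.atoms
                             if a.serial in serials])
            xyz_na = np.array([a.position for a in posed.atoms
                               if a.serial not in serials])
            r_na = np.array([a.vdw_radius for a in posed.atoms
                             if a.serial not in serials])
            ratio = (cdist(xyz_cd, xyz_na) / (r_cd[:, None] + r_na[None, :])).min()
            assert ratio >= 0.8, mode

    def test_tetrad_requires_quartet_annotation(self, cd0, duplex20):
        with pytest.raises(ValueError, match="quartet"):
            place_cd_pose(duplex20, cd0, PoseSpec("tetrad_stack"))

    def test_tetrad_mock_quartets(self, tetrad_mock):
        assert len(tetrad_mock.annotations["quartets"]) == 2
        assert len(select(tetrad_mock, "residue_name=DG")) == tetrad_mock.n_atoms


class TestTrajectory:
    def test_zero_noise_all_frames_identical(self, cd0, duplex20):
        posed = place_cd_pose(duplex20, cd0, PoseSpec("terminal_stack"))
        tr = synthesize_trajectory(posed, SynthTrajectorySpec(5, 0.0, seed=1))
        for f in range(1, 5):
            np.testing.assert_array_equal(tr.frames[f], tr.frames[0])

    def test_seed_determinism_and_variation(self, duplex20):
        spec = SynthTrajectorySpec(10, 0.03, seed=9)
        a = synthesize_trajectory(duplex20, spec)
        b = synthesize_trajectory(duplex20, spec)
        np.testing.assert_array_equal(a.frames, b.frames)
        c = synthesize_trajectory(duplex20, SynthTrajectorySpec(10, 0.03, seed=10))
        assert not np.array_equal(a.frames, c.frames)

    def test_noise_amplitude_calibrated(self, duplex20):
        sigma = 0.05
        tr = synthesize_trajectory(
            duplex20, SynthTrajectorySpec(201, sigma, seed=3)
        )
        disp = tr.frames[1:] - tr.frames[0]
        assert disp.std() == pytest.approx(sigma, rel=0.05)

    def test_event_moves_cd_from_bulk_to_pose(self, cd0, duplex20):
        from cdnakit.contacts import min_heavy_distance

        posed = place_cd_pose(duplex20, cd0, PoseSpec("major_groove"))
        tr = synthesize_trajectory(
            posed, SynthTrajectorySpec(40, 0.0, event_frame=20, seed=0)
        )
        serials = set(posed.annotations["cd_serials"])
        cd_atoms = [a for a in posed.atoms if a.serial in serials]
        na_atoms = [a for a in posed.atoms if a.serial not in serials]
        idx_cd = [k for k, a in enumerate(posed.atoms) if a.serial in serials]
        idx_na = [k for k, a in enumerate(posed.atoms) if a.serial not in serials]

        def dmin(f):
            from scipy.spatial.distance import cdist

            return cdist(tr.frames[f][idx_cd], tr.frames[f][idx_na]).min()

        assert dmin(0) > 2.0  # bulk before the event
        np.testing.assert_allclose(
            tr.frames[35], posed.coordinates()[: len(posed.atoms)], atol=1e-12
        )

    def test_event_requires_placed_cd(self, duplex20):
        with pytest.raises(ValueError, match="cd_serials"):
            synthesize_trajectory(
                duplex20, SynthTrajectorySpec(10, 0.0, event_frame=2)
            )
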