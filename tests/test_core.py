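"""Structure model, PDB/XYZ I/O and superposition."""

import numpy as np
import pytest

from cdnakit.core import (
    AtomRecord,
    MolecularStructure,
    PDBFormatError,
    SelectionError,
    Trajectory,
    read_pdb,
    read_xyz,
    select,
    superpose_rmsd,
    write_pdb,
    write_xyz,
)
from cdnakit.geometry import rotation_about


def _toy_structure(n=5):
    atoms = [
        AtomRecord(i + 1, f"C{i+1}", "C", 1 + i // 3, "UNK", "A",
                   [0.1 * i, 0.02 * i * i, 0.3 - 0.05 * i])
        for i in range(n)
    ]
    return MolecularStructure(atoms=atoms, title="toy")


class TestPDBRoundTrip:
    def test_coordinates_and_metadata_survive(self, tmp_path):
        s = _toy_structure()
        s.atoms[2].formal_charge = -1
        path = tmp_path / "toy.pdb"
        write_pdb(s, path)
        back = read_pdb(path)
        assert back.n_atoms == s.n_atoms
        np.testing.assert_allclose(back.coordinates(), s.coordinates(), atol=1e-4)
        for a, b in zip(s.atoms, back.atoms):
            assert (a.residue_index, a.residue_name, a.chain_id, a.element) == (
                b.residue_index, b.residue_name, b.chain_id, b.element
            )
        assert back.atoms[2].formal_charge == -1

    def test_angstrom_to_nm_conversion(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(
            "ATOM      1  C   UNK A   1       3.400   0.000   0.000"
            "  1.00  0.00           C\nEND\n"
        )
        s = read_pdb(path)
        assert s.atoms[0].position[0] == pytest.approx(0.340, abs=1e-9)

    def test_multimodel_yields_trajectory(self, tmp_path):
        s = _toy_structure(10)
        frames = np.stack([s.coordinates() + 0.01 * k for k in range(5)])
        path = tmp_path / "traj.pdb"
        write_pdb(Trajectory(s, frames), path)
        t = read_pdb(path)
        assert isinstance(t, Trajectory)
        assert t.n_frames == 5 and t.topology.n_atoms == 10
        np.testing.assert_allclose(t.frames, frames, atol=1e-4)

    def test_inconsistent_model_sizes_rejected(self, tmp_path):
        lines = ["MODEL     1"]
        lines += ["ATOM      1  C   UNK A   1       0.000   0.000   0.000"
                  "  1.00  0.00           C"]
        lines += ["ENDMDL", "MODEL     2", "ENDMDL", "END"]
        # second model empty -> dropped; craft a real mismatch instead
        path = tmp_path / "bad.pdb"
        body = (
            "MODEL     1\n"
            "ATOM      1  C   UNK A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  C   UNK A   1       1.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\nMODEL     2\n"
            "ATOM      1  C   UNK A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n"
        )
        path.write_text(body)
        with pytest.raises(PDBFormatError, match="model 2"):
            read_pdb(path)

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "ATOM      1  C   UNK A   1       xx.xxx   0.000   0.000"
            "  1.00  0.00           C\n"
        )
        with pytest.raises(PDBFormatError, match="line 1"):
            read_pdb(path)

    def test_empty_structure_refused(self, tmp_path):
        with pytest.raises(ValueError):
            write_pdb(MolecularStructure(), tmp_path / "x.pdb")

    def test_biotite_reads_our_output(self, tmp_path):
        """Independent reader oracle: biotite agrees on coordinates."""
        biotite_pdb = pytest.importorskip("biotite.structure.io.pdb")
        s = _toy_structure(7)
        path = tmp_path / "toy.pdb"
        write_pdb(s, path)
        arr = biotite_pdb.PDBFile.read(str(path)).get_structure(model=1)
        np.testing.assert_allclose(arr.coord * 0.1, s.coordinates(), atol=1e-4)
        assert list(arr.res_id) == [a.residue_index for a in s.atoms]


class TestXYZ:
    def test_round_trip(self, tmp_path):
        s = _toy_structure(4)
        path = tmp_path / "s.xyz"
        write_xyz(s, path)
        back = read_xyz(path)
        np.testing.assert_allclose(back.coordinates(), s.coordinates(), atol=1e-6)

    def test_concatenated_frames(self, tmp_path):
        s = _toy_structure(4)
        tr = Trajectory(s, np.stack([s.coordinates(), s.coordinates() + 0.1]))
        path = tmp_path / "t.xyz"
        write_xyz(tr, path)
        back = read_xyz(path)
        assert isinstance(back, Trajectory) and back.n_frames == 2


class TestSelect:
    def test_empty_query_is_identity(self, duplex20):
        assert len(select(duplex20, "")) == duplex20.n_atoms

    def test_phosphate_count_excludes_5prime_termini(self):
        from cdnakit.na_synth import DuplexSpec, build_duplex

        d = build_duplex(DuplexSpec("ACGTACGTACGT"))
        assert len(select(d, "element=P")) == 22  # 2*12 - 2

    def test_conjunction_and_ranges(self, duplex20):
        sub = select(duplex20, "element=P chain=A residue_index=2:5")
        assert len(sub) == 4 and all(a.chain_id == "A" for a in sub)

    def test_tag_selection_counts_functional_groups(self, cd_plus):
        atoms = select(cd_plus.structure, "tag=func:NH3+")
        sites = {t for a in atoms for t in a.tags if t.startswith("site:")}
        assert len(sites) == 9  # one tag group per NH3+ site

    def test_unknown_key_raises(self, duplex20):
        with pytest.raises(SelectionError):
            select(duplex20, "flavour=up")


def _quaternion_grid_rmsd(mobile, reference, n=20000, seed=11):
    """Brute-force oracle: best RMSD over many random rotations, polished
    with a derivative-free local search (independent of the Kabsch path)."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    A = mobile - mobile.mean(axis=0)
    B = reference - reference.mean(axis=0)

    def rmsd_of(R):
        return np.sqrt(((A @ R.T - B) ** 2).sum(axis=1).mean())

    rng = np.random.default_rng(seed)
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    mats = Rotation.from_quat(q).as_matrix()
    vals = ((np.einsum("nij,kj->nki", mats, A) - B) ** 2).sum(-1).mean(-1)
    best = np.sqrt(vals.min())
    rv0 = Rotation.from_matrix(mats[vals.argmin()]).as_rotvec()
    res = minimize(
        lambda rv: rmsd_of(Rotation.from_rotvec(rv).as_matrix()),
        rv0, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
    )
    return min(best, res.fun)


class TestSuperpose:
    def test_identity_is_zero(self):
        x = np.random.default_rng(0).normal(size=(6, 3))
        _, _, rmsd = superpose_rmsd(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_invariance_and_symmetry(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 3))
        R = rotation_about([0, 0, 1], 90.0)
        y = x @ R.T + np.array([1.0, -2.0, 0.5])
        _, _, fwd = superpose_rmsd(x, y)
        _, _, bwd = superpose_rmsd(y, x)
        assert fwd == pytest.approx(0.0, abs=1e-9)
        assert abs(fwd - bwd) < 1e-9

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        # near-planar set that would tempt a reflection
        x = rng.normal(size=(5, 3)) * np.array([1.0, 1.0, 1e-4])
        y = -x
        R, _, _ = superpose_rmsd(x, y)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_bruteforce_rotation_search(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(4, 3)) * 0.4
        b = rng.normal(size=(4, 3)) * 0.4
        _, _, rmsd = superpose_rmsd(a, b)
        oracle = _quaternion_grid_rmsd(a, b)
        assert rmsd == pytest.approx(oracle, abs=1e-4)
        assert rmsd <= oracle + 1e-9  # Kabsch is the true minimum

    def test_collinear_set_flagged_translation_only(self):
        from cdnakit.geometry import kabsch

        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        R, t, rmsd, degenerate = kabsch(line, line + [0.0, 1.0, 0.0])
        assert degenerate
        np.testing.assert_allclose(R, np.eye(3))
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_counts_raise(self):
        with pytest.raises(ValueError):
            superpose_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))
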