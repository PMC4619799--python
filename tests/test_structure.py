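import numpy as np
import pytest

from polyqlab import synthetic as syn
from polyqlab.structure import (
    Conformer,
    Ensemble,
    PDBParseError,
    Residue,
    read_pdb,
    read_xyz,
    superpose_rmsd,
    superpose_rmsd_coords,
    write_pdb,
    write_xyz,
)

from conftest import random_rotation


def _tiny_pdb(path, models):
    lines = []
    serial = 1
    for m, coords in enumerate(models, start=1):
        if len(models) > 1:
            lines.append(f"MODEL     {m:>4}")
        for r, xyz in enumerate(coords, start=1):
            x, y, z = xyz
            lines.append(
                f"ATOM  {serial:>5}  CA  GLN A{r:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        if len(models) > 1:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


class TestReadPDB:
    def test_single_model_two_residues(self, tmp_path):
        p = tmp_path / "a.pdb"
        _tiny_pdb(p, [[(0, 0, 0), (3.8, 0, 0)]])
        ens = read_pdb(p)
        assert len(ens) == 1
        assert len(ens[0]) == 2

    def test_two_models(self, tmp_path):
        p = tmp_path / "b.pdb"
        _tiny_pdb(p, [[(0, 0, 0), (3.8, 0, 0)], [(0, 0, 0), (0, 3.8, 0)]])
        ens = read_pdb(p)
        assert len(ens) == 2

    def test_missing_ca_names_residue(self, tmp_path):
        p = tmp_path / "c.pdb"
        text = (
            "ATOM      1  CA  GLN A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLN A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  N   GLN A   3       7.600   0.000   0.000  1.00  0.00           N\n"
            "END\n"
        )
        p.write_text(text)
        with pytest.raises(PDBParseError, match="residue 3"):
            read_pdb(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "d.pdb"
        p.write_text("END\n")
        with pytest.raises((PDBParseError, ValueError)):
            read_pdb(p)


class TestWritePDB:
    def test_round_trip_helix(self, tmp_path, helix20):
        p = tmp_path / "h.pdb"
        write_pdb(Ensemble([helix20]), p)
        back = read_pdb(p)
        for res_in, res_out in zip(helix20.residues, back[0].residues):
            assert set(res_in.atoms) == set(res_out.atoms)
            for name in res_in.atoms:
                dev = np.abs(res_in.atoms[name] - res_out.atoms[name]).max()
                assert dev <= 1e-3
        assert back[0].sequence == helix20.sequence

    def test_multi_model_round_trip(self, tmp_path):
        ens = Ensemble([syn.make_self_avoiding_coil(12, s) for s in range(3)])
        p = tmp_path / "m.pdb"
        write_pdb(ens, p)
        back = read_pdb(p)
        assert len(back) == 3
        for a, b in zip(ens, back):
            assert np.abs(a.ca_coords() - b.ca_coords()).max() <= 1e-3

    def test_empty_ensemble_errors(self, tmp_path):
        with pytest.raises(ValueError):
            write_pdb(Ensemble([]), tmp_path / "x.pdb")


class TestXYZ:
    def test_round_trip(self, tmp_path):
        coil = syn.make_self_avoiding_coil(15, 4)
        p = tmp_path / "c.xyz"
        write_xyz(Ensemble([coil]), p)
        back = read_xyz(p)
        assert np.abs(back[0].ca_coords() - coil.ca_coords()).max() < 1e-5


class TestSuperposeRmsd:
    def test_identity(self, helix20):
        assert superpose_rmsd(helix20, helix20) == pytest.approx(0, abs=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rigid_motion_invariance(self, helix20, seed):
        rot = random_rotation(seed)
        coords = helix20.ca_coords() @ rot.T + np.array([5.0, -3.0, 9.0])
        moved = helix20.with_ca_coords(coords)
        assert superpose_rmsd(helix20, moved) == pytest.approx(0, abs=1e-6)

    def test_matches_brute_force_rotation_grid(self):
        """Closed-form Kabsch RMSD equals a dense rotation-grid minimum."""
        p = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        q = np.array([[0.0, 0, 0], [1, 0, 0], [2, 1, 0]])
        pc = p - p.mean(0)
        qc = q - q.mean(0)

        def rmsd_at(a, b, c):
            ca_, sa = np.cos(a), np.sin(a)
            cb, sb = np.cos(b), np.sin(b)
            cc, sc = np.cos(c), np.sin(c)
            rz = np.array([[ca_, -sa, 0], [sa, ca_, 0], [0, 0, 1]])
            ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
            rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
            r = rz @ ry @ rz2
            return np.sqrt(((pc @ r.T - qc) ** 2).sum() / 3)

        coarse = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        best, arg = np.inf, (0, 0, 0)
        for a in coarse:
            for b in coarse:
                for c in coarse:
                    val = rmsd_at(a, b, c)
                    if val < best:
                        best, arg = val, (a, b, c)
        step = coarse[1]
        fine = np.linspace(-step, step, 41)
        for da in fine:
            for db in fine:
                for dc in fine:
                    best = min(best, rmsd_at(arg[0] + da, arg[1] + db,
                                             arg[2] + dc))
        assert superpose_rmsd_coords(p, q) == pytest.approx(best, abs=1e-3)

    def test_symmetric(self):
        a = syn.make_self_avoiding_coil(10, 0)
        b = syn.make_self_avoiding_coil(10, 1)
        assert superpose_rmsd(a, b) == pytest.approx(superpose_rmsd(b, a))

    def test_length_mismatch_errors(self):
        a = syn.make_self_avoiding_coil(10, 0)
        b = syn.make_self_avoiding_coil(12, 0)
        with pytest.raises(ValueError):
            superpose_rmsd(a, b)


class TestInvariants:
    def test_conformer_requires_ca(self):
        with pytest.raises(PDBParseError):
            Conformer("x", "QQ", [
                Residue("GLN", {"CA": [0, 0, 0]}),
                Residue("GLN", {"N": [3.8, 0, 0]}),
            ])

    def test_time_ordered_needs_increasing_stamps(self):
        a = syn.make_self_avoiding_coil(6, 0)
        b = syn.make_self_avoiding_coil(6, 1)
        a.timestamp, b.timestamp = 10.0, 5.0
        with pytest.raises(ValueError):
            Ensemble([a, b], is_time_ordered=True)
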