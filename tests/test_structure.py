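import math

import numpy as np
import pytest

from hittriage import synthetic_data as sd
from hittriage.structure import (
    Atom,
    InteractionType,
    Residue,
    Structure,
    build_interaction_matrix,
    contact_surface_area,
    define_pocket,
    detect_interactions,
    parse_pdb,
    sasa,
    superpose,
    write_pdb,
)


# ---------------------------------------------------------------------------
# Independent superposition oracle: Horn's quaternion method
# ---------------------------------------------------------------------------

def quaternion_superpose(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD of the optimal rigid superposition of b onto a (Horn 1987)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    s = b0.T @ a0
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    n = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    eigvals, eigvecs = np.linalg.eigh(n)
    w, x, y, z = eigvecs[:, -1]
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    moved = (rot @ b0.T).T
    return float(np.sqrt(np.mean(np.sum((moved - a0) ** 2, axis=1))))


def make_toy_structure() -> Structure:
    residues = []
    for chain, offsets in (("A", (0.0, 10.0, 20.0)), ("B", (40.0, 50.0, 60.0))):
        for i, off in enumerate(offsets, start=1):
            atoms = [
                Atom(name="N", element="N", coord=np.array([off, 0.0, 0.0])),
                Atom(name="CA", element="C", coord=np.array([off + 1.5, 0.0, 0.0])),
                Atom(name="C", element="C", coord=np.array([off + 3.0, 0.0, 0.0])),
            ]
            residues.append(Residue(chain=chain, name="GLY", seq=i, atoms=atoms))
    return Structure(residues=residues)


class TestParsePdb:
    def test_roundtrip_two_chains(self, tmp_path):
        s = make_toy_structure()
        path = tmp_path / "toy.pdb"
        write_pdb(s, path)
        back = parse_pdb(path)
        assert back.chains == ["A", "B"]
        assert len(back.residues) == 6
        assert back.find_residue("A", 2).atom("CA").coord[0] == pytest.approx(11.5)

    def test_hetatm_ligand_isolated(self, tmp_path):
        s = make_toy_structure()
        s.residues.append(Residue(
            chain="L", name="LIG", seq=1, het=True,
            atoms=[Atom(name="C1", element="C", coord=np.zeros(3))]))
        path = tmp_path / "lig.pdb"
        write_pdb(s, path)
        back = parse_pdb(path)
        ligands = back.ligands()
        assert len(ligands) == 1 and ligands[0].name == "LIG"
        assert all(not r.het for r in back.polymer())

    def test_empty_file_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\n")
        with pytest.raises(ValueError, match="no ATOM"):
            parse_pdb(p)

    def test_malformed_line_skipped_with_warning(self, tmp_path):
        p = tmp_path / "bad.pdb"
        good = ("ATOM      1  CA  GLY A   1      11.104   6.134  "
                "-6.504  1.00  0.00           C")
        bad = ("ATOM      2  CB  GLY A   1      xx.xxx   6.134  "
               "-6.504  1.00  0.00           C")
        p.write_text(good + "\n" + bad + "\n")
        with pytest.warns(UserWarning, match="malformed"):
            s = parse_pdb(p)
        assert len(s.atoms) == 1

    def test_waters_separable(self, tmp_path):
        p = tmp_path / "wat.pdb"
        p.write_text(
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "HETATM    2  O   HOH A 101       5.000   0.000   0.000"
            "  1.00  0.00           O\n")
        s = parse_pdb(p)
        assert len(s.waters()) == 1
        assert len(s.polymer()) == 1


class TestSuperpose:
    def test_identity(self, rng):
        p = rng.normal(size=(8, 3))
        _, _, rmsd = superpose(p, p)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_recovered(self, rng):
        p = rng.normal(size=(10, 3))
        theta = math.radians(30)
        rot = np.array([
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ])
        q = (rot @ p.T).T + np.array([1.0, 2.0, 3.0])
        _, _, rmsd = superpose(p, q)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_fixed_four_points_vs_quaternion_oracle(self):
        a = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.4, 1.2]])
        b = np.array([[0.1, 0, 0], [1.2, 0.1, 0], [0, 0.9, 0.2], [0.5, 0.5, 1.0]])
        _, _, rmsd = superpose(a, b)
        assert rmsd == pytest.approx(quaternion_superpose(a, b), abs=1e-8)

    def test_random_sets_vs_quaternion_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            a = rng.normal(size=(n, 3))
            b = rng.normal(size=(n, 3))
            _, _, rmsd = superpose(a, b)
            assert rmsd == pytest.approx(quaternion_superpose(a, b), abs=1e-8)

    def test_rmsd_invariance_under_random_rigid_motions(self, rng):
        p = rng.normal(size=(12, 3))
        for _ in range(10):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            moved = (q @ p.T).T + rng.normal(size=3)
            _, _, rmsd = superpose(p, moved)
            assert rmsd < 1e-6

    def test_count_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_collinear_degenerate(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line + 1.0)


class TestPocket:
    def test_radius_zero_only_center(self):
        s = make_toy_structure()
        pocket = define_pocket(s, "A", 1, 0.0)
        assert pocket.member_specs() == {("A", 1, "")}

    def test_monotone_in_radius(self):
        s = make_toy_structure()
        small = define_pocket(s, "A", 1, 5.0).member_specs()
        big = define_pocket(s, "A", 1, 15.0).member_specs()
        assert small <= big

    def test_infinite_radius_all_residues(self):
        s = make_toy_structure()
        pocket = define_pocket(s, "A", 1, 1e9)
        assert len(pocket.member_residues) == len(s.residues)

    def test_missing_center_error(self):
        s = make_toy_structure()
        with pytest.raises(ValueError, match="99"):
            define_pocket(s, "A", 99, 5.0)


class TestContactArea:
    def test_separated_chains_zero(self):
        s = make_toy_structure()  # chains 40 A apart
        assert contact_surface_area(s, "A", "B", n_points=240) == 0.0

    def test_two_spheres_analytic_and_dense_oracle(self):
        # two C atoms (r_vdw 1.70), centers 3.0 A apart, probe 1.4:
        # each expanded sphere (R = 3.1) loses a cap of height R - d/2
        a = Atom(name="C1", element="C", coord=np.array([0.0, 0, 0]))
        b = Atom(name="C2", element="C", coord=np.array([3.0, 0, 0]))
        r = 1.70 + 1.4
        analytic = 2 * math.pi * r * (r - 1.5)  # one cap, = buried/partner
        s = Structure(residues=[
            Residue(chain="A", name="UNK", seq=1, atoms=[a]),
            Residue(chain="B", name="UNK", seq=1, atoms=[b]),
        ])
        buried = contact_surface_area(s, "A", "B", n_points=960)
        dense = contact_surface_area(s, "A", "B", n_points=12000)
        assert buried == pytest.approx(dense, rel=0.02)
        assert buried == pytest.approx(analytic, rel=0.02)

    def test_convergence(self):
        s, _ = sd.gen_toy_complex("HBOND", margin=1.0)
        a1 = sasa([a for r in s.residues for a in r.atoms], n_points=960)
        a2 = sasa([a for r in s.residues for a in r.atoms], n_points=1920)
        assert abs(a1 - a2) / a2 < 0.01

    def test_symmetry(self):
        a = Atom(name="C1", element="C", coord=np.array([0.0, 0, 0]))
        b = Atom(name="N1", element="N", coord=np.array([2.8, 0, 0]))
        s = Structure(residues=[
            Residue(chain="A", name="UNK", seq=1, atoms=[a]),
            Residue(chain="B", name="UNK", seq=1, atoms=[b]),
        ])
        assert contact_surface_area(s, "A", "B", n_points=960) == pytest.approx(
            contact_surface_area(s, "B", "A", n_points=960), abs=1e-9)

    def test_absent_chain_error(self):
        s = make_toy_structure()
        with pytest.raises(ValueError, match="'Z'"):
            contact_surface_area(s, "A", "Z")


class TestInteractions:
    def _detect(self, motif, margin, radius=12.0):
        s, lig = sd.gen_toy_complex(motif, margin)
        pocket = define_pocket(s, "A", 1, radius)
        return detect_interactions(s, lig, pocket, compound_id="X")

    def test_far_ligand_empty(self):
        assert self._detect("NONE", 1.0, radius=30.0) == []

    def test_constructed_hbond(self):
        # N-H...N(zeta) with N...N = 2.9 A and a linear donor angle
        s, lig = sd.gen_toy_complex("HBOND", margin=1.2)
        recs = self._detect("HBOND", 1.2)
        assert [r.type for r in recs] == [InteractionType.HBOND]
        assert recs[0].distance == pytest.approx(2.9)
        assert recs[0].angle == pytest.approx(180.0, abs=1.0)
        assert not recs[0].distance_only

    def test_constructed_pi_cation(self):
        # benzene centroid 4.0 A from the lysine ammonium nitrogen
        recs = self._detect("PI_CATION", 2.0)
        assert [r.type for r in recs] == [InteractionType.PI_CATION]
        assert recs[0].distance == pytest.approx(4.0)

    def test_hydrophobic(self):
        recs = self._detect("HYDROPHOBIC", 0.5)
        assert [r.type for r in recs] == [InteractionType.HYDROPHOBIC]
        assert recs[0].distance == pytest.approx(3.5)

    @pytest.mark.parametrize("motif", ["HBOND", "HYDROPHOBIC", "PI_CATION"])
    def test_flips_exactly_at_threshold(self, motif):
        inside = self._detect(motif, 0.05)
        assert len(inside) == 1
        # rebuild just outside the cutoff: jitter outward past the margin
        s, lig = sd.gen_toy_complex(motif, 0.1)
        direction = {"HBOND": np.array([1.0, 0, 0]),
                     "HYDROPHOBIC": np.array([0.0, 1.0, 0]),
                     "PI_CATION": np.array([0.0, 0, 1.0])}[motif]
        for atom in lig:
            atom.coord = atom.coord + 0.2 * direction
        pocket = define_pocket(s, "A", 1, 12.0)
        assert detect_interactions(s, lig, pocket, compound_id="X") == []

    def test_small_jitter_does_not_flip(self, rng):
        # margin 0.5 A >> jitter 0.01 A: records must be stable
        s, lig = sd.gen_toy_complex("HBOND", 0.5)
        pocket = define_pocket(s, "A", 1, 12.0)
        base = detect_interactions(s, lig, pocket, compound_id="X")
        for _ in range(5):
            for atom in lig:
                atom.coord = atom.coord + rng.normal(0, 0.003, 3)
            recs = detect_interactions(s, lig, pocket, compound_id="X")
            assert [r.type for r in recs] == [r.type for r in base]

    def test_unknown_element_warns(self):
        s, lig = sd.gen_toy_complex("HBOND", 0.5)
        lig.append(Atom(name="XX", element="Xx", coord=np.array([2.0, 5.0, 0.0])))
        pocket = define_pocket(s, "A", 1, 12.0)
        with pytest.warns(UserWarning, match="unknown element"):
            recs = detect_interactions(s, lig, pocket, compound_id="X")
        assert [r.type for r in recs] == [InteractionType.HBOND]


class TestInteractionMatrix:
    def test_empty(self):
        m = build_interaction_matrix([])
        assert m.residues == [] and m.compounds == []

    def test_marginal_by_construction(self):
        s1, lig1 = sd.gen_toy_complex("HBOND", 0.5, chain="X", seq=860)
        pocket = define_pocket(s1, "X", 860, 12.0)
        recs = []
        for cid in ("c1", "c2"):
            recs.extend(detect_interactions(s1, lig1, pocket, compound_id=cid))
        m = build_interaction_matrix(recs)
        assert m.residue_marginal(("X", 860, "")) == 2
        assert m.types(("X", 860, ""), "c1") == {InteractionType.HBOND}

    def test_cell_nonempty_iff_record_exists(self):
        s, lig = sd.gen_toy_complex("PI_CATION", 0.5)
        pocket = define_pocket(s, "A", 1, 12.0)
        recs = detect_interactions(s, lig, pocket, compound_id="only")
        m = build_interaction_matrix(recs)
        for r in m.residues:
            for c in m.compounds:
                cell = m.types(r, c)
                has_rec = any(
                    rec.residue == r and rec.compound_id == c for rec in recs)
                assert bool(cell) == has_rec

    def test_fixture_reproducing_reported_marginals(self):
        """A synthetic contact table whose busiest residues are the four
        named hydrophobic anchors must rank them on top."""
        from hittriage.structure import InteractionRecord
        anchors = [("TYR", 833), ("PRO", 837), ("LEU", 841), ("MET", 856)]
        others = [("ASN", 834), ("PHE", 840), ("VAL", 859), ("LYS", 860),
                  ("ILE", 862)]
        recs = []
        for name, seq in anchors:
            for i in range(18):
                recs.append(InteractionRecord(
                    compound_id=f"c{i}", residue=("X", seq, ""),
                    residue_name=name, type=InteractionType.HYDROPHOBIC,
                    distance=3.6))
        for name, seq in others:
            for i in range(7):
                recs.append(InteractionRecord(
                    compound_id=f"c{i}", residue=("X", seq, ""),
                    residue_name=name, type=InteractionType.HBOND,
                    distance=3.0))
        m = build_interaction_matrix(recs)
        ranked = sorted(m.residues, key=lambda r: -m.residue_marginal(r))
        top4 = {(m.residue_names[r], r[1]) for r in ranked[:4]}
        assert top4 == set(anchors)

    def test_frame_mirrors_cells(self):
        s, lig = sd.gen_toy_complex("HBOND", 0.5)
        pocket = define_pocket(s, "A", 1, 12.0)
        recs = detect_interactions(s, lig, pocket, compound_id="cpd")
        df = build_interaction_matrix(recs).to_frame()
        assert df.loc["LYS1(A)", "cpd"] == "HBOND"
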