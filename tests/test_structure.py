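"""Geometric detection, superposition, and structure I/O."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from statenav import structure as st

LIG_RING = [["C1", "C2", "C3", "C4", "C5", "C6"]]


def rigid(structure: st.Structure, seed: int) -> st.Structure:
    """Apply a random rotation + translation."""
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.normal(0.0, 20.0, 3)
    return structure.transformed(rot, trans)


class TestIO:
    def test_write_read_round_trip(self, structure_fixtures, tmp_path):
        s = structure_fixtures["hbond"]
        path = tmp_path / "fixture.pdb"
        st.write_structure(s, path)
        s2 = st.read_structure(path)
        assert len(s2) == len(s)
        d1 = {(a.chain, a.resnum, a.name): a.xyz for a in s.atoms}
        d2 = {(a.chain, a.resnum, a.name): a.xyz for a in s2.atoms}
        assert d1.keys() == d2.keys()
        # PDB stores three decimals
        assert max(np.abs(d1[k] - d2[k]).max() for k in d1) < 1e-3

    def test_twelve_atom_chain(self, structure_fixtures, tmp_path):
        path = tmp_path / "chain.pdb"
        st.write_structure(structure_fixtures["chain"], path)
        assert len(st.read_structure(path)) == 12

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(ValueError):
            st.read_structure(path)


class TestContacts:
    def test_planted_contacts_sorted_by_distance(self, structure_fixtures):
        contacts = st.ligand_contacts(structure_fixtures["hbond"], "CBD")
        assert [c[0][1] for c in contacts] == [10, 20]
        assert contacts[0][1] == pytest.approx(2.8, abs=1e-6)

    def test_zero_cutoff_empty(self, structure_fixtures):
        assert st.ligand_contacts(structure_fixtures["hbond"], "CBD", cutoff=0.0) == []

    def test_missing_ligand_raises(self, structure_fixtures):
        with pytest.raises(ValueError, match="not present"):
            st.ligand_contacts(structure_fixtures["hbond"], "XYZ")

    def test_brute_force_oracle(self, structure_fixtures):
        # all-pairs double loop over heavy atoms must agree with the kd-tree
        for name in ("hbond", "pistack"):
            s = structure_fixtures[name]
            lig = [a for a in s.heavy_atoms() if a.resname == "CBD"]
            best = {}
            for a in s.heavy_atoms():
                if a.resname == "CBD":
                    continue
                for b in lig:
                    d = float(np.linalg.norm(a.xyz - b.xyz))
                    if d <= 4.5 and d < best.get(a.residue_id, math.inf):
                        best[a.residue_id] = d
            expected = sorted(best.items(), key=lambda kv: kv[1])
            got = st.ligand_contacts(s, "CBD", 4.5)
            assert [g[0] for g in got] == [e[0] for e in expected]
            assert np.allclose([g[1] for g in got], [e[1] for e in expected])


class TestHBonds:
    def test_planted_triad_detected(self, structure_fixtures):
        hbonds = st.detect_hbonds(structure_fixtures["hbond"], "CBD")
        assert len(hbonds) == 1
        hb = hbonds[0]
        assert hb.donor.name == "OG" and hb.acceptor.name == "O1"
        assert hb.distance == pytest.approx(2.8, abs=1e-6)
        assert hb.angle == pytest.approx(170.0, abs=1e-6)

    def test_decoy_beyond_cutoff_not_detected(self, structure_fixtures):
        hbonds = st.detect_hbonds(structure_fixtures["hbond"], "CBD")
        partners = {h.donor.resnum for h in hbonds} | {h.acceptor.resnum for h in hbonds}
        assert 20 not in partners and 91 not in partners

    def test_angle_criterion_rejects_perpendicular_geometry(self):
        # both candidate donors have bonded neighbors at ~90 deg: no H-bond
        atoms = [
            st.Atom("A", 10, "SER", "CB", "C", 0.0, 0.0, 1.43),
            st.Atom("A", 10, "SER", "OG", "O", 0.0, 0.0, 0.0),
            st.Atom("L", 90, "CBD", "O1", "O", 2.8, 0.0, 0.0),
            st.Atom("L", 90, "CBD", "C1", "C", 2.8, 0.0, -1.43),
        ]
        s = st.Structure(atoms)
        assert st.detect_hbonds(s, "CBD") == []

    def test_no_angle_fallback_is_flagged(self, structure_fixtures):
        # a donor without resolved neighbors falls back to distance-only
        # detection, flagged by angle=None
        hbonds = st.detect_hbonds(structure_fixtures["hbond"], "CBD", angle_min=175.0)
        assert len(hbonds) == 1
        assert hbonds[0].angle is None

    def test_rigid_motion_invariance(self, structure_fixtures):
        s = structure_fixtures["hbond"]
        moved = rigid(s, 5)
        a = st.detect_hbonds(s, "CBD")
        b = st.detect_hbonds(moved, "CBD")
        assert len(a) == len(b) == 1
        assert b[0].distance == pytest.approx(a[0].distance, abs=1e-9)
        assert b[0].angle == pytest.approx(a[0].angle, abs=1e-9)


class TestPiStacks:
    def test_parallel_rings_detected(self, structure_fixtures):
        stacks = st.detect_pi_stacks(structure_fixtures["pistack"], "CBD", LIG_RING)
        assert len(stacks) == 1
        assert stacks[0].residue == ("A", 387, "PHE")
        assert stacks[0].centroid_distance == pytest.approx(4.0, abs=1e-6)
        assert stacks[0].interplanar_angle == pytest.approx(0.0, abs=1e-6)

    def test_distant_rings_not_detected(self, structure_fixtures):
        s = structure_fixtures["pistack"]
        # move the ligand ring to 8 A centroid separation
        moved = st.Structure(
            [
                a if a.resname != "CBD"
                else st.Atom(a.chain, a.resnum, a.resname, a.name, a.element,
                             a.x, a.y, a.z + 4.0)
                for a in s.atoms
            ]
        )
        assert st.detect_pi_stacks(moved, "CBD", LIG_RING) == []

    def test_perpendicular_rings_rejected_by_angle(self, structure_fixtures):
        s = structure_fixtures["pistack"]
        # rotate the ligand ring 90 deg about x through its centroid
        rot = Rotation.from_euler("x", 90, degrees=True).as_matrix()
        centroid = np.array([0.0, 0.0, 4.0])
        moved = st.Structure(
            [
                a if a.resname != "CBD"
                else st.Atom(a.chain, a.resnum, a.resname, a.name, a.element,
                             *(rot @ (a.xyz - centroid) + centroid))
                for a in s.atoms
            ]
        )
        assert st.detect_pi_stacks(moved, "CBD", LIG_RING, angle_max=30.0) == []

    def test_rigid_motion_invariance(self, structure_fixtures):
        s = structure_fixtures["pistack"]
        a = st.detect_pi_stacks(s, "CBD", LIG_RING)
        b = st.detect_pi_stacks(rigid(s, 8), "CBD", LIG_RING)
        assert b[0].centroid_distance == pytest.approx(a[0].centroid_distance, abs=1e-9)
        assert b[0].interplanar_angle == pytest.approx(a[0].interplanar_angle, abs=1e-6)


class TestSuperposition:
    def test_identical_structures(self, structure_fixtures):
        s = structure_fixtures["chain"]
        res = st.superpose(s, s)
        assert res.rmsd < 1e-12
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-8)

    def test_translated_copy(self, structure_fixtures):
        s = structure_fixtures["chain"]
        moved = s.transformed(np.eye(3), np.array([10.0, -4.0, 2.5]))
        assert st.superpose(s, moved).rmsd < 1e-9

    def test_planted_rotation_round_trip(self, structure_fixtures):
        s = structure_fixtures["chain"]
        moved = structure_fixtures["chain_rotated"]
        # pre-alignment displacement equals the planted transform's
        planted = np.linalg.norm(
            s.coords() @ structure_fixtures["rotation"].T
            + structure_fixtures["translation"]
            - s.coords(),
            axis=1,
        )
        pre = np.linalg.norm(moved.coords() - s.coords(), axis=1)
        assert np.allclose(pre, planted)
        res = st.superpose(s, moved)
        assert res.rmsd < 1e-6
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_rmsd_invariant_under_rigid_motion_of_either_input(self, structure_fixtures):
        s = structure_fixtures["chain"]
        bent = st.Structure(
            [
                st.Atom(a.chain, a.resnum, a.resname, a.name, a.element,
                        a.x + 0.2 * i, a.y, a.z)
                for i, a in enumerate(s.atoms)
            ]
        )
        base = st.superpose(s, bent).rmsd
        assert base > 0
        assert st.superpose(rigid(s, 2), bent).rmsd == pytest.approx(base, abs=1e-9)
        assert st.superpose(s, rigid(bent, 3)).rmsd == pytest.approx(base, abs=1e-9)

    def test_unmatched_selection_raises(self, structure_fixtures):
        s = structure_fixtures["chain"]
        with pytest.raises(ValueError, match="paired"):
            st.superpose(s, structure_fixtures["hbond"])


def test_atom_order_invariance(structure_fixtures):
    s = structure_fixtures["hbond"]
    rev = st.Structure(list(reversed(s.atoms)))
    a = st.detect_hbonds(s, "CBD")
    b = st.detect_hbonds(rev, "CBD")
    assert [(h.donor.name, h.acceptor.name) for h in a] == [
        (h.donor.name, h.acceptor.name) for h in b
    ]
    assert st.ligand_contacts(rev, "CBD") == st.ligand_contacts(s, "CBD")
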