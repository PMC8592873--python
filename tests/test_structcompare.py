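import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dimerlink.structcompare import (
    atom_distance,
    buried_surface_area,
    interface_residues,
    pair_ca_coords,
    polar_contacts,
    sasa,
    superpose,
)


def carbon_atoms(structure_factory, positions, chain="A", resname="ALA"):
    return structure_factory([
        (chain, i, resname, "C", "C", xyz) for i, xyz in enumerate(positions, start=1)
    ])


class TestSuperpose:
    def test_identity(self):
        rng = np.random.default_rng(0)
        P = rng.uniform(-10, 10, (8, 3))
        res = superpose(P, P)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-8)

    def test_rigid_recovery(self):
        rng = np.random.default_rng(1)
        P = rng.uniform(-10, 10, (10, 3))
        R = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
        t = np.array([3.0, -4.0, 5.0])
        mob = (P - t) @ R  # so that mob @ R.T + ... recovers
        res = superpose(P, mob)
        assert res.rmsd < 1e-8
        np.testing.assert_allclose(res.apply(mob), P, atol=1e-8)

    def test_outlier_oracle(self):
        """All-pairs and rejected RMSD against an independent Kabsch (scipy)."""
        rng = np.random.default_rng(2)
        ref = rng.uniform(-5, 5, (10, 3))
        mob = ref.copy()
        mob[0] += np.array([1.0, 0.0, 0.0])  # one 1 Å outlier
        res_all = superpose(ref, mob, mode="all_pairs")
        rot, rssd = Rotation.align_vectors(ref - ref.mean(0), mob - mob.mean(0))
        assert res_all.rmsd == pytest.approx(rssd / np.sqrt(10), abs=1e-6)
        res_rej = superpose(ref, mob, mode="iterative_reject")
        # oracle for the rejected fit: perfect match on the clean pairs
        assert res_rej.rejected == [0]
        assert res_rej.rmsd == pytest.approx(0.0, abs=1e-8)

    def test_reject_rmsd_never_larger(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            r2 = np.random.default_rng(seed)
            ref = r2.uniform(-8, 8, (12, 3))
            mob = ref + r2.normal(0, 0.3, ref.shape)
            mob[r2.integers(0, 12)] += r2.normal(0, 3.0, 3)
            res_all = superpose(ref, mob, mode="all_pairs")
            res_rej = superpose(ref, mob, mode="iterative_reject")
            assert res_rej.rmsd <= res_all.rmsd + 1e-12

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_pair_ca_coords(self, structure_factory):
        a = structure_factory([
            ("A", 1, "GLY", "CA", "C", (0, 0, 0)),
            ("A", 2, "GLY", "CA", "C", (3, 0, 0)),
            ("A", 3, "GLY", "CA", "C", (0, 3, 0)),
            ("A", 4, "GLY", "CA", "C", (1, 1, 1)),
        ])
        b = structure_factory([
            ("A", 2, "GLY", "CA", "C", (3, 0, 1)),
            ("A", 3, "GLY", "CA", "C", (0, 3, 1)),
            ("A", 4, "GLY", "CA", "C", (1, 1, 2)),
            ("A", 5, "GLY", "CA", "C", (9, 9, 9)),
        ])
        ra, rb, keys = pair_ca_coords(a, b)
        assert keys == [("A", 2), ("A", 3), ("A", 4)]
        np.testing.assert_array_equal(rb - ra, [[0, 0, 1]] * 3)


class TestSasa:
    def test_isolated_carbon_sphere(self, single_carbon):
        res = sasa(single_carbon)
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert res.total == pytest.approx(exact, rel=0.015)

    def test_tangent_spheres_unperturbed(self, structure_factory):
        d = 2 * (1.7 + 1.4)
        st = carbon_atoms(structure_factory, [(0, 0, 0), (d, 0, 0)])
        res = sasa(st)
        exact = 4 * np.pi * 3.1**2
        for a in res.atom_sasa:
            assert a == pytest.approx(exact, rel=0.015)

    def test_overlapping_spheres_analytic_cap(self, structure_factory):
        d = 3.0  # centers closer than 2(r + probe): symmetric burial
        st = carbon_atoms(structure_factory, [(0, 0, 0), (d, 0, 0)])
        res = sasa(st)
        R = 1.7 + 1.4
        cap_h = R - d / 2.0
        exact_each = 4 * np.pi * R**2 - 2 * np.pi * R * cap_h
        for a in res.atom_sasa:
            assert a == pytest.approx(exact_each, rel=0.01)

    def test_rigid_motion_equivariance(self, structure_factory):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 8, (10, 3))
        st = carbon_atoms(structure_factory, pts)
        base = sasa(st).atom_sasa
        R = Rotation.random(random_state=np.random.RandomState(11)).as_matrix()
        st2 = carbon_atoms(structure_factory, pts @ R.T + np.array([5.0, -3.0, 2.0]))
        moved = sasa(st2).atom_sasa
        np.testing.assert_allclose(moved, base, atol=1e-9)

    def test_unknown_element_without_fallback(self, structure_factory):
        st = structure_factory([("A", 1, "UNK", "X1", "Xe", (0, 0, 0))])
        with pytest.raises(ValueError, match="radius"):
            sasa(st)
        assert sasa(st, fallback_radius=1.8).total > 0


class TestInterface:
    def test_distant_chains_empty(self, structure_factory):
        a = [(f, i) for i, f in enumerate(np.zeros(3))]
        st = structure_factory(
            [("A", i, "ALA", "C", "C", (7.0 * i, 0, 0)) for i in range(1, 4)]
            + [("B", i, "ALA", "C", "C", (7.0 * i, 0, 100.0)) for i in range(1, 4)]
        )
        rep = interface_residues(st, "A", "B")
        assert rep.flagged("A") == [] and rep.flagged("B") == []

    def test_planted_buried_core(self, structure_factory):
        """Chains touch only at four middle columns; exactly those are flagged."""
        atoms = []
        for i in range(1, 9):
            atoms.append(("A", i, "ALA", "C", "C", (7.0 * i, 0.0, 0.0)))
        for i in range(1, 9):
            z = 4.2 if 3 <= i <= 6 else 60.0
            atoms.append(("B", i, "ALA", "C", "C", (7.0 * i, 0.0, z)))
        st = structure_factory(atoms)
        rep = interface_residues(st, "A", "B", threshold=10.0)
        assert rep.flagged("A") == [3, 4, 5, 6]
        assert rep.flagged("B") == [3, 4, 5, 6]

    def test_missing_chain(self, structure_factory):
        st = carbon_atoms(structure_factory, [(0, 0, 0), (7, 0, 0), (0, 7, 0)])
        with pytest.raises(KeyError):
            interface_residues(st, "A", "Z")


class TestBsa:
    def test_non_touching_zero(self, structure_factory):
        st = structure_factory(
            [("A", 1, "ALA", "C", "C", (0.0, 0.0, 0.0)),
             ("B", 1, "ALA", "C", "C", (50.0, 0.0, 0.0))]
        )
        bsa, half = buried_surface_area(st, "A", "B")
        assert bsa == pytest.approx(0.0, abs=1e-9)

    def test_tangent_zero(self, structure_factory):
        d = 2 * (1.7 + 1.4)
        st = structure_factory(
            [("A", 1, "ALA", "C", "C", (0.0, 0.0, 0.0)),
             ("B", 1, "ALA", "C", "C", (d, 0.0, 0.0))]
        )
        bsa, _ = buried_surface_area(st, "A", "B")
        assert bsa == pytest.approx(0.0, abs=1e-6)

    def test_overlapping_analytic(self, structure_factory):
        d = 3.0
        st = structure_factory(
            [("A", 1, "ALA", "C", "C", (0.0, 0.0, 0.0)),
             ("B", 1, "ALA", "C", "C", (d, 0.0, 0.0))]
        )
        bsa, half = buried_surface_area(st, "A", "B")
        R = 3.1
        exact_bsa = 2 * (2 * np.pi * R * (R - d / 2.0))
        assert bsa == pytest.approx(exact_bsa, rel=0.01)
        assert half == pytest.approx(exact_bsa / 2.0, rel=0.01)

    def test_chain_swap_symmetry(self, structure_factory):
        rng = np.random.default_rng(6)
        atoms = [("A", i, "ALA", "C", "C", rng.uniform(0, 6, 3)) for i in range(1, 5)]
        atoms += [("B", i, "ALA", "C", "C", rng.uniform(3, 9, 3)) for i in range(1, 5)]
        st = structure_factory(atoms)
        ab, _ = buried_surface_area(st, "A", "B")
        ba, _ = buried_surface_area(st, "B", "A")
        assert ab == pytest.approx(ba, abs=1e-9)


class TestPolarContacts:
    def arg_asp_pair(self, structure_factory, nh1_od1_distance):
        return structure_factory([
            ("A", 10, "ARG", "CZ", "C", (-1.4, 0.0, 0.0)),
            ("A", 10, "ARG", "NH1", "N", (0.0, 0.0, 0.0)),
            ("B", 94, "ASP", "OD1", "O", (nh1_od1_distance, 0.0, 0.0)),
            ("B", 94, "ASP", "CG", "C", (nh1_od1_distance + 1.3, 0.0, 0.0)),
        ])

    def test_salt_bridge_within_cutoff(self, structure_factory):
        st = self.arg_asp_pair(structure_factory, 3.9)
        contacts = polar_contacts(st)
        assert [c.kind for c in contacts] == ["salt_bridge"]
        assert contacts[0].distance == pytest.approx(3.9)

    def test_no_salt_bridge_beyond_cutoff(self, structure_factory):
        st = self.arg_asp_pair(structure_factory, 4.1)
        assert polar_contacts(st) == []

    def test_glycine_pair_no_salt_bridges(self, structure_factory):
        st = structure_factory([
            ("A", 1, "GLY", "N", "N", (0.0, 0.0, 0.0)),
            ("A", 1, "GLY", "O", "O", (1.5, 0.0, 0.0)),
            ("B", 1, "GLY", "N", "N", (4.0, 0.0, 0.0)),
            ("B", 1, "GLY", "O", "O", (5.5, 0.0, 0.0)),
        ])
        kinds = {c.kind for c in polar_contacts(st)}
        assert "salt_bridge" not in kinds
        assert "hbond" in kinds  # O...N at 2.5 Å across chains

    def test_backbone_hbond_to_lysine_nz(self, structure_factory):
        # main-chain O accepting from a side-chain amine across the interface
        st = structure_factory([
            ("A", 16, "GLY", "O", "O", (0.0, 0.0, 0.0)),
            ("B", 98, "LYS", "NZ", "N", (2.9, 0.0, 0.0)),
        ])
        [c] = polar_contacts(st, cross_chain_only=True)
        assert c.kind == "hbond" and c.distance == pytest.approx(2.9)

    def test_cross_chain_only_filter(self, structure_factory):
        st = structure_factory([
            ("A", 1, "SER", "OG", "O", (0.0, 0.0, 0.0)),
            ("A", 3, "THR", "OG1", "O", (3.0, 0.0, 0.0)),
        ])
        assert len(polar_contacts(st)) == 1
        assert polar_contacts(st, cross_chain_only=True) == []


class TestAtomDistance:
    def test_same_atom_zero(self, single_carbon):
        assert atom_distance(single_carbon, "A:1:C", "A:1:C") == 0.0

    def test_three_four_five(self, structure_factory):
        st = structure_factory([
            ("A", 16, "GLY", "CA", "C", (0.0, 0.0, 0.0)),
            ("B", 16, "GLY", "CA", "C", (3.0, 4.0, 0.0)),
        ])
        assert atom_distance(st, "A:16:CA", "B:16:CA") == pytest.approx(5.0)

    def test_unresolvable_spec(self, single_carbon):
        with pytest.raises(KeyError):
            atom_distance(single_carbon, "A:1:C", "A:2:C")
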