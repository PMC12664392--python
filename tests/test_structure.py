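"""SASA, interface areas, contacts, and Kabsch superposition."""

import math

import numpy as np
import pytest

from xscan.simulate import gen_toy_structure
from xscan.structure import (
    Atom,
    Chain,
    GroupPartition,
    Residue,
    SasaConfig,
    Structure,
    detect_contacts,
    interface_area,
    kabsch,
    parse_selection,
    read_structure,
    sasa,
    superpose_rmsd,
)

from conftest import ALTLOC_PDB, MINIMAL_PDB

R_C = 1.70
PROBE = 1.4


def transformed(structure, rotation, translation):
    out = Structure(id=structure.id)
    for chain in structure.chains:
        new_chain = Chain(id=chain.id)
        for res in chain.residues:
            new_res = Residue(name=res.name, seq_id=res.seq_id)
            for atom in res.atoms:
                new_res.atoms.append(
                    Atom(atom.name, atom.element, rotation @ atom.pos + translation)
                )
            new_chain.residues.append(new_res)
        out.chains.append(new_chain)
    return out


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestReadStructure:
    def test_minimal_pdb(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        st = read_structure(p)
        assert len(st.chains) == 1
        assert len(st.chains[0].residues) == 1
        assert len(st.chains[0].residues[0].atoms) == 3

    def test_pdb_and_mmcif_identical_coordinates(self, tmp_path):
        import gemmi

        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        g = gemmi.read_structure(str(p))
        g.setup_entities()
        cif = tmp_path / "mini.cif"
        g.make_mmcif_document().write_file(str(cif))
        st_pdb = read_structure(p)
        st_cif = read_structure(cif)
        a = np.array([at.pos for _, _, at in st_pdb.iter_atoms()])
        b = np.array([at.pos for _, _, at in st_cif.iter_atoms()])
        assert np.allclose(a, b, atol=1e-3)

    def test_altloc_keeps_highest_occupancy_and_drops_water(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        st = read_structure(p)
        res = st.chains[0].residues[0]
        cas = [a for a in res.atoms if a.name == "CA"]
        assert len(cas) == 1
        assert cas[0].occupancy == pytest.approx(0.70)
        assert all(r.name != "HOH" for c in st.chains for r in c.residues)

    def test_unparseable_file_rejected(self, tmp_path):
        p = tmp_path / "bad.cif"
        p.write_text("this is not a structure\n")
        with pytest.raises(ValueError):
            read_structure(p)


class TestSasa:
    def test_single_carbon_analytic_sphere(self):
        st = gen_toy_structure("single_atom")
        total = sasa(st)["area"].sum()
        analytic = 4 * math.pi * (R_C + PROBE) ** 2
        assert total == pytest.approx(analytic, rel=0.01)

    def test_distant_spheres_unoccluded(self):
        r = R_C + PROBE
        st = gen_toy_structure("two_spheres", distance=2 * r + 1.0)
        areas = sasa(st)["area"]
        full = 4 * math.pi * r**2
        assert np.allclose(areas, full, rtol=1e-9)

    @pytest.mark.parametrize("distance", [3.0, 4.0, 5.0])
    def test_overlapping_spheres_match_cap_formula(self, distance):
        r = R_C + PROBE
        st = gen_toy_structure("two_spheres", distance=distance)
        areas = sasa(st)["area"]
        cap_height = r - distance / 2
        expected = 4 * math.pi * r**2 - 2 * math.pi * r * cap_height
        assert np.allclose(areas, expected, rtol=0.02)

    def test_quadrature_convergence(self):
        st = gen_toy_structure("mini_interface")
        a960 = sasa(st, SasaConfig(n_points=960))["area"].sum()
        a1920 = sasa(st, SasaConfig(n_points=1920))["area"].sum()
        assert abs(a1920 - a960) / a960 < 0.005

    def test_matches_independent_sasa_oracle(self):
        """Cross-check the whole-structure SASA against biotite's Shrake-Rupley."""
        biotite_struc = pytest.importorskip("biotite.structure")
        st = gen_toy_structure("mini_interface")
        rows = [(c, r, a) for c, r, a in st.iter_atoms()]
        arr = biotite_struc.AtomArray(len(rows))
        for i, (c, r, a) in enumerate(rows):
            arr.coord[i] = a.pos
            arr.chain_id[i] = c.id
            arr.res_id[i] = r.seq_id
            arr.res_name[i] = r.name
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
        cfg = SasaConfig(n_points=1920)
        radii = np.array([cfg.radius_of(a.element) for _, _, a in rows])
        oracle = biotite_struc.sasa(
            arr, probe_radius=PROBE, point_number=1000, vdw_radii=radii
        ).sum()
        ours = sasa(st, cfg)["area"].sum()
        assert ours == pytest.approx(oracle, rel=0.01)

    def test_unknown_element_rejected(self):
        st = Structure(
            chains=[
                Chain(
                    id="A",
                    residues=[Residue("ALA", 1, [Atom("FE", "FE", (0, 0, 0))])],
                )
            ]
        )
        with pytest.raises(ValueError, match="radius"):
            sasa(st)


class TestInterfaceArea:
    def test_far_apart_groups_zero_area(self):
        st = gen_toy_structure("mini_interface")
        moved = Structure(id=st.id, chains=[st.chains[0]])
        far = transformed(
            Structure(chains=[st.chains[1]]), np.eye(3), np.array([0.0, 0.0, 50.0])
        )
        moved.chains.append(far.chains[0])
        rep = interface_area(moved, GroupPartition(group_a="A", group_b="B"))
        assert rep.interface_area == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_under_group_swap(self):
        st = gen_toy_structure("mini_interface")
        r1 = interface_area(st, GroupPartition(group_a="A", group_b="B"))
        r2 = interface_area(st, GroupPartition(group_a="B", group_b="A"))
        assert r1.interface_area == pytest.approx(r2.interface_area, rel=1e-9)

    def test_rigid_motion_invariance(self):
        st = gen_toy_structure("mini_interface")
        part = GroupPartition(group_a="A", group_b="B")
        base = interface_area(st, part).interface_area
        rng = np.random.default_rng(5)
        moved = transformed(st, random_rotation(rng), rng.normal(size=3) * 10)
        assert interface_area(moved, part).interface_area == pytest.approx(
            base, rel=0.02
        )

    def test_per_residue_areas_sum_to_twice_interface(self):
        st = gen_toy_structure("mini_interface")
        rep = interface_area(st, GroupPartition(group_a="A", group_b="B"))
        assert rep.per_atom["buried"].sum() == pytest.approx(
            2 * rep.interface_area, rel=1e-6
        )
        assert (rep.per_residue["buried"] >= 0).all()

    def test_matches_independent_sasa_difference(self):
        """Interface area re-derived from raw per-group SASA sums."""
        st = gen_toy_structure("mini_interface")
        rep = interface_area(st, GroupPartition(group_a="A", group_b="B"))
        part_a = Structure(chains=[st.chains[0]])
        part_b = Structure(chains=[st.chains[1]])
        expected = 0.5 * (
            sasa(part_a)["area"].sum()
            + sasa(part_b)["area"].sum()
            - sasa(st)["area"].sum()
        )
        assert rep.interface_area == pytest.approx(expected, rel=1e-9)

    def test_overlapping_partition_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GroupPartition(group_a="A", group_b="A,B")


class TestContacts:
    def test_mini_interface_hydrophobic_only(self):
        st = gen_toy_structure("mini_interface")
        contacts = detect_contacts(
            Structure(chains=[st.chains[0]]), Structure(chains=[st.chains[1]])
        )
        kinds = {c.kind for c in contacts}
        assert kinds == {"hydrophobic"}
        assert all(c.atom_a == "CB" and c.atom_b == "CB" for c in contacts)

    def test_distant_atoms_no_contacts(self):
        a = Structure(chains=[Chain("A", [Residue("ALA", 1, [Atom("CB", "C", (0, 0, 0))])])])
        b = Structure(chains=[Chain("B", [Residue("ALA", 1, [Atom("CB", "C", (10, 0, 0))])])])
        assert detect_contacts(a, b) == []

    def test_donor_acceptor_pair_is_hydrogen_bond(self):
        a = Structure(
            chains=[Chain("A", [Residue("LYS", 1, [Atom("NZ", "N", (0, 0, 0))])])]
        )
        b = Structure(
            chains=[Chain("B", [Residue("GLU", 1, [Atom("OE1", "O", (2.9, 0, 0))])])]
        )
        contacts = detect_contacts(a, b)
        assert len(contacts) == 1
        assert contacts[0].kind == "hydrogen_bond"
        assert contacts[0].distance == pytest.approx(2.9)

    def test_two_donors_do_not_bond(self):
        a = Structure(
            chains=[Chain("A", [Residue("LYS", 1, [Atom("NZ", "N", (0, 0, 0))])])]
        )
        b = Structure(
            chains=[Chain("B", [Residue("ARG", 1, [Atom("NH1", "N", (2.9, 0, 0))])])]
        )
        assert detect_contacts(a, b) == []

    def test_contact_residue_labels(self):
        st = gen_toy_structure("mini_interface")
        rep = interface_area(st, GroupPartition(group_a="A", group_b="B"))
        assert rep.contact_residues("A") <= {"A1", "A2", "A3"}


class TestBackboneFraction:
    def test_all_sidechain_interface_is_zero(self):
        st = gen_toy_structure("mini_interface")
        rep = interface_area(st, GroupPartition(group_a="A", group_b="B"))
        bb = rep.backbone_fraction()
        assert bb["A"] == pytest.approx(0.0)
        assert bb["B"] == pytest.approx(0.0)

    def test_all_glycine_interface_is_one(self):
        def gly_strand(chain_id, z):
            residues = []
            for i in range(3):
                x = i * 3.8
                atoms = [
                    Atom("N", "N", (x - 1.2, 0.5, z)),
                    Atom("CA", "C", (x, 0.0, z)),
                    Atom("C", "C", (x + 1.2, 0.6, z)),
                    Atom("O", "O", (x + 1.3, 1.8, z)),
                ]
                residues.append(Residue("GLY", i + 1, atoms))
            return Chain(chain_id, residues)

        st = Structure(chains=[gly_strand("A", 0.0), gly_strand("B", 4.5)])
        rep = interface_area(st, GroupPartition(group_a="A", group_b="B"))
        bb = rep.backbone_fraction()
        assert bb["A"] == pytest.approx(1.0)
        assert bb["B"] == pytest.approx(1.0)

    def test_matches_direct_per_atom_summation(self):
        st = gen_toy_structure("mini_interface")
        rep = interface_area(st, GroupPartition(group_a="A", group_b="B"))
        per_atom = rep.per_atom
        for side in ("A", "B"):
            grp = per_atom[per_atom["side"] == side]
            direct = (
                grp.loc[grp["atom"].isin({"N", "CA", "C", "O", "OXT"}), "buried"].sum()
                / grp["buried"].sum()
            )
            assert rep.backbone_fraction()[side] == pytest.approx(direct)


class TestSuperposition:
    def test_identical_copies_zero_rmsd(self):
        st = gen_toy_structure("mini_interface")
        assert superpose_rmsd(st, st, chain_map={"A": "A", "B": "B"}) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_rigid_transform_zero_rmsd(self):
        rng = np.random.default_rng(9)
        st = gen_toy_structure("mini_interface")
        moved = transformed(st, random_rotation(rng), rng.normal(size=3) * 20)
        rmsd = superpose_rmsd(st, moved, chain_map={"A": "A", "B": "B"})
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_rmsd_invariant_under_rigid_motion_of_either_input(self):
        rng = np.random.default_rng(10)
        st = gen_toy_structure("mini_interface")
        noisy = transformed(st, np.eye(3), np.zeros(3))
        for chain in noisy.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    atom.pos = atom.pos + rng.normal(0, 0.3, size=3)
        cm = {"A": "A", "B": "B"}
        base = superpose_rmsd(st, noisy, chain_map=cm)
        moved = transformed(noisy, random_rotation(rng), rng.normal(size=3) * 15)
        assert superpose_rmsd(st, moved, chain_map=cm) == pytest.approx(base, rel=1e-6)

    def test_kabsch_matches_scipy_oracle(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(11)
        P = rng.normal(size=(25, 3))
        Q = P + rng.normal(0, 0.5, size=(25, 3))
        _, _, ours = kabsch(P, Q)
        Pc, Qc = P - P.mean(0), Q - Q.mean(0)
        _, ssd = Rotation.align_vectors(Qc, Pc)
        oracle = ssd / math.sqrt(len(P))
        assert ours == pytest.approx(oracle, rel=1e-6)

    def test_reflection_degenerate_planar_case(self):
        # planar points whose best orthogonal map is a reflection
        P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        Q = P.copy()
        Q[:, 2] = 0.0
        Q[:, 0] *= -1  # mirrored
        R, _, _ = kabsch(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError, match="3"):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_ca_pairing_skips_unmodeled_residues(self):
        st = gen_toy_structure("mini_interface")
        partial = Structure(chains=[Chain("A", st.chains[0].residues[:2])])
        full = Structure(chains=[Chain("A", st.chains[0].residues)])
        rmsd = superpose_rmsd(full, partial, chain_map={"A": "A"}, atoms="all")
        assert rmsd == pytest.approx(0.0, abs=1e-9)


class TestSelections:
    def test_chain_and_range(self):
        assert parse_selection("A:5-20,B") == [("A", 5, 20), ("B", None, None)]

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            parse_selection("A:5")
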