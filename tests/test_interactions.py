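"""PDB parsing, hydrogen-bond detection, and contact shells."""
import math

import numpy as np
import pytest

from gsk3pipe.interactions import (parse_complex, find_hbonds, contact_residues,
                                   fingerprint, compare_fingerprints,
                                   AtomRecord, ComplexStructure, ContactFingerprint,
                                   InteractionParams, SelectionError, FormatError)
from gsk3pipe.synthetic import SyntheticComplexSpec, gen_complex


def pdb_line(record, serial, name, resname, chain, resseq, xyz, element,
             altloc=" ", occ=1.0):
    return (f"{record:<6}{serial:>5} {name:<4}{altloc}{resname:<3} {chain}"
            f"{resseq:>4}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{occ:6.2f}{0.00:6.2f}          {element:>2}")


def minimal_complex(donor_acceptor_distance=2.9, with_hydrogen=True,
                    nh_tilt_deg=0.0):
    """One VAL backbone O acceptor facing a ligand N-H donor.

    ``nh_tilt_deg`` tilts the N-H bond off the donor-acceptor axis; 0 gives
    a collinear D-H...A geometry (180 degrees), 45 gives ~117 degrees at
    the default 2.9 A separation.
    """
    lines = [
        pdb_line("ATOM", 1, "N", "VAL", "A", 135, (0, 0, 8), "N"),
        pdb_line("ATOM", 2, "CA", "VAL", "A", 135, (0, 0, 6.5), "C"),
        pdb_line("ATOM", 3, "C", "VAL", "A", 135, (0, 0, 5.2), "C"),
        pdb_line("ATOM", 4, "O", "VAL", "A", 135, (0, 0, donor_acceptor_distance), "O"),
        pdb_line("HETATM", 5, "N1", "LIG", "L", 1, (0, 0, 0), "N"),
    ]
    if with_hydrogen:
        alpha = math.radians(nh_tilt_deg)
        h = (math.sin(alpha), 0.0, math.cos(alpha))
        lines.append(pdb_line("HETATM", 6, "H1", "LIG", "L", 1, h, "H"))
    lines.append(pdb_line("HETATM", 7, "C1", "LIG", "L", 1, (1.4, 0, -0.5), "C"))
    return "\n".join(lines + ["END"]) + "\n"


class TestParseComplex:
    def test_splits_receptor_and_ligand(self):
        c = parse_complex(minimal_complex(), "LIG")
        assert len(c.receptor) == 4
        assert {a.name for a in c.ligand} == {"N1", "H1", "C1"}
        assert c.ligand_id == "LIG"

    def test_chain_resnum_selector(self):
        c = parse_complex(minimal_complex(), "L:1")
        assert len(c.ligand) == 3

    def test_ambiguous_selector_raises(self):
        text = minimal_complex()
        dup = pdb_line("HETATM", 8, "N1", "LIG", "L", 2, (20, 20, 20), "N")
        text = text.replace("END", dup + "\nEND")
        with pytest.raises(SelectionError):
            parse_complex(text, "LIG")

    def test_no_receptor_raises(self):
        lig_only = "\n".join([pdb_line("HETATM", 1, "N1", "LIG", "L", 1,
                                       (0, 0, 0), "N"), "END"])
        with pytest.raises(FormatError):
            parse_complex(lig_only, "LIG")

    def test_altloc_resolved_to_highest_occupancy_ties_to_A(self):
        lines = [
            pdb_line("ATOM", 1, "CA", "VAL", "A", 1, (0, 0, 0), "C", "A", 0.5),
            pdb_line("ATOM", 2, "CA", "VAL", "A", 1, (9, 9, 9), "C", "B", 0.5),
            pdb_line("ATOM", 3, "O", "VAL", "A", 1, (1, 0, 0), "O"),
            pdb_line("HETATM", 4, "C1", "LIG", "L", 2, (2, 0, 0), "C"),
        ]
        c = parse_complex("\n".join(lines + ["END"]), "LIG")
        ca = next(a for a in c.receptor if a.name == "CA")
        assert ca.coord == (0.0, 0.0, 0.0)

    def test_waters_and_ions_excluded(self):
        text = minimal_complex().replace(
            "END", pdb_line("HETATM", 9, "O", "HOH", "W", 300, (0, 0, 3.0), "O")
            + "\nEND")
        c = parse_complex(text, "LIG")
        assert all(a.res_name != "HOH" for a in c.receptor)


class TestHBonds:
    def test_planted_pair_detected(self):
        bonds = find_hbonds(parse_complex(minimal_complex(2.9), "LIG"))
        assert len(bonds) == 1
        b = bonds[0]
        assert b.direction == "ligand-donor"
        assert b.distance == pytest.approx(2.9, abs=1e-6)
        assert b.angle == pytest.approx(180.0, abs=1e-4)
        assert b.receptor_residue == "Val135"

    def test_distance_cutoff_boundary(self):
        assert find_hbonds(parse_complex(minimal_complex(3.6), "LIG"),
                           d_max=3.5) == []
        assert len(find_hbonds(parse_complex(minimal_complex(3.5), "LIG"),
                               d_max=3.5)) == 1

    def test_angle_cutoff(self):
        # 45-degree N-H tilt at 2.9 A -> D-H...A angle of ~117 degrees,
        # verified against the planar closed form below
        bent = parse_complex(minimal_complex(2.9, nh_tilt_deg=45.0), "LIG")
        (bond,) = find_hbonds(bent, angle_min=90.0)
        h = np.array([math.sin(math.radians(45)), 0.0, math.cos(math.radians(45))])
        v1, v2 = -h, np.array([0, 0, 2.9]) - h
        expected = math.degrees(math.acos(
            float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))))
        assert bond.angle == pytest.approx(expected, abs=0.01)
        assert find_hbonds(bent, angle_min=120.0) == []

    def test_distance_only_without_hydrogens(self):
        c = parse_complex(minimal_complex(2.9, with_hydrogen=False), "LIG")
        (bond,) = find_hbonds(c)
        assert bond.hydrogen is None and bond.angle is None

    def test_monotone_in_d_max(self):
        c = parse_complex(minimal_complex(3.2), "LIG")
        n = [len(find_hbonds(c, d_max=d)) for d in (2.5, 3.0, 3.3, 3.5, 4.0)]
        assert n == sorted(n)


class TestContacts:
    def test_radius_boundary(self):
        for d, included in ((4.99, True), (5.01, False)):
            text = "\n".join([
                pdb_line("ATOM", 1, "CB", "ALA", "A", 7, (0, 0, d), "C"),
                pdb_line("ATOM", 2, "CA", "ALA", "A", 7, (0, 0, d + 1.5), "C"),
                pdb_line("HETATM", 3, "C1", "LIG", "L", 1, (0, 0, 0), "C"),
                "END"])
            got = contact_residues(parse_complex(text, "LIG"), radius=5.0)
            assert (got == {"Ala7"}) is included

    def test_hydrogens_ignored(self):
        text = "\n".join([
            pdb_line("ATOM", 1, "CB", "ALA", "A", 7, (0, 0, 8), "C"),
            pdb_line("ATOM", 2, "HB1", "ALA", "A", 7, (0, 0, 3.0), "H"),
            pdb_line("HETATM", 3, "C1", "LIG", "L", 1, (0, 0, 0), "C"),
            "END"])
        assert contact_residues(parse_complex(text, "LIG"), 5.0) == set()

    def test_monotone_in_radius(self):
        pdb_text, _ = gen_complex(SyntheticComplexSpec(seed=11))
        c = parse_complex(pdb_text, "LIG")
        sets = [contact_residues(c, r) for r in (3.0, 5.0, 7.0, 12.0)]
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger


class TestFingerprint:
    def test_composes_bonds_and_contacts(self):
        pdb_text, truth = gen_complex(SyntheticComplexSpec(seed=2))
        fp = fingerprint(parse_complex(pdb_text, "LIG"))
        assert fp.n_hbonds == truth.n_hbonds
        assert set(fp.hbond_residues) == set(truth.hbond_residues)
        assert set(fp.hydrophobic_residues) == set(truth.hydrophobic_residues)

    def test_exclusive_mode_removes_hbond_partners(self):
        pdb_text, _ = gen_complex(SyntheticComplexSpec(seed=2))
        c = parse_complex(pdb_text, "LIG")
        fp = fingerprint(c, InteractionParams(exclusive_hydrophobic=True))
        assert not set(fp.hbond_residues) & set(fp.hydrophobic_residues)

    def test_apolar_ligand_has_no_hbonds_but_contacts(self):
        pdb_text, _ = gen_complex(SyntheticComplexSpec(
            seed=3, n_planted_hbonds=0, n_contact_residues=4))
        fp = fingerprint(parse_complex(pdb_text, "LIG"))
        assert fp.n_hbonds == 0 and len(fp.hydrophobic_residues) == 4

    def test_empty_interface(self):
        text = "\n".join([
            pdb_line("ATOM", 1, "CB", "ALA", "A", 7, (40, 40, 40), "C"),
            pdb_line("HETATM", 2, "C1", "LIG", "L", 1, (0, 0, 0), "C"),
            "END"])
        fp = fingerprint(parse_complex(text, "LIG"))
        assert fp.n_hbonds == 0 and fp.hydrophobic_residues == ()

    def test_rigid_motion_invariance(self):
        """Rotation + translation of the whole complex preserves the result."""
        pdb_text, _ = gen_complex(SyntheticComplexSpec(seed=4))
        c = parse_complex(pdb_text, "LIG")
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                        [math.sin(theta), math.cos(theta), 0],
                        [0, 0, 1.0]])
        shift = np.array([5.0, -3.0, 11.0])

        def move(atom):
            xyz = tuple((rot @ atom.xyz + shift).tolist())
            return AtomRecord(atom.name, atom.element, xyz, atom.res_name,
                              atom.res_seq, atom.chain)

        moved = ComplexStructure(tuple(move(a) for a in c.receptor),
                                 tuple(move(a) for a in c.ligand), c.ligand_id)
        assert fingerprint(moved) == fingerprint(c)
        for b1, b2 in zip(find_hbonds(c), find_hbonds(moved)):
            assert b1.distance == pytest.approx(b2.distance, abs=1e-6)
            assert b1.angle == pytest.approx(b2.angle, abs=1e-6)


class TestCompare:
    def test_identical_and_disjoint(self):
        a = ContactFingerprint("L", 1, ("Ile62",), ("Val135",))
        b = ContactFingerprint("L", 1, ("Asp133",), ("Gln185",))
        assert compare_fingerprints(a, a) == 1.0
        assert compare_fingerprints(a, b) == 0.0

    def test_partial_overlap(self):
        a = ContactFingerprint("L", 0, (), ("Ile62", "Val135"))
        b = ContactFingerprint("L", 0, (), ("Ile62", "Gln185", "Val135"))
        assert compare_fingerprints(a, b) == pytest.approx(2 / 3)

    def test_both_empty_defined_as_one(self):
        e = ContactFingerprint("L", 0, (), ())
        assert compare_fingerprints(e, e) == 1.0
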