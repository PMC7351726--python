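"""Protein-ligand interaction fingerprints from PDB complexes.

Detects geometric hydrogen bonds across the receptor-ligand interface and
the shell of receptor residues with any heavy atom within a contact radius
(5 A by default) of the ligand, mirroring the shape of the study's
interaction table: per ligand, the number of H-bonds, the residues engaged
in them, and the hydrophobic-contact residues.

Criteria: a hydrogen bond is an N/O donor bearing a hydrogen and an N/O
acceptor with heavy-atom distance <= d_max (3.5 A default); when explicit
hydrogens are present the D-H...A angle must additionally be >= angle_min
(120 degrees default), otherwise the criterion is distance-only.
"""
from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom

WATER_AND_IONS = {"HOH", "WAT", "DOD", "NA", "CL", "K", "MG", "ZN", "CA", "SO4", "PO4"}

#: maximum covalent D-H distance used to associate hydrogens with donors, A
H_COVALENT_MAX = 1.25

# receptor donor/acceptor atom names per standard residue (N/O only);
# backbone N is a donor (except proline), backbone O/OXT acceptors.
SIDECHAIN_DONORS: dict[str, frozenset[str]] = {
    "SER": frozenset({"OG"}), "THR": frozenset({"OG1"}), "TYR": frozenset({"OH"}),
    "ASN": frozenset({"ND2"}), "GLN": frozenset({"NE2"}),
    "HIS": frozenset({"ND1", "NE2"}), "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}), "TRP": frozenset({"NE1"}),
}
SIDECHAIN_ACCEPTORS: dict[str, frozenset[str]] = {
    "SER": frozenset({"OG"}), "THR": frozenset({"OG1"}), "TYR": frozenset({"OH"}),
    "ASN": frozenset({"OD1"}), "GLN": frozenset({"OE1"}),
    "ASP": frozenset({"OD1", "OD2"}), "GLU": frozenset({"OE1", "OE2"}),
    "HIS": frozenset({"ND1", "NE2"}), "MET": frozenset(),
}


class SelectionError(ValueError):
    """Ligand selector matched no residue, or more than one."""


class FormatError(ValueError):
    """The PDB text contains no usable receptor."""


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    coord: tuple[float, float, float]
    res_name: str
    res_seq: str       # residue number with any insertion code appended
    chain: str

    @property
    def residue_label(self) -> str:
        """Three-letter-code label such as 'Val135'."""
        return self.res_name.capitalize() + self.res_seq

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass(frozen=True)
class ComplexStructure:
    receptor: tuple[AtomRecord, ...]
    ligand: tuple[AtomRecord, ...]
    ligand_id: str

    def __post_init__(self) -> None:
        if not self.ligand:
            raise SelectionError("ligand is empty")
        for atom in self.receptor + self.ligand:
            if not all(math.isfinite(c) for c in atom.coord):
                raise FormatError(f"non-finite coordinate on atom {atom.name}")


@dataclass(frozen=True)
class HBond:
    donor: AtomRecord
    acceptor: AtomRecord
    distance: float               # heavy-atom D...A distance, A
    direction: str                # "ligand-donor" | "receptor-donor"
    hydrogen: AtomRecord | None = None
    angle: float | None = None    # D-H...A angle, degrees

    def __post_init__(self) -> None:
        assert self.distance > 0
        assert self.angle is None or 0 <= self.angle <= 180

    @property
    def receptor_residue(self) -> str:
        atom = self.acceptor if self.direction == "ligand-donor" else self.donor
        return atom.residue_label


@dataclass(frozen=True)
class ContactFingerprint:
    ligand_id: str
    n_hbonds: int
    hbond_residues: tuple[str, ...]
    hydrophobic_residues: tuple[str, ...]


@dataclass(frozen=True)
class InteractionParams:
    d_max: float = 3.5            # heavy-atom H-bond cutoff, A
    angle_min: float = 120.0      # D-H...A angle cutoff, degrees
    contact_radius: float = 5.0   # residue-shell radius, A
    exclusive_hydrophobic: bool = False


def _pick_altloc(atom):
    """Resolve a possibly-disordered atom: highest occupancy, ties -> 'A'."""
    if isinstance(atom, DisorderedAtom):
        children = atom.disordered_get_list()
        return max(children, key=lambda a: (a.get_occupancy() or 0.0,
                                            -ord(a.get_altloc() or "A")))
    return atom


def _res_seq(residue) -> str:
    _, seq, icode = residue.id
    return f"{seq}{icode.strip()}"


def _to_record(atom, residue, chain_id) -> AtomRecord:
    element = (atom.element or atom.get_name()[0]).strip().upper()
    x, y, z = (float(c) for c in atom.get_coord())
    return AtomRecord(name=atom.get_name(), element=element, coord=(x, y, z),
                      res_name=residue.get_resname().strip(),
                      res_seq=_res_seq(residue), chain=chain_id)


def parse_complex(pdb_text: str, ligand_selector: str) -> ComplexStructure:
    """Parse a PDB document into receptor and ligand atom sets.

    ``ligand_selector`` is either a HETATM residue name (e.g. "LIG") or a
    "chain:resnum" pair.  It must match exactly one residue.  Waters and
    common ions are dropped; alternate locations are resolved to the
    highest-occupancy conformer (ties to altloc 'A').
    """
    structure = PDBParser(QUIET=True).get_structure("complex", io.StringIO(pdb_text))
    model = next(structure.get_models())

    receptor: list[AtomRecord] = []
    ligand_matches = []
    by_chain_num = ":" in ligand_selector
    want_chain, want_num = (ligand_selector.split(":", 1) if by_chain_num
                            else (None, None))
    for chain in model:
        for residue in chain:
            hetflag = residue.id[0]
            resname = residue.get_resname().strip()
            if resname in WATER_AND_IONS or hetflag == "W":
                continue
            if hetflag == " ":
                # residue iteration yields DisorderedAtom once per site
                receptor.extend(_to_record(_pick_altloc(a), residue, chain.id)
                                for a in residue)
                continue
            matches = (f"{chain.id}" == want_chain and _res_seq(residue) == want_num
                       if by_chain_num else resname == ligand_selector)
            if matches:
                ligand_matches.append((chain, residue))
    if not receptor:
        raise FormatError("no polymer ATOM records found")
    if len(ligand_matches) != 1:
        raise SelectionError(
            f"ligand selector {ligand_selector!r} matched {len(ligand_matches)} residues")
    chain, residue = ligand_matches[0]
    lig_atoms = tuple(_to_record(_pick_altloc(a), residue, chain.id)
                      for a in residue)
    return ComplexStructure(receptor=tuple(receptor), ligand=lig_atoms,
                            ligand_id=residue.get_resname().strip())


def _heavy(atoms):
    return [a for a in atoms if a.element != "H"]


def _attached_hydrogens(donor: AtomRecord, pool) -> list[AtomRecord]:
    dxyz = donor.xyz
    return [a for a in pool
            if a.element == "H" and np.linalg.norm(a.xyz - dxyz) <= H_COVALENT_MAX]


def _receptor_polar(receptor):
    donors, acceptors = [], []
    for atom in receptor:
        if atom.element not in ("N", "O"):
            continue
        name, res = atom.name, atom.res_name
        if name == "N" and res != "PRO":
            donors.append(atom)
        elif name in ("O", "OXT"):
            acceptors.append(atom)
        else:
            if name in SIDECHAIN_DONORS.get(res, frozenset()):
                donors.append(atom)
            if name in SIDECHAIN_ACCEPTORS.get(res, frozenset()):
                acceptors.append(atom)
    return donors, acceptors


def _ligand_polar(ligand):
    heavies = [a for a in ligand if a.element in ("N", "O")]
    if any(a.element == "H" for a in ligand):
        donors = [a for a in heavies if _attached_hydrogens(a, ligand)]
    else:
        # no explicit hydrogens: donor typing is impossible, so every polar
        # atom is a candidate donor and the criterion is distance-only
        donors = list(heavies)
    return donors, heavies  # every ligand N/O may accept


def _angle(d, h, a) -> float:
    v1, v2 = d.xyz - h.xyz, a.xyz - h.xyz
    cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def find_hbonds(complex_: ComplexStructure, d_max: float = 3.5,
                angle_min: float = 120.0) -> list[HBond]:
    """All interface hydrogen bonds, sorted by heavy-atom distance."""
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    rec_donors, rec_acceptors = _receptor_polar(complex_.receptor)
    lig_donors, lig_acceptors = _ligand_polar(complex_.ligand)

    bonds: list[HBond] = []
    for donors, acceptors, direction, h_pool in (
        (lig_donors, rec_acceptors, "ligand-donor", complex_.ligand),
        (rec_donors, lig_acceptors, "receptor-donor", complex_.receptor),
    ):
        for donor in donors:
            hydrogens = _attached_hydrogens(donor, h_pool)
            for acceptor in acceptors:
                dist = float(np.linalg.norm(donor.xyz - acceptor.xyz))
                if dist > d_max or dist == 0.0:
                    continue
                if hydrogens:
                    best = max(hydrogens, key=lambda h: _angle(donor, h, acceptor))
                    ang = _angle(donor, best, acceptor)
                    if ang < angle_min:
                        continue
                    bonds.append(HBond(donor, acceptor, dist, direction, best, ang))
                else:
                    bonds.append(HBond(donor, acceptor, dist, direction))
    bonds.sort(key=lambda b: b.distance)
    return bonds


def contact_residues(complex_: ComplexStructure, radius: float = 5.0) -> set[str]:
    """Receptor residues with any heavy atom within ``radius`` of any ligand
    heavy atom (hydrogens ignored on both sides)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    lig = np.array([a.coord for a in _heavy(complex_.ligand)], dtype=float)
    labels: set[str] = set()
    for atom in _heavy(complex_.receptor):
        if atom.residue_label in labels:
            continue
        d2 = np.sum((lig - atom.xyz) ** 2, axis=1)
        if np.any(d2 <= radius * radius):
            labels.add(atom.residue_label)
    return labels


def _residue_sort_key(label: str):
    i = 3
    while i < len(label) and label[i].isdigit():
        i += 1
    return (int(label[3:i] or 0), label)


def fingerprint(complex_: ComplexStructure,
                params: InteractionParams = InteractionParams()) -> ContactFingerprint:
    """Compose H-bond detection and the contact shell into one fingerprint.

    By default the hydrophobic set may overlap the H-bond residues (the
    study lists them separately); ``exclusive_hydrophobic`` removes H-bond
    partners from the contact listing.
    """
    bonds = find_hbonds(complex_, params.d_max, params.angle_min)
    hb_res = sorted({b.receptor_residue for b in bonds}, key=_residue_sort_key)
    contacts = contact_residues(complex_, params.contact_radius)
    if params.exclusive_hydrophobic:
        contacts -= set(hb_res)
    return ContactFingerprint(
        ligand_id=complex_.ligand_id,
        n_hbonds=len(bonds),
        hbond_residues=tuple(hb_res),
        hydrophobic_residues=tuple(sorted(contacts, key=_residue_sort_key)),
    )


def compare_fingerprints(a: ContactFingerprint, b: ContactFingerprint) -> float:
    """Tanimoto similarity of the combined residue sets; both-empty -> 1."""
    sa = set(a.hbond_residues) | set(a.hydrophobic_residues)
    sb = set(b.hbond_residues) | set(b.hydrophobic_residues)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)
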