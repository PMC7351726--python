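"""Synthetic inputs with planted ground truth.

The study's docked poses and pulling trajectories are not deposited, so
every structural input is generated here with known ground truth instead:

* protein-ligand complexes in PDB format with planted hydrogen bonds,
  contact-shell residues and out-of-shell decoys, with geometric margins so
  the detectors in :mod:`gsk3pipe.interactions` must recover the plant
  exactly;
* dock-score / IC50 tables with a controlled linear relation in free-energy
  space plus Gaussian noise, for exercising the correlation machinery;
* LJ + Coulomb binding pockets of controlled well depth and charge for the
  pulling engine.

All generators are deterministic for a fixed seed (NumPy PCG64).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import ThermoConstants, DEFAULT_THERMO
from .fpl import PullSystem
from .interactions import ContactFingerprint
from .thermo import dg_to_ki

# geometric margins guaranteeing detector stability under float noise
HBOND_D_PLANT = (2.7, 3.3)      # A, vs 3.5 cutoff (>= 0.2 margin)
CONTACT_D_PLANT = (4.0, 4.8)    # A, vs 5.0 radius
DECOY_D_MIN = 6.0               # A, beyond radius + margin


class GenerationError(RuntimeError):
    """Requested geometry cannot be planted without violating margins."""


@dataclass(frozen=True)
class SyntheticComplexSpec:
    seed: int = 0
    n_planted_hbonds: int = 3
    n_contact_residues: int = 5
    n_decoy_residues: int = 4
    jitter: float = 0.05        # A, applied within margins

    def __post_init__(self) -> None:
        if min(self.n_planted_hbonds, self.n_contact_residues,
               self.n_decoy_residues) < 0 or self.jitter < 0:
            raise ValueError("counts and jitter must be non-negative")

    @property
    def n_residues(self) -> int:
        return self.n_planted_hbonds + self.n_contact_residues + self.n_decoy_residues


@dataclass(frozen=True)
class SyntheticAffinitySpec:
    seed: int = 0
    n_compounds: int = 19
    slope: float = 0.55         # kcal/mol of dG_exp per kcal/mol of dock score
    intercept: float = -2.8     # kcal/mol
    noise_sd: float = 0.0       # kcal/mol, applied in dG space
    dock_range: tuple = (-14.0, -8.5)

    def __post_init__(self) -> None:
        if self.n_compounds < 3:
            raise ValueError("need at least 3 compounds")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class PocketSpec:
    seed: int = 0
    n_sites: int = 6
    eps: float = 10.0           # kJ/mol per site
    sigma: float = 0.34         # nm
    site_charge: float = 0.0    # e, alternating sign across sites
    ligand_charge: float = 0.0  # e
    channel_length: float = 1.6  # nm, free exit beyond this z
    jitter: float = 0.01        # nm

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.eps < 0 or self.n_sites < 1:
            raise ValueError("need eps >= 0 and at least one site")


# ---------------------------------------------------------------------------
# planted-interaction complexes
# ---------------------------------------------------------------------------

def _unit_directions(n: int) -> np.ndarray:
    """n well-separated unit vectors (golden-spiral points on the sphere)."""
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def _pdb_line(record, serial, name, resname, chain, resseq, xyz, element):
    return (f"{record:<6}{serial:>5} {name:<4}{'':1}{resname:<3} {chain}"
            f"{resseq:>4}{'':1}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element:>2}")


def gen_complex(spec: SyntheticComplexSpec) -> tuple[str, ContactFingerprint]:
    """Synthetic receptor-ligand complex with a known fingerprint.

    The ligand is a small heavy-atom core at the origin: a six-carbon ring
    plus one polar atom per planted hydrogen bond (donor N-H or acceptor O,
    alternating).  Each planted bond gets a glycine whose backbone O
    (receptor acceptor) or backbone N-H (receptor donor) sits at 2.7-3.3 A
    from the ligand polar atom with a collinear D-H...A geometry; contact
    alanines put their CB at 4.0-4.8 A from the nearest ligand atom; decoy
    leucines stay beyond 6 A.  Returns the PDB text and the ground-truth
    fingerprint under default detector parameters.
    """
    if spec.n_residues > 30:
        raise GenerationError("too many residues to place without crowding")
    rng = np.random.default_rng(spec.seed)
    dirs = _unit_directions(max(spec.n_residues, 1))
    rng.shuffle(dirs)

    lig_atoms = []  # (name, element, xyz)
    ring_r = 1.4
    for i in range(6):
        ang = 2 * math.pi * i / 6
        lig_atoms.append((f"C{i+1}", "C",
                          np.array([ring_r * math.cos(ang),
                                    ring_r * math.sin(ang), 0.0])))
    hb_labels, contact_labels = [], []
    receptor_lines = []
    rec_polar = []       # (xyz, hbond_index or None) for every receptor N/O
    planted = []         # (ligand polar xyz, partner xyz) per planted bond
    serial = 1
    res_num = 10

    def emit(record, name, resname, chain, resseq, xyz, element):
        nonlocal serial
        line = _pdb_line(record, serial, name, resname, chain, resseq, xyz, element)
        serial += 1
        return line

    d_idx = 0
    for j in range(spec.n_planted_hbonds):
        u = dirs[d_idx]; d_idx += 1
        lig_polar_pos = 2.6 * u
        d_da = rng.uniform(*HBOND_D_PLANT)
        partner_pos = lig_polar_pos + d_da * u
        ligand_is_donor = j % 2 == 0
        if ligand_is_donor:
            # ligand N-H pointing straight at a backbone carbonyl O
            lig_atoms.append((f"N{j+1}", "N", lig_polar_pos))
            lig_atoms.append((f"H{j+1}", "H", lig_polar_pos + 1.0 * u))
            partner = ("O", "O")
        else:
            lig_atoms.append((f"O{j+1}", "O", lig_polar_pos))
            partner = ("N", "N")
        resname, resseq = "GLY", res_num; res_num += 1
        hb_labels.append(f"Gly{resseq}")
        receptor_lines.append(emit("ATOM", partner[0], resname, "A", resseq,
                                   partner_pos, partner[1]))
        rec_polar.append((partner_pos, j))
        planted.append((lig_polar_pos, partner_pos))
        if not ligand_is_donor:
            # receptor N-H pointing back at the ligand acceptor
            receptor_lines.append(emit("ATOM", "H", resname, "A", resseq,
                                       partner_pos - 1.0 * u, "H"))
        # backbone stub further out along u (never inside H-bond range);
        # the partner of a ligand donor is itself the backbone O, so the
        # stub carbonyl becomes OXT to keep atom names unique
        stub_o = "OXT" if ligand_is_donor else "O"
        for name, el, extra in (("CA", "C", 1.5), ("C", "C", 2.6),
                                (stub_o, "O", 3.4)):
            pos = partner_pos + extra * u
            receptor_lines.append(emit("ATOM", name, resname, "A", resseq, pos, el))
            if el == "O":
                rec_polar.append((pos, None))

    lig_heavy = np.array([xyz for _, el, xyz in lig_atoms if el != "H"])
    for _ in range(spec.n_contact_residues):
        u = dirs[d_idx]; d_idx += 1
        d_c = rng.uniform(*CONTACT_D_PLANT)
        # place CB so its distance to the nearest ligand heavy atom is d_c
        base = lig_heavy[np.argmax(lig_heavy @ u)]
        cb = base + d_c * u
        resname, resseq = "ALA", res_num; res_num += 1
        contact_labels.append(f"Ala{resseq}")
        receptor_lines.append(emit("ATOM", "CB", resname, "A", resseq, cb, "C"))
        for name, el, extra in (("CA", "C", 1.5), ("N", "N", 2.4),
                                ("C", "C", 2.6), ("O", "O", 3.5)):
            pos = cb + extra * u
            receptor_lines.append(emit("ATOM", name, resname, "A", resseq, pos, el))
            if el in ("N", "O"):
                rec_polar.append((pos, None))

    for _ in range(spec.n_decoy_residues):
        u = dirs[d_idx % len(dirs)]; d_idx += 1
        base = DECOY_D_MIN + 3.0 + rng.uniform(0.0, 1.5)
        origin = base * u + rng.normal(0.0, spec.jitter, 3)
        resname, resseq = "LEU", res_num; res_num += 1
        for name, el, extra in (("N", "N", 0.0), ("CA", "C", 1.0),
                                ("C", "C", 2.0), ("O", "O", 2.8)):
            pos = origin + extra * u
            receptor_lines.append(emit("ATOM", name, resname, "A", resseq, pos, el))
            if el in ("N", "O"):
                rec_polar.append((pos, None))

    lig_lines = [emit("HETATM", name, "LIG", "L", 900, xyz, el)
                 for name, el, xyz in lig_atoms]
    pdb_text = "\n".join(receptor_lines + lig_lines + ["END"]) + "\n"

    truth = ContactFingerprint(
        ligand_id="LIG",
        n_hbonds=spec.n_planted_hbonds,
        hbond_residues=tuple(hb_labels),
        hydrophobic_residues=tuple(hb_labels + contact_labels),
    )
    _assert_margins(lig_atoms, rec_polar, planted)
    return pdb_text, truth


def _assert_margins(lig_atoms, rec_polar, planted) -> None:
    """Defensive check: every receptor-polar/ligand-polar pair is either the
    planted bond it belongs to (inside the plant range) or comfortably
    outside the detector cutoff."""
    lig_polar = [(xyz, k) for k, (name, el, xyz) in
                 enumerate(a for a in lig_atoms if a[1] in "NO")]
    planted_idx = {}
    for j, (lp, pp) in enumerate(planted):
        planted_idx[j] = (lp, pp)
    for rxyz, rtag in rec_polar:
        for (lxyz, _ltag) in lig_polar:
            d = float(np.linalg.norm(rxyz - lxyz))
            is_planted_pair = (rtag is not None
                               and np.allclose(lxyz, planted_idx[rtag][0]))
            if is_planted_pair:
                if not d <= HBOND_D_PLANT[1]:
                    raise GenerationError("planted bond fell outside plant range")
            elif d <= 3.7:
                raise GenerationError("overcrowded geometry: stray polar contact")


# ---------------------------------------------------------------------------
# affinity datasets
# ---------------------------------------------------------------------------

def gen_affinity_dataset(
    spec: SyntheticAffinitySpec,
    constants: ThermoConstants = DEFAULT_THERMO,
) -> tuple[list[dict], dict]:
    """Paired (dock score, IC50) rows with a controlled linear relation.

    dG_exp = slope * dock + intercept + N(0, noise_sd) in kcal/mol, then
    back-transformed to an IC50 in uM through the same convention the
    analysis uses (IC50 == Ki at T_exp), so noise is multiplicative in
    concentration.  Returns rows and the true generating parameters.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.dock_range
    dock = rng.uniform(lo, hi, spec.n_compounds)
    dg_exp = spec.slope * dock + spec.intercept
    if spec.noise_sd > 0:
        dg_exp = dg_exp + rng.normal(0.0, spec.noise_sd, spec.n_compounds)
    rows = []
    for i, (d, g) in enumerate(zip(dock, dg_exp)):
        ki_M = dg_to_ki(float(g), constants.T_exp, constants.R_kcal)
        rows.append({"compound_id": f"S{i+1}", "dg_dock_kcal": float(d),
                     "ic50_uM": ki_M * 1e6})
    truth = {"slope": spec.slope, "intercept": spec.intercept,
             "noise_sd": spec.noise_sd, "seed": spec.seed}
    return rows, truth


# ---------------------------------------------------------------------------
# pulling pockets
# ---------------------------------------------------------------------------

def gen_pocket(spec: PocketSpec) -> PullSystem:
    """LJ + Coulomb pocket with the bound minimum near z = 0.

    Sites sit on a jittered ring of radius 2^(1/6) sigma around the origin
    in the xy-plane (so a ligand bead at the origin is at every site's LJ
    minimum) and the +z channel is free of sites; every site carries
    ``site_charge``, so opposite-signed ligand/site charges give a net
    electrostatic attraction.
    """
    rng = np.random.default_rng(spec.seed)
    r0 = 2.0 ** (1.0 / 6.0) * spec.sigma
    angles = 2.0 * math.pi * np.arange(spec.n_sites) / spec.n_sites
    pos = np.stack([r0 * np.cos(angles), r0 * np.sin(angles),
                    np.zeros(spec.n_sites)], axis=1)
    pos[:, :2] += rng.normal(0.0, spec.jitter, (spec.n_sites, 2))
    pos[:, 2] -= rng.uniform(0.0, spec.jitter, spec.n_sites)  # keep channel clear
    return PullSystem(
        site_pos=tuple(map(tuple, pos.tolist())),
        eps=(spec.eps,) * spec.n_sites,
        sigma=(spec.sigma,) * spec.n_sites,
        site_charge=(spec.site_charge,) * spec.n_sites,
        bead_mass=(100.0,),
        bead_charge=(spec.ligand_charge,),
        bead_pos=((0.0, 0.0, 0.0),),
    )
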