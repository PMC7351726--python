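"""Physical constants and unit conventions.

Thermodynamics is done in kcal/mol (the docking convention); the pulling
engine works internally in GROMACS-style units (kJ/mol, nm, ps, amu, e) and
converts to kcal/mol only at the reporting boundary.
"""
from __future__ import annotations

from dataclasses import dataclass

#: gas constant in kcal K^-1 mol^-1
R_KCAL = 1.987e-3
#: Boltzmann constant in kJ mol^-1 K^-1 (internal simulation units)
KB_KJ = 0.00831446261815324
#: Coulomb prefactor f = 1/(4*pi*eps0) in kJ mol^-1 nm e^-2
COULOMB_KJ = 138.935458
#: kJ per kcal; the single conversion factor used everywhere
KJ_PER_KCAL = 4.184

#: IUPAC standard atomic weights (conventional values), g/mol, frozen here so
#: molar masses are reproducible independent of any toolkit version.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.00800, "B": 10.81000, "C": 12.01100, "N": 14.00700,
    "O": 15.99900, "F": 18.99840, "Na": 22.98977, "Mg": 24.30500,
    "Si": 28.08500, "P": 30.97376, "S": 32.06000, "Cl": 35.45000,
    "K": 39.09800, "Ca": 40.07800, "Br": 79.90400, "I": 126.90447,
}


@dataclass(frozen=True)
class ThermoConstants:
    """Temperature/gas-constant conventions for the affinity conversions.

    ``T_dock`` is the ambient temperature a docking engine assumes when it
    converts a score to an inhibition constant (298.15 K); ``T_exp`` is the
    temperature used for the IC50-derived experimental binding free energy
    (300 K).  Both conversions share the same gas constant ``R_kcal``.
    """

    R_kcal: float = R_KCAL
    T_dock: float = 298.15
    T_exp: float = 300.0

    def __post_init__(self) -> None:
        if self.R_kcal <= 0 or self.T_dock <= 0 or self.T_exp <= 0:
            raise ValueError("thermodynamic constants must be strictly positive")


DEFAULT_THERMO = ThermoConstants()

#: dock-score cut below which (more negative) a compound is called a
#: potential inhibitor; the score of the weaker reference inhibitor.
SCREEN_THRESHOLD_KCAL = -10.69
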