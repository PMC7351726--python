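"""Typed access to the packaged study tables.

The four tables of the source study (cytotoxicity IC50s, dock scores with
predicted inhibition constants, hydrogen-bond fingerprints, and
pharmacokinetic descriptors) ship with the package as TSV fixtures, plus a
JSON compound registry and atom-typed molecule graphs for the certified core
compounds.  Everything downstream consumes the record types defined here.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .constants import ThermoConstants, DEFAULT_THERMO

CELL_LINES = ("HepG2", "LU-1", "SW480", "HL-60", "HEK-293")
ROLES = ("parent", "intermediate", "designed", "reference-inhibitor", "reference-drug")


class FixtureError(ValueError):
    """A packaged table failed to parse or validate."""


@dataclass(frozen=True)
class CompoundRecord:
    id: str
    role: str
    formula: str | None = None
    graph_ref: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise FixtureError(f"unknown compound role {self.role!r} for {self.id}")


@dataclass(frozen=True)
class CytotoxEntry:
    """One compound x cell-line IC50.  ``censored`` means the assay only
    bounded the value from below ('> 20 uM'); censored entries carry the
    bound in ``ic50_uM`` and no standard deviation."""

    compound_id: str
    cell_line: str
    ic50_uM: float
    censored: bool
    sd_uM: float | None = None

    def __post_init__(self) -> None:
        if self.cell_line not in CELL_LINES:
            raise FixtureError(f"unknown cell line {self.cell_line!r}")
        if self.ic50_uM <= 0:
            raise FixtureError(f"non-positive IC50 for {self.compound_id}")
        if self.censored and self.sd_uM is not None:
            raise FixtureError(f"censored entry with sd for {self.compound_id}")
        if self.sd_uM is not None and self.sd_uM < 0:
            raise FixtureError(f"negative sd for {self.compound_id}")


@dataclass(frozen=True)
class DockRecord:
    compound_id: str
    dg_dock: float  # kcal/mol
    ki_pred: float  # mol/L

    def __post_init__(self) -> None:
        if not self.dg_dock < 0:
            raise FixtureError(f"dock score must be negative for {self.compound_id}")
        if not self.ki_pred > 0:
            raise FixtureError(f"Ki must be positive for {self.compound_id}")


@dataclass(frozen=True)
class InteractionRow:
    compound_id: str
    n_hbonds: int
    residues: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_hbonds < 0:
            raise FixtureError("negative H-bond count")
        if self.n_hbonds > 0 and not self.residues:
            raise FixtureError(f"H-bonds without residues for {self.compound_id}")


@dataclass(frozen=True)
class DescriptorRow:
    compound_id: str
    milogp: float
    tpsa: float      # A^2
    mw: float        # g/mol
    ld50_pred: float  # mg/kg
    tox_class: int

    def __post_init__(self) -> None:
        if self.tpsa < 0 or self.mw <= 0:
            raise FixtureError(f"bad descriptor row for {self.compound_id}")
        if not 1 <= self.tox_class <= 6:
            raise FixtureError(f"toxicity class out of range for {self.compound_id}")


def fixture_path(name: str) -> Path:
    """Resolve a packaged fixture by file name."""
    return Path(str(resources.files("gsk3pipe").joinpath("fixtures", name)))


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FixtureError(f"fixture not found: {path}")
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def load_compounds(path: str | Path | None = None) -> dict[str, CompoundRecord]:
    path = Path(path) if path else fixture_path("compounds.json")
    records = [CompoundRecord(r["id"], r["role"], r.get("formula"), r.get("graph_ref"))
               for r in json.loads(path.read_text())]
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise FixtureError("duplicate compound ids in registry")
    return {r.id: r for r in records}


def _normalize(cell: str) -> str:
    # the printed tables use a Unicode minus and stray spacing
    return cell.replace("−", "-").replace("–", "-").strip()


def load_cytotoxicity(path: str | Path | None = None) -> list[CytotoxEntry]:
    """Load the cytotoxicity table (one row per compound x cell line).

    Cells printed "> 20" are loaded as right-censored entries with the bound
    recorded in ``ic50_uM`` and no standard deviation.
    """
    df = _read_tsv(path or fixture_path("table1_cytotoxicity.tsv"))
    entries = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            raw = _normalize(row.ic50_uM)
            censored = _normalize(row.censored).lower() in ("true", "1", "yes")
            if raw.startswith(">"):
                censored, raw = True, raw.lstrip("> ")
            sd = _normalize(row.sd_uM)
            entries.append(CytotoxEntry(
                compound_id=_normalize(row.compound_id),
                cell_line=_normalize(row.cell_line),
                ic50_uM=float(raw),
                censored=censored,
                sd_uM=None if censored or sd == "" else float(sd),
            ))
        except (ValueError, AttributeError) as exc:
            raise FixtureError(f"malformed cytotoxicity row at line {line_no}: {exc}") from exc
    return entries


def parse_ki(text: str) -> float:
    """Parse a printed inhibition constant such as '46.6E-12' to mol/L."""
    value = float(_normalize(text).replace("E", "e"))
    if not math.isfinite(value):
        raise FixtureError(f"non-finite Ki {text!r}")
    return value


def load_docking(path: str | Path | None = None) -> list[DockRecord]:
    df = _read_tsv(path or fixture_path("table2_docking.tsv"))
    records = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(DockRecord(
                compound_id=_normalize(row.compound_id),
                dg_dock=float(_normalize(row.dg_dock_kcal)),
                ki_pred=parse_ki(row.ki_pred_M),
            ))
        except ValueError as exc:
            raise FixtureError(f"malformed docking row at line {line_no}: {exc}") from exc
    return records


def load_interactions(path: str | Path | None = None) -> list[InteractionRow]:
    df = _read_tsv(path or fixture_path("table3_interactions.tsv"))
    return [InteractionRow(
        compound_id=_normalize(row.compound_id),
        n_hbonds=int(row.n_hbonds),
        residues=tuple(r.strip() for r in row.residues.split(",") if r.strip()),
    ) for row in df.itertuples(index=False)]


def load_descriptors(path: str | Path | None = None) -> list[DescriptorRow]:
    df = _read_tsv(path or fixture_path("table4_descriptors.tsv"))
    return [DescriptorRow(
        compound_id=_normalize(row.compound_id),
        milogp=float(row.milogp),
        tpsa=float(row.tpsa_A2),
        mw=float(row.mw_g_mol),
        ld50_pred=float(row.ld50_mg_kg),
        tox_class=int(row.tox_class),
    ) for row in df.itertuples(index=False)]


def load_molecule_graphs(path: str | Path | None = None) -> dict[str, dict]:
    path = Path(path) if path else fixture_path("molecule_graphs.json")
    return json.loads(path.read_text())


def validate_dock_consistency(
    records: list[DockRecord],
    rel_tol_dg: float = 0.05,
    constants: ThermoConstants = DEFAULT_THERMO,
) -> list[str]:
    """Flag rows whose printed (dock score, Ki) pair is internally inconsistent.

    Each Ki is converted back to a free energy at ``constants.T_dock`` and
    compared with the printed dock score; ids whose relative disagreement
    exceeds ``rel_tol_dg`` are returned.  On the packaged table exactly one
    row (compound 6b) fails this check.
    """
    if not 0 < rel_tol_dg < 0.5:
        raise ValueError("rel_tol_dg must lie in (0, 0.5)")
    from .thermo import ki_to_dg  # local import to avoid a cycle

    anomalies = []
    for rec in records:
        dg_back = ki_to_dg(rec.ki_pred, constants.T_dock, constants.R_kcal)
        if abs(dg_back - rec.dg_dock) / abs(rec.dg_dock) > rel_tol_dg:
            anomalies.append(rec.compound_id)
    return anomalies


def cross_check_registry(
    compounds: dict[str, CompoundRecord],
    *tables: list,
) -> list[str]:
    """Return compound ids referenced by any table but missing from the registry."""
    missing = []
    for table in tables:
        for row in table:
            if row.compound_id not in compounds:
                missing.append(row.compound_id)
    return sorted(set(missing))
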