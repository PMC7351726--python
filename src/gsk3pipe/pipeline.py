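"""End-to-end orchestration of the analysis stages.

``run_all`` executes, in order: table validation (including the internal
dock-score/Ki consistency check), the four per-cell-line dock-vs-experiment
correlations, threshold screening, descriptor recomputation for the
certified compounds, interaction fingerprints on synthetic complexes, and a
demonstration pulling estimate on a generated pocket.  All outputs carry
the seed and a hash of the configuration for reproducibility.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .constants import ThermoConstants, DEFAULT_THERMO, SCREEN_THRESHOLD_KCAL
from . import data as paper_data
from .descriptors import MoleculeGraph, ertl_tpsa, mol_weight, formula_of
from .fpl import PullSchedule, run_replicas, estimate_delta_e
from .interactions import InteractionParams, parse_complex, fingerprint
from .synthetic import SyntheticComplexSpec, PocketSpec, gen_complex, gen_pocket
from .thermo import dock_vs_exp, screen_by_threshold, DEFAULT_CENSORING


@dataclass(frozen=True)
class PipelineConfig:
    fixture_dir: str | None = None      # None -> packaged fixtures
    out_dir: str = "results"
    seed: int = 0
    thermo: ThermoConstants = DEFAULT_THERMO
    censoring: str = DEFAULT_CENSORING
    threshold: float = SCREEN_THRESHOLD_KCAL
    rel_tol_dg: float = 0.05
    interaction: InteractionParams = InteractionParams()
    n_synthetic_complexes: int = 3
    fpl_schedule: PullSchedule = field(
        default_factory=lambda: PullSchedule(equil_ps=50.0, pull_ps=400.0))
    fpl_replicas: int = 8
    fpl_pocket: PocketSpec = PocketSpec(eps=12.0, site_charge=0.1,
                                        ligand_charge=-0.08)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(doc)
        if "thermo" in kwargs:
            kwargs["thermo"] = ThermoConstants(**kwargs["thermo"])
        if "interaction" in kwargs:
            kwargs["interaction"] = InteractionParams(**kwargs["interaction"])
        if "fpl_schedule" in kwargs:
            kwargs["fpl_schedule"] = PullSchedule(**kwargs["fpl_schedule"])
        if "fpl_pocket" in kwargs:
            kwargs["fpl_pocket"] = PocketSpec(**kwargs["fpl_pocket"])
        return cls(**kwargs)


def stage_seed(global_seed: int, stage: str) -> int:
    """Fan a global seed out to a per-stage seed by stable hashing."""
    digest = zlib.crc32(f"{stage}:{global_seed}".encode())
    return int(digest % (2**31 - 1))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage, self.cause = stage, cause


def _fix(config: PipelineConfig, name: str):
    if config.fixture_dir is None:
        return None
    path = Path(config.fixture_dir) / name
    if not path.exists():
        raise FileNotFoundError(path)
    return path


def run_all(config: PipelineConfig = PipelineConfig()) -> dict:
    """Run every stage; returns the report bundle as a plain dict."""
    if config.fixture_dir is not None and not Path(config.fixture_dir).is_dir():
        raise StageError("startup", FileNotFoundError(config.fixture_dir))
    bundle: dict = {
        "provenance": {
            "seed": config.seed,
            "version": __version__,
            "config_sha1": hashlib.sha1(
                json.dumps(asdict(config), sort_keys=True, default=str).encode()
            ).hexdigest(),
        }
    }
    stage = "data"
    try:
        compounds = paper_data.load_compounds(_fix(config, "compounds.json"))
        cytotox = paper_data.load_cytotoxicity(_fix(config, "table1_cytotoxicity.tsv"))
        dock = paper_data.load_docking(_fix(config, "table2_docking.tsv"))
        interactions_tbl = paper_data.load_interactions(_fix(config, "table3_interactions.tsv"))
        descriptors_tbl = paper_data.load_descriptors(_fix(config, "table4_descriptors.tsv"))
        missing = paper_data.cross_check_registry(
            compounds, cytotox, dock, interactions_tbl, descriptors_tbl)
        anomalies = paper_data.validate_dock_consistency(
            dock, config.rel_tol_dg, config.thermo)
        bundle["data"] = {
            "rows": {"cytotoxicity": len(cytotox), "docking": len(dock),
                     "interactions": len(interactions_tbl),
                     "descriptors": len(descriptors_tbl)},
            "unregistered_ids": missing,
            "ki_consistency_anomalies": anomalies,
        }

        stage = "correlations"
        summaries = {}
        for cell in ("HepG2", "LU-1", "SW480", "HL-60"):
            s = dock_vs_exp(cytotox, dock, cell, config.thermo, config.censoring)
            summaries[cell] = {"n": s.n, "r": round(s.r, 2),
                               "slope": s.slope, "intercept": s.intercept,
                               "rmse_kcal": s.rmse}
        bundle["correlations"] = summaries

        stage = "screening"
        designed = [r for r in dock
                    if compounds[r.compound_id].role not in
                    ("reference-inhibitor", "reference-drug")]
        parts = screen_by_threshold(designed, config.threshold)
        bundle["screening"] = {
            "threshold_kcal": config.threshold,
            "potential_inhibitors": sorted(parts["potential-inhibitor"]),
            "below_threshold": sorted(parts["below-threshold"]),
        }

        stage = "descriptors"
        graphs = paper_data.load_molecule_graphs(_fix(config, "molecule_graphs.json"))
        table4 = {r.compound_id: r for r in descriptors_tbl}
        desc = {}
        for cid, doc in sorted(graphs.items()):
            g = MoleculeGraph.from_dict(doc)
            formula = formula_of(g)
            desc[cid] = {
                "formula": formula,
                "tpsa_A2": round(ertl_tpsa(g), 2),
                "mw_g_mol": mol_weight(formula),
                "tpsa_printed": table4[cid].tpsa,
                "mw_printed": table4[cid].mw,
            }
        bundle["descriptors"] = desc

        stage = "fingerprints"
        fps = []
        for i in range(config.n_synthetic_complexes):
            spec = SyntheticComplexSpec(seed=stage_seed(config.seed, f"complex{i}"))
            pdb_text, truth = gen_complex(spec)
            fp = fingerprint(parse_complex(pdb_text, "LIG"), config.interaction)
            fps.append({
                "seed": spec.seed,
                "n_hbonds": fp.n_hbonds,
                "hbond_residues": list(fp.hbond_residues),
                "hydrophobic_residues": list(fp.hydrophobic_residues),
                "matches_ground_truth": (
                    fp.n_hbonds == truth.n_hbonds
                    and set(fp.hbond_residues) == set(truth.hbond_residues)
                    and set(fp.hydrophobic_residues) == set(truth.hydrophobic_residues)),
            })
        bundle["fingerprints"] = fps

        stage = "fpl"
        pocket_spec = dataclasses.replace(
            config.fpl_pocket, seed=stage_seed(config.seed, "pocket"))
        system = gen_pocket(pocket_spec)
        seeds = [stage_seed(config.seed, f"fpl-replica{i}")
                 for i in range(config.fpl_replicas)]
        results = run_replicas(system, config.fpl_schedule, seeds)
        est = estimate_delta_e(results, system)
        bundle["fpl"] = {
            "replicas": config.fpl_replicas,
            "seeds": seeds,
            "delta_e_cou_kcal": {"mean": est.mean_cou, "sd": est.sd_cou},
            "delta_e_vdw_kcal": {"mean": est.mean_vdw, "sd": est.sd_vdw},
            "delta_e_total_kcal": {"mean": est.mean_total, "sd": est.sd_total},
            "vdw_fraction": est.vdw_fraction,
            "mean_f_max_kj_nm": float(np.mean([r.f_max for r in results])),
            "mean_work_kj": float(np.mean([r.total_work for r in results])),
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
    return bundle


#: required bundle sections and the keys each must carry
BUNDLE_SCHEMA: dict[str, tuple[str, ...]] = {
    "provenance": ("seed", "version", "config_sha1"),
    "data": ("rows", "unregistered_ids", "ki_consistency_anomalies"),
    "correlations": ("HepG2", "LU-1", "SW480", "HL-60"),
    "screening": ("threshold_kcal", "potential_inhibitors", "below_threshold"),
    "descriptors": (),
    "fingerprints": (),
    "fpl": ("delta_e_cou_kcal", "delta_e_vdw_kcal", "delta_e_total_kcal",
            "vdw_fraction"),
}


def validate_bundle(bundle: dict) -> None:
    """Raise ValueError unless the bundle has every section the schema names."""
    for section, keys in BUNDLE_SCHEMA.items():
        if section not in bundle:
            raise ValueError(f"bundle missing section {section!r}")
        for key in keys:
            if key not in bundle[section]:
                raise ValueError(f"bundle section {section!r} missing {key!r}")


def report(bundle: dict, fmt: str = "json") -> str:
    """Render a report bundle as JSON, TSV, or a human-readable summary."""
    if not bundle:
        raise ValueError("empty bundle")
    if fmt == "json":
        return json.dumps(bundle, indent=1, sort_keys=True, default=str)
    if fmt == "tsv":
        lines = ["section\tkey\tvalue"]
        def walk(prefix, obj):
            if isinstance(obj, dict):
                for k, v in obj.items():
                    walk(f"{prefix}.{k}" if prefix else str(k), v)
            elif isinstance(obj, (list, tuple)):
                lines.append(f"{prefix.split('.')[0]}\t{prefix}\t"
                             + ",".join(map(str, obj)))
            else:
                lines.append(f"{prefix.split('.')[0]}\t{prefix}\t{obj}")
        walk("", bundle)
        return "\n".join(lines) + "\n"
    if fmt == "text":
        c = bundle["correlations"]
        rows = [
            "dock-score vs experimental binding free energy (Pearson r):",
            *(f"  {cell}: r = {c[cell]['r']:.2f} (n = {c[cell]['n']})"
              for cell in c),
            f"Ki-consistency anomalies: "
            f"{', '.join(bundle['data']['ki_consistency_anomalies']) or 'none'}",
            f"potential inhibitors at {bundle['screening']['threshold_kcal']} "
            f"kcal/mol: {len(bundle['screening']['potential_inhibitors'])} of "
            f"{len(bundle['screening']['potential_inhibitors']) + len(bundle['screening']['below_threshold'])}",
            "descriptors (computed vs printed):",
            *(f"  {cid}: TPSA {d['tpsa_A2']} / {d['tpsa_printed']} A^2, "
              f"MW {d['mw_g_mol']} / {d['mw_printed']} g/mol"
              for cid, d in bundle["descriptors"].items()),
            f"FPL dE_total = {bundle['fpl']['delta_e_total_kcal']['mean']:.2f} "
            f"+/- {bundle['fpl']['delta_e_total_kcal']['sd']:.2f} kcal/mol "
            f"(vdW fraction {bundle['fpl']['vdw_fraction']:.2f})",
        ]
        return "\n".join(rows) + "\n"
    raise ValueError(f"unknown report format {fmt!r}")


def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report(bundle, "json") + "\n")
    (out / "report.tsv").write_text(report(bundle, "tsv"))
    (out / "report.txt").write_text(report(bundle, "text"))
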