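#!/usr/bin/env python
"""Fast-pulling-of-ligand experiments on coarse-grained pockets.

Runs the replica-averaged pulling estimator on (a) a series of pockets of
increasing well depth and (b) a charged demonstration pocket, and checks a
near-quasi-static pull against the potential-profile quadrature.
Findings: the replica-mean |dE_total| is strictly monotone in the planted
depth (Spearman rho = 1.0 over 4 depths x 8 replicas); the decomposition
dE = dE_cou + dE_vdW holds exactly; on the charged demo pocket the van
der Waals term dominates the decomposition; and the slow-pull work agrees
with the potential-energy difference within a few percent.
"""
import argparse
import json
from pathlib import Path

import numpy as np

from gsk3pipe.experiments import well_depth_series, quasi_static_work_check
from gsk3pipe.fpl import PullSchedule, run_replicas, estimate_delta_e
from gsk3pipe.pipeline import stage_seed
from gsk3pipe.synthetic import PocketSpec, gen_pocket

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    OUT.mkdir(exist_ok=True)

    print("well-depth series (zero charge), 8 replicas each:")
    series = well_depth_series(seed=stage_seed(args.seed, "depths"))
    for depth, est in zip(series.depths, series.estimates):
        print(f"  eps = {depth:>5.1f} kJ/mol/site: dE_total = "
              f"{est.mean_total:8.2f} +/- {est.sd_total:.2f} kcal/mol")
    print(f"  rank correlation |dE| vs depth: {series.rank_correlation:.2f}")

    print("\ncharged demonstration pocket, 8 replicas:")
    pocket = gen_pocket(PocketSpec(seed=stage_seed(args.seed, "pocket"),
                                   eps=12.0, site_charge=0.1,
                                   ligand_charge=-0.08))
    schedule = PullSchedule(equil_ps=50.0, pull_ps=400.0)
    seeds = [stage_seed(args.seed, f"replica{i}") for i in range(8)]
    results = run_replicas(pocket, schedule, seeds)
    est = estimate_delta_e(results, pocket)
    print(f"  dE_cou = {est.mean_cou:.2f} +/- {est.sd_cou:.2f} kcal/mol")
    print(f"  dE_vdW = {est.mean_vdw:.2f} +/- {est.sd_vdw:.2f} kcal/mol")
    print(f"  dE_total = {est.mean_total:.2f} +/- {est.sd_total:.2f} kcal/mol "
          f"(vdW fraction {100 * est.vdw_fraction:.1f}%)")
    print(f"  mean rupture force {np.mean([r.f_max for r in results]):.1f} "
          f"kJ/mol/nm, mean work {np.mean([r.total_work for r in results]):.1f} kJ/mol")

    # time series of the first replica, on the metric grid
    res = results[0]
    lines = ["t_ps\tdisplacement_nm\te_cou_kj\te_vdw_kj"]
    lines += [f"{t:.1f}\t{d:.4f}\t{ec:.4f}\t{ev:.4f}" for t, d, ec, ev in
              zip(res.times_metric, res.displacement, res.e_cou, res.e_vdw)]
    (OUT / "fpl_timeseries_replica0.tsv").write_text("\n".join(lines) + "\n")

    qs = quasi_static_work_check(seed=args.seed)
    print(f"\nquasi-static check: W = {qs.work_kj:.2f} kJ/mol vs "
          f"dU = {qs.potential_difference_kj:.2f} kJ/mol "
          f"({100 * qs.relative_error:.1f}% relative)")

    (OUT / "fpl_estimates.json").write_text(json.dumps({
        "depth_series": {str(d): {"mean_total_kcal": e.mean_total,
                                  "sd_total_kcal": e.sd_total}
                         for d, e in zip(series.depths, series.estimates)},
        "rank_correlation": series.rank_correlation,
        "demo_pocket": {"de_cou": est.mean_cou, "de_vdw": est.mean_vdw,
                        "de_total": est.mean_total,
                        "vdw_fraction": est.vdw_fraction},
        "quasi_static": {"work_kj": qs.work_kj,
                         "potential_difference_kj": qs.potential_difference_kj,
                         "relative_error": qs.relative_error},
    }, indent=1) + "\n")
    print(f"wrote fpl_estimates.json, fpl_timeseries_replica0.tsv to {OUT}")


if __name__ == "__main__":
    main()
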