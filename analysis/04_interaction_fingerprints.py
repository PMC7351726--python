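#!/usr/bin/env python
"""Interaction fingerprints on synthetic complexes with planted geometry.

The study's docked poses are not deposited, so the hydrogen-bond and
contact-shell detectors are exercised on generated complexes whose
fingerprints are known by construction.  Finding: across 20 seeded
complexes the detectors recover every planted fingerprint exactly
(hydrogen-bond count, bonded residues, and the 5 A contact shell).
Writes a fingerprint table shaped like the study's interaction table.
"""
import argparse
from pathlib import Path

from gsk3pipe.experiments import fingerprint_recovery
from gsk3pipe.interactions import parse_complex, fingerprint
from gsk3pipe.synthetic import SyntheticComplexSpec, gen_complex

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n", type=int, default=20)
    args = parser.parse_args()

    lines = ["ligand_id\tseed\tn_hbonds\thbond_residues\thydrophobic_residues"]
    for k in range(args.n):
        spec = SyntheticComplexSpec(seed=args.seed + k)
        pdb_text, _ = gen_complex(spec)
        fp = fingerprint(parse_complex(pdb_text, "LIG"))
        lines.append(f"{fp.ligand_id}\t{spec.seed}\t{fp.n_hbonds}\t"
                     f"{','.join(fp.hbond_residues)}\t"
                     f"{','.join(fp.hydrophobic_residues)}")

    outcome = fingerprint_recovery(n_complexes=args.n, seed=args.seed)
    print(f"planted fingerprints recovered exactly: "
          f"{outcome['exact_recoveries']}/{outcome['n_complexes']}")

    OUT.mkdir(exist_ok=True)
    (OUT / "fingerprints.tsv").write_text("\n".join(lines) + "\n")
    print(f"wrote {OUT / 'fingerprints.tsv'}")


if __name__ == "__main__":
    main()
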