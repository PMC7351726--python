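# Methods

## Scope and data

The pipeline re-analyzes the computational layer of a structure–activity
study of indirubin-3′-oxime derivatives against GSK-3β.  Everything the
study prints is packaged as fixtures (TSV tables, a JSON compound registry,
atom-typed molecule graphs); everything it does **not** deposit — docked
poses, pulling trajectories — is replaced by synthetic systems with planted
ground truth, so the detectors and estimators can be validated exactly
while making no claim of reproducing pose-dependent numbers.

Censoring is explicit: "> 20 µM" cytotoxicity cells become right-censored
entries carrying the 20 µM bound and no standard deviation, and no code
path ever treats a censored entry as a measured value without saying so
(see the inclusion rule below).

## Thermodynamic conventions

All conversions use ΔG = R·T·ln K_i with R = 1.987×10⁻³ kcal K⁻¹ mol⁻¹.
Two temperatures coexist by design, both fields of `ThermoConstants`:

* **T_dock = 298.15 K** — back-converting the printed K_i,pred reproduces
  the printed dock scores to ≤ 0.01 kcal/mol at this temperature (at 300 K
  the residuals grow to ~0.05 kcal/mol), so it is the docking engine's
  convention.
* **T_exp = 300 K** — the stated convention for IC50-derived experimental
  binding free energies, with the IC50 (µM → mol/L) taken equal to K_i.

Because the printed dock scores carry only two decimals, *forward*
agreement with the printed K_i is limited to ~1%; consistency checks
therefore operate in ΔG-space, where rounding contributes ≤ 0.01 kcal/mol.
`validate_dock_consistency` flags rows whose back-converted ΔG deviates
from the printed score by more than 5% relative: exactly one row (compound
6b) fails, by ~1.3 kcal/mol.  It is reported, never silently corrected.

### Inclusion rule for the dock-vs-experiment correlations

The correlation of ΔG_exp against dock score per cell line needs a rule for
censored IC50s.  Both candidate rules are implemented:

* **at-bound** (default): censored entries enter at their 20 µM bound;
* **drop**: censored entries are excluded.

Calibrating against the published per-cell-line correlation strengths
decides the default: at-bound reproduces r = 0.90 / 0.93 / 0.93 / 0.90
(HepG2 / LU-1 / SW480 / HL-60, n = 19 each) to two decimals, while drop
gives 0.84 / 0.90 / 0.91 / 0.87.  The at-bound values are biased low in
principle (a "> 20" compound is weaker than 20 µM), which is the right
direction for a conservative screen; the drop rule is retained as an
option because it is the statistically cleaner convention.  Reported
precision follows the tables: r to two decimals, ΔG to two, K_i to three
significant figures.

## Descriptors

TPSA follows Ertl's fragment scheme: each N/O (and, for completeness, S/P)
atom is matched by (element, aromaticity, formal charge, hydrogen count,
bond-order multiset) against the published contribution table and the
contributions summed.  Atom typing is part of the input graph, not
perceived from connectivity: the certified graphs for compounds 1–4 type
the five-membered indole-type rings as aromatic, so their N–H matches the
aromatic nH fragment (15.79 Å²).  That convention is what the printed
table implies — it yields 65.72 Å² for the parent exactly — and differs
from toolkits that perceive the 2-oxindole five-ring as non-aromatic
(N–H at 12.03 Å², a ~7.5 Å² shift).  With this typing the four certified
compounds give 65.72 / 81.24 / 54.86 / 70.38 Å² against printed
65.72 / 81.25 / 54.87 / 70.39 — the oxime/propargyl rows differ in the
last printed digit, consistent with the source server's rounding, so
comparisons carry a ±0.01 Å² tolerance.  Ertl's three-membered-ring
variants (aziridine-type) are not in the table; an unmatched polar atom
raises a typing error naming the atom.

Molar masses come from a frozen table of IUPAC conventional atomic weights;
graph formulas are emitted in Hill order with implicit hydrogens from the
per-atom H counts.  miLogP and LD50/toxicity class are third-party model
outputs and are only ever loaded, never computed.

## Interaction fingerprints

PDB complexes are parsed with Biopython (first model; waters and common
ions dropped; alternate locations resolved to the highest-occupancy
conformer, ties to altloc 'A'; insertion codes appended to residue
numbers).  The study does not state its hydrogen-bond criteria (its counts
come from a visualization tool), so defaults were chosen and are
configurable: donor–acceptor heavy-atom distance ≤ 3.5 Å, and a D–H⋯A
angle ≥ 120° whenever explicit hydrogens are present (attached hydrogens
are those within 1.25 Å of the donor).  Structures without hydrogens fall
back to a distance-only criterion, since donor typing is then undecidable
on the ligand side.  Receptor donors/acceptors come from a rule table over
the 20 standard residues (backbone N donor except proline, backbone O/OXT
acceptor, the usual side-chain sets); ligand N/O atoms accept always and
donate when they carry a hydrogen.  Contact residues are those with any
heavy atom within 5 Å of any ligand heavy atom.  By default the
hydrophobic listing may overlap the H-bond residues, matching how the
study lists them separately; an exclusive mode subtracts them.  The
study's printed per-compound H-bond counts are a format reference only:
without the docked poses they are not reproducible, and the detectors are
instead validated by exact recovery of planted fingerprints.

## Synthetic generators

All generators are deterministic NumPy PCG64 streams keyed by explicit
seeds; seeds are recorded in every output.

* **Complexes**: a six-carbon ligand core with one polar atom per planted
  hydrogen bond, each paired with a glycine partner (backbone O acceptor
  or N–H donor) at 2.7–3.3 Å in collinear geometry; contact alanines with
  CB at 4.0–4.8 Å; decoy leucines beyond 6 Å.  Margins of ≥ 0.2 Å / 10°
  against the detector cutoffs guarantee stability under float noise, and
  a generation-time audit verifies that no unplanned polar pair slipped
  inside 3.7 Å (raising a generation error rather than emitting a complex
  whose truth is wrong).  Residues are placed on shuffled golden-spiral
  directions so they cannot crowd each other; requests beyond 30 residues
  are refused.
* **Affinity tables**: dock scores uniform on a configurable range,
  ΔG_exp = slope·dock + intercept + N(0, σ) in kcal/mol, back-transformed
  to IC50 through the same T_exp convention the analysis uses — i.e. noise
  is multiplicative in concentration, matching how assay error behaves on
  a log scale.
* **Pockets**: n sites on a jittered ring of radius 2^(1/6)σ around the
  origin, so a ligand bead at the origin sits at every site's LJ minimum
  (bound energy ≈ −n·ε) with the +z channel free.  Site charges are
  uniform; the demonstration pocket uses ε = 12 kJ/mol, site charge
  +0.1 e, ligand −0.08 e, chosen so the electrostatic term is a clear
  minority contribution as expected for an uncharged heteroaromatic
  binder in a kinase pocket.

What the generators do **not** emulate: real GSK-3β geometry, solvent
structure, ligand flexibility, or pose-dependent interaction patterns.
Passing tests therefore demonstrate that the detectors and estimators are
correct on systems whose answers are known — not that the study's specific
poses or pulling profiles are recovered.

## The pulling engine

The explicit-solvent steered-MD protocol (PME, ~26,000 waters, restrained
backbone) is deliberately replaced by the smallest model that preserves
the estimator and protocol: rigid interaction sites (standing in for the
restrained receptor), a ligand bead (or beads — nonbonded, sharing the
center-of-mass spring mass-weighted) under Langevin dynamics, pairwise
12-6 LJ plus cutoff Coulomb (no periodicity at this scale), both truncated
at 0.9 nm.  Internal units are GROMACS-style (kJ/mol, nm, ps, amu, e) with
kB = 0.008314463 kJ/mol/K and f = 138.935458 kJ·mol⁻¹·nm·e⁻²; affinities
are reported in kcal/mol at exactly 4.184 kJ/kcal.

Integration is BAOAB Langevin splitting with timestep 0.002 ps and
friction 10 ps⁻¹ (stable at T = 300 K for the masses and well depths
used; both configurable).  The spring anchor holds still for an
equilibration window (100 ps by default, mirroring the study's 100 ps
NVT/NPT), then moves at v = 0.005 nm/ps along +z with k = 600 kJ/mol/nm².
Spring force is recorded every 0.1 ps, displacement and the energy
decomposition every 10 ps; the pulling work is the trapezoidal integral of
the recorded force times anchor speed.  Every replica draws its noise from
its own seeded generator, so results are bitwise identical whether a
replica runs alone or inside the vectorized batch.

The estimator averages E_cou and E_vdW over the equilibration window
(bound) and the final 10% of the trajectory (unbound; identically zero
once all sites are beyond the cutoff, which is verified per replica —
an incomplete unbinding raises rather than biasing the estimate), forms
ΔE = ΔE_cou + ΔE_vdW per replica, and reports mean ± SD over eight
replicas (SD, not standard error, matching how the study reports spread).
Whether the study's "work" plots use spring or total force is unstated;
spring force is used here.

The study's pulling-vs-experiment correlation (R = 0.88, RMSE = 0.8
kcal/mol over ten complexes) and its 79%/21% vdW/electrostatic split
require the undeposited trajectories and are out of scope; the engine is
validated by properties instead: exact energy decomposition, brute-force
pair-sum agreement (≤ 100 sites, 1e-10), strict monotonicity of the
replica-mean |ΔE| across planted well depths ({5, 10, 20, 40} kJ/mol/site,
8 replicas each, Spearman ρ = 1.0), zero Coulomb on zero-charge pockets,
and near-quasi-static pulls (T = 0, v = 5×10⁻⁴ nm/ps) recovering the
potential-profile quadrature within 10% (observed ~2%, the residual being
friction work m·γ·v per unit distance).

## Problem sizes and numerical choices

Depth-series runs use a 20 ps equilibration and 300 ps pull (the demo
pocket 50/400 ps), sizes at which the bound-window averages are stable to
well under the depth spacing; the quasi-static check pulls 0.8 nm at
5×10⁻⁴ nm/ps.  Divergence is guarded by a 50 nm box bound (raising with
the step index), coincident bead/site pairs raise a singularity error, and
pathological schedules (timestep > 0.005 ps) are rejected up front.
Pearson r is clamped to [−1, 1] against float overshoot on exact lines;
regression RMSE is the root-mean-square residual with no
degrees-of-freedom correction, in y-units.

## Known limitations

* Only compounds 1–4 have certified molecule graphs; the 6a–p conjugates
  lack authoritative structures, so their descriptor rows are loaded, not
  recomputed.
* The coarse pulling model has no solvent structure or ligand
  conformational entropy; its ΔE values are internally meaningful
  (monotone in the planted depth) but not comparable to experiment.
* π-stacking, salt bridges, and halogen bonds are not detected; the
  fingerprint is hydrogen bonds plus a heavy-atom contact shell.
* The at-bound inclusion rule treats a censored IC50 as if it were at its
  bound; analyses needing unbiased effect sizes should use the drop rule
  and accept the smaller n.
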