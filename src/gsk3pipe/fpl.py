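"""Coarse-grained fast-pulling-of-ligand (FPL) engine.

A ligand (one or more nonbonded beads) sits in a pocket of fixed
Lennard-Jones + Coulomb interaction sites and is dragged out along a pull
axis by a harmonic spring whose anchor moves at constant speed, while the
beads follow Langevin dynamics at the bath temperature.  This is the
desk-scale analogue of a steered-MD unbinding run: the receptor is rigid,
solvent enters only through friction and noise, and plain cutoffs replace
lattice electrostatics.

The observable of interest is the interaction-energy difference between the
bound and unbound states,

    dE = dE_cou + dE_vdW = (E_cou^full - E_cou^0) + (E_vdW^full - E_vdW^0),

estimated per trajectory by averaging the ligand-receptor Coulomb and LJ
energies over a pre-pull equilibration window (bound) and the final window
(unbound, identically zero once every site is beyond the cutoff), then
averaged over independent replicas.  Internal units are GROMACS-style
(kJ/mol, nm, ps, amu, e); reported affinities are kcal/mol.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import KB_KJ, COULOMB_KJ, KJ_PER_KCAL


class SimulationDivergedError(RuntimeError):
    def __init__(self, step: int):
        super().__init__(f"integrator diverged at step {step}")
        self.step = step


class IncompleteUnbindingError(RuntimeError):
    """A replica finished with the ligand still inside the cutoff of a site."""


@dataclass(frozen=True)
class PullSystem:
    """Fixed interaction sites plus ligand bead(s).

    ``site_pos`` is (S, 3) in nm; ``eps`` (kJ/mol), ``sigma`` (nm) and
    ``site_charge`` (e) are per-site.  Ligand beads are nonbonded among
    themselves and share the center-of-mass pulling spring.
    """

    site_pos: tuple
    eps: tuple
    sigma: tuple
    site_charge: tuple
    bead_mass: tuple      # amu
    bead_charge: tuple    # e
    bead_pos: tuple       # nm, initial
    cutoff: float = 0.9   # nm, for both LJ and Coulomb
    temperature: float = 300.0
    friction: float = 10.0   # ps^-1
    dielectric: float = 1.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if any(m <= 0 for m in self.bead_mass):
            raise ValueError("bead masses must be positive")
        if any(s <= 0 for s in self.sigma):
            raise ValueError("sigma must be positive")
        if any(e < 0 for e in self.eps):
            raise ValueError("epsilon must be non-negative")
        sites = np.asarray(self.site_pos, float).reshape(-1, 3)
        beads = np.asarray(self.bead_pos, float).reshape(-1, 3)
        if sites.size and not np.any(
                np.linalg.norm(sites[None] - beads[:, None], axis=-1) < self.cutoff):
            raise ValueError("ligand must start within cutoff of at least one site")

    # -- array views -------------------------------------------------------
    @property
    def sites(self) -> np.ndarray:
        return np.asarray(self.site_pos, float).reshape(-1, 3)

    @property
    def beads(self) -> np.ndarray:
        return np.asarray(self.bead_pos, float).reshape(-1, 3)

    @property
    def masses(self) -> np.ndarray:
        return np.asarray(self.bead_mass, float)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, doc: dict) -> "PullSystem":
        def tup(x):
            return tuple(tuple(v) if isinstance(v, (list, tuple)) else v for v in x)
        kwargs = dict(doc)
        for key in ("site_pos", "eps", "sigma", "site_charge",
                    "bead_mass", "bead_charge", "bead_pos"):
            kwargs[key] = tup(doc[key])
        return cls(**kwargs)


@dataclass(frozen=True)
class PullSchedule:
    """Spring/anchor protocol: stiffness k (kJ/mol/nm^2), speed v (nm/ps),
    timestep (ps), equilibration hold before the anchor moves, pull
    duration, and the two recording intervals."""

    k: float = 600.0
    v: float = 0.005
    dt: float = 0.002
    equil_ps: float = 100.0
    pull_ps: float = 500.0
    force_interval: float = 0.1
    metric_interval: float = 10.0
    axis: tuple = (0.0, 0.0, 1.0)
    box_bound: float = 50.0   # nm, divergence guard

    def __post_init__(self) -> None:
        if min(self.k, self.v, self.dt, self.pull_ps,
               self.force_interval, self.metric_interval) <= 0:
            raise ValueError("schedule parameters must be positive")
        if self.equil_ps < 0:
            raise ValueError("equilibration must be non-negative")
        if self.dt > 0.005:
            raise ValueError("timestep unstable (> 0.005 ps) at default friction")

    @property
    def unit_axis(self) -> np.ndarray:
        a = np.asarray(self.axis, float)
        return a / np.linalg.norm(a)


@dataclass(frozen=True)
class PullTrajectoryResult:
    """Time series from one pulling replica.

    Spring force is recorded every ``force_interval``; displacement and the
    energy decomposition every ``metric_interval``.  ``work`` is the
    trapezoidal integral of the recorded spring force times anchor speed.
    """

    seed: int
    times_force: np.ndarray       # ps
    force: np.ndarray             # kJ/mol/nm, signed along the axis
    times_metric: np.ndarray      # ps
    displacement: np.ndarray      # nm, COM projection minus start
    e_cou: np.ndarray             # kJ/mol
    e_vdw: np.ndarray             # kJ/mol
    work: np.ndarray              # kJ/mol, cumulative, on the force grid
    f_max: float
    equil_ps: float
    pull_speed: float
    final_min_site_dist: float    # nm, min bead-site distance at the end

    @property
    def total_work(self) -> float:
        return float(self.work[-1])


@dataclass(frozen=True)
class FplEstimate:
    """Replica-resolved interaction-energy differences, kcal/mol."""

    de_cou: np.ndarray
    de_vdw: np.ndarray
    de_total: np.ndarray
    mean_cou: float
    sd_cou: float
    mean_vdw: float
    sd_vdw: float
    mean_total: float
    sd_total: float
    vdw_fraction: float

    @classmethod
    def from_replicas(cls, de_cou, de_vdw) -> "FplEstimate":
        de_cou = np.asarray(de_cou, float)
        de_vdw = np.asarray(de_vdw, float)
        de_total = de_cou + de_vdw
        vc, vv = abs(float(np.mean(de_cou))), abs(float(np.mean(de_vdw)))
        return cls(
            de_cou=de_cou, de_vdw=de_vdw, de_total=de_total,
            mean_cou=float(np.mean(de_cou)), sd_cou=float(np.std(de_cou)),
            mean_vdw=float(np.mean(de_vdw)), sd_vdw=float(np.std(de_vdw)),
            mean_total=float(np.mean(de_total)), sd_total=float(np.std(de_total)),
            vdw_fraction=(vv / (vv + vc)) if (vv + vc) > 0 else float("nan"),
        )


# ---------------------------------------------------------------------------
# energies and forces
# ---------------------------------------------------------------------------

def _pair_terms(system: PullSystem, beads: np.ndarray):
    """Displacements, distances and cutoff mask, shapes (..., B, S[, 3])."""
    diff = beads[..., :, None, :] - system.sites[None, :, :]     # (..., B, S, 3)
    r = np.linalg.norm(diff, axis=-1)
    if np.any(r == 0.0):
        raise ZeroDivisionError("coincident ligand bead and site (r = 0)")
    mask = r <= system.cutoff
    return diff, r, mask


def interaction_energy(system: PullSystem,
                       beads: np.ndarray | None = None) -> tuple[float, float]:
    """Ligand-receptor (E_cou, E_vdW) in kJ/mol at the given bead coordinates.

    Pairwise 12-6 Lennard-Jones and Coulomb 1/(4 pi eps0 eps_r r), each term
    zero beyond the cutoff.
    """
    beads = system.beads if beads is None else np.asarray(beads, float).reshape(-1, 3)
    if system.sites.size == 0:
        return 0.0, 0.0
    _, r, mask = _pair_terms(system, beads)
    sr6 = (np.asarray(system.sigma) / r) ** 6
    e_vdw = 4.0 * np.asarray(system.eps) * (sr6**2 - sr6)
    qq = np.outer(system.bead_charge, system.site_charge)
    e_cou = COULOMB_KJ * qq / (system.dielectric * r)
    return float(np.sum(e_cou * mask)), float(np.sum(e_vdw * mask))


def _forces(system, beads):
    """Nonbonded force on each bead, shape like ``beads``."""
    diff, r, mask = _pair_terms(system, beads)
    sig = np.asarray(system.sigma)
    eps = np.asarray(system.eps)
    sr6 = (sig / r) ** 6
    # dU/dr for LJ: 4 eps (6 sr6 - 12 sr6^2)/r ; Coulomb: -f qq / (eps_r r^2)
    qq = np.asarray(system.bead_charge)[..., :, None] * np.asarray(system.site_charge)
    dudr = (4.0 * eps * (6.0 * sr6 - 12.0 * sr6**2) / r
            - COULOMB_KJ * qq / (system.dielectric * r**2))
    coeff = np.where(mask, -dudr / r, 0.0)
    return np.sum(coeff[..., None] * diff, axis=-2)


# ---------------------------------------------------------------------------
# the integrator
# ---------------------------------------------------------------------------

def run_replicas(system: PullSystem, schedule: PullSchedule,
                 seeds: list[int]) -> list[PullTrajectoryResult]:
    """Integrate several replicas of the same pull, batched over replicas.

    Each replica draws its noise from its own seeded generator, so the
    result for a given seed is bitwise identical whether it is run alone or
    inside a batch.  BAOAB Langevin splitting; T = 0 switches the noise off.
    """
    R = len(seeds)
    B = system.beads.shape[0]
    dt, gamma = schedule.dt, system.friction
    axis = schedule.unit_axis
    masses = system.masses[None, :, None]           # (1, B, 1)
    mass_total = float(system.masses.sum())
    mass_frac = (system.masses / mass_total)[None, :, None]

    n_equil = int(round(schedule.equil_ps / dt))
    n_pull = int(round(schedule.pull_ps / dt))
    n_steps = n_equil + n_pull
    every_f = max(1, int(round(schedule.force_interval / dt)))
    every_m = max(1, int(round(schedule.metric_interval / dt)))

    # per-replica noise streams, drawn up front for batched integration
    kT = KB_KJ * system.temperature
    if kT > 0:
        noise = np.stack([np.random.default_rng(s).standard_normal((n_steps, B, 3))
                          for s in seeds])            # (R, n, B, 3)
    else:
        noise = np.zeros((R, 1, B, 3))
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(kT * (1.0 - c1 * c1)) / np.sqrt(masses)

    x = np.broadcast_to(system.beads, (R, B, 3)).copy()
    v = np.zeros((R, B, 3))
    anchor0 = float(system.beads.T @ system.masses / mass_total @ axis)

    n_f = n_pull // every_f + 1
    n_m = n_steps // every_m + 1
    t_force = np.empty(n_f); f_rec = np.empty((R, n_f))
    t_metric = np.empty(n_m)
    disp = np.empty((R, n_m)); ecou = np.empty((R, n_m)); evdw = np.empty((R, n_m))
    i_f = i_m = 0

    def com_proj(x):
        return np.sum(x * mass_frac, axis=1) @ axis   # (R,)

    def spring_and_nb(x, t_pull):
        f_nb = _forces(system, x)
        anchor = anchor0 + schedule.v * max(0.0, t_pull)
        f_spring = schedule.k * (anchor - com_proj(x))          # (R,)
        f_total = f_nb + f_spring[:, None, None] * mass_frac * axis
        return f_total, f_spring

    def record_metric(step, x):
        nonlocal i_m
        t_metric[i_m] = step * dt
        disp[:, i_m] = com_proj(x) - com_proj(np.broadcast_to(system.beads, (R, B, 3)))
        for rr in range(R):
            ec, ev = interaction_energy(system, x[rr])
            ecou[rr, i_m], evdw[rr, i_m] = ec, ev
        i_m += 1

    f_total, f_spring = spring_and_nb(x, -1.0)
    record_metric(0, x)
    for step in range(n_steps):
        t_pull = (step + 1) * dt - schedule.equil_ps   # anchor time after this step
        v += 0.5 * dt * f_total / masses
        x += 0.5 * dt * v
        if kT > 0:
            v = c1 * v + c2 * noise[:, step]
        else:
            v = c1 * v
        x += 0.5 * dt * v
        f_total, f_spring = spring_and_nb(x, t_pull)
        v += 0.5 * dt * f_total / masses
        if np.any(np.abs(x) > schedule.box_bound) or not np.all(np.isfinite(x)):
            raise SimulationDivergedError(step)
        done = step + 1
        if done > n_equil and (done - n_equil) % every_f == 0:
            t_force[i_f] = done * dt
            f_rec[:, i_f] = f_spring
            i_f += 1
        if done % every_m == 0:
            record_metric(done, x)

    # pad the force grid origin (pull start, zero elapsed pull work)
    t_force[i_f:] = t_force[i_f - 1] if i_f else schedule.equil_ps
    results = []
    final_r = np.linalg.norm(
        x[:, :, None, :] - system.sites[None, None, :, :], axis=-1
    ).min(axis=(1, 2)) if system.sites.size else np.full(R, np.inf)
    for rr in range(R):
        force = f_rec[rr, :i_f]
        # work: trapezoid of F(t) * v dt over the recorded pull-phase grid
        work = np.concatenate([
            [0.0],
            np.cumsum(0.5 * (force[1:] + force[:-1]) * schedule.v
                      * np.diff(t_force[:i_f]))
        ]) if i_f > 1 else np.zeros(max(i_f, 1))
        results.append(PullTrajectoryResult(
            seed=seeds[rr],
            times_force=t_force[:i_f].copy(), force=force.copy(),
            times_metric=t_metric[:i_m].copy(),
            displacement=disp[rr, :i_m].copy(),
            e_cou=ecou[rr, :i_m].copy(), e_vdw=evdw[rr, :i_m].copy(),
            work=work, f_max=float(force.max()) if i_f else 0.0,
            equil_ps=schedule.equil_ps, pull_speed=schedule.v,
            final_min_site_dist=float(final_r[rr]),
        ))
    return results


def run_pull(system: PullSystem, schedule: PullSchedule,
             seed: int) -> PullTrajectoryResult:
    """Integrate a single pulling replica (see :func:`run_replicas`)."""
    return run_replicas(system, schedule, [seed])[0]


def pull_work(result: PullTrajectoryResult) -> float:
    """Total pulling work, kJ/mol: trapezoidal integral of F(t) * v dt."""
    if result.force.size == 0:
        raise ValueError("empty force series")
    return float(np.trapezoid(result.force, result.times_force) * result.pull_speed)


def estimate_delta_e(results: list[PullTrajectoryResult],
                     system: PullSystem,
                     unbound_fraction: float = 0.1) -> FplEstimate:
    """Interaction-energy-difference estimate over replicas, kcal/mol.

    Bound-state energies are averaged over each replica's pre-pull
    equilibration window, unbound over the final ``unbound_fraction`` of the
    trajectory; with plain cutoffs the unbound terms vanish once every site
    is out of range, which is verified per replica.
    """
    de_cou, de_vdw = [], []
    for res in results:
        if res.final_min_site_dist <= system.cutoff:
            raise IncompleteUnbindingError(
                f"replica seed={res.seed} ended {res.final_min_site_dist:.3f} nm "
                f"from the nearest site (cutoff {system.cutoff} nm)")
        bound = res.times_metric <= res.equil_ps
        n_tail = max(1, int(round(unbound_fraction * res.times_metric.size)))
        cou_bound = float(np.mean(res.e_cou[bound]))
        vdw_bound = float(np.mean(res.e_vdw[bound]))
        cou_unbound = float(np.mean(res.e_cou[-n_tail:]))
        vdw_unbound = float(np.mean(res.e_vdw[-n_tail:]))
        de_cou.append((cou_bound - cou_unbound) / KJ_PER_KCAL)
        de_vdw.append((vdw_bound - vdw_unbound) / KJ_PER_KCAL)
    return FplEstimate.from_replicas(de_cou, de_vdw)
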