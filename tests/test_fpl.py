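"""Pulling engine: energies, dynamics, work, and the replica estimator."""
import math

import numpy as np
import pytest

from gsk3pipe.constants import COULOMB_KJ
from gsk3pipe.fpl import (PullSystem, PullSchedule, interaction_energy,
                          run_pull, run_replicas, pull_work, estimate_delta_e,
                          IncompleteUnbindingError)
from gsk3pipe.synthetic import PocketSpec, gen_pocket

SIGMA = 0.33


def single_site_system(eps=10.0, q_site=0.0, q_lig=0.0, r0=None, mass=50.0,
                       temperature=0.0):
    """One site at the origin, bead on the +z axis (default: LJ minimum)."""
    z0 = r0 if r0 is not None else 2.0 ** (1 / 6) * SIGMA
    return PullSystem(site_pos=((0.0, 0.0, 0.0),), eps=(eps,), sigma=(SIGMA,),
                      site_charge=(q_site,), bead_mass=(mass,),
                      bead_charge=(q_lig,), bead_pos=((0.0, 0.0, z0),),
                      temperature=temperature)


class TestInteractionEnergy:
    def test_lj_closed_form_points(self):
        at_sigma = single_site_system(eps=10.0, r0=SIGMA)
        assert interaction_energy(at_sigma)[1] == pytest.approx(0.0, abs=1e-9)
        at_min = single_site_system(eps=10.0)
        assert interaction_energy(at_min)[1] == pytest.approx(-10.0, abs=1e-9)

    def test_zero_charges_give_exactly_zero_coulomb(self):
        assert interaction_energy(single_site_system())[0] == 0.0

    def test_coulomb_closed_form(self):
        s = single_site_system(eps=0.0, q_site=0.5, q_lig=-0.4, r0=0.5)
        expected = COULOMB_KJ * 0.5 * -0.4 / 0.5
        assert interaction_energy(s)[0] == pytest.approx(expected, rel=1e-12)

    def test_zero_beyond_cutoff(self):
        s = single_site_system(eps=10.0, q_site=0.5, q_lig=0.5)
        assert interaction_energy(s, np.array([[0.0, 0.0, 0.95]])) == (0.0, 0.0)

    def test_coincident_points_raise(self):
        s = single_site_system()
        with pytest.raises(ZeroDivisionError):
            interaction_energy(s, np.array([[0.0, 0.0, 0.0]]))

    def test_matches_brute_force_summation(self):
        """Direct pair re-summation oracle on random many-site systems."""
        rng = np.random.default_rng(12)
        for trial in range(5):
            n = int(rng.integers(5, 100))
            pos = rng.uniform(-1.0, 1.0, (n, 3))
            eps = rng.uniform(0.1, 5.0, n)
            sig = rng.uniform(0.2, 0.4, n)
            q = rng.uniform(-0.5, 0.5, n)
            bead = rng.uniform(-0.5, 0.5, 3)
            system = PullSystem(site_pos=tuple(map(tuple, pos)),
                                eps=tuple(eps), sigma=tuple(sig),
                                site_charge=tuple(q), bead_mass=(50.0,),
                                bead_charge=(0.3,), bead_pos=(tuple(bead),),
                                dielectric=2.0)
            ec_ref = ev_ref = 0.0
            for i in range(n):
                r = math.dist(bead, pos[i])
                if r > system.cutoff:
                    continue
                sr6 = (sig[i] / r) ** 6
                ev_ref += 4.0 * eps[i] * (sr6 * sr6 - sr6)
                ec_ref += COULOMB_KJ * 0.3 * q[i] / (2.0 * r)
            ec, ev = interaction_energy(system)
            assert ec == pytest.approx(ec_ref, abs=1e-10)
            assert ev == pytest.approx(ev_ref, abs=1e-10)


class TestRunPull:
    def test_deterministic_for_fixed_seed(self):
        pocket = gen_pocket(PocketSpec(seed=1, eps=6.0))
        sched = PullSchedule(equil_ps=2.0, pull_ps=20.0)
        a = run_pull(pocket, sched, seed=42)
        b = run_pull(pocket, sched, seed=42)
        assert np.array_equal(a.force, b.force)
        assert np.array_equal(a.e_vdw, b.e_vdw)

    def test_single_replica_bitwise_equals_batch_member(self):
        pocket = gen_pocket(PocketSpec(seed=1, eps=6.0))
        sched = PullSchedule(equil_ps=2.0, pull_ps=20.0)
        batch = run_replicas(pocket, sched, [7, 8, 9])
        solo = run_pull(pocket, sched, seed=8)
        assert np.array_equal(solo.force, batch[1].force)

    def test_free_bead_tracks_anchor_with_friction_limited_lag(self):
        """No sites, T = 0: the steady spring force balances friction,
        F = m * gamma * v (overdamped closed form)."""
        mass, gamma, v = 100.0, 10.0, 0.005
        system = PullSystem(site_pos=(), eps=(), sigma=(), site_charge=(),
                            bead_mass=(mass,), bead_charge=(0.0,),
                            bead_pos=((0.0, 0.0, 0.0),), temperature=0.0,
                            friction=gamma)
        sched = PullSchedule(equil_ps=0.0, pull_ps=200.0, v=v)
        res = run_pull(system, sched, seed=0)
        f_steady = mass * gamma * v
        tail = res.force[len(res.force) // 2:]
        assert np.mean(tail) == pytest.approx(f_steady, rel=0.02)
        # and the bead indeed moved with the anchor
        assert res.displacement[-1] == pytest.approx(v * 200.0, rel=0.05)

    def test_deeper_well_needs_larger_rupture_force(self):
        sched = PullSchedule(equil_ps=5.0, pull_ps=150.0)
        fmax = {}
        for eps in (5.0, 40.0):
            pocket = gen_pocket(PocketSpec(seed=2, eps=eps))
            res = run_replicas(pocket, sched, seeds=list(range(8)))
            fmax[eps] = np.mean([r.f_max for r in res])
        assert fmax[40.0] > fmax[5.0]

    def test_work_identity_on_recorded_grid(self):
        pocket = gen_pocket(PocketSpec(seed=1, eps=6.0))
        res = run_pull(pocket, PullSchedule(equil_ps=2.0, pull_ps=30.0), seed=3)
        ref = np.trapezoid(res.force, res.times_force) * res.pull_speed
        assert res.work[-1] == pytest.approx(ref, abs=1e-9)
        assert pull_work(res) == pytest.approx(ref, abs=1e-12)

    def test_no_sites_zero_temperature_work_is_friction_only(self):
        mass, gamma, v = 100.0, 10.0, 0.005
        system = PullSystem(site_pos=(), eps=(), sigma=(), site_charge=(),
                            bead_mass=(mass,), bead_charge=(0.0,),
                            bead_pos=((0.0, 0.0, 0.0),), temperature=0.0,
                            friction=gamma)
        res = run_pull(system, PullSchedule(equil_ps=0.0, pull_ps=200.0, v=v),
                       seed=0)
        # steady state: W ~ F_fric * distance = m gamma v * (v T)
        assert pull_work(res) == pytest.approx(mass * gamma * v * v * 200.0,
                                               rel=0.05)


@pytest.fixture(scope="module")
def charged_run():
    pocket = gen_pocket(PocketSpec(seed=5, eps=10.0, site_charge=0.1,
                                   ligand_charge=-0.08))
    sched = PullSchedule(equil_ps=20.0, pull_ps=300.0, metric_interval=5.0)
    results = run_replicas(pocket, sched, seeds=list(range(4)))
    return pocket, results


class TestEstimator:
    def test_decomposition_identity_exact(self, charged_run):
        pocket, results = charged_run
        est = estimate_delta_e(results, pocket)
        assert np.array_equal(est.de_total, est.de_cou + est.de_vdw)

    def test_unbound_state_is_zero_so_delta_is_minus_bound(self, charged_run):
        pocket, results = charged_run
        for res in results:
            assert res.e_cou[-1] == 0.0 and res.e_vdw[-1] == 0.0
        est = estimate_delta_e(results, pocket)
        assert est.mean_total < 0  # attraction lost on unbinding

    def test_zero_charge_system_has_unit_vdw_fraction(self):
        pocket = gen_pocket(PocketSpec(seed=5, eps=8.0))
        sched = PullSchedule(equil_ps=10.0, pull_ps=300.0)
        results = run_replicas(pocket, sched, seeds=[0, 1])
        est = estimate_delta_e(results, pocket)
        assert np.all(est.de_cou == 0.0)
        assert est.vdw_fraction == 1.0

    def test_incomplete_unbinding_detected(self):
        pocket = gen_pocket(PocketSpec(seed=5, eps=8.0))
        short = PullSchedule(equil_ps=5.0, pull_ps=20.0)  # anchor moves 0.1 nm
        results = run_replicas(pocket, short, seeds=[0])
        with pytest.raises(IncompleteUnbindingError):
            estimate_delta_e(results, pocket)
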