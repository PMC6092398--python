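"""Stochastic population model: state space, partitioning, stepping, runs."""
import numpy as np
import pytest
from scipy.integrate import quad

from kaisim.population import (
    ModelParams,
    PopulationState,
    enumerate_compositions,
    kaia_partition,
    kaia_protocol,
    phospho_step,
    run_simulation,
    sequestration_step,
)
from dataclasses import replace


class TestCompositions:
    def test_enumeration(self):
        comps = enumerate_compositions()
        assert len(comps) == 84  # C(9,3) multisets of 6 protomers over 4 forms
        assert tuple(comps[0]) == (6, 0, 0, 0)
        assert all(sum(c) == 6 for c in comps)
        assert len(set(map(tuple, comps))) == 84


class TestKaiAPartition:
    def test_single_state_quadratic_closed_form(self):
        """A_tot = C_tot = Kd gives bound fraction (3 - sqrt 5)/2."""
        frac, a_free = kaia_partition(1.0, np.array([1.0]), np.array([1.0]))
        assert frac[0] == pytest.approx((3 - np.sqrt(5)) / 2, abs=1e-9)
        # KaiA conserved exactly
        assert a_free + frac[0] * 1.0 == pytest.approx(1.0, abs=1e-9)

    def test_weak_binding_limit(self):
        frac, a_free = kaia_partition(1.0, np.array([1.0]), np.array([1e12]))
        assert frac[0] == pytest.approx(0.0, abs=1e-9)
        assert a_free == pytest.approx(1.0, rel=1e-9)

    def test_stoichiometric_limit(self):
        """Kd -> 0 with excess KaiA binds every hexamer."""
        frac, a_free = kaia_partition(2.0, np.array([0.5, 0.5]), np.array([1e-12, 1e-12]))
        assert np.allclose(frac, 1.0, atol=1e-6)
        assert a_free == pytest.approx(1.0, rel=1e-6)

    def test_negative_pool_rejected(self):
        with pytest.raises(ValueError):
            kaia_partition(-0.1, np.array([1.0]), np.array([1.0]))


class TestPhosphoStep:
    def test_pure_dephosphorylation_is_monotone(self, rng):
        """No KaiA, kphos=0, start all-pS/pT: %P decays to zero."""
        params = ModelParams(n_hexamers=200, kphos=0.0, a2_ratio=0.0, b_uM=0.0)
        active = np.zeros(84, dtype=np.int64)
        idx = [i for i, c in enumerate(enumerate_compositions())
               if tuple(c) == (0, 0, 6, 0)][0]
        active[idx] = 200
        state = PopulationState(active=active, sequestering=np.zeros(84, np.int64),
                                a2_total=0.0, seq_a2=0.0, free_b=0.0)
        last = state.percent_p()
        for k in range(4000):
            state, _ = phospho_step(state, params, rng)
            if k % 100 == 0:
                pp = state.percent_p()
                assert pp <= last + 1e-9  # monotone decay
                last = pp
        assert state.percent_p() < 1.0
        assert state.active[0] >= 190  # essentially all back to all-S/T

    def test_saturating_kaia_phosphorylates_fully(self, rng):
        params = ModelParams(n_hexamers=100, kdephos=0.0, a2_ratio=1000.0,
                             kd_scale=1e-6, b_uM=0.0, bound_back_reaction=False)
        state = PopulationState.initial(params)
        last = 0.0
        for k in range(1500):
            state, _ = phospho_step(state, params, rng)
            pp = state.percent_p()
            assert pp >= last - 1e-9  # non-decreasing (no dephospho channel)
            last = pp
        assert last == pytest.approx(100.0)

    def test_per_step_flux_matches_binomial_oracle(self):
        """Mean ST->SpT hexamer flux equals trials x p within 3 binomial SE."""
        params = ModelParams(n_hexamers=400, a2_ratio=1000.0, kd_scale=1e-6,
                             kdephos=0.0, b_uM=0.0, bound_back_reaction=False)
        rng = np.random.default_rng(0)
        moved = []
        for _ in range(1000):
            state = PopulationState.initial(params)
            new, _ = phospho_step(state, params, rng)
            moved.append(400 - new.active[0])
        n_trials = 400 * 6  # protomer trials in the all-S/T composition
        p = params.kphos * params.dt
        expect = n_trials * p
        se = np.sqrt(n_trials * p * (1 - p) / len(moved))
        assert abs(np.mean(moved) - expect) < 3 * se


class TestSequestrationStep:
    def _state_with(self, comp, n, params):
        active = np.zeros(84, dtype=np.int64)
        idx = [i for i, c in enumerate(enumerate_compositions()) if tuple(c) == comp][0]
        active[idx] = n
        return PopulationState(
            active=active, sequestering=np.zeros(84, np.int64),
            a2_total=params.a2_uM, seq_a2=0.0, free_b=params.b_uM,
        )

    def test_ineligible_composition_never_switches(self, rng):
        params = ModelParams(n_hexamers=100)
        state = self._state_with((6, 0, 0, 0), 100, params)
        new = sequestration_step(state, params, rng)
        assert new.sequestering.sum() == 0
        assert new.seq_a2 == 0.0

    def test_capture_bookkeeping(self, rng):
        """Each sequestering hexamer holds up to g KaiA dimer equivalents."""
        params = ModelParams(n_hexamers=100, kb_switch=40.0, dt=0.01)
        state = self._state_with((0, 0, 0, 6), 100, params)
        new = sequestration_step(state, params, rng)
        n_seq = int(new.sequestering.sum())
        assert n_seq > 0
        unit = params.conc_per_hexamer
        expect = min(n_seq * params.seq_capacity * unit, params.a2_uM)
        assert new.seq_a2 == pytest.approx(expect)
        # KaiB consumed: 6 monomers per sequestered hexamer
        assert new.free_b == pytest.approx(params.b_uM - n_seq * 6 * unit)

    def test_no_kaib_no_sequestration(self, rng):
        params = ModelParams(n_hexamers=100, b_uM=0.0, kb_switch=40.0)
        state = self._state_with((0, 0, 0, 6), 100, params)
        state = replace(state, free_b=0.0)
        new = sequestration_step(state, params, rng)
        assert new.sequestering.sum() == 0


class TestRunSimulation:
    def test_same_seed_identical_trajectory(self):
        p = ModelParams(n_hexamers=300)
        t1 = run_simulation(p, 30.0, seed=5)
        t2 = run_simulation(p, 30.0, seed=5)
        assert np.array_equal(t1.percent_p, t2.percent_p)
        assert np.array_equal(t1.free_a2, t2.free_a2)

    def test_kaia_conservation_along_run(self):
        """free + instantaneously-bound + sequestered = total at 1e-9."""
        p = ModelParams(n_hexamers=1000)
        traj = run_simulation(p, 60.0, seed=2)
        total = traj.free_a2 + traj.bound_a2 + traj.seq_a2
        assert np.max(np.abs(total - traj.a2_total)) < 1e-9 * p.a2_uM

    def test_no_kaia_stays_dephosphorylated(self):
        traj = run_simulation(ModelParams(n_hexamers=200, a2_ratio=0.0), 20.0, seed=1)
        assert traj.percent_p.max() == 0.0

    def test_kaib_null_saturates_high_without_oscillation(self):
        """No KaiB: %P rises to a high plateau and stays there."""
        traj = run_simulation(ModelParams(n_hexamers=1000, b_uM=0.0), 100.0, seed=4)
        late = traj.percent_p[traj.time_h > 50]
        assert late.min() > 80.0
        assert late.max() - late.min() < 5.0

    def test_default_conditions_oscillate(self):
        """Standard ratio 1.33, +PDDA: at least 4 peaks in 120 h."""
        from scipy.signal import find_peaks

        traj = run_simulation(ModelParams(), 120.0, seed=1)
        sm = np.convolve(traj.percent_p, np.ones(21) / 21, mode="same")
        peaks, _ = find_peaks(sm, prominence=10)
        assert len(peaks) >= 4

    def test_single_hexamer_completion_time_matches_analytic(self):
        """1 hexamer, saturating KaiA, no dephospho: mean time to all-pS/pT
        equals the expectation of the slowest of six 2-stage protomers."""
        k = 1.0
        cdf = lambda t: 1 - np.exp(-k * t) * (1 + k * t)
        oracle = quad(lambda t: 1 - cdf(t) ** 6, 0, 80)[0]
        p = ModelParams(n_hexamers=1, kphos=k, kdephos=0.0, b_uM=0.0,
                        a2_ratio=500.0, kd_scale=1e-5, bound_back_reaction=False)
        times = []
        for seed in range(150):
            traj = run_simulation(p, 30.0, record_every_h=0.05, seed=seed)
            idx = np.where(traj.form_fractions[:, 2] >= 1.0)[0]
            times.append(traj.time_h[idx[0]] if len(idx) else 30.0)
        times = np.array(times)
        se = times.std(ddof=1) / np.sqrt(len(times))
        assert abs(times.mean() - oracle) < 3 * se

    def test_pdda_raises_pst_fraction_in_kaib_free_reaction(self):
        """+PDDA increases the steady pS/T site fraction versus -PDDA."""
        fracs = {}
        for pdda in (True, False):
            p = ModelParams(b_uM=0.0, pdda_enabled=pdda, n_hexamers=2000)
            traj = run_simulation(p, 60.0, seed=1)
            tail = traj.form_fractions[traj.time_h > 40]
            fracs[pdda] = tail[:, 3].mean()
        assert fracs[True] > fracs[False]


class TestKaiAProtocol:
    def test_step_protocol_values(self):
        c6 = 0.58
        prot = kaia_protocol("step", before_uM=1.33 * c6, after_uM=3.0 * c6,
                             step_hour=27.0)
        assert prot(26.9) == pytest.approx(1.33 * c6)
        assert prot(27.1) == pytest.approx(3.0 * c6)

    def test_constant_is_flat(self):
        prot = kaia_protocol("constant", a2_uM=0.77)
        t = np.linspace(0, 100, 50)
        assert np.allclose(prot(t), 0.77)

    def test_random_walk_reproducible(self):
        kw = dict(lo_uM=0.3, hi_uM=1.5, resample_interval_h=6.0,
                  duration_h=100.0, seed=9)
        a = kaia_protocol("random_walk", **kw)
        b = kaia_protocol("random_walk", **kw)
        t = np.linspace(0, 100, 200)
        assert np.array_equal(a(t), b(t))
        assert (a(t) >= 0.3).all() and (a(t) <= 1.5).all()

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            kaia_protocol("constant", a2_uM=-1.0)
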