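import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy import stats

from grsvd import _kernels
from grsvd.dmd import (
    NonConvergenceError, InitializationError, PairEvent, ReferenceEngine,
    Simulation, SimulationConfig, SystemState, box_length, init_fcc,
    init_velocities, initial_state, measure_pressure, predict_pair_event,
    resolve_event, run_equilibration, run_production,
)
from grsvd.potentials import make_spec


def min_image_dists(pos, L):
    """Brute-force minimum-image pair distances."""
    n = len(pos)
    d = []
    for i in range(n):
        delta = pos[i + 1:] - pos[i]
        delta -= L * np.round(delta / L)
        d.append(np.sqrt((delta ** 2).sum(axis=1)))
    return np.concatenate(d) if d else np.array([])


class TestBoxLength:
    def test_unit_density(self):
        # phi = pi/6 corresponds to rho = 1, so one particle needs L = 1
        assert box_length(1, math.pi / 6) == pytest.approx(1.0, abs=1e-12)

    def test_eighth_density(self):
        assert box_length(8, math.pi / 48) == pytest.approx(4.0, abs=1e-12)

    def test_closed_form(self):
        L = box_length(4096, 0.46)
        assert L == pytest.approx((4096 * math.pi / (6 * 0.46)) ** (1 / 3), rel=1e-12)
        assert L == pytest.approx(16.70, abs=0.01)

    def test_phi_out_of_range(self):
        with pytest.raises(ValueError):
            box_length(100, 0.8)
        with pytest.raises(ValueError):
            box_length(100, 0.0)


class TestInitFCC:
    def test_no_overlap_at_moderate_density(self):
        L = box_length(500, 0.46)
        pos = init_fcc(500, L, rng=3)
        assert min_image_dists(pos, L).min() >= 1.0

    def test_minimal_cell(self):
        # 4 sites in one conventional cell; nearest-neighbour = a/sqrt(2)
        L = 2.0 * math.sqrt(2.0)
        pos = init_fcc(4, L, rng=0)
        assert pos.shape == (4, 3)
        assert min_image_dists(pos, L).min() == pytest.approx(L / math.sqrt(2), rel=1e-12)

    def test_too_dense_rejected(self):
        with pytest.raises(InitializationError):
            init_fcc(4096, box_length(4096, 0.70), rng=0)


class TestInitVelocities:
    def test_momentum_and_energy_exact(self):
        v = init_velocities(100, rng=0)
        assert np.abs(v.sum(axis=0)).max() < 1e-12
        assert 0.5 * np.sum(v ** 2) / 100 == pytest.approx(1.5, abs=1e-12)

    def test_maxwell_speed_distribution(self):
        v = init_velocities(10_000, rng=1)
        speeds = np.linalg.norm(v, axis=1)
        # Maxwell speed distribution with scale sqrt(kT/m) = 1
        _, p = stats.kstest(speeds, stats.maxwell.cdf)
        assert p > 0.01

    def test_needs_two_particles(self):
        with pytest.raises(ValueError):
            init_velocities(1)


class TestPredictPairEvent:
    def test_head_on_core_collision(self, two_particle_state, hs_spec):
        ev = predict_pair_event(two_particle_state, 0, 1, hs_spec)
        assert ev.kind == "core_collision"
        assert ev.time == pytest.approx(2.0, abs=1e-12)

    def test_receding_pair_has_no_event(self, two_particle_state, hs_spec):
        two_particle_state.velocities *= -1.0
        assert predict_pair_event(two_particle_state, 0, 1, hs_spec) is None

    def test_large_impact_parameter_misses(self, hs_spec):
        state = SystemState(
            2, 20.0,
            np.array([[2.0, 5.0, 5.0], [8.0, 6.2, 5.0]]),  # offset 1.2 sigma
            np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 0.0]]))
        assert predict_pair_event(state, 0, 1, hs_spec) is None
        # fine-step oracle: the pair never approaches below sigma
        best = math.inf
        for t in np.linspace(0.0, 12.0, 20001):
            d = np.linalg.norm(np.array([2.0 + t, 5.0, 5.0])
                               - np.array([8.0, 6.2, 5.0]))
            best = min(best, d)
        assert best > 1.0

    def test_shell_entry_time_matches_trajectory_oracle(self, sw_spec):
        state = SystemState(
            2, 20.0,
            np.array([[2.0, 5.0, 5.0], [4.0, 5.3, 5.0]]),
            np.array([[0.7, 0.1, 0.0], [-0.3, 0.0, 0.0]]))
        ev = predict_pair_event(state, 0, 1, sw_spec)
        assert ev.kind == "shell_cross_in"
        assert ev.boundary == pytest.approx(1.25)
        # bisect the crossing of r(t) = 1.25 on the straight-line trajectory
        def sep(t):
            p0 = state.positions[0] + state.velocities[0] * t
            p1 = state.positions[1] + state.velocities[1] * t
            return np.linalg.norm(p0 - p1) - 1.25
        lo, hi = 0.0, 2.0   # closest approach is near t ~ 2
        assert sep(lo) > 0 > sep(hi)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if sep(mid) > 0:
                lo = mid
            else:
                hi = mid
        assert ev.time == pytest.approx(0.5 * (lo + hi), abs=1e-12)

    def test_overlapping_pair_is_corruption(self, hs_spec):
        state = SystemState(
            2, 10.0,
            np.array([[1.0, 1.0, 1.0], [1.5, 1.0, 1.0]]),
            np.zeros((2, 3)))
        from grsvd.dmd import StateCorruptionError
        with pytest.raises(StateCorruptionError):
            predict_pair_event(state, 0, 1, hs_spec)


class TestResolveEvent:
    def _contact_state(self, d, vel):
        pos = np.array([[5.0, 5.0, 5.0], [5.0 + d, 5.0, 5.0]])
        return SystemState(2, 20.0, pos, np.asarray(vel, dtype=float))

    def test_head_on_collision_exchanges_velocities(self, hs_spec):
        state = self._contact_state(1.0, [[1.0, 0, 0], [-1.0, 0, 0]])
        ev = PairEvent(0.0, (0, 1), 1.0, 0, "core_collision")
        resolve_event(ev, state, hs_spec)
        np.testing.assert_allclose(state.velocities,
                                   [[-1.0, 0, 0], [1.0, 0, 0]], atol=1e-14)

    def test_capture_gains_radial_speed(self, sw_spec):
        # relative radial speed 1 entering a well of depth 1:
        # v_r'^2 = v_r^2 + 4 (reduced mass 1/2)
        state = self._contact_state(1.25, [[0.5, 0, 0], [-0.5, 0, 0]])
        ev = PairEvent(0.0, (0, 1), 1.25, 1, "shell_cross_in")
        resolve_event(ev, state, sw_spec)
        vr = state.velocities[0, 0] - state.velocities[1, 0]
        assert vr ** 2 == pytest.approx(1.0 + 4.0, rel=1e-12)
        # particle 0 sits left of particle 1: positive x-velocity difference
        # means the pair is still closing after capture
        assert vr > 0
        assert state.potential_energy == pytest.approx(-1.0)

    def test_escape_blocked_bounces(self, sw_spec):
        # outward radial speed too small to pay the well depth: bounce
        state = self._contact_state(1.25, [[-0.3, 0, 0], [0.3, 0, 0]])
        ke0 = state.kinetic_energy
        ev = PairEvent(0.0, (0, 1), 1.25, 1, "shell_cross_out")
        resolve_event(ev, state, sw_spec)
        vr = state.velocities[0, 0] - state.velocities[1, 0]
        assert vr == pytest.approx(0.6, rel=1e-12)   # sign flipped
        assert state.kinetic_energy == pytest.approx(ke0, rel=1e-12)

    def test_escape_allowed_loses_radial_speed(self, sw_spec):
        state = self._contact_state(1.25, [[-1.5, 0, 0], [1.5, 0, 0]])
        ev = PairEvent(0.0, (0, 1), 1.25, 1, "shell_cross_out")
        e0 = state.total_energy
        state.potential_energy = -1.0
        resolve_event(ev, state, sw_spec)
        vr = state.velocities[0, 0] - state.velocities[1, 0]
        assert vr ** 2 == pytest.approx(9.0 - 4.0, rel=1e-12)
        assert state.potential_energy == pytest.approx(0.0)

    def test_momentum_conserved(self, sw_spec):
        rng = np.random.default_rng(5)
        state = self._contact_state(1.25, rng.normal(size=(2, 3)))
        p0 = state.total_momentum.copy()
        ev = PairEvent(0.0, (0, 1), 1.25, 1, "shell_cross_in")
        resolve_event(ev, state, sw_spec)
        np.testing.assert_allclose(state.total_momentum, p0, atol=1e-14)


class TestPressure:
    def test_no_events_gives_ideal_gas(self, hs_spec):
        state = SystemState(2, 10.0, np.array([[1.0, 1, 1], [5.0, 5, 5]]),
                            np.zeros((2, 3)))
        rho = 2 / 1000.0
        assert measure_pressure(0.0, state, 1.0, kT=1.0) == pytest.approx(rho)

    def test_zero_window_rejected(self, two_particle_state):
        with pytest.raises(ValueError):
            measure_pressure(0.0, two_particle_state, 0.0)

    def test_carnahan_starling_at_phi_030(self, hs_spec, warm_kernel):
        phi = 0.30
        config = SimulationConfig(phi=phi, N=512, seed=7, snapshot_count=1)
        state = initial_state(hs_spec, config)
        run_equilibration(state, hs_spec, config)
        sim = Simulation(state, hs_spec)
        out = sim.advance(60.0)
        P = measure_pressure(out["virial"], state, 60.0)
        rho = 512 / state.box_length ** 3
        Z = P / rho
        Z_cs = (1 + phi + phi ** 2 - phi ** 3) / (1 - phi) ** 3
        assert Z == pytest.approx(Z_cs, rel=0.02)


class TestConservation:
    def test_sw_energy_and_momentum(self, sw_spec, warm_kernel):
        config = SimulationConfig(phi=0.3, N=256, seed=2)
        state = initial_state(sw_spec, config)
        sim = Simulation(state, sw_spec)
        state.potential_energy = sim.recompute_potential_energy()
        e0, p0 = state.total_energy, state.total_momentum.copy()
        out = sim.advance(40.0)
        assert out["n_events"] > 10_000
        assert abs(state.total_energy - e0) / abs(e0) < 1e-8
        assert np.abs(state.total_momentum - p0).max() < 1e-9
        # the running potential-energy ledger agrees with a recount of
        # shell occupancy from the final positions
        assert state.potential_energy == pytest.approx(
            sim.recompute_potential_energy(), abs=1e-9)

    def test_hs_kinetic_energy_constant(self, hs_spec, warm_kernel):
        config = SimulationConfig(phi=0.2, N=64, seed=4)
        state = initial_state(hs_spec, config)
        sim = Simulation(state, hs_spec)
        ke0 = state.kinetic_energy
        sim.advance(20.0)
        assert state.kinetic_energy == pytest.approx(ke0, rel=1e-10)

    def test_no_core_overlap_at_snapshots(self, sw_spec, warm_kernel):
        config = SimulationConfig(phi=0.35, N=128, seed=9, snapshot_count=25,
                                  snapshot_interval=0.4)
        state = initial_state(sw_spec, config)
        prod = run_production(state, sw_spec, config)
        assert prod.snapshots.shape == (25, 128, 3)
        for snap in prod.snapshots:
            assert min_image_dists(snap, state.box_length).min() >= 1.0 - 1e-9


class TestSchedules:
    def test_production_snapshot_times(self, hs_spec, warm_kernel):
        config = SimulationConfig(phi=0.2, N=64, seed=1, snapshot_count=10,
                                  snapshot_interval=0.5)
        state = initial_state(hs_spec, config)
        prod = run_production(state, hs_spec, config)
        assert len(prod.snapshots) == 10
        assert np.all(np.diff(prod.snapshot_times) > 0)
        np.testing.assert_allclose(np.diff(prod.snapshot_times), 0.5)

    def test_equilibration_tiny_event_budget_raises(self, hs_spec, warm_kernel):
        config = SimulationConfig(phi=0.3, N=64, seed=1, max_events=50)
        state = initial_state(hs_spec, config)
        with pytest.raises(NonConvergenceError):
            run_equilibration(state, hs_spec, config)

    def test_hs_equilibration_reaches_cs_pressure(self, hs_spec, warm_kernel):
        phi = 0.05
        config = SimulationConfig(phi=phi, N=256, seed=3, snapshot_count=1)
        state = initial_state(hs_spec, config)
        run_equilibration(state, hs_spec, config)
        sim = Simulation(state, hs_spec)
        out = sim.advance(80.0)
        Z = measure_pressure(out["virial"], state, 80.0) \
            / (256 / state.box_length ** 3)
        Z_cs = (1 + phi + phi ** 2 - phi ** 3) / (1 - phi) ** 3
        assert Z == pytest.approx(Z_cs, rel=0.05)


class TestCollisionRate:
    def test_enskog_rate(self, hs_spec, warm_kernel):
        """HS collision rate at equilibrium vs the Enskog estimate
        nu = 4 rho g(sigma) sigma^2 sqrt(pi kT / m) per particle."""
        phi = 0.2
        config = SimulationConfig(phi=phi, N=256, seed=6, snapshot_count=1)
        state = initial_state(hs_spec, config)
        run_equilibration(state, hs_spec, config)
        sim = Simulation(state, hs_spec)
        t_span = 40.0
        out = sim.advance(t_span)
        rate = 2.0 * out["n_core"] / (256 * t_span)
        rho = 256 / state.box_length ** 3
        g_contact = (1 - phi / 2) / (1 - phi) ** 3        # Carnahan-Starling
        nu = 4.0 * rho * g_contact * math.sqrt(math.pi)
        assert rate == pytest.approx(nu, rel=0.10)


class TestEngineOracle:
    """Event-by-event validation of the optimised (slots + cell lists)
    engine against brute-force all-pairs search.

    Hard-sphere dynamics is chaotic: any two implementations whose
    floating-point operations differ at the last bit diverge exponentially,
    so exact agreement over arbitrarily long runs is not a meaningful test.
    Two complementary checks instead: (a) the event sequence and times match
    the independent pure-Python oracle exactly (1e-9) over a horizon short
    enough that roundoff has not been amplified; (b) over thousands of
    events, a brute-force all-pairs scan at every single event confirms no
    pair ever has a distance inconsistent with its tracked potential region
    -- which is exactly what a missed or misordered event would produce.
    """

    @pytest.mark.parametrize("kind,params,phi,horizon", [
        ("hs", {}, 0.25, 250),
        ("sw", {"lam": 1.25, "eps": 1.0}, 0.20, 400),
    ])
    def test_sequence_matches_brute_force(self, kind, params, phi, horizon,
                                          warm_kernel):
        spec = make_spec(kind, params)
        config = SimulationConfig(phi=phi, N=24, seed=12)
        state = initial_state(spec, config)
        ref = ReferenceEngine(state, spec)
        log_ref = ref.run(horizon)
        assert len(log_ref) == horizon
        opt_state = state.copy()
        sim = Simulation(opt_state, spec)
        out = sim.advance(ref.state.time + 1e-6, max_events=10 ** 6,
                          log_events=10_000)
        log_opt = out["events"][:horizon]
        assert [(e.pair, e.kind, e.boundary_index) for e in log_opt] == \
               [(e.pair, e.kind, e.boundary_index) for e in log_ref]
        times_ref = np.array([e.time for e in log_ref])
        times_opt = np.array([e.time for e in log_opt])
        np.testing.assert_allclose(times_opt, times_ref, rtol=0, atol=1e-9)

    @pytest.mark.parametrize("kind,params,phi", [
        ("hs", {}, 0.25),
        ("sw", {"lam": 1.25, "eps": 1.0}, 0.20),
    ])
    def test_no_scheduling_violations_long_run(self, kind, params, phi,
                                               warm_kernel):
        spec = make_spec(kind, params)
        config = SimulationConfig(phi=phi, N=32, seed=3)
        state = initial_state(spec, config)
        sim = Simulation(state, spec)
        out = sim.advance(1000.0, max_events=3000, verify=True)
        assert out["n_events"] >= 1000
        assert out["n_violations"] == 0
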