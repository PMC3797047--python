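"""Event-driven molecular dynamics for stepwise pair potentials.

Hard-sphere and square-well dynamics are advanced exactly from event to
event: core collisions reverse the radial relative velocity, shell-boundary
crossings exchange kinetic and potential energy (capture/escape) or bounce
when the radial kinetic energy cannot pay the potential step.  The optimised
engine (:class:`Simulation`) uses per-particle event slots refreshed by
cell-boundary crossings; :class:`ReferenceEngine` is an independent
brute-force all-pairs implementation used as a correctness oracle.

Reduced units throughout: sigma = m = kT = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .potentials import PotentialSpec

__all__ = [
    "SimulationConfig", "SystemState", "PairEvent",
    "box_length", "init_fcc", "init_velocities", "initial_state",
    "predict_pair_event", "resolve_event", "measure_pressure",
    "run_equilibration", "run_production", "Simulation", "ReferenceEngine",
    "InitializationError", "NonConvergenceError", "StateCorruptionError",
]

EVENT_NAMES = {1: "core_collision", 2: "shell_cross_in", 3: "shell_cross_out"}

CLOSE_PACKING = math.pi / (3.0 * math.sqrt(2.0))  # ~0.7405


class InitializationError(ValueError):
    pass


class NonConvergenceError(RuntimeError):
    pass


class StateCorruptionError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Schedule and bookkeeping knobs for one simulation state point."""

    phi: float
    N: int
    seed: int = 0
    snapshot_count: int = 100
    snapshot_interval: float = 0.25
    production_time: float | None = None
    equil_window: float = 1.0
    equil_windows: int = 5          # consecutive steady windows required
    equil_tol: float = 1e-2         # relative spread of window pressures
    max_equil_windows: int = 400
    min_window_events: int = 1000   # windows grow until they hold this many
    thermostat: str = "rescale"     # "rescale" | "andersen" | "none"
    andersen_fraction: float = 0.1
    max_events: int = 500_000_000

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < CLOSE_PACKING:
            raise ValueError(
                f"packing fraction must lie in (0, {CLOSE_PACKING:.4f}); got {self.phi}")
        if self.snapshot_count < 1:
            raise ValueError("snapshot_count must be >= 1")


@dataclass
class SystemState:
    """Particle positions/velocities in a cubic periodic box."""

    N: int
    box_length: float
    positions: np.ndarray      # (N, 3), wrapped into [0, L)
    velocities: np.ndarray     # (N, 3)
    time: float = 0.0
    potential_energy: float = 0.0

    @property
    def kinetic_energy(self) -> float:
        return 0.5 * float(np.sum(self.velocities ** 2))

    @property
    def total_energy(self) -> float:
        return self.kinetic_energy + self.potential_energy

    @property
    def total_momentum(self) -> np.ndarray:
        return self.velocities.sum(axis=0)

    def copy(self) -> "SystemState":
        return SystemState(self.N, self.box_length, self.positions.copy(),
                           self.velocities.copy(), self.time,
                           self.potential_energy)


@dataclass(frozen=True)
class PairEvent:
    time: float
    pair: tuple[int, int]
    boundary: float            # radius of the crossed discontinuity
    boundary_index: int        # index into spec.boundaries
    kind: str                  # core_collision | shell_cross_in | shell_cross_out


def box_length(N: int, phi: float, sigma: float = 1.0) -> float:
    """Edge of the cubic box with N spheres at packing fraction phi.

    phi = rho * pi * sigma^3 / 6 with rho = N / L^3, so
    L = (N pi sigma^3 / (6 phi))^(1/3).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0.0 < phi < CLOSE_PACKING:
        raise ValueError(f"phi must lie in (0, {CLOSE_PACKING:.4f})")
    return (N * math.pi * sigma ** 3 / (6.0 * phi)) ** (1.0 / 3.0)


def init_fcc(N: int, L: float, sigma: float = 1.0,
             rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Place N particles on randomly chosen sites of an FCC lattice.

    The number of conventional cells per side is the smallest that provides
    at least N sites; placement order is randomised.  Raises
    :class:`InitializationError` if nearest-neighbour sites would overlap.
    """
    rng = np.random.default_rng(rng)
    nc = max(1, math.ceil((N / 4.0) ** (1.0 / 3.0)))
    while 4 * nc ** 3 < N:
        nc += 1
    a = L / nc
    nn_dist = a / math.sqrt(2.0)
    if nn_dist < sigma:
        raise InitializationError(
            f"FCC nearest-neighbour distance {nn_dist:.4f} < sigma: "
            "packing fraction too high for lattice initialisation")
    base = np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.0],
                     [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]])
    cells = np.stack(np.meshgrid(np.arange(nc), np.arange(nc), np.arange(nc),
                                 indexing="ij"), axis=-1).reshape(-1, 3)
    sites = (cells[:, None, :] + base[None, :, :]).reshape(-1, 3) * a
    chosen = rng.choice(len(sites), size=N, replace=False)
    return np.ascontiguousarray(sites[chosen] % L)


def init_velocities(N: int, kT: float = 1.0,
                    rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Maxwell-Boltzmann velocities, zero total momentum, KE/N = 3kT/2 exactly."""
    if N < 2:
        raise ValueError("need at least 2 particles")
    rng = np.random.default_rng(rng)
    v = rng.normal(0.0, math.sqrt(kT), size=(N, 3))
    v -= v.mean(axis=0)
    ke = 0.5 * np.sum(v ** 2)
    v *= math.sqrt(1.5 * N * kT / ke)
    return v


def initial_state(spec: PotentialSpec, config: SimulationConfig,
                  rng: np.random.Generator | None = None) -> SystemState:
    """FCC positions + Maxwell velocities for the configured state point."""
    if rng is None:
        seq = np.random.SeedSequence(config.seed)
    else:
        seq = np.random.SeedSequence(int(rng.integers(2 ** 31)))
    pos_rng, vel_rng = (np.random.default_rng(s) for s in seq.spawn(2))
    L = box_length(config.N, config.phi, spec.sigma)
    pos = init_fcc(config.N, L, spec.sigma, pos_rng)
    vel = init_velocities(config.N, spec.thermal_energy, vel_rng)
    state = SystemState(config.N, L, pos, vel)
    sim = Simulation(state, spec)           # computes shell occupancy / PE
    state.potential_energy = sim.recompute_potential_energy()
    return state


# ---------------------------------------------------------------------------
# single-pair mechanics (public API, shared with the reference engine)
# ---------------------------------------------------------------------------

def _min_image_vec(d: np.ndarray, L: float) -> np.ndarray:
    return d - L * np.round(d / L)


def _pair_region_of(r: float, boundaries: np.ndarray) -> int:
    """Region index: 0 between core and first shell edge, last = outside."""
    for s in range(len(boundaries) - 1):
        if r < boundaries[s + 1]:
            return s
    return len(boundaries) - 1


def predict_pair_event(state: SystemState, i: int, j: int,
                       spec: PotentialSpec,
                       region: int | None = None) -> PairEvent | None:
    """Earliest boundary crossing of pair (i, j) on free-flight trajectories.

    Uses the minimum-image displacement at the current time; ``region`` may
    pin the pair's current potential region explicitly (needed immediately
    after an event when the pair sits exactly on a boundary).
    """
    db = spec.boundaries
    dr = _min_image_vec(state.positions[i] - state.positions[j],
                        state.box_length)
    dv = state.velocities[i] - state.velocities[j]
    r = float(np.linalg.norm(dr))
    if region is None:
        if r < spec.sigma * (1.0 - 1e-9):
            raise StateCorruptionError(f"pair ({i},{j}) overlaps: r={r:.6f}")
        region = _pair_region_of(r, db)
    dt, bidx, inward = _kernels._pair_candidate(
        dr[0], dr[1], dr[2], dv[0], dv[1], dv[2], region, db, len(db))
    if dt < 0.0:
        return None
    if inward:
        kind = "core_collision" if bidx == 0 else "shell_cross_in"
    else:
        kind = "shell_cross_out"
    return PairEvent(state.time + dt, (i, j), float(db[bidx]), int(bidx), kind)


def resolve_event(event: PairEvent, state: SystemState,
                  spec: PotentialSpec) -> np.ndarray:
    """Apply the collision rule for an event whose pair sits at its boundary.

    Core collision: reverse the radial relative velocity (equal masses
    exchange radial components).  Shell crossings change the radial speed so
    that (mu/2) v_r'^2 = (mu/2) v_r^2 - delta_u with reduced mass mu = 1/2,
    bouncing elastically when the step cannot be paid.  Returns the updated
    (N, 3) velocity array (state is modified in place); the pair's potential
    energy change is applied to ``state.potential_energy``.
    """
    i, j = event.pair
    db = spec.boundaries
    ureg = spec.region_values
    dr = _min_image_vec(state.positions[i] - state.positions[j],
                        state.box_length)
    d = float(np.linalg.norm(dr))
    if abs(d - event.boundary) > 1e-6 * event.boundary:
        raise StateCorruptionError(
            f"pair ({i},{j}) at r={d:.8f}, expected boundary {event.boundary:.8f}")
    n = dr / d
    vr = float((state.velocities[i] - state.velocities[j]) @ n)
    bidx = event.boundary_index
    if event.kind == "core_collision":
        dv = -vr
    elif event.kind == "shell_cross_in":
        du = float(ureg[bidx - 1] - ureg[bidx])
        if vr * vr > 4.0 * du:
            dv = 0.5 * (-math.sqrt(vr * vr - 4.0 * du) - vr)
            state.potential_energy += du
        else:
            dv = -vr
    elif event.kind == "shell_cross_out":
        du = float(ureg[bidx] - ureg[bidx - 1])
        if vr * vr > 4.0 * du:
            dv = 0.5 * (math.sqrt(vr * vr - 4.0 * du) - vr)
            state.potential_energy += du
        else:
            dv = -vr
    else:
        raise ValueError(f"unknown event kind {event.kind!r}")
    state.velocities[i] += dv * n
    state.velocities[j] -= dv * n
    return state.velocities


def measure_pressure(virial: float, state: SystemState, elapsed: float,
                     kT: float | None = None) -> float:
    """Virial pressure P = rho kT + (1/(3 V dt)) sum_events m dv_i . r_ij."""
    if elapsed <= 0.0:
        raise ValueError("elapsed time must be positive")
    V = state.box_length ** 3
    rho = state.N / V
    if kT is None:
        kT = 2.0 * state.kinetic_energy / (3.0 * state.N)
    return rho * kT + virial / (3.0 * V * elapsed)


# ---------------------------------------------------------------------------
# optimised engine
# ---------------------------------------------------------------------------

class Simulation:
    """Driver around the compiled event loop for one (state, potential) pair."""

    def __init__(self, state: SystemState, spec: PotentialSpec,
                 force_brute: bool = False):
        self.state = state
        self.spec = spec
        self.force_brute = force_brute
        self.db = np.ascontiguousarray(spec.boundaries, dtype=np.float64)
        self.ureg = np.ascontiguousarray(spec.region_values, dtype=np.float64)
        self.pair_region = np.empty((state.N, state.N), dtype=np.int8)
        _kernels.init_pair_regions(state.positions, state.box_length,
                                   self.db, self.pair_region)
        mind = _kernels.min_pair_distance(state.positions, state.box_length)
        if mind < spec.sigma * (1.0 - 1e-9):
            raise StateCorruptionError(
                f"initial configuration overlaps: min pair distance {mind:.6f}")

    def recompute_potential_energy(self) -> float:
        return float(_kernels.potential_energy(self.pair_region, self.ureg))

    def advance(self, duration: float, snap_times: np.ndarray | None = None,
                max_events: int = 2 ** 62, log_events: int = 0,
                verify: bool = False) -> dict:
        """Run until ``state.time + duration`` collecting optional snapshots.

        Returns a dict with the virial sum, event counts, snapshots and the
        (possibly truncated) event log.
        """
        st = self.state
        if snap_times is None:
            snap_times = np.empty(0, dtype=np.float64)
        snaps = np.empty((len(snap_times), st.N, 3), dtype=np.float64)
        cap = int(log_events)
        log_t = np.empty(cap, dtype=np.float64)
        log_i = np.empty(cap, dtype=np.int64)
        log_j = np.empty(cap, dtype=np.int64)
        log_kind = np.empty(cap, dtype=np.int64)
        log_b = np.empty(cap, dtype=np.int64)
        status, t, n_events, n_core, virial, dpe, n_snap, n_log, n_viol = \
            _kernels.run_kernel(
                st.positions, st.velocities, st.box_length, self.db,
                self.ureg, self.pair_region, st.time, st.time + duration,
                max_events, np.asarray(snap_times, dtype=np.float64), snaps,
                cap, log_t, log_i, log_j, log_kind, log_b, self.force_brute,
                verify)
        st.time = t
        st.potential_energy += dpe
        events = [
            PairEvent(log_t[k], (int(log_i[k]), int(log_j[k])),
                      float(self.db[log_b[k]]), int(log_b[k]),
                      EVENT_NAMES[int(log_kind[k])])
            for k in range(n_log)
        ]
        return {
            "status": status,
            "n_events": int(n_events),
            "n_violations": int(n_viol),
            "n_core": int(n_core),
            "virial": float(virial),
            "snapshots": snaps[:n_snap],
            "snapshot_times": np.asarray(snap_times)[:n_snap],
            "events": events,
        }

    def rescale_velocities(self, kT: float = 1.0) -> None:
        v = self.state.velocities
        v -= v.mean(axis=0)
        ke = 0.5 * np.sum(v ** 2)
        if ke > 0:
            v *= math.sqrt(1.5 * self.state.N * kT / ke)

    def andersen_kick(self, rng: np.random.Generator, fraction: float,
                      kT: float = 1.0) -> None:
        n = self.state.N
        mask = rng.random(n) < fraction
        if mask.any():
            self.state.velocities[mask] = rng.normal(
                0.0, math.sqrt(kT), size=(int(mask.sum()), 3))


def run_equilibration(state: SystemState, spec: PotentialSpec,
                      config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> SystemState:
    """Two-phase equilibration to a steady pressure.

    Phase 1 switches the attractive shells off (pure hard spheres) to
    decorrelate the lattice start; phase 2 restores the potential.  Each
    phase ends once the last ``equil_windows`` window-averaged pressures have
    relative spread below ``equil_tol``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    hs = PotentialSpec(sigma=spec.sigma)
    phases = [hs] if spec.n_shells == 0 else [hs, spec]
    for phase_idx, phase_spec in enumerate(phases):
        sim = Simulation(state, phase_spec)
        state.potential_energy = sim.recompute_potential_energy()
        window = config.equil_window
        pressures: list[float] = []
        window_events: list[int] = []
        events_used = 0
        for w in range(config.max_equil_windows):
            out = sim.advance(window, max_events=config.max_events - events_used)
            events_used += out["n_events"]
            if out["status"] == _kernels.MAX_EVENTS:
                raise NonConvergenceError(
                    f"equilibration phase {phase_idx + 1}: max_events "
                    f"({config.max_events}) exceeded after {w + 1} windows")
            if config.thermostat == "rescale":
                sim.rescale_velocities(phase_spec.thermal_energy)
            elif config.thermostat == "andersen":
                sim.andersen_kick(rng, config.andersen_fraction,
                                  phase_spec.thermal_energy)
            if out["n_events"] < config.min_window_events and window < 64 * config.equil_window:
                window *= 2.0
                pressures.clear()
                window_events.clear()
                continue
            pressures.append(measure_pressure(out["virial"], state, window))
            window_events.append(out["n_events"])
            tail = pressures[-config.equil_windows:]
            if len(tail) == config.equil_windows and events_used >= 10 * state.N:
                mean_p = abs(np.mean(tail))
                spread = (max(tail) - min(tail)) / max(mean_p, 1e-12)
                # counting-noise floor of a window: the virial part of P
                # fluctuates by ~1/sqrt(events); spreads below a few times
                # that are indistinguishable from steady state
                rho_kT = state.N / state.box_length ** 3 \
                    * 2.0 * state.kinetic_energy / (3.0 * state.N)
                vir_frac = abs(np.mean(tail) - rho_kT) / max(mean_p, 1e-12)
                n_ev = max(int(np.mean(window_events[-config.equil_windows:])), 1)
                noise_floor = 6.0 * vir_frac / math.sqrt(n_ev)
                if spread < max(config.equil_tol, noise_floor):
                    break
        else:
            raise NonConvergenceError(
                f"equilibration phase {phase_idx + 1}: pressure not steady "
                f"after {config.max_equil_windows} windows")
    return state


@dataclass
class ProductionResult:
    snapshots: np.ndarray       # (n_snap, N, 3)
    snapshot_times: np.ndarray
    n_events: int
    n_core: int
    virial: float
    pressure: float
    elapsed: float
    energy_drift: float         # relative drift of KE + PE over the run


def run_production(state: SystemState, spec: PotentialSpec,
                   config: SimulationConfig) -> ProductionResult:
    """NVE production run collecting ``snapshot_count`` equally spaced frames."""
    sim = Simulation(state, spec)
    state.potential_energy = sim.recompute_potential_energy()
    total = (config.production_time if config.production_time is not None
             else config.snapshot_count * config.snapshot_interval)
    interval = total / config.snapshot_count
    snap_times = state.time + interval * np.arange(1, config.snapshot_count + 1)
    e0 = state.total_energy
    out = sim.advance(total, snap_times=snap_times,
                      max_events=config.max_events)
    if out["status"] == _kernels.MAX_EVENTS:
        raise NonConvergenceError(
            f"production: max_events ({config.max_events}) exceeded with "
            f"{len(out['snapshots'])}/{config.snapshot_count} snapshots taken")
    e1 = state.total_energy
    drift = abs(e1 - e0) / max(abs(e0), 1e-12)
    pressure = measure_pressure(out["virial"], state, total)
    return ProductionResult(out["snapshots"], out["snapshot_times"],
                            out["n_events"], out["n_core"], out["virial"],
                            pressure, total, drift)


# ---------------------------------------------------------------------------
# brute-force reference engine (correctness oracle)
# ---------------------------------------------------------------------------

class ReferenceEngine:
    """All-pairs next-event search with no queue and no cell lists.

    Every step recomputes each pair's earliest boundary crossing from the
    current minimum-image displacement, processes the globally earliest one
    (ties broken by particle indices) and repeats.  O(N^2) per event - usable
    only for small N, which is exactly its role: an independent oracle for
    the optimised engine.
    """

    def __init__(self, state: SystemState, spec: PotentialSpec):
        self.state = state.copy()
        self.spec = spec
        self.db = spec.boundaries
        self.ureg = spec.region_values
        N = state.N
        self.region = np.empty((N, N), dtype=np.int8)
        _kernels.init_pair_regions(self.state.positions, state.box_length,
                                   self.db, self.region)

    def _next_event(self) -> PairEvent | None:
        best: PairEvent | None = None
        st = self.state
        for i in range(st.N):
            for j in range(i + 1, st.N):
                ev = predict_pair_event(st, i, j, self.spec,
                                        region=int(self.region[i, j]))
                if ev is None:
                    continue
                if best is None or (ev.time, ev.pair) < (best.time, best.pair):
                    best = ev
        return best

    def run(self, n_events: int, t_max: float = math.inf) -> list[PairEvent]:
        """Process up to n_events events (or until t_max); returns the log."""
        st = self.state
        log: list[PairEvent] = []
        for _ in range(n_events):
            ev = self._next_event()
            if ev is None or ev.time > t_max:
                if math.isfinite(t_max) and t_max > st.time:
                    st.positions += st.velocities * (t_max - st.time)
                    st.positions %= st.box_length
                    st.time = t_max
                break
            dt = ev.time - st.time
            st.positions += st.velocities * dt
            st.positions %= st.box_length
            st.time = ev.time
            i, j = ev.pair
            old_region = int(self.region[i, j])
            resolve_event(ev, st, self.spec)
            self._sync_region(ev, old_region)
            log.append(ev)
        return log

    def _sync_region(self, ev: PairEvent, old_region: int) -> None:
        i, j = ev.pair
        dr = _min_image_vec(self.state.positions[i] - self.state.positions[j],
                            self.state.box_length)
        d = float(np.linalg.norm(dr))
        n = dr / d
        vr = float((self.state.velocities[i] - self.state.velocities[j]) @ n)
        bidx = ev.boundary_index
        if ev.kind == "shell_cross_in" and vr < 0.0:
            new = bidx - 1
        elif ev.kind == "shell_cross_out" and vr > 0.0:
            new = bidx
        else:
            new = old_region
        self.region[i, j] = new
        self.region[j, i] = new
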