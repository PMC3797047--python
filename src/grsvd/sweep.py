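"""Parameter-sweep orchestration: one simulation + RDF per grid point.

A sweep fixes a potential template, varies one or two of (phi, eps, lam)
over uniform grids, and stacks the measured g(r) rows into an
:class:`~grsvd.rdf.RDFMatrix`.  Per-point seeds are a pure function of the
master seed and the point index, so sweeps are reproducible, resumable and
order-independent.  State points inside the configured single-phase
exclusion region are rejected when the grid is enumerated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .dmd import SimulationConfig, initial_state, run_equilibration, run_production
from .potentials import PotentialSpec, make_spec
from .rdf import RadialGrid, RDFSample, RDFMatrix, build_rdf_matrix, estimate_rdf

__all__ = ["SweepAxis", "SweepSpec", "enumerate_points", "run_sweep",
           "default_exclusion", "desk_preset", "full_scale_preset",
           "HS_FREEZING_PHI"]

HS_FREEZING_PHI = 0.494          # hard-sphere freezing transition
SW_CRITICAL_EPS = 0.821          # 1 / T_c* for a lambda = 1.25 square well


def default_exclusion(theta: dict[str, float]) -> str | None:
    """Conservative single-phase guard; returns a reason or None if allowed.

    Rejects packing fractions beyond the hard-sphere freezing transition and,
    for attractive wells, a rectangular band around the liquid-vapor
    coexistence region of the lambda ~ 1.25 well (attraction stronger than
    the critical inverse temperature at intermediate densities).  The band is
    deliberately generous; users with better coexistence data can supply
    their own rule.
    """
    phi = theta.get("phi", 0.0)
    eps = theta.get("eps", 0.0)
    if phi >= HS_FREEZING_PHI:
        return f"phi={phi:g} at or beyond the freezing transition {HS_FREEZING_PHI}"
    if eps >= SW_CRITICAL_EPS and 0.02 <= phi <= 0.40:
        return (f"(phi={phi:g}, eps={eps:g}) inside the conservative "
                "liquid-vapor coexistence guard")
    return None


@dataclass(frozen=True)
class SweepAxis:
    name: str                    # "phi" | "eps" | "lam"
    lo: float
    hi: float
    k: int

    def __post_init__(self) -> None:
        if self.name not in ("phi", "eps", "lam"):
            raise ValueError(f"unknown sweep parameter {self.name!r}")
        if not self.hi > self.lo:
            raise ValueError("sweep range must be non-degenerate")
        if self.k < 2:
            raise ValueError("need at least 2 points per axis")

    @property
    def points(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.k)


@dataclass(frozen=True)
class SweepSpec:
    """Definition of a full sweep (potential template + axes + schedule)."""

    kind: str                                     # "hs" | "sw" | "double_sw"
    axes: tuple[SweepAxis, ...]
    fixed: dict = field(default_factory=dict)     # e.g. {"eps": 0.5, "lam": 1.25}
    config: SimulationConfig | None = None        # template; phi/seed overridden
    seed: int = 0
    N: int = 256
    grid: RadialGrid | None = None                # default: dr=0.01 up to
                                                  # min(6, L_min/2)
    exclusion: Callable[[dict], str | None] = default_exclusion

    def __post_init__(self) -> None:
        if not 1 <= len(self.axes) <= 2:
            raise ValueError("sweeps support 1 or 2 axes")
        names = [a.name for a in self.axes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sweep axes")
        for a in self.axes:
            if a.name in self.fixed:
                raise ValueError(f"{a.name} both swept and fixed")


def desk_preset(kind: str = "hs", seed: int = 0) -> SweepSpec:
    """Desk-scale sweep: k = 32, N = 256, minutes of runtime."""
    axes = (SweepAxis("phi", 0.05, 0.45, 32),)
    fixed = {} if kind == "hs" else {"eps": 0.5, "lam": 1.25}
    return SweepSpec(kind=kind, axes=axes, fixed=fixed, seed=seed, N=256,
                     config=SimulationConfig(phi=0.3, N=256,
                                             snapshot_count=1200,
                                             snapshot_interval=0.25))


def full_scale_preset(kind: str = "hs", seed: int = 0,
                       N: int = 4096, k: int = 1024) -> SweepSpec:
    """Full-scale sweep: N = 2^12, 10^4 snapshots, k ~ 10^3 points.

    Long-running (days of CPU); k defaults to the order of magnitude a
    full tabulation uses.
    """
    axes = (SweepAxis("phi", 0.05, 0.45, k),)
    fixed = {} if kind == "hs" else {"eps": 0.5, "lam": 1.25}
    return SweepSpec(kind=kind, axes=axes, fixed=fixed, seed=seed, N=N,
                     config=SimulationConfig(phi=0.3, N=N,
                                             snapshot_count=10_000,
                                             snapshot_interval=0.25))


def enumerate_points(spec: SweepSpec,
                     with_rejections: bool = False):
    """Uniform (Cartesian, row-major) grid over the axes, minus exclusions."""
    grids = [a.points for a in spec.axes]
    names = [a.name for a in spec.axes]
    if len(grids) == 1:
        pts = grids[0][:, None]
    else:
        A, B = np.meshgrid(grids[0], grids[1], indexing="ij")
        pts = np.column_stack([A.ravel(), B.ravel()])
    rows, rejected = [], []
    for vec in pts:
        theta = dict(zip(names, (float(v) for v in vec)))
        full = {**spec.fixed, **theta}
        reason = spec.exclusion(full)
        if reason is None:
            rows.append(theta)
        else:
            rejected.append((theta, reason))
    if not rows:
        raise ValueError(
            "sweep is empty after the single-phase exclusion; first reason: "
            + rejected[0][1])
    table = pd.DataFrame(rows)
    if with_rejections:
        return table, rejected
    return table


def point_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Per-point seed: pure function of (master seed, point index)."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def _potential_for(spec: SweepSpec, theta: dict[str, float]) -> PotentialSpec:
    params = {**spec.fixed, **theta}
    params.pop("phi", None)
    if spec.kind == "hs":
        return make_spec("hs", {})
    if spec.kind == "sw":
        return make_spec("sw", {k: v for k, v in params.items()
                                if k in ("lam", "eps", "sigma")})
    if spec.kind == "double_sw":
        return make_spec("double_sw", params)
    raise ValueError(f"unknown potential kind {spec.kind!r}")


def sweep_grid(spec: SweepSpec, table: pd.DataFrame) -> RadialGrid:
    """Radial grid valid for every point: r_max = min(6, L_min/2), dr = 0.01."""
    if spec.grid is not None:
        return spec.grid
    phis = (table["phi"] if "phi" in table.columns
            else pd.Series([spec.fixed["phi"]]))
    phi_max = float(phis.max())
    L_min = (spec.N * math.pi / (6.0 * phi_max)) ** (1.0 / 3.0)
    dr = 0.01
    r_max = min(6.0, math.floor((0.5 * L_min) / dr) * dr)
    return RadialGrid(r_max=r_max, m=round(r_max / dr))


def simulate_point(spec: SweepSpec, theta: dict[str, float], index: int,
                   grid: RadialGrid) -> RDFSample:
    """Equilibrate + produce + histogram one state point."""
    pot = _potential_for(spec, theta)
    full = {**spec.fixed, **theta}
    phi = float(full["phi"])
    seq = point_seed(spec.seed, index)
    child = int(seq.generate_state(1)[0] % (2 ** 31))
    base = spec.config or SimulationConfig(phi=phi, N=spec.N)
    config = replace(base, phi=phi, N=spec.N, seed=child)
    state = initial_state(pot, config)
    run_equilibration(state, pot, config)
    prod = run_production(state, pot, config)
    sample = estimate_rdf(prod.snapshots, state.box_length, grid,
                          theta=theta,
                          provenance={"seed": child, "index": index,
                                      "N": spec.N, "phi": phi,
                                      "potential": pot.to_dict(),
                                      "pressure": prod.pressure,
                                      "n_events": prod.n_events})
    return sample


def run_sweep(spec: SweepSpec, cache_dir: str | Path | None = None,
              progress: bool = False) -> RDFMatrix:
    """Run every sweep point (independent derived seeds) and stack the RDFs.

    With ``cache_dir``, each finished point is persisted and re-used on
    resumption; an interrupted sweep rerun with the same master seed yields
    a bit-identical matrix.
    """
    table = enumerate_points(spec)
    grid = sweep_grid(spec, table)
    samples = []
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    for index, row in table.iterrows():
        theta = {k: float(v) for k, v in row.items()}
        path = (cache / f"point_{index:04d}.npz") if cache is not None else None
        if path is not None and path.exists():
            with np.load(path) as z:
                values = z["values"]
            sample = RDFSample(grid, values, theta, {"cached": True})
        else:
            try:
                sample = simulate_point(spec, theta, int(index), grid)
            except Exception as exc:
                raise RuntimeError(
                    f"sweep point {index} (theta={theta}) failed: {exc}") from exc
            if path is not None:
                np.savez(path, values=sample.values,
                         theta=np.array(sorted(theta.items()), dtype=object))
        if progress:
            print(f"[sweep] point {index + 1}/{len(table)} theta={theta} done")
        samples.append(sample)
    return build_rdf_matrix(samples)
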