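"""Small deterministic objects for tests and demos."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dmd import SimulationConfig, SystemState
from .potentials import make_spec
from .rdf import RadialGrid, RDFMatrix

__all__ = ["make_fixture"]


def make_fixture(kind: str, seed: int = 0):
    """Deterministic test objects keyed by kind.

    two_particle       -- head-on pair with an analytically known first event
    ideal_gas          -- random-point snapshots (no interactions)
    dilute_hs          -- config + spec for a phi = 0.01 hard-sphere mini-run
    rank1_matrix       -- an exactly rank-1 RDFMatrix
    poly_coeff_vectors -- coefficient vectors that are exact polynomials
    """
    rng = np.random.default_rng(seed)
    if kind == "two_particle":
        L = 10.0
        pos = np.array([[2.0, 5.0, 5.0], [6.0, 5.0, 5.0]])
        vel = np.array([[0.5, 0.0, 0.0], [-0.5, 0.0, 0.0]])
        # gap = 4 - sigma = 3 along x at closing speed 1 -> contact at t = 3
        return SystemState(2, L, pos, vel), make_spec("hs"), 3.0
    if kind == "ideal_gas":
        N, L, n_snap = 128, 8.0, 64
        return rng.uniform(0.0, L, size=(n_snap, N, 3)), L
    if kind == "dilute_hs":
        spec = make_spec("hs")
        config = SimulationConfig(phi=0.01, N=128, seed=seed,
                                  snapshot_count=200, snapshot_interval=1.0)
        return spec, config
    if kind == "rank1_matrix":
        grid = RadialGrid(r_max=3.0, m=60)
        k = 6
        a = 1.0 + rng.random(k)
        b = np.abs(np.sin(grid.centers)) + 0.5
        params = pd.DataFrame({"phi": np.linspace(0.1, 0.35, k)})
        return RDFMatrix(grid, params, np.outer(a, b))
    if kind == "poly_coeff_vectors":
        k = 16
        phi = np.linspace(0.05, 0.45, k)
        z = 2.0 * (phi - phi.min()) / (phi.max() - phi.min()) - 1.0
        degrees = [4, 5]
        vecs = [sum(((-0.5) ** p + 0.1 * p) * z ** p for p in range(d + 1))
                for d in degrees]
        return phi, np.column_stack(vecs), degrees
    raise ValueError(f"unknown fixture kind {kind!r}")
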