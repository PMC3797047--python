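"""Radial distribution function estimation and the parameter-sweep matrix.

g(r) is estimated as a pair-distance histogram over snapshots, normalised by
the ideal-gas expectation on the same grid, so that g -> 1 at large
separation.  A sweep of state points stacks its g(r) rows into an
:class:`RDFMatrix` (rows = parameter points, columns = radial bins), the
input to the SVD compression layer.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels

__all__ = ["RadialGrid", "RDFSample", "RDFMatrix", "accumulate_pairs",
           "normalize_histogram", "estimate_rdf", "build_rdf_matrix"]


@dataclass(frozen=True)
class RadialGrid:
    """Uniform bins on (0, r_max] starting at r = 0."""

    r_max: float = 6.0
    m: int = 600

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least 2 bins")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")

    @property
    def dr(self) -> float:
        return self.r_max / self.m

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, self.r_max, self.m + 1)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    def shell_volumes(self) -> np.ndarray:
        e = self.edges
        return (4.0 * np.pi / 3.0) * (e[1:] ** 3 - e[:-1] ** 3)


@dataclass(frozen=True)
class RDFSample:
    """One g(r) curve with the parameter point it was measured at."""

    grid: RadialGrid
    values: np.ndarray
    theta: dict[str, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.m,):
            raise ValueError(f"values shape {v.shape} != ({self.grid.m},)")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("g(r) values must be finite and non-negative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class RDFMatrix:
    """k stacked g(r) curves over an ordered table of parameter points."""

    grid: RadialGrid
    params: pd.DataFrame            # k rows, one column per swept parameter
    values: np.ndarray              # (k, m)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        k = len(self.params)
        if k < 2:
            raise ValueError("need at least 2 parameter points")
        if v.shape != (k, self.grid.m):
            raise ValueError(f"values shape {v.shape} != ({k}, {self.grid.m})")
        if v.shape[1] <= k:
            raise ValueError("need more radial bins than parameter points")
        object.__setattr__(self, "values", v)

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def m(self) -> int:
        return self.grid.m

    # -- tab-separated round trip ------------------------------------------
    def to_tsv(self, path) -> None:
        """First column r bin centers, one column per parameter point.

        The header row carries the parameter values as ``name=value``
        tuples joined by commas; a comment block stores the grid.
        """
        cols = {}
        for idx, row in self.params.iterrows():
            label = ",".join(f"{k}={v:.10g}" for k, v in row.items())
            cols[label] = self.values[self.params.index.get_loc(idx)]
        df = pd.DataFrame({"r": self.grid.centers, **cols})
        with open(path, "w") as fh:
            fh.write(f"# r_max: {self.grid.r_max:.12g}\n# m: {self.grid.m}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RDFMatrix":
        meta = {}
        with open(path) as fh:
            text = fh.read()
        lines = text.splitlines()
        body = []
        for ln in lines:
            if ln.startswith("#"):
                key, _, val = ln[1:].partition(":")
                meta[key.strip()] = val.strip()
            else:
                body.append(ln)
        df = pd.read_csv(io.StringIO("\n".join(body)), sep="\t")
        grid = RadialGrid(float(meta["r_max"]), int(meta["m"]))
        labels = [c for c in df.columns if c != "r"]
        rows = []
        for lab in labels:
            rows.append({kv.split("=")[0]: float(kv.split("=")[1])
                         for kv in lab.split(",")})
        params = pd.DataFrame(rows)
        return cls(grid, params, df[labels].to_numpy().T)


def accumulate_pairs(positions: np.ndarray, L: float,
                     grid: RadialGrid,
                     counts: np.ndarray | None = None) -> np.ndarray:
    """Histogram minimum-image pair distances of one snapshot into grid bins."""
    if grid.r_max > 0.5 * L + 1e-12:
        raise ValueError(
            f"r_max={grid.r_max} exceeds L/2={0.5 * L:.4f}: minimum image invalid")
    if counts is None:
        counts = np.zeros(grid.m, dtype=np.int64)
    _kernels.pair_distance_histogram(
        np.ascontiguousarray(positions, dtype=np.float64), L, grid.r_max, counts)
    return counts


def normalize_histogram(counts: np.ndarray, N: int, L: float,
                        n_snapshots: int, grid: RadialGrid) -> np.ndarray:
    """Convert pair counts into g(r) on the grid.

    g_b = counts_b * V / (n_snap * N(N-1)/2 * V_shell(b)), the ratio of the
    observed pair density to the ideal-gas expectation.
    """
    if n_snapshots < 1:
        raise ValueError("need at least one snapshot")
    V = L ** 3
    npairs = N * (N - 1) / 2.0
    return counts * V / (n_snapshots * npairs * grid.shell_volumes())


def estimate_rdf(snapshots: np.ndarray, L: float, grid: RadialGrid,
                 theta: dict[str, float] | None = None,
                 provenance: dict | None = None) -> RDFSample:
    """Estimate g(r) from a stack of (n_snap, N, 3) position snapshots."""
    snapshots = np.asarray(snapshots, dtype=np.float64)
    n_snap, N, _ = snapshots.shape
    counts = np.zeros(grid.m, dtype=np.int64)
    for s in range(n_snap):
        accumulate_pairs(snapshots[s], L, grid, counts)
    values = normalize_histogram(counts, N, L, n_snap, grid)
    return RDFSample(grid, values, dict(theta or {}), dict(provenance or {}))


def build_rdf_matrix(samples: list[RDFSample]) -> RDFMatrix:
    """Stack samples (in the given sweep order) into an RDFMatrix."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    grid = samples[0].grid
    for s in samples[1:]:
        if s.grid != grid:
            raise ValueError("all samples must share one radial grid")
    thetas = [tuple(sorted(s.theta.items())) for s in samples]
    if len(set(thetas)) != len(thetas):
        raise ValueError("duplicate parameter points in sweep")
    params = pd.DataFrame([s.theta for s in samples])
    values = np.vstack([s.values for s in samples])
    return RDFMatrix(grid, params, values)
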