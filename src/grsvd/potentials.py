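"""Stepwise pair potentials: hard spheres and (multi-shell) square wells.

Everything is in reduced units: the core diameter sigma is the length unit,
particle mass is the mass unit, and kT is the energy unit, so time is measured
in ``sigma * sqrt(m / kT)``.  A potential is a hard core at ``r = sigma``
followed by zero or more constant shells; the pure hard sphere is the
zero-shell limiting case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PotentialSpec", "make_spec", "evaluate_potential"]


@dataclass(frozen=True)
class PotentialSpec:
    """A hard core plus an ordered list of constant-energy shells.

    Parameters
    ----------
    sigma : float
        Core diameter (default 1, the reduced length unit).
    shells : tuple of (float, float)
        Ordered ``(boundary_ratio, depth)`` pairs.  ``boundary_ratio`` is the
        outer edge of the shell in units of sigma (lambda_i > 1, strictly
        increasing); ``depth`` is the potential *value* u(r) inside the shell
        in units of kT (negative = attractive).  The potential is zero beyond
        the last boundary and +inf below sigma.
    thermal_energy : float
        kT; fixed at 1 in reduced units.
    """

    sigma: float = 1.0
    shells: tuple[tuple[float, float], ...] = ()
    thermal_energy: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        last = 1.0
        for lam, _depth in self.shells:
            if lam <= last:
                raise ValueError(
                    "shell boundary ratios must be strictly increasing and > 1; "
                    f"got {[s[0] for s in self.shells]}"
                )
            last = lam

    @property
    def n_shells(self) -> int:
        return len(self.shells)

    @property
    def boundaries(self) -> np.ndarray:
        """Radii of all discontinuities: sigma, then sigma*lambda_i."""
        return self.sigma * np.concatenate(
            ([1.0], [lam for lam, _ in self.shells])
        )

    @property
    def region_values(self) -> np.ndarray:
        """Potential value in each region between consecutive boundaries.

        Region ``s`` spans ``boundaries[s] <= r < boundaries[s+1]`` (the last
        region is unbounded with value 0).  Length is ``n_shells + 1``.
        """
        return np.concatenate(([d for _, d in self.shells], [0.0]))

    @property
    def interaction_range(self) -> float:
        """Outermost discontinuity radius (sigma for pure hard spheres)."""
        return float(self.boundaries[-1])

    def to_dict(self) -> dict:
        return {
            "sigma": self.sigma,
            "shells": [[lam, depth] for lam, depth in self.shells],
            "thermal_energy": self.thermal_energy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PotentialSpec":
        return cls(
            sigma=float(d.get("sigma", 1.0)),
            shells=tuple((float(l), float(u)) for l, u in d.get("shells", [])),
            thermal_energy=float(d.get("thermal_energy", 1.0)),
        )


def make_spec(kind: str, params: dict | None = None) -> PotentialSpec:
    """Build a validated :class:`PotentialSpec` from a short-hand description.

    Parameters
    ----------
    kind : {"hs", "sw", "double_sw"}
        Hard sphere, single square well, or double square well.
    params : dict
        For ``"sw"``: ``lam`` (well width ratio) and ``eps`` (attractive
        strength; the well value is ``-eps``) or an explicit ``depth``.
        For ``"double_sw"``: ``boundaries`` and ``depths`` sequences.
        ``sigma`` is accepted everywhere (default 1).
    """
    params = dict(params or {})
    sigma = float(params.pop("sigma", 1.0))
    if kind == "hs":
        if params:
            raise ValueError(f"unexpected hard-sphere parameters: {sorted(params)}")
        return PotentialSpec(sigma=sigma)
    if kind == "sw":
        lam = float(params.pop("lam", params.pop("lambda", 1.25)))
        if "depth" in params:
            depth = float(params.pop("depth"))
        else:
            depth = -float(params.pop("eps", 1.0))
        if params:
            raise ValueError(f"unexpected square-well parameters: {sorted(params)}")
        return PotentialSpec(sigma=sigma, shells=((lam, depth),))
    if kind == "double_sw":
        bounds = params.pop("boundaries")
        depths = params.pop("depths")
        if params:
            raise ValueError(f"unexpected double-well parameters: {sorted(params)}")
        if len(bounds) != len(depths):
            raise ValueError("boundaries and depths must have equal length")
        return PotentialSpec(
            sigma=sigma,
            shells=tuple((float(l), float(u)) for l, u in zip(bounds, depths)),
        )
    raise ValueError(f"unknown potential kind: {kind!r}")


def evaluate_potential(spec: PotentialSpec, r):
    """Pair potential u(r) in kT units; +inf inside the hard core.

    Accepts a scalar or array ``r`` (all entries must be positive).  Values
    exactly at a discontinuity take the inner-region value (left-closed
    intervals seen from inside): ``u(lambda_i * sigma)`` is the value of
    shell ``i``.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("r must be positive")
    bounds = spec.boundaries
    values = spec.region_values
    # region index = number of boundaries at or below r; searchsorted with
    # side="left" makes r == boundary fall in the inner region.
    idx = np.searchsorted(bounds, r_arr, side="left")
    out = np.where(idx == 0, math.inf, 0.0)
    inner = idx > 0
    out = np.where(inner, values[np.minimum(idx, len(values)) - 1], out)
    # the region value array is indexed by (idx-1) clipped; beyond the last
    # boundary values[-1] == 0 already.
    if r_arr.ndim == 0:
        return float(out)
    return out
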