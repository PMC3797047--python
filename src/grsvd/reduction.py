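"""Low-rank SVD representation of an RDF sweep with polynomial surrogates.

The k x m matrix G of g(r) curves factorises as G = U S V^T.  Columns of V
("basis vectors") are functions of r; columns of U ("coefficient vectors")
are functions of the swept parameters and turn out to be smooth enough to be
replaced by low-order polynomials, the degree growing linearly with the rank
order.  Keeping the leading p triplets plus the fitted polynomials yields a
compact representation that evaluates g(r; theta) at any interpolated theta.

The user-facing surface follows the model/results idiom:
``RDFBasisModel(matrix).fit(rank=...)`` returns an :class:`RDFBasisResults`
carrying the factorisation, surrogate fits, diagnostics and a ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .rdf import RadialGrid, RDFMatrix, RDFSample

__all__ = [
    "SVDModel", "PolySurrogate", "CompactRepresentation",
    "decompose", "truncation_rank", "reconstruct_truncated",
    "fit_coefficient_polynomials", "fit_residual_report", "evaluate_model",
    "RDFBasisModel", "RDFBasisResults", "ExtrapolationError",
]

FORMAT_VERSION = 1


class ExtrapolationError(ValueError):
    """theta lies outside the parameter domain the model was trained on."""


class ModelFormatError(ValueError):
    """Compact-model file is corrupt or has an unsupported format version."""


@dataclass(frozen=True)
class SVDModel:
    """Thin SVD of an RDF matrix with a deterministic sign convention."""

    singular_values: np.ndarray     # (k,), non-increasing
    coefficient_vectors: np.ndarray  # U, (k, k): columns u_n(theta)
    basis_vectors: np.ndarray        # V, (m, k): columns v_n(r), orthonormal
    grid: RadialGrid
    params: pd.DataFrame

    @property
    def k(self) -> int:
        return len(self.singular_values)


def decompose(matrix: RDFMatrix) -> SVDModel:
    """Thin SVD of G with each basis vector's largest entry made positive."""
    G = matrix.values
    if not np.all(np.isfinite(G)):
        raise ValueError("RDF matrix contains non-finite entries")
    U, s, Vt = np.linalg.svd(G, full_matrices=False)
    V = Vt.T
    # sign convention: flip v_n so its largest-magnitude entry is positive
    for n in range(V.shape[1]):
        idx = int(np.argmax(np.abs(V[:, n])))
        if V[idx, n] < 0:
            V[:, n] = -V[:, n]
            U[:, n] = -U[:, n]
    return SVDModel(s, U, V, matrix.grid, matrix.params)


def truncation_rank(singular_values: np.ndarray, delta: float = 1e-6) -> int:
    """Largest p with sigma_p >= delta * sigma_1 (relative threshold)."""
    s = np.asarray(singular_values, dtype=float)
    if np.any(np.diff(s) > 0):
        raise ValueError("singular values must be sorted non-increasing")
    if s[0] <= 0:
        raise ValueError("all-zero singular spectrum")
    return int(np.sum(s >= delta * s[0]))


def reconstruct_truncated(model: SVDModel, p: int) -> np.ndarray:
    """Best rank-p approximation (Eckart-Young) of the original matrix."""
    if not 1 <= p <= model.k:
        raise ValueError(f"rank p={p} out of range [1, {model.k}]")
    U = model.coefficient_vectors[:, :p]
    s = model.singular_values[:p]
    V = model.basis_vectors[:, :p]
    return (U * s) @ V.T


def _scale(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        raise ValueError("degenerate parameter domain")
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def _bivariate_design(z1: np.ndarray, z2: np.ndarray, deg: int) -> tuple[np.ndarray, list]:
    terms = [(i, j) for d in range(deg + 1) for i in range(d + 1)
             for j in [d - i]]
    A = np.column_stack([z1 ** i * z2 ** j for i, j in terms])
    return A, terms


@dataclass(frozen=True)
class PolySurrogate:
    """Per-rank polynomial fits to the coefficient vectors u_n(theta).

    Coefficients are stored in the monomial basis of the *scaled* parameter
    z = 2(x - lo)/(hi - lo) - 1 (each parameter mapped to [-1, 1]), which
    keeps degree ~10 fits well conditioned; the fits themselves are done in
    a Chebyshev basis.  ``monomial_coefficients`` converts a univariate fit
    back to the raw parameter for reporting.
    """

    param_names: tuple[str, ...]
    domains: tuple[tuple[float, float], ...]
    degrees: tuple[int, ...]
    coefficients: tuple[np.ndarray, ...]   # per rank; 1-D (univariate) or
                                           # list-of-terms vector (bivariate)
    terms: tuple[tuple[tuple[int, int], ...], ...] | None  # bivariate only
    residuals_log10: tuple[float, ...]

    @property
    def bivariate(self) -> bool:
        return len(self.param_names) == 2

    def evaluate(self, theta: Sequence[float]) -> np.ndarray:
        """Values of every rank's polynomial at one parameter point."""
        zs = [ _scale(np.asarray(float(t)), lo, hi)
               for t, (lo, hi) in zip(theta, self.domains) ]
        out = np.empty(len(self.coefficients))
        for n, c in enumerate(self.coefficients):
            if self.bivariate:
                val = 0.0
                for (i, j), cc in zip(self.terms[n], c):
                    val += cc * zs[0] ** i * zs[1] ** j
                out[n] = val
            else:
                out[n] = np.polynomial.polynomial.polyval(zs[0], c)
        return out

    def monomial_coefficients(self, n: int) -> np.ndarray:
        """Univariate rank-n fit as monomial coefficients of the raw parameter."""
        if self.bivariate:
            raise ValueError("raw-parameter conversion is univariate only")
        lo, hi = self.domains[0]
        p = np.polynomial.Polynomial(self.coefficients[n],
                                     domain=[lo, hi], window=[-1, 1])
        return p.convert(domain=[lo, hi], window=[lo, hi]).coef

    def to_dict(self) -> dict:
        return {
            "param_names": list(self.param_names),
            "domains": [list(d) for d in self.domains],
            "degrees": list(self.degrees),
            "coefficients": [c.tolist() for c in self.coefficients],
            "terms": ([[list(t) for t in tt] for tt in self.terms]
                      if self.terms is not None else None),
            "residuals_log10": list(self.residuals_log10),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolySurrogate":
        return cls(
            tuple(d["param_names"]),
            tuple(tuple(x) for x in d["domains"]),
            tuple(d["degrees"]),
            tuple(np.asarray(c, dtype=float) for c in d["coefficients"]),
            (tuple(tuple(tuple(t) for t in tt) for tt in d["terms"])
             if d.get("terms") is not None else None),
            tuple(d["residuals_log10"]),
        )


def default_degree_rule(n: int) -> int:
    """Polynomial degree for rank n (1-based): linear growth, offset 3."""
    return n + 3


def fit_coefficient_polynomials(
        model: SVDModel, degree_rule: Callable[[int], int] | None = None,
        p: int | None = None) -> PolySurrogate:
    """Least-squares polynomial fits to u_1..u_p over the parameter grid.

    Univariate sweeps use a Chebyshev basis on the scaled parameter;
    two-parameter sweeps use a total-degree bivariate monomial basis in the
    scaled parameters.  Degrees follow ``degree_rule(n)`` (1-based rank).
    """
    if degree_rule is None:
        degree_rule = default_degree_rule
    if p is None:
        p = model.k
    names = tuple(model.params.columns)
    if len(names) not in (1, 2):
        raise ValueError("surrogates support 1- or 2-parameter sweeps")
    k = model.coefficient_vectors.shape[0]   # number of parameter points
    X = model.params.to_numpy(dtype=float)
    domains = tuple((float(X[:, c].min()), float(X[:, c].max()))
                    for c in range(X.shape[1]))
    Z = np.column_stack([_scale(X[:, c], *domains[c])
                         for c in range(X.shape[1])])
    coeffs, degrees, resids, terms_all = [], [], [], []
    for n in range(1, p + 1):
        deg = int(degree_rule(n))
        u = model.coefficient_vectors[:, n - 1]
        if len(names) == 1:
            if deg >= k:
                raise ValueError(
                    f"degree {deg} >= number of parameter points {k}: ill-posed fit")
            cheb = np.polynomial.chebyshev.chebfit(Z[:, 0], u, deg)
            c = np.polynomial.chebyshev.cheb2poly(cheb)
            fit = np.polynomial.polynomial.polyval(Z[:, 0], c)
            terms_all = None
        else:
            A, terms = _bivariate_design(Z[:, 0], Z[:, 1], deg)
            if A.shape[1] >= k:
                raise ValueError(
                    f"{A.shape[1]} bivariate terms >= {k} points: ill-posed fit")
            c, *_ = np.linalg.lstsq(A, u, rcond=None)
            fit = A @ c
            if terms_all is not None:
                terms_all.append(tuple(terms))
        rms = float(np.sqrt(np.mean((u - fit) ** 2)))
        resids.append(float(np.log10(max(rms, 1e-300))))
        coeffs.append(np.asarray(c, dtype=float))
        degrees.append(deg)
    return PolySurrogate(
        names, domains, tuple(degrees), tuple(coeffs),
        tuple(terms_all) if terms_all is not None else None, tuple(resids))


def fit_residual_report(model: SVDModel, surrogate: PolySurrogate) -> np.ndarray:
    """log10 RMS residual of each rank's polynomial on the training grid."""
    X = model.params.to_numpy(dtype=float)
    out = []
    for n in range(len(surrogate.coefficients)):
        vals = np.array([surrogate.evaluate(x)[n] for x in X])
        u = model.coefficient_vectors[:, n]
        rms = float(np.sqrt(np.mean((u - vals) ** 2)))
        out.append(np.log10(max(rms, 1e-300)))
    return np.asarray(out)


@dataclass(frozen=True)
class CompactRepresentation:
    """The serialisable artifact: singular values + basis vectors +
    polynomial coefficients + parameter domain."""

    grid: RadialGrid
    singular_values: np.ndarray    # (p,)
    basis_vectors: np.ndarray      # (m, p)
    surrogate: PolySurrogate
    delta: float
    version: int = FORMAT_VERSION

    @property
    def rank(self) -> int:
        return len(self.singular_values)

    def in_domain(self, theta: Sequence[float], tol: float = 1e-12) -> bool:
        return all(lo - tol <= float(t) <= hi + tol
                   for t, (lo, hi) in zip(theta, self.surrogate.domains))

    def evaluate(self, theta, strict: bool = True) -> RDFSample:
        return evaluate_model(self, theta, strict=strict)

    def to_dict(self) -> dict:
        return {
            "format_version": self.version,
            "grid": {"r_max": self.grid.r_max, "m": self.grid.m},
            "delta": self.delta,
            "singular_values": self.singular_values.tolist(),
            "basis_vectors": self.basis_vectors.tolist(),
            "surrogate": self.surrogate.to_dict(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "CompactRepresentation":
        version = d.get("format_version")
        if version != FORMAT_VERSION:
            raise ModelFormatError(
                f"unsupported compact-model format version {version!r}; "
                f"this build reads version {FORMAT_VERSION}")
        return cls(
            RadialGrid(float(d["grid"]["r_max"]), int(d["grid"]["m"])),
            np.asarray(d["singular_values"], dtype=float),
            np.asarray(d["basis_vectors"], dtype=float),
            PolySurrogate.from_dict(d["surrogate"]),
            float(d["delta"]),
        )

    @classmethod
    def load(cls, path) -> "CompactRepresentation":
        with open(path) as fh:
            try:
                d = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelFormatError(f"corrupt compact-model file: {exc}") from exc
        return cls.from_dict(d)


def _as_theta(theta, names) -> tuple[float, ...]:
    if isinstance(theta, dict):
        return tuple(float(theta[n]) for n in names)
    if np.isscalar(theta):
        return (float(theta),)
    return tuple(float(t) for t in theta)


def evaluate_model(compact: CompactRepresentation, theta,
                   strict: bool = True) -> RDFSample:
    """g~(r; theta) = sum_n sigma_n Poly_n(theta) v_n(r) on the stored grid."""
    th = _as_theta(theta, compact.surrogate.param_names)
    if len(th) != len(compact.surrogate.param_names):
        raise ValueError("theta dimensionality mismatch")
    if not compact.in_domain(th):
        msg = (f"theta={th} outside interpolated parameter domain "
               f"{compact.surrogate.domains}; reconstruction is only "
               "accurate within the trained region")
        if strict:
            raise ExtrapolationError(msg)
        import warnings
        warnings.warn(msg, stacklevel=2)
    weights = compact.singular_values * compact.surrogate.evaluate(th)
    g = compact.basis_vectors @ weights
    return RDFSample(compact.grid, np.clip(g, 0.0, None),
                     dict(zip(compact.surrogate.param_names, th)))


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------

class RDFBasisModel:
    """Low-rank basis model for a sweep of radial distribution functions.

    Parameters
    ----------
    matrix : RDFMatrix
        Stacked g(r) measurements over an ordered parameter table.
    delta : float
        Relative singular-value threshold used when no explicit rank is
        passed to :meth:`fit`.
    degree_rule : callable, optional
        Maps 1-based rank n to the polynomial degree of its surrogate
        (default ``n + 3``).
    """

    def __init__(self, matrix: RDFMatrix, delta: float = 1e-6,
                 degree_rule: Callable[[int], int] | None = None):
        self.matrix = matrix
        self.delta = delta
        self.degree_rule = degree_rule or default_degree_rule

    @classmethod
    def from_samples(cls, samples, **kwargs) -> "RDFBasisModel":
        from .rdf import build_rdf_matrix
        return cls(build_rdf_matrix(samples), **kwargs)

    def fit(self, rank: int | None = None) -> "RDFBasisResults":
        svd = decompose(self.matrix)
        if rank is None:
            rank = truncation_rank(svd.singular_values, self.delta)
        rank = int(rank)
        if not 1 <= rank <= svd.k:
            raise ValueError(f"rank must lie in [1, {svd.k}]")
        max_fittable = rank
        surrogate = fit_coefficient_polynomials(svd, self.degree_rule,
                                                p=max_fittable)
        return RDFBasisResults(self, svd, surrogate, rank)


class RDFBasisResults:
    """Fitted factorisation + surrogates with diagnostics."""

    def __init__(self, model: RDFBasisModel, svd: SVDModel,
                 surrogate: PolySurrogate, rank: int):
        self.model = model
        self.svd = svd
        self.surrogate = surrogate
        self.rank = rank

    @property
    def singular_values(self) -> np.ndarray:
        return self.svd.singular_values

    @property
    def residuals_log10(self) -> np.ndarray:
        return np.asarray(self.surrogate.residuals_log10)

    def reconstruct(self, p: int | None = None) -> np.ndarray:
        return reconstruct_truncated(self.svd, p or self.rank)

    def truncation_error(self, p: int | None = None) -> float:
        """Frobenius norm of the discarded tail, relative to ||G||_F."""
        p = p or self.rank
        s = self.svd.singular_values
        return float(np.sqrt(np.sum(s[p:] ** 2)) / np.sqrt(np.sum(s ** 2)))

    def to_compact(self) -> CompactRepresentation:
        p = self.rank
        return CompactRepresentation(
            self.svd.grid, self.svd.singular_values[:p].copy(),
            self.svd.basis_vectors[:, :p].copy(), self.surrogate,
            self.model.delta)

    def evaluate(self, theta, strict: bool = True) -> RDFSample:
        return evaluate_model(self.to_compact(), theta, strict=strict)

    def summary(self) -> str:
        s = self.svd.singular_values
        lines = [
            "RDF basis model",
            "=" * 64,
            f"parameter(s):     {', '.join(self.surrogate.param_names)}",
            f"domain:           {self.surrogate.domains}",
            f"sweep points k:   {self.svd.k}",
            f"radial bins m:    {self.svd.grid.m}  (r_max={self.svd.grid.r_max})",
            f"truncation rank:  {self.rank}   (delta={self.model.delta:g})",
            f"tail energy:      {self.truncation_error():.3e} (rel. Frobenius)",
            "",
            f"{'rank':>4} {'sigma_n':>14} {'sigma_n/sigma_1':>16} "
            f"{'poly deg':>9} {'log10 RMS resid':>16}",
        ]
        for n in range(self.rank):
            lines.append(
                f"{n + 1:>4} {s[n]:>14.6e} {s[n] / s[0]:>16.3e} "
                f"{self.surrogate.degrees[n]:>9d} "
                f"{self.surrogate.residuals_log10[n]:>16.2f}")
        return "\n".join(lines)
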