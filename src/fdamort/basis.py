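"""B-spline basis systems and functional-data smoothing.

Discrete measurements (hourly temperatures, daily counts) are turned into
continuous curves by ordinary least-squares spline smoothing with equally
spaced interior knots; the number of knots is selected by leave-one-out
cross-validation.  The module also provides the quadrature machinery (Gram,
cross-Gram and roughness-penalty matrices) that implements the integrals
appearing in the functional regression models.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = [
    "Interval",
    "BasisSystem",
    "FunctionalSample",
    "PenaltyMatrix",
    "make_basis",
    "evaluate",
    "smooth",
    "select_knots_loocv",
    "gram_matrix",
    "cross_gram",
    "inner_product",
    "penalty",
    "natural_spline_design",
    "NaturalSplineBasis",
    "drop_constant_direction",
    "project_curve",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    """A closed interval [lower, upper] on which curves live."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError(
                f"Interval bounds must be finite, got lower={self.lower!r}, "
                f"upper={self.upper!r}"
            )
        if not self.upper > self.lower:
            raise ValueError(
                f"Interval requires upper > lower, got [{self.lower}, {self.upper}]"
            )

    @property
    def span(self) -> float:
        return self.upper - self.lower

    def contains(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x >= self.lower) & (x <= self.upper)


@dataclass(frozen=True)
class BasisSystem:
    """A B-spline basis of given order on an interval.

    ``order`` is the spline order (4 = cubic).  ``interior_knots`` are sorted
    and strictly inside the domain; the boundary knots are replicated to
    ``order`` multiplicity, so ``dimension = len(interior_knots) + order``.
    """

    domain: Interval
    order: int
    interior_knots: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got order={self.order}")
        kn = np.asarray(self.interior_knots, dtype=float)
        if kn.size:
            if np.any(np.diff(kn) < 0):
                raise ValueError("interior_knots must be sorted")
            if kn[0] <= self.domain.lower or kn[-1] >= self.domain.upper:
                raise ValueError("interior_knots must lie strictly inside the domain")
        object.__setattr__(self, "interior_knots", tuple(float(k) for k in kn))

    @property
    def dimension(self) -> int:
        return len(self.interior_knots) + self.order

    @property
    def degree(self) -> int:
        return self.order - 1

    def knot_vector(self) -> np.ndarray:
        """Full knot vector with order-fold replicated boundary knots."""
        return np.concatenate([
            np.full(self.order, self.domain.lower),
            np.asarray(self.interior_knots, dtype=float),
            np.full(self.order, self.domain.upper),
        ])

    def breakpoints(self) -> np.ndarray:
        """Distinct knots delimiting the polynomial pieces."""
        return np.concatenate([
            [self.domain.lower],
            np.asarray(self.interior_knots, dtype=float),
            [self.domain.upper],
        ])

    def support(self, j: int) -> tuple[float, float]:
        """Support interval of the j-th basis function."""
        t = self.knot_vector()
        return float(t[j]), float(t[j + self.order])

    def design_matrix(self, x, derivative: int = 0) -> np.ndarray:
        """Evaluate all basis functions (or a derivative) at points ``x``."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if not np.all(self.domain.contains(x)):
            bad = x[~self.domain.contains(x)]
            raise ValueError(
                f"evaluation points outside domain [{self.domain.lower}, "
                f"{self.domain.upper}]: {bad[:5]}"
            )
        t = self.knot_vector()
        if derivative == 0:
            return BSpline.design_matrix(x, t, self.degree, extrapolate=False).toarray()
        if derivative >= self.order:
            return np.zeros((x.size, self.dimension))
        spl = BSpline(t, np.eye(self.dimension), self.degree, extrapolate=False)
        out = spl.derivative(derivative)(x)
        # right endpoint of the domain: take the left limit
        at_end = x == self.domain.upper
        if np.any(at_end):
            eps = 1e-9 * max(1.0, abs(self.domain.span))
            out[at_end] = spl.derivative(derivative)(
                np.full(at_end.sum(), self.domain.upper - eps)
            )
        return np.nan_to_num(out)


@dataclass(frozen=True)
class PenaltyMatrix:
    """Roughness penalty: entry (j,k) = integral of D^m b_j * D^m b_k."""

    basis: BasisSystem
    derivative_order: int
    matrix: np.ndarray


@dataclass
class FunctionalSample:
    """n curves sharing one basis, stored as an (n, dimension) coefficient table."""

    basis: BasisSystem
    coefficients: np.ndarray
    curve_labels: Sequence = None

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.coefficients, dtype=float))
        if c.shape[1] != self.basis.dimension:
            raise ValueError(
                f"coefficient table has {c.shape[1]} columns but basis dimension "
                f"is {self.basis.dimension}"
            )
        self.coefficients = c
        if self.curve_labels is None:
            self.curve_labels = list(range(c.shape[0]))
        elif len(self.curve_labels) != c.shape[0]:
            raise ValueError("curve_labels length does not match number of curves")

    @property
    def n_curves(self) -> int:
        return self.coefficients.shape[0]

    def evaluate(self, grid) -> np.ndarray:
        return evaluate(self, grid)

    def mean_curve(self) -> "FunctionalSample":
        return FunctionalSample(
            self.basis, self.coefficients.mean(axis=0, keepdims=True), ["mean"]
        )


# ---------------------------------------------------------------------------
# Basis construction and evaluation
# ---------------------------------------------------------------------------

def make_basis(domain: Interval, n_interior_knots: int, order: int = 4) -> BasisSystem:
    """B-spline basis with ``n_interior_knots`` equally spaced interior knots."""
    if n_interior_knots < 0:
        raise ValueError(f"n_interior_knots must be >= 0, got {n_interior_knots}")
    if order < 1:
        raise ValueError(f"order must be >= 1, got order={order}")
    h = domain.span / (n_interior_knots + 1)
    interior = tuple(domain.lower + k * h for k in range(1, n_interior_knots + 1))
    return BasisSystem(domain=domain, order=order, interior_knots=interior)


def evaluate(sample: FunctionalSample, grid) -> np.ndarray:
    """Evaluate every curve at the grid points: (n_curves, len(grid)) table."""
    B = sample.basis.design_matrix(grid)
    return sample.coefficients @ B.T


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def _as_curve_dict(measurements) -> dict:
    """Normalize measurement input to {label: (positions, values)}."""
    if isinstance(measurements, Mapping):
        return {
            lab: (np.asarray(p, dtype=float), np.asarray(v, dtype=float))
            for lab, (p, v) in measurements.items()
        }
    # (positions, values_matrix) fast-path layout: shared positions
    positions, values = measurements
    positions = np.asarray(positions, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return {i: (positions, values[i]) for i in range(values.shape[0])}


def smooth(measurements, basis: BasisSystem, curve_labels=None) -> FunctionalSample:
    """Least-squares spline fit of each curve's (position, value) pairs.

    ``measurements`` is either a mapping {label: (positions, values)} or a
    pair ``(positions, values_matrix)`` when all curves share the same
    measurement positions (the usual regular-sampling case, solved with a
    single factorization).
    """
    if not isinstance(measurements, Mapping):
        positions, values = measurements
        positions = np.asarray(positions, dtype=float)
        values = np.atleast_2d(np.asarray(values, dtype=float))
        if positions.size < basis.dimension:
            raise ValueError(
                f"curves have {positions.size} points but basis dimension is "
                f"{basis.dimension}"
            )
        B = basis.design_matrix(positions)
        coefs, _, rank, _ = np.linalg.lstsq(B, values.T, rcond=None)
        if rank < basis.dimension:
            raise ValueError("rank-deficient smoothing design (shared positions)")
        labels = curve_labels if curve_labels is not None else list(range(values.shape[0]))
        return FunctionalSample(basis, coefs.T, labels)

    data = _as_curve_dict(measurements)
    coefs = np.empty((len(data), basis.dimension))
    labels = []
    for row, (lab, (pos, val)) in enumerate(data.items()):
        ok = np.isfinite(val)
        pos, val = pos[ok], val[ok]
        if pos.size < basis.dimension:
            raise ValueError(
                f"curve {lab!r} has {pos.size} points but basis dimension is "
                f"{basis.dimension}"
            )
        B = basis.design_matrix(pos)
        c, _, rank, _ = np.linalg.lstsq(B, val, rcond=None)
        if rank < basis.dimension:
            raise ValueError(f"rank-deficient smoothing design for curve {lab!r}")
        coefs[row] = c
        labels.append(lab)
    return FunctionalSample(basis, coefs, labels)


def _loocv_score_curve(pos: np.ndarray, val: np.ndarray, basis: BasisSystem):
    """Sum of squared leave-one-out residuals via the hat-matrix identity."""
    B = basis.design_matrix(pos)
    # hat diagonal h_i = b_i' (B'B)^{-1} b_i
    BtB = B.T @ B
    sol = np.linalg.solve(BtB, B.T)
    h = np.einsum("ij,ji->i", B, sol)
    resid = val - B @ (sol @ val)
    denom = 1.0 - h
    denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
    loo = resid / denom
    return float(np.sum(loo**2)), pos.size


def select_knots_loocv(
    measurements,
    domain: Interval,
    order: int,
    candidate_knot_counts: Sequence[int],
) -> tuple[int, pd.DataFrame]:
    """Pick the equally-spaced interior-knot count minimizing point-level LOO-CV.

    The score for a candidate is the mean over all measurement points (summed
    across curves) of the squared error predicting each point from a fit that
    excludes it.  Ties break toward fewer knots.
    """
    if len(candidate_knot_counts) == 0:
        raise ValueError("candidate_knot_counts must be non-empty")
    data = _as_curve_dict(measurements)
    min_pts = min(np.sum(np.isfinite(v)) for _, v in data.values())
    rows = []
    for cand in candidate_knot_counts:
        basis = make_basis(domain, cand, order)
        if basis.dimension > min_pts:
            raise ValueError(
                f"candidate {cand} interior knots gives dimension {basis.dimension} "
                f"> smallest curve size {min_pts}"
            )
        sse, n_pts = 0.0, 0
        for lab, (pos, val) in data.items():
            ok = np.isfinite(val)
            s, n = _loocv_score_curve(pos[ok], val[ok], basis)
            sse += s
            n_pts += n
        rows.append({"n_interior_knots": int(cand), "cv_score": sse / n_pts})
    scores = pd.DataFrame(rows).sort_values("n_interior_knots").reset_index(drop=True)
    best_score = scores["cv_score"].min()
    # numerical ties (e.g. nested bases reproducing noise-free data exactly)
    # resolve toward fewer knots
    tol = best_score * 1e-8 + 1e-12
    best = scores.loc[scores["cv_score"] <= best_score + tol, "n_interior_knots"].iloc[0]
    return int(best), scores


# ---------------------------------------------------------------------------
# Quadrature: Gram, cross-Gram, penalties, inner products
# ---------------------------------------------------------------------------

def _panel_nodes(breaks: np.ndarray, n_nodes: int):
    """Gauss-Legendre nodes/weights on each panel [breaks[i], breaks[i+1]]."""
    x01, w01 = leggauss(n_nodes)
    lo, hi = breaks[:-1], breaks[1:]
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    pts = (mid[:, None] + half[:, None] * x01[None, :]).ravel()
    wts = (half[:, None] * w01[None, :]).ravel()
    return pts, wts


def _integrate_products(
    basis_a: BasisSystem, deriv_a: int, basis_b: BasisSystem, deriv_b: int
) -> np.ndarray:
    """Matrix of integrals of D^{da} a_j * D^{db} b_k over the common domain.

    Exact for splines: Gauss-Legendre per panel of the union breakpoint grid
    with enough nodes for the product's polynomial degree.
    """
    if (basis_a.domain.lower, basis_a.domain.upper) != (
        basis_b.domain.lower,
        basis_b.domain.upper,
    ):
        raise ValueError("bases must share the same domain for product integrals")
    breaks = np.unique(
        np.concatenate([basis_a.breakpoints(), basis_b.breakpoints()])
    )
    deg = (basis_a.degree - deriv_a) + (basis_b.degree - deriv_b)
    n_nodes = max(1, deg // 2 + 1)
    pts, wts = _panel_nodes(breaks, n_nodes)
    A = basis_a.design_matrix(pts, derivative=deriv_a)
    Bm = basis_b.design_matrix(pts, derivative=deriv_b)
    return (A * wts[:, None]).T @ Bm


def gram_matrix(basis: BasisSystem) -> np.ndarray:
    """Gram matrix G[j,k] = integral of b_j b_k (symmetric PSD)."""
    G = _integrate_products(basis, 0, basis, 0)
    return 0.5 * (G + G.T)


def cross_gram(basis_a: BasisSystem, basis_b: BasisSystem) -> np.ndarray:
    """Cross-Gram J[j,k] = integral of a_j b_k over the shared domain."""
    return _integrate_products(basis_a, 0, basis_b, 0)


def inner_product(f: FunctionalSample, g: FunctionalSample) -> float:
    """L2 inner product of two single curves on the same basis."""
    if f.basis != g.basis:
        raise ValueError("inner_product requires both curves on the same basis")
    if f.n_curves != 1 or g.n_curves != 1:
        raise ValueError("inner_product expects single curves")
    G = gram_matrix(f.basis)
    return float(f.coefficients[0] @ G @ g.coefficients[0])


def penalty(basis: BasisSystem, derivative_order: int = 2) -> PenaltyMatrix:
    """Roughness penalty matrix for the given derivative order."""
    if derivative_order < 0:
        raise ValueError("derivative_order must be >= 0")
    if derivative_order >= basis.order:
        raise ValueError(
            f"derivative_order {derivative_order} must be < spline order {basis.order}"
        )
    P = _integrate_products(basis, derivative_order, basis, derivative_order)
    return PenaltyMatrix(basis, derivative_order, 0.5 * (P + P.T))


# ---------------------------------------------------------------------------
# Natural cubic splines (long-term trend terms) and identifiability helpers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NaturalSplineBasis:
    """Natural cubic spline basis: cubic B-splines constrained to zero second
    derivative at the boundaries, hence linear extrapolation beyond them."""

    knots: tuple[float, ...]  # full sorted knot sequence incl. boundaries

    def __post_init__(self) -> None:
        kn = np.asarray(self.knots, dtype=float)
        if kn.size < 2 or np.any(np.diff(kn) <= 0):
            raise ValueError("need >= 2 strictly increasing knots")
        object.__setattr__(self, "knots", tuple(float(k) for k in kn))

    @property
    def _bspline_basis(self) -> BasisSystem:
        kn = np.asarray(self.knots)
        return BasisSystem(
            Interval(kn[0], kn[-1]), order=4, interior_knots=tuple(kn[1:-1])
        )

    @property
    def dimension(self) -> int:
        return self._bspline_basis.dimension - 2

    def _null_transform(self) -> np.ndarray:
        b = self._bspline_basis
        C = b.design_matrix(np.array([b.domain.lower, b.domain.upper]), derivative=2)
        return null_space(C)  # (dim_b, dim_b - 2)

    def design(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        b = self._bspline_basis
        Z = self._null_transform()
        lo, hi = b.domain.lower, b.domain.upper
        out = np.empty((x.size, self.dimension))
        inside = (x >= lo) & (x <= hi)
        if np.any(inside):
            out[inside] = b.design_matrix(x[inside]) @ Z
        for bound, mask in ((lo, x < lo), (hi, x > hi)):
            if np.any(mask):
                v = (b.design_matrix([bound]) @ Z)[0]
                d = (b.design_matrix([bound], derivative=1) @ Z)[0]
                out[mask] = v[None, :] + (x[mask] - bound)[:, None] * d[None, :]
        return out

    def penalty(self, derivative_order: int = 2) -> np.ndarray:
        """Roughness penalty in the natural-spline coefficient space."""
        b = self._bspline_basis
        Z = self._null_transform()
        P = penalty(b, derivative_order).matrix
        return Z.T @ P @ Z


def natural_spline_design(x, knots) -> np.ndarray:
    """Design matrix of a natural cubic spline with the given full knot set."""
    return NaturalSplineBasis(tuple(np.asarray(knots, dtype=float))).design(x)


def drop_constant_direction(M: np.ndarray):
    """Reparameterize a design block to exclude the constant function.

    Returns (M @ Z, Z) where Z spans the null space of the column-mean row, so
    every column of the new block has zero mean and constants leave its span.
    Used to keep smooth blocks identifiable next to an explicit intercept.
    """
    m = M.mean(axis=0, keepdims=True)
    Z = null_space(m)
    return M @ Z, Z


def project_curve(
    fn: Callable[[np.ndarray], np.ndarray], basis: BasisSystem, n_grid: int = 400,
    label="projection",
) -> FunctionalSample:
    """Least-squares projection of a callable onto the basis span."""
    g = np.linspace(basis.domain.lower, basis.domain.upper, n_grid)
    B = basis.design_matrix(g)
    c, *_ = np.linalg.lstsq(B, fn(g), rcond=None)
    return FunctionalSample(basis, c[None, :], [label])
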