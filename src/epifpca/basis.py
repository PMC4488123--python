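"""B-spline basis construction and least-squares expansion of profiles.

Coverage profiles observed on a discrete grid are represented as smooth
functions x_i(t) = sum_k c_ik phi_k(t) in a B-spline basis with equidistant
interior knots.  The coefficients are estimated by ordinary least squares;
the Gram matrix W (pairwise L2 inner products of the basis functions) is
computed by per-span Gauss-Legendre quadrature that is exact for the
piecewise-polynomial integrands, so downstream function-space algebra
carries no quadrature tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

__all__ = ["BSplineBasis", "FunctionalDataset", "make_basis", "fit_coefficients"]


class BSplineBasis:
    """K B-spline basis functions of a given order on [a, b].

    Parameters
    ----------
    a, b : float
        Interval endpoints, b > a.
    n_basis : int
        Number of basis functions K; must satisfy K >= order.
    order : int, default 4
        Spline order (polynomial degree + 1); 4 = cubic.

    Attributes
    ----------
    knots : ndarray
        Full knot vector: boundary knots repeated `order` times, K - order
        equidistant interior knots.
    gram : ndarray of shape (K, K)
        W with W_jk = integral of phi_j * phi_k over [a, b].
    """

    def __init__(self, a: float, b: float, n_basis: int, order: int = 4):
        if not b > a:
            raise ValueError(f"interval must satisfy b > a, got [{a}, {b}]")
        if n_basis < order:
            raise ValueError(
                f"need at least as many basis functions as the order "
                f"(K={n_basis} < order={order})"
            )
        self.a = float(a)
        self.b = float(b)
        self.n_basis = int(n_basis)
        self.order = int(order)
        n_interior = self.n_basis - self.order
        interior = np.linspace(self.a, self.b, n_interior + 2)[1:-1]
        self.knots = np.concatenate(
            [np.full(self.order, self.a), interior, np.full(self.order, self.b)]
        )
        self._gram: np.ndarray | None = None

    @property
    def interval(self) -> tuple[float, float]:
        return (self.a, self.b)

    @property
    def degree(self) -> int:
        return self.order - 1

    def evaluate(self, grid) -> np.ndarray:
        """Evaluate all basis functions at the points of `grid`.

        Returns a (G, K) design matrix; each row sums to 1 (partition of
        unity).  Points outside [a, b] raise ValueError.
        """
        t = np.asarray(grid, dtype=float)
        if t.ndim != 1:
            t = t.ravel()
        if t.size and (t.min() < self.a or t.max() > self.b):
            raise ValueError(
                f"evaluation points outside basis interval [{self.a}, {self.b}]"
            )
        dm = BSpline.design_matrix(t, self.knots, self.degree, extrapolate=False)
        return np.asarray(dm.todense())

    @property
    def gram(self) -> np.ndarray:
        """Gram matrix W_jk = int phi_j phi_k dt, exact quadrature."""
        if self._gram is None:
            # integrand is piecewise degree 2*(order-1); n-point Gauss-Legendre
            # is exact through degree 2n-1, so n = order suffices
            n_nodes = self.order
            x, w = leggauss(n_nodes)
            spans = np.unique(self.knots)
            W = np.zeros((self.n_basis, self.n_basis))
            for lo, hi in zip(spans[:-1], spans[1:]):
                half = 0.5 * (hi - lo)
                pts = lo + half * (x + 1.0)
                Phi = self.evaluate(pts)
                W += (Phi * (w * half)[:, None]).T @ Phi
            W = 0.5 * (W + W.T)
            self._gram = W
        return self._gram

    def gram_cholesky(self) -> np.ndarray:
        """Upper-triangular R with W = R.T @ R."""
        return np.linalg.cholesky(self.gram).T

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BSplineBasis)
            and self.interval == other.interval
            and self.n_basis == other.n_basis
            and self.order == other.order
        )

    def __repr__(self) -> str:
        return (
            f"BSplineBasis(a={self.a}, b={self.b}, "
            f"n_basis={self.n_basis}, order={self.order})"
        )


@dataclass
class FunctionalDataset:
    """Basis-expanded profiles: coefficient rows c_i per region."""

    basis: BSplineBasis
    coeffs: np.ndarray  # (L, K)
    region_ids: list[str]
    residual_rms: np.ndarray = field(default=None)  # (L,)

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 2 or self.coeffs.shape[1] != self.basis.n_basis:
            raise ValueError("coeffs must be (L, K) matching the basis")
        if len(self.region_ids) != self.coeffs.shape[0]:
            raise ValueError("region_ids length must match number of rows")
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("non-finite coefficients")

    @property
    def n_regions(self) -> int:
        return self.coeffs.shape[0]


def make_basis(a: float, b: float, n_basis: int, order: int = 4) -> BSplineBasis:
    """Construct a B-spline basis with equidistant interior knots."""
    return BSplineBasis(a, b, n_basis, order)


def fit_coefficients(profiles, basis: BSplineBasis, grid=None) -> FunctionalDataset:
    """Least-squares basis expansion of each profile row.

    Parameters
    ----------
    profiles : ProfileMatrix or ndarray (L, G)
        Observed profiles.  If an ndarray is given, `grid` is required.
    basis : BSplineBasis
    grid : array-like, optional
        Sampling points; taken from `profiles.grid` when absent.

    One normal-equations Cholesky factorization is shared across all rows.
    """
    if hasattr(profiles, "values") and hasattr(profiles, "region_ids"):
        values = np.asarray(profiles.values, dtype=float)
        region_ids = list(profiles.region_ids)
        if grid is None:
            grid = profiles.grid
    else:
        if grid is None:
            raise ValueError("grid is required when profiles is a plain array")
        values = np.asarray(profiles, dtype=float)
        region_ids = [f"row_{i}" for i in range(values.shape[0])]
    grid = np.asarray(grid, dtype=float)
    if values.ndim != 2 or values.shape[1] != grid.size:
        raise ValueError("profiles must be (L, G) with G matching the grid")
    G, K = grid.size, basis.n_basis
    if G < K:
        raise ValueError(f"need at least K={K} grid points, got G={G}")
    Phi = basis.evaluate(grid)
    XtX = Phi.T @ Phi
    try:
        factor = cho_factor(XtX)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate grid
        raise ValueError("rank-deficient design: degenerate fitting grid") from exc
    coeffs = cho_solve(factor, Phi.T @ values.T).T
    resid = values - coeffs @ Phi.T
    rms = np.sqrt(np.mean(resid**2, axis=1))
    return FunctionalDataset(basis=basis, coeffs=coeffs,
                             region_ids=region_ids, residual_rms=rms)
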