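"""Functional principal component analysis of basis-expanded profiles.

Given profiles x_i(t) = sum_k c_ik phi_k(t), the Karhunen-Loeve expansion

    x_i(t) = mu(t) + sum_k eta_ik xi_k(t)

is estimated by solving the covariance eigenproblem in basis coordinates.
With Gram matrix W = int phi phi^T and coefficient covariance S_c
(divisor L - 1), factor W = R^T R, eigendecompose R S_c R^T = U Lam U^T
and set B = R^{-1} U: the columns of B give eigenfunctions
xi_k(t) = sum_j B_jk phi_j(t) that are orthonormal in L2
(B^T W B = I), with eigenvalues Lam sorted in decreasing order.  Scores
are the exact projections eta_ik = (c_i - c_bar)^T W B_k, realizing
int (x_i - mu) xi_k in basis algebra; their sample variance equals the
eigenvalue and distinct score columns are uncorrelated.

Eigenfunction signs are fixed by requiring a positive value at the grid
point (2001 equidistant points over the interval) where |xi_k| is largest,
so results are reproducible across linear-algebra backends.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator, TransformerMixin

from .basis import BSplineBasis, FunctionalDataset, fit_coefficients

__all__ = [
    "FunctionalPCA",
    "fit_fpca",
    "evaluate_eigenfunctions",
    "project_scores",
    "covariance_function",
    "reconstruct",
]

_SIGN_GRID_POINTS = 2001


class FunctionalPCA(BaseEstimator, TransformerMixin):
    """Functional PCA of profiles observed on a common grid.

    Parameters
    ----------
    n_components : int or None
        Number of eigenfunctions J to retain; None keeps
        min(n_basis, L - 1).
    n_basis : int, default 50
        Number K of B-spline basis functions for the smoothing expansion.
    order : int, default 4
        Spline order (4 = cubic).
    interval : (float, float), default (-5000, 5000)
        Domain [a, b] of the functional coordinate, in bp relative to the
        anchor.

    Attributes
    ----------
    basis_ : BSplineBasis
    mean_coeffs_ : ndarray (K,)
        Mean function mu(t) in basis coordinates.
    eig_coeffs_ : ndarray (K, J)
        Column k holds the basis coefficients of eigenfunction xi_k.
    eigenvalues_ : ndarray (J,)
        lambda_1 >= ... >= lambda_J >= 0 (variance of the k-th scores).
    scores_ : ndarray (L, J)
        Training-set scores eta_ik.
    explained_variance_ratio_ : ndarray (J,)
        lambda_k divided by the total functional variance trace(W S_c).
    total_variance_ : float
    region_ids_ : list of str
    """

    def __init__(self, n_components: int | None = None, n_basis: int = 50,
                 order: int = 4, interval=(-5000.0, 5000.0)):
        self.n_components = n_components
        self.n_basis = n_basis
        self.order = order
        self.interval = interval

    # ------------------------------------------------------------------ fit

    def fit(self, X, y=None, grid=None, region_ids=None):
        """Fit the decomposition.

        X may be a ProfileMatrix, a FunctionalDataset (already expanded),
        or an (L, G) array with `grid` giving the sampling points
        (defaults to bin centers spread over `interval`).
        """
        data = self._as_dataset(X, grid, region_ids)
        basis = data.basis
        L, K = data.coeffs.shape
        if L < 2:
            raise ValueError("need at least 2 regions")
        J = self.n_components if self.n_components is not None else min(K, L - 1)
        if J > min(K, L - 1):
            raise ValueError(
                f"n_components={J} exceeds min(K, L-1)={min(K, L - 1)}"
            )
        W = basis.gram
        mean_coeffs = data.coeffs.mean(axis=0)
        Cc = data.coeffs - mean_coeffs
        S_c = (Cc.T @ Cc) / (L - 1)
        R = basis.gram_cholesky()  # W = R^T R
        M = R @ S_c @ R.T
        M = 0.5 * (M + M.T)
        lam, U = np.linalg.eigh(M)
        lam = lam[::-1][:J]
        U = U[:, ::-1][:, :J]
        lam = np.where(lam > -1e-10, np.clip(lam, 0.0, None), lam)
        if np.any(lam < 0):
            raise ValueError("covariance eigenproblem produced a negative "
                             "eigenvalue beyond numerical tolerance")
        B = solve_triangular(R, U)  # R B = U
        # sign convention: positive value at the argmax of |xi_k|
        sgrid = np.linspace(basis.a, basis.b, _SIGN_GRID_POINTS)
        Xi = basis.evaluate(sgrid) @ B
        idx = np.argmax(np.abs(Xi), axis=0)
        signs = np.sign(Xi[idx, np.arange(J)])
        signs[signs == 0] = 1.0
        B = B * signs
        self.basis_ = basis
        self.mean_coeffs_ = mean_coeffs
        self.eig_coeffs_ = B
        self.eigenvalues_ = lam
        self.total_variance_ = float(np.trace(W @ S_c))
        self.explained_variance_ratio_ = lam / self.total_variance_
        self.region_ids_ = list(data.region_ids)
        self.n_samples_ = L
        self.n_components_ = J
        self.residual_rms_ = data.residual_rms
        self.scores_ = self.transform_dataset(data)
        return self

    def _as_dataset(self, X, grid=None, region_ids=None) -> FunctionalDataset:
        if isinstance(X, FunctionalDataset):
            return X
        a, b = self.interval
        if hasattr(X, "values") and hasattr(X, "grid"):
            ds = fit_coefficients(
                X, BSplineBasis(a, b, self.n_basis, self.order))
        else:
            X = np.asarray(X, dtype=float)
            if grid is None:
                G = X.shape[1]
                step = (b - a) / G
                grid = a + step * (np.arange(G) + 0.5)
            ds = fit_coefficients(
                X, BSplineBasis(a, b, self.n_basis, self.order), grid=grid)
        if region_ids is not None:
            ds = FunctionalDataset(basis=ds.basis, coeffs=ds.coeffs,
                                   region_ids=list(region_ids),
                                   residual_rms=ds.residual_rms)
        return ds

    # ------------------------------------------------------------- methods

    def transform_dataset(self, data: FunctionalDataset) -> np.ndarray:
        """Scores for an expanded dataset sharing the fitted basis."""
        if data.basis != self.basis_:
            raise ValueError("basis mismatch: dataset was expanded in a "
                             "different basis than the fitted one")
        Cc = data.coeffs - self.mean_coeffs_
        return Cc @ self.basis_.gram @ self.eig_coeffs_

    def transform(self, X, grid=None, region_ids=None) -> np.ndarray:
        """Project (possibly new) profiles onto the fitted eigenfunctions."""
        return self.transform_dataset(self._as_dataset(X, grid, region_ids))

    def evaluate_eigenfunctions(self, grid) -> np.ndarray:
        """(G, J) values of xi_1..xi_J at the given points."""
        return self.basis_.evaluate(grid) @ self.eig_coeffs_

    def mean_function(self, grid) -> np.ndarray:
        return self.basis_.evaluate(grid) @ self.mean_coeffs_

    def covariance_function(self, s_grid, t_grid) -> np.ndarray:
        """v(s, t) = sum_k lambda_k xi_k(s) xi_k(t) over retained components."""
        Xs = self.evaluate_eigenfunctions(s_grid)
        Xt = self.evaluate_eigenfunctions(t_grid)
        return (Xs * self.eigenvalues_) @ Xt.T

    def reconstruct(self, grid, n_components: int | None = None,
                    scores: np.ndarray | None = None) -> np.ndarray:
        """Truncated KL reconstruction mu(t) + sum_{k<=J_use} eta_ik xi_k(t)."""
        J_use = self.n_components_ if n_components is None else n_components
        if J_use > self.n_components_:
            raise ValueError("n_components exceeds the fitted number")
        eta = self.scores_ if scores is None else scores
        mu = self.mean_function(grid)
        Xi = self.evaluate_eigenfunctions(grid)
        return mu[None, :] + eta[:, :J_use] @ Xi[:, :J_use].T

    @property
    def cumulative_variance_ratio_(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio_)

    # ------------------------------------------------------------- storage

    def save(self, outdir) -> None:
        """Serialize to a directory: JSON model + TSV eigenfunctions/scores."""
        os.makedirs(outdir, exist_ok=True)
        meta = {
            "interval": [self.basis_.a, self.basis_.b],
            "n_basis": self.basis_.n_basis,
            "order": self.basis_.order,
            "n_components": int(self.n_components_),
            "n_samples": int(self.n_samples_),
            "total_variance": self.total_variance_,
            "mean_coeffs": self.mean_coeffs_.tolist(),
            "eig_coeffs": self.eig_coeffs_.tolist(),
            "eigenvalues": self.eigenvalues_.tolist(),
            "sign_grid_points": _SIGN_GRID_POINTS,
        }
        with open(os.path.join(outdir, "model.json"), "w") as fh:
            json.dump(meta, fh, indent=1)
        grid = np.linspace(self.basis_.a, self.basis_.b, 1001)
        Xi = self.evaluate_eigenfunctions(grid)
        with open(os.path.join(outdir, "eigenfunctions.tsv"), "w") as fh:
            fh.write("t\t" + "\t".join(f"xi_{k+1}" for k in
                                       range(self.n_components_)) + "\n")
            for t, row in zip(grid, Xi):
                fh.write("%.17g\t" % t
                         + "\t".join("%.17g" % x for x in row) + "\n")
        with open(os.path.join(outdir, "scores.tsv"), "w") as fh:
            fh.write("region_id\t" + "\t".join(
                f"eta_{k+1}" for k in range(self.n_components_)) + "\n")
            for rid, row in zip(self.region_ids_, self.scores_):
                fh.write(str(rid) + "\t"
                         + "\t".join("%.17g" % x for x in row) + "\n")
        tot = self.total_variance_
        with open(os.path.join(outdir, "eigenvalues.tsv"), "w") as fh:
            fh.write("component\teigenvalue\tvar_ratio\tcum_var_ratio\n")
            cum = 0.0
            for k, lam in enumerate(self.eigenvalues_, start=1):
                cum += lam / tot
                fh.write(f"{k}\t%.17g\t%.17g\t%.17g\n" % (lam, lam / tot, cum))

    @classmethod
    def load(cls, indir) -> "FunctionalPCA":
        with open(os.path.join(indir, "model.json")) as fh:
            meta = json.load(fh)
        a, b = meta["interval"]
        est = cls(n_components=meta["n_components"], n_basis=meta["n_basis"],
                  order=meta["order"], interval=(a, b))
        est.basis_ = BSplineBasis(a, b, meta["n_basis"], meta["order"])
        est.mean_coeffs_ = np.array(meta["mean_coeffs"])
        est.eig_coeffs_ = np.array(meta["eig_coeffs"])
        est.eigenvalues_ = np.array(meta["eigenvalues"])
        est.total_variance_ = meta["total_variance"]
        est.explained_variance_ratio_ = est.eigenvalues_ / est.total_variance_
        est.n_components_ = meta["n_components"]
        est.n_samples_ = meta["n_samples"]
        sdf = pd.read_csv(os.path.join(indir, "scores.tsv"), sep="\t",
                          index_col=0, float_precision="round_trip")
        est.region_ids_ = [str(i) for i in sdf.index]
        est.scores_ = sdf.to_numpy(dtype=float)
        return est


# ------------------------------------------------------- thin functional API

def fit_fpca(data, n_components: int | None = None, n_basis: int = 50,
             order: int = 4, interval=(-5000.0, 5000.0)) -> FunctionalPCA:
    """Fit a FunctionalPCA on a ProfileMatrix or FunctionalDataset."""
    if isinstance(data, FunctionalDataset):
        a, b = data.basis.interval
        est = FunctionalPCA(n_components=n_components,
                            n_basis=data.basis.n_basis,
                            order=data.basis.order, interval=(a, b))
    else:
        est = FunctionalPCA(n_components=n_components, n_basis=n_basis,
                            order=order, interval=interval)
    return est.fit(data)


def evaluate_eigenfunctions(result: FunctionalPCA, grid) -> np.ndarray:
    return result.evaluate_eigenfunctions(grid)


def project_scores(result: FunctionalPCA, data) -> np.ndarray:
    """Scores of (possibly new) regions under the stored mean/eigenfunctions."""
    if isinstance(data, FunctionalDataset):
        return result.transform_dataset(data)
    return result.transform(data)


def covariance_function(result: FunctionalPCA, s_grid, t_grid) -> np.ndarray:
    return result.covariance_function(s_grid, t_grid)


def reconstruct(result: FunctionalPCA, n_components: int, grid) -> np.ndarray:
    return result.reconstruct(grid, n_components=n_components)
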