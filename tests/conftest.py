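import numpy as np
import pytest

from epifpca import FunctionalPCA, SimulationSpec, write_fixture_bundle


@pytest.fixture(scope="session")
def small_spec():
    """Tiny but complete simulation: both strands, blacklist, expression."""
    return SimulationSpec(
        L=12, flank=500, grid_bin=10, n_components=2, eigen_family="bumps",
        lambdas=(4.0, 1.0), cross_rho=(0.8, 0.0), noise_sd=0.05,
        baseline=1.0, expression_weights=(1.0, 0.5),
        expression_noise_sd=0.3, seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return write_fixture_bundle(small_spec, outdir)


@pytest.fixture(scope="session")
def rank1_case():
    """Profiles x_i = a_i * f(t): one exact component, known eigenvalue.

    f is built inside the spline span so the construction is exactly
    representable and tolerances probe the eigenproblem, not smoothing.
    """
    from epifpca import BSplineBasis

    rng = np.random.default_rng(42)
    grid = np.linspace(-1.0, 1.0, 201)
    basis = BSplineBasis(-1.0, 1.0, 12, 4)
    c = rng.normal(size=12)
    f = basis.evaluate(grid) @ c
    W = basis.gram
    norm_f = float(np.sqrt(c @ W @ c))
    amps = rng.normal(0.0, 2.0, size=100)
    X = np.outer(amps, f)
    est = FunctionalPCA(n_components=5, n_basis=12, interval=(-1.0, 1.0))
    est.fit(X, grid=grid)
    return {
        "grid": grid, "f": f, "amps": amps, "X": X, "est": est,
        "lam1": float(np.var(amps, ddof=1) * norm_f**2),
        "xi1": f / norm_f,
    }


def dense_pca_oracle(values, grid, n_components):
    """Weighted multivariate PCA on densely sampled profiles.

    Independent reference for the basis-algebra eigenproblem: trapezoid
    quadrature weights turn the discrete covariance eigenproblem into the
    functional one.  Returns eigenvalues, eigenfunction values on the grid
    and the scores, with the same positive-at-argmax sign convention.
    """
    values = np.asarray(values, dtype=float)
    w = np.empty_like(grid)
    w[1:-1] = 0.5 * (grid[2:] - grid[:-2])
    w[0] = 0.5 * (grid[1] - grid[0])
    w[-1] = 0.5 * (grid[-1] - grid[-2])
    Xc = values - values.mean(axis=0)
    C = (Xc.T @ Xc) / (values.shape[0] - 1)
    d = np.sqrt(w)
    M = d[:, None] * C * d[None, :]
    lam, U = np.linalg.eigh(M)
    lam = lam[::-1][:n_components]
    U = U[:, ::-1][:, :n_components]
    Xi = U / d[:, None]
    idx = np.argmax(np.abs(Xi), axis=0)
    signs = np.sign(Xi[idx, np.arange(n_components)])
    signs[signs == 0] = 1.0
    Xi = Xi * signs
    scores = Xc @ (w[:, None] * Xi)
    return lam, Xi, scores


@pytest.fixture(scope="session")
def oracle():
    return dense_pca_oracle


def random_smooth_profiles(rng, n_regions, n_basis, interval, n_grid=2001):
    """Random functions drawn inside a B-spline span, densely sampled."""
    from epifpca import BSplineBasis

    a, b = interval
    basis = BSplineBasis(a, b, n_basis, 4)
    grid = np.linspace(a, b, n_grid)
    coeffs = rng.normal(size=(n_regions, n_basis))
    return grid, coeffs @ basis.evaluate(grid).T


@pytest.fixture(scope="session")
def smooth_profiles():
    return random_smooth_profiles
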