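"""Synthetic coverage data with planted Karhunen-Loeve structure.

Profiles are generated from the model

    x_i(t) = baseline + sum_k eta_ik xi_k(t) + eps_i(t)

with a known orthonormal eigenfunction set xi_k, per-component score
variances lambda_k, and (for a mark pair A/B) planted correlations
cross_rho[k] between the two marks' k-th scores.  Mark B's eigenfunctions
may be circularly shifted relative to A's, producing the "correlated but
not co-localized" scenario in which score correlation is high while
ordinary coverage correlation is near zero.

`write_fixture_bundle` materializes a pair as bedGraph/BED/TSV files on a
toy two-chromosome genome (both strands represented, two regions designated
for blacklist removal), so every I/O stage of the pipeline is exercised
without external data.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre

from .genomic_io import ProfileMatrix

__all__ = [
    "SimulationSpec",
    "make_orthonormal_set",
    "simulate_mark_pair",
    "write_fixture_bundle",
]

_FLOAT_FMT = "%.17g"


@dataclass
class SimulationSpec:
    """Generator parameters; defaults are the standard study conditions.

    flank/grid_bin give +-5 kb windows at 10 bp resolution (G = 1000);
    three planted components with variances (9, 4, 1), white observation
    noise of sd 0.1 per grid point, and a first-component cross-mark score
    correlation of 0.8.  The expression model links RPKM to mark A's scores
    through a softplus of a weighted score sum, with the second component
    carrying the strongest effect (expression tracking a non-primary
    component).
    """

    L: int = 1000
    flank: int = 5000
    grid_bin: int = 10
    n_components: int = 3
    eigen_family: str = "fourier"
    eigen_shift_B: int = 0
    lambdas: tuple = (9.0, 4.0, 1.0)
    cross_rho: tuple = (0.8, 0.0, 0.0)
    noise_sd: float = 0.1
    baseline: float = 1.0
    expression_weights: tuple = (0.3, 1.0, 0.0)
    expression_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.L < 10:
            raise ValueError("L must be at least 10")
        lam = np.asarray(self.lambdas, dtype=float)
        if len(lam) != self.n_components:
            raise ValueError("lambdas length must equal n_components")
        if np.any(lam <= 0) or np.any(np.diff(lam) > 0):
            raise ValueError("lambdas must be positive and non-increasing")
        rho = np.asarray(self.cross_rho, dtype=float)
        if len(rho) != self.n_components:
            raise ValueError("cross_rho length must equal n_components")
        if np.any(np.abs(rho) > 1):
            raise ValueError("cross_rho entries must lie in [-1, 1]")
        if len(self.expression_weights) != self.n_components:
            raise ValueError(
                "expression_weights length must equal n_components")
        if (2 * self.flank) % self.grid_bin != 0:
            raise ValueError("2*flank must be divisible by grid_bin")

    @property
    def interval(self) -> tuple:
        return (-float(self.flank), float(self.flank))

    @property
    def n_grid(self) -> int:
        return (2 * self.flank) // self.grid_bin

    def grid(self) -> np.ndarray:
        return -self.flank + self.grid_bin * (np.arange(self.n_grid) + 0.5)

    def to_json_dict(self) -> dict:
        return dataclasses.asdict(self)


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty_like(grid)
    w[1:-1] = 0.5 * (grid[2:] - grid[:-2])
    w[0] = 0.5 * (grid[1] - grid[0])
    w[-1] = 0.5 * (grid[-1] - grid[-2])
    return w


def _raw_family(family: str, J: int, interval, grid: np.ndarray) -> np.ndarray:
    a, b = interval
    u = (grid - a) / (b - a)
    if family == "fourier":
        cols = []
        for k in range(J):
            freq = 2.0 * np.pi * (k // 2 + 1)
            cols.append(np.sin(freq * u) if k % 2 == 0 else np.cos(freq * u))
        return np.column_stack(cols)
    if family == "legendre":
        return np.column_stack(
            [eval_legendre(n, 2.0 * u - 1.0) for n in range(1, J + 1)])
    if family == "bumps":
        centers = (np.arange(J) + 0.5) / J
        # narrow enough that adjacent bumps and half-interval shifts of a
        # single bump are numerically disjoint
        sd = 1.0 / (6.0 * max(J, 3))
        return np.column_stack(
            [np.exp(-0.5 * ((u - c) / sd) ** 2) for c in centers])
    raise ValueError(f"unsupported eigenfunction family {family!r}")


def make_orthonormal_set(family: str, J: int, interval, shift: float = 0.0,
                         grid=None):
    """J pairwise-orthonormal functions sampled on an equidistant grid.

    Orthonormality holds under trapezoid quadrature on the returned grid.
    `shift` applies a circular translation (in the grid's units) before
    orthonormalization, used to de-localize one mark's variability
    relative to the other's.

    Returns (grid, Xi) with Xi of shape (G, J).
    """
    if J < 1:
        raise ValueError("J must be at least 1")
    a, b = interval
    if grid is None:
        G = 1000
        step = (b - a) / G
        grid = a + step * (np.arange(G) + 0.5)
    grid = np.asarray(grid, dtype=float)
    raw = _raw_family(family, J, interval, grid)
    if shift:
        step = grid[1] - grid[0]
        nbins = int(round(shift / step))
        raw = np.roll(raw, nbins, axis=0)
    w = _trapezoid_weights(grid)
    # Gram-Schmidt under the quadrature inner product
    Xi = np.empty_like(raw)
    for j in range(J):
        v = raw[:, j].copy()
        for i in range(j):
            v -= np.sum(w * v * Xi[:, i]) * Xi[:, i]
        nrm = np.sqrt(np.sum(w * v * v))
        if nrm < 1e-12:
            raise ValueError("degenerate raw family: functions not "
                             "linearly independent on the grid")
        Xi[:, j] = v / nrm
    return grid, Xi


def _draw_scores(rng: np.random.Generator, L: int, lambdas, cross_rho):
    """Per-component bivariate-normal scores for marks A and B."""
    lam = np.asarray(lambdas, dtype=float)
    rho = np.asarray(cross_rho, dtype=float)
    J = len(lam)
    z1 = rng.standard_normal((L, J))
    z2 = rng.standard_normal((L, J))
    eta_a = np.sqrt(lam) * z1
    eta_b = np.sqrt(lam) * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)
    return eta_a, eta_b


def simulate_mark_pair(spec: SimulationSpec):
    """Generate the profile-matrix pair and a ground-truth record.

    Profiles are in transcription orientation (the strand bookkeeping only
    matters once tracks are written to disk).  Fully deterministic given
    spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid()
    _, xi_a = make_orthonormal_set(spec.eigen_family, spec.n_components,
                                   spec.interval, shift=0.0, grid=grid)
    _, xi_b = make_orthonormal_set(spec.eigen_family, spec.n_components,
                                   spec.interval, shift=spec.eigen_shift_B,
                                   grid=grid)
    eta_a, eta_b = _draw_scores(rng, spec.L, spec.lambdas, spec.cross_rho)
    ids = [f"region_{i:05d}" for i in range(spec.L)]
    noise_a = spec.noise_sd * rng.standard_normal((spec.L, spec.n_grid))
    noise_b = spec.noise_sd * rng.standard_normal((spec.L, spec.n_grid))
    values_a = spec.baseline + eta_a @ xi_a.T + noise_a
    values_b = spec.baseline + eta_b @ xi_b.T + noise_b
    prof_a = ProfileMatrix(region_ids=ids, grid=grid, values=values_a)
    prof_b = ProfileMatrix(region_ids=ids, grid=grid, values=values_b)
    truth = {
        "spec": spec.to_json_dict(),
        "region_ids": ids,
        "grid": grid,
        "xi_a": xi_a,
        "xi_b": xi_b,
        "scores_a": eta_a,
        "scores_b": eta_b,
    }
    return prof_a, prof_b, truth


def _simulate_expression(rng, truth, weights, noise_sd):
    """Softplus link keeps RPKM non-negative, monotone in the score sum."""
    eta = truth["scores_a"]
    w = np.asarray(weights, dtype=float)
    z = eta @ w + noise_sd * rng.standard_normal(eta.shape[0])
    return np.logaddexp(0.0, z)


def _region_layout(spec: SimulationSpec):
    """Non-overlapping windows on a toy 2-chromosome genome, both strands."""
    gap = 1000
    margin = spec.flank + gap
    pitch = 2 * spec.flank + gap
    rows = []
    counts = {"chrA": 0, "chrB": 0}
    for i in range(spec.L):
        chrom = "chrA" if i % 2 == 0 else "chrB"
        anchor = margin + counts[chrom] * pitch
        counts[chrom] += 1
        strand = "+" if (i // 2) % 2 == 0 else "-"
        label = "pc" if i < spec.L // 2 else "nc"
        rows.append((f"region_{i:05d}", chrom, anchor, strand, label))
    sizes = {c: margin + counts[c] * pitch for c in counts}
    return rows, sizes


def write_fixture_bundle(spec: SimulationSpec, outdir) -> dict:
    """Materialize a simulated mark pair as on-disk fixture files.

    Writes per-mark bedGraphs (markA/markB), regions.bed (BED6 + class
    label), chrom.sizes, blacklist.bed (two intervals hitting the two
    designated regions), expression.tsv and truth.json.  Byte-identical
    across runs with the same spec.  Returns a dict of file paths plus the
    ground truth.
    """
    os.makedirs(outdir, exist_ok=True)
    prof_a, prof_b, truth = simulate_mark_pair(spec)
    rng = np.random.default_rng(spec.seed + 1)
    rpkm = _simulate_expression(rng, truth, spec.expression_weights,
                                spec.expression_noise_sd)
    layout, sizes = _region_layout(spec)
    blacklisted = [layout[-2][0], layout[-1][0]]

    paths = {k: os.path.join(outdir, v) for k, v in [
        ("chrom_sizes", "chrom.sizes"), ("regions", "regions.bed"),
        ("blacklist", "blacklist.bed"), ("expression", "expression.tsv"),
        ("truth", "truth.json"), ("track_a", "markA.bedGraph"),
        ("track_b", "markB.bedGraph")]}

    with open(paths["chrom_sizes"], "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")

    gene_len = 2000
    with open(paths["regions"], "w") as fh:
        for rid, chrom, anchor, strand, label in layout:
            if strand == "+":
                start, end = anchor, anchor + gene_len
            else:
                start, end = anchor - gene_len + 1, anchor + 1
            fh.write(f"{chrom}\t{start}\t{end}\t{rid}\t0\t{strand}\t{label}\n")

    with open(paths["blacklist"], "w") as fh:
        for rid, chrom, anchor, strand, _ in layout[-2:]:
            fh.write(f"{chrom}\t{anchor - 50}\t{anchor + 50}\n")

    with open(paths["expression"], "w") as fh:
        fh.write("gene_id\trpkm\n")
        for (rid, *_), x in zip(layout, rpkm):
            fh.write(f"{rid}\t{_FLOAT_FMT % x}\n")

    for key, prof in (("track_a", prof_a), ("track_b", prof_b)):
        _write_track(paths[key], prof, layout, spec)

    truth_json = {
        "spec": truth["spec"],
        "region_ids": truth["region_ids"],
        "blacklisted_ids": blacklisted,
        "grid": truth["grid"].tolist(),
        "xi_a": truth["xi_a"].tolist(),
        "xi_b": truth["xi_b"].tolist(),
        "scores_a": truth["scores_a"].tolist(),
        "scores_b": truth["scores_b"].tolist(),
        "rpkm": rpkm.tolist(),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_json, fh)
    paths["truth_record"] = truth_json
    return paths


def _write_track(path, prof: ProfileMatrix, layout, spec: SimulationSpec):
    """One bedGraph interval per bin; minus-strand profiles are written
    reversed on the genome so transcription-oriented extraction recovers
    the planted values exactly."""
    G, bs = spec.n_grid, spec.grid_bin
    per_chrom: dict[str, list] = {}
    for (rid, chrom, anchor, strand, _), row in zip(layout, prof.values):
        w0 = anchor - spec.flank
        vals = row if strand == "+" else row[::-1]
        per_chrom.setdefault(chrom, []).append((w0, vals))
    with open(path, "w") as fh:
        for chrom in sorted(per_chrom):
            for w0, vals in sorted(per_chrom[chrom]):
                for g in range(G):
                    fh.write(f"{chrom}\t{w0 + g * bs}\t{w0 + (g + 1) * bs}\t"
                             f"{_FLOAT_FMT % vals[g]}\n")
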