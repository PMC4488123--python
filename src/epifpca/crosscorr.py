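"""Cross-dataset correlation of functional principal components.

For two decompositions A and B of coverage around the same anchors, two
coefficients are computed per component pair (j, k):

* eigenfunction correlation r_xi[j, k] — Pearson correlation of xi^A_j and
  xi^B_k evaluated on a common grid; measures whether the two components'
  regions of variability co-localize;
* score correlation r_eta[j, k] — Pearson correlation of the score vectors
  over shared regions; measures whether the two marks co-vary across
  regions in their respective variability intervals.

A mark pair can thus co-vary strongly (high r_eta) while its variability
intervals do not overlap (negative r_xi) — a relationship invisible to the
ordinary coverage correlation, which is provided as the baseline.
Significance of score correlations uses two-sided t-tests with Bonferroni
correction over the J_A x J_B component-pair family of the mark pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genomic_io import extract_profiles

log = logging.getLogger(__name__)

__all__ = [
    "CrossCorrSummary",
    "MaxRecord",
    "eigenfunction_correlation",
    "score_correlation",
    "score_correlation_arrays",
    "bonferroni_significant",
    "max_summary",
    "ordinary_coverage_correlation",
    "ordinary_profile_correlation",
    "compare_correlation_distributions",
    "cross_correlation_summary",
]


def _column_pearson(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """All-pairs Pearson correlation between columns of X and of Y.

    Zero-variance columns yield r = 0 in their row/column.
    """
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((Yc**2).sum(axis=0))
    zx, zy = sx == 0, sy == 0
    sx = np.where(zx, 1.0, sx)
    sy = np.where(zy, 1.0, sy)
    r = (Xc / sx).T @ (Yc / sy)
    r[zx, :] = 0.0
    r[:, zy] = 0.0
    return np.clip(r, -1.0, 1.0)


def eigenfunction_correlation(res_a, res_b, grid_points: int = 1000) -> np.ndarray:
    """(J_A, J_B) Pearson correlations of eigenfunctions on a common grid."""
    if res_a.basis_.interval != res_b.basis_.interval:
        raise ValueError("results have mismatched intervals: "
                         f"{res_a.basis_.interval} vs {res_b.basis_.interval}")
    a, b = res_a.basis_.interval
    grid = np.linspace(a, b, grid_points)
    Xa = res_a.evaluate_eigenfunctions(grid)
    Xb = res_b.evaluate_eigenfunctions(grid)
    return _column_pearson(Xa, Xb)


def _pearson_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the t-distribution with n-2 df."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def score_correlation_arrays(scores_a: np.ndarray, scores_b: np.ndarray):
    """(r, p) matrices between score columns of two aligned score matrices."""
    n = scores_a.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 shared regions, got {n}")
    zero_a = scores_a.std(axis=0) == 0
    zero_b = scores_b.std(axis=0) == 0
    if zero_a.any() or zero_b.any():
        log.warning("zero-variance score column(s); r set to 0, p to 1")
    r = _column_pearson(scores_a, scores_b)
    p = _pearson_pvalues(r, n)
    p[zero_a, :] = 1.0
    p[:, zero_b] = 1.0
    return r, p


def score_correlation(res_a, res_b):
    """Pearson r and two-sided p per component pair over shared regions.

    Regions are matched by id (inner join, order of A preserved).
    Returns (r_eta, p_eta, n_shared).
    """
    ids_b = {rid: i for i, rid in enumerate(res_b.region_ids_)}
    pairs = [(i, ids_b[rid]) for i, rid in enumerate(res_a.region_ids_)
             if rid in ids_b]
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 shared regions, got {len(pairs)}")
    ia, ib = map(np.array, zip(*pairs))
    r, p = score_correlation_arrays(res_a.scores_[ia], res_b.scores_[ib])
    return r, p, len(pairs)


def bonferroni_significant(p_eta: np.ndarray, alpha: float = 1e-6):
    """Bonferroni over the J_A x J_B component-pair family.

    Returns (mask, count, alpha_corrected) with
    alpha_corrected = alpha / (J_A * J_B).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    alpha_corrected = alpha / p_eta.size
    mask = p_eta <= alpha_corrected
    return mask, int(mask.sum()), alpha_corrected


@dataclass
class MaxRecord:
    """Largest |correlation| with its 1-based component pair and the
    companion coefficient of the other kind at the same pair."""

    value: float
    components: tuple  # (j, k), 1-based
    companion: float


def max_summary(r_xi: np.ndarray, r_eta: np.ndarray, j_report: int = 5):
    """Maximum |r_xi| and |r_eta| over the first `j_report` components.

    Mirrors the per-mark-pair summary table: the maximal eigenfunction
    correlation with the score correlation at the same component pair, and
    vice versa.  Ties break row-major; indices are reported 1-based.
    """
    ja = min(j_report, r_xi.shape[0])
    jb = min(j_report, r_xi.shape[1])
    sub_xi = r_xi[:ja, :jb]
    sub_eta = r_eta[:ja, :jb]
    fx = int(np.argmax(np.abs(sub_xi)))
    jx, kx = divmod(fx, jb)
    fe = int(np.argmax(np.abs(sub_eta)))
    je, ke = divmod(fe, jb)
    return (
        MaxRecord(value=float(abs(sub_xi[jx, kx])), components=(jx + 1, kx + 1),
                  companion=float(sub_eta[jx, kx])),
        MaxRecord(value=float(abs(sub_eta[je, ke])), components=(je + 1, ke + 1),
                  companion=float(sub_xi[je, ke])),
    )


def ordinary_profile_correlation(prof_a, prof_b) -> float:
    """Pearson correlation of two flattened profile matrices."""
    x = np.asarray(prof_a.values if hasattr(prof_a, "values") else prof_a,
                   dtype=float).ravel()
    y = np.asarray(prof_b.values if hasattr(prof_b, "values") else prof_b,
                   dtype=float).ravel()
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in flattened coverage values")
    return float(np.corrcoef(x, y)[0, 1])


def ordinary_coverage_correlation(track_a, track_b, regions,
                                  bin_size: int = 10) -> float:
    """Coverage-correlation baseline restricted to the region windows.

    Pearson correlation over the concatenated binned values of all windows
    in genome orientation (no strand flip), emulating the conventional
    coverage-correlation utilities.
    """
    pa = extract_profiles(track_a, regions, bin_size=bin_size,
                          reverse_minus=False)
    pb = extract_profiles(track_b, regions, bin_size=bin_size,
                          reverse_minus=False)
    return ordinary_profile_correlation(pa, pb)


def compare_correlation_distributions(r_list_1, r_list_2):
    """Two-sample Kolmogorov-Smirnov test between two collections of
    correlation coefficients (e.g. pc-gene vs nc-gene component pairs).

    Returns (D, p) with the asymptotic two-sided p-value.
    """
    r1 = np.asarray(r_list_1, dtype=float)
    r2 = np.asarray(r_list_2, dtype=float)
    if r1.size < 2 or r2.size < 2:
        raise ValueError("both collections need at least 2 values")
    res = stats.ks_2samp(r1, r2, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class CrossCorrSummary:
    """All per-mark-pair correlation outputs in one record."""

    marks: tuple
    j_pair: tuple
    r_xi: np.ndarray
    r_eta: np.ndarray
    p_eta: np.ndarray
    n_shared: int
    alpha: float
    alpha_corrected: float
    n_significant: int
    max_xi: MaxRecord
    max_eta: MaxRecord
    ordinary_r: float | None = None

    def to_json_dict(self) -> dict:
        return {
            "marks": list(self.marks),
            "J_pair": list(self.j_pair),
            "n_shared": self.n_shared,
            "alpha": self.alpha,
            "alpha_corrected": self.alpha_corrected,
            "n_significant": self.n_significant,
            "max_xi": {"value": self.max_xi.value,
                       "components": list(self.max_xi.components),
                       "r_eta_at_pair": self.max_xi.companion},
            "max_eta": {"value": self.max_eta.value,
                        "components": list(self.max_eta.components),
                        "r_xi_at_pair": self.max_eta.companion},
            "ordinary_r": self.ordinary_r,
        }


def cross_correlation_summary(res_a, res_b, marks=("A", "B"),
                              alpha: float = 1e-6, j_report: int = 5,
                              grid_points: int = 1000,
                              ordinary_r: float | None = None) -> CrossCorrSummary:
    """Compute the full cross-correlation record for one mark pair."""
    r_xi = eigenfunction_correlation(res_a, res_b, grid_points=grid_points)
    r_eta, p_eta, n_shared = score_correlation(res_a, res_b)
    _, n_sig, alpha_corr = bonferroni_significant(p_eta, alpha=alpha)
    max_xi, max_eta = max_summary(r_xi, r_eta, j_report=j_report)
    return CrossCorrSummary(
        marks=tuple(marks), j_pair=(r_xi.shape[0], r_xi.shape[1]),
        r_xi=r_xi, r_eta=r_eta, p_eta=p_eta, n_shared=n_shared,
        alpha=alpha, alpha_corrected=alpha_corr, n_significant=n_sig,
        max_xi=max_xi, max_eta=max_eta, ordinary_r=ordinary_r,
    )
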