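"""Association of functional principal component scores with gene expression.

Two views are provided: per-component Pearson correlation between scores
and RPKM values, and quantile contrasts in which anchors are ranked by the
score of one component, cut into equal-count quantile bins, and expression
in the lowest (Q1) and highest (Q10) bins is compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionTable",
    "read_expression_table",
    "score_expression_correlation",
    "quantile_bins",
    "quantile_expression_test",
    "cross_mark_quantile_comparison",
]


@dataclass
class ExpressionTable:
    """Mapping region_id -> non-negative expression value (RPKM)."""

    entries: pd.Series  # index region_id, float values

    def __post_init__(self):
        if not isinstance(self.entries, pd.Series):
            self.entries = pd.Series(self.entries, dtype=float)
        self.entries = self.entries.astype(float)
        self.entries.index = self.entries.index.astype(str)
        if self.entries.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression table")
        vals = self.entries.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite expression values")
        if np.any(vals < 0):
            raise ValueError("negative expression values")

    def __len__(self) -> int:
        return len(self.entries)


def read_expression_table(path) -> ExpressionTable:
    """TSV with required header columns gene_id, rpkm."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("gene_id", "rpkm"):
        if col not in df.columns:
            raise ValueError(f"{path}: expression TSV must have a "
                             f"'{col}' column")
    return ExpressionTable(entries=pd.Series(
        df["rpkm"].to_numpy(dtype=float), index=df["gene_id"].astype(str)))


def _shared(result, expr: ExpressionTable):
    """Inner join of fitted regions with expression ids, result order kept."""
    ids = [str(r) for r in result.region_ids_]
    mask = [rid in expr.entries.index for rid in ids]
    shared_ids = [rid for rid, m in zip(ids, mask) if m]
    if len(shared_ids) < 3:
        raise ValueError(
            f"need at least 3 shared region ids, got {len(shared_ids)}")
    scores = result.scores_[np.array(mask)]
    rpkm = expr.entries.loc[shared_ids].to_numpy()
    return shared_ids, scores, rpkm


def score_expression_correlation(result, expr: ExpressionTable,
                                 alpha: float = 1e-6,
                                 log2_transform: bool = False) -> pd.DataFrame:
    """Per-component Pearson correlation of scores with expression.

    Returns a DataFrame with columns component (1-based), r, p, significant;
    the significance threshold is applied per component (no Bonferroni),
    as in genome-scale correlation screens at a stringent fixed alpha.
    """
    _, scores, rpkm = _shared(result, expr)
    y = np.log2(rpkm + 1.0) if log2_transform else rpkm
    n = len(y)
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    rows = []
    for k in range(scores.shape[1]):
        x = scores[:, k]
        xc = x - x.mean()
        sx = np.sqrt((xc**2).sum())
        if sx == 0 or sy == 0:
            r, p = 0.0, 1.0
        else:
            r = float(np.clip((xc @ yc) / (sx * sy), -1, 1))
            t = r * np.sqrt((n - 2) / max(1.0 - r**2, 1e-300))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        rows.append({"component": k + 1, "r": r, "p": p,
                     "significant": p <= alpha})
    return pd.DataFrame(rows)


def quantile_bins(n: int, n_quantiles: int) -> list[np.ndarray]:
    """Index arrays of equal-count bins; remainder spread over lowest bins."""
    base, rem = divmod(n, n_quantiles)
    sizes = [base + (1 if q < rem else 0) for q in range(n_quantiles)]
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [np.arange(edges[q], edges[q + 1]) for q in range(n_quantiles)]


@dataclass
class QuantileTestRecord:
    component: int
    n_quantiles: int
    q_low_ids: list
    q_high_ids: list
    mean_low: float
    mean_high: float
    t_welch: float
    p_welch: float
    t_rank_paired: float
    p_rank_paired: float


def _welch(x: np.ndarray, y: np.ndarray):
    """Welch two-sample t-test; degenerate all-equal input gives (0, 1)."""
    if x.std() == 0 and y.std() == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return np.inf, 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def quantile_expression_test(result, expr: ExpressionTable, component: int,
                             n_quantiles: int = 10) -> QuantileTestRecord:
    """Expression contrast between the lowest and highest score quantiles.

    Regions are ranked by the score of `component` (1-based; ties keep the
    fitted region order) and cut into `n_quantiles` equal-count bins.  The
    primary statistic is a Welch two-sample t-test between Q1 and Q_top
    expression; a rank-paired variant (i-th order statistic of Q1 paired
    with i-th of Q_top after truncation to equal length) is also reported.
    """
    if not 1 <= component <= result.n_components_:
        raise ValueError(f"component {component} outside 1..{result.n_components_}")
    ids, scores, rpkm = _shared(result, expr)
    order = np.argsort(scores[:, component - 1], kind="mergesort")
    bins = quantile_bins(len(ids), n_quantiles)
    if min(len(b) for b in bins) < 2:
        raise ValueError("need at least 2 regions per quantile")
    lo, hi = order[bins[0]], order[bins[-1]]
    x_lo = rpkm[lo]
    x_hi = rpkm[hi]
    t_w, p_w = _welch(x_lo, x_hi)
    m = min(len(x_lo), len(x_hi))
    a = np.sort(x_lo)[:m]
    b = np.sort(x_hi)[:m]
    d = b - a
    if np.all(d == d[0]):
        t_p, p_p = (0.0, 1.0) if d[0] == 0 else (np.inf, 0.0)
    else:
        res = stats.ttest_rel(b, a)
        t_p, p_p = float(res.statistic), float(res.pvalue)
    return QuantileTestRecord(
        component=component, n_quantiles=n_quantiles,
        q_low_ids=[ids[i] for i in lo], q_high_ids=[ids[i] for i in hi],
        mean_low=float(x_lo.mean()), mean_high=float(x_hi.mean()),
        t_welch=t_w, p_welch=p_w, t_rank_paired=t_p, p_rank_paired=p_p,
    )


@dataclass
class CrossMarkQuantileRecord:
    component: int
    quantile_index: int
    n_a: int
    n_b: int
    jaccard: float
    t_welch: float
    p_welch: float


def cross_mark_quantile_comparison(res_a, res_b, expr: ExpressionTable,
                                   component: int, quantile_index: int,
                                   n_quantiles: int = 10) -> CrossMarkQuantileRecord:
    """Compare expression of the genes falling in the same score quantile of
    two different marks.

    The gene sets in quantile `quantile_index` (1-based, 1 = lowest) of
    `component` are selected per mark; their expression values are compared
    with a Welch t-test (identical sets give p = 1 by convention) and the
    Jaccard overlap of the sets is reported as a diagnostic.
    """
    sets = []
    for res in (res_a, res_b):
        ids, scores, rpkm = _shared(res, expr)
        order = np.argsort(scores[:, component - 1], kind="mergesort")
        bins = quantile_bins(len(ids), n_quantiles)
        if not 1 <= quantile_index <= n_quantiles:
            raise ValueError("quantile_index outside range")
        if min(len(b) for b in bins) < 2:
            raise ValueError("need at least 2 regions per quantile")
        sel = order[bins[quantile_index - 1]]
        sets.append(({ids[i] for i in sel}, rpkm[sel]))
    (set_a, x_a), (set_b, x_b) = sets
    jacc = len(set_a & set_b) / len(set_a | set_b) if (set_a | set_b) else 1.0
    if set_a == set_b:
        t_w, p_w = 0.0, 1.0
    else:
        t_w, p_w = _welch(x_a, x_b)
    return CrossMarkQuantileRecord(
        component=component, quantile_index=quantile_index,
        n_a=len(x_a), n_b=len(x_b), jaccard=float(jacc),
        t_welch=t_w, p_welch=p_w,
    )
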