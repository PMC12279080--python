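"""Statistical validation toolkit.

QC filtering, Wilcoxon rank-sum tests, Benjamini-Hochberg adjustment,
Pearson's p-value combination, gene-set enrichment fractions between
conditions, and 1-D Wasserstein distribution-shift distances.

Conventions that matter
-----------------------
* Pearson's combination statistic is P = -2 * sum(log(1 - p_i)), referred to
  the LOWER tail of a chi-squared distribution with 2n degrees of freedom, so
  that small input p-values give a small combined p and n=1 recovers the
  input exactly. The method therefore emphasizes the LARGE p-values in a set:
  a single p_i near 1 drives P toward +inf and the combined p toward 1.
* Rank-sum tests use exact enumeration when the pooled sample is small
  (n+m <= 20) and tie-free, and the tie-corrected, continuity-corrected
  normal approximation otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CombinedTestResult",
    "EnrichmentSummary",
    "qc_filter",
    "rank_sum_test",
    "rank_sum_matrix",
    "bh_adjust",
    "pearson_combine",
    "geneset_enrichment",
    "celltype_combined_enrichment",
    "wasserstein_shift",
]

EXACT_MAX_N = 20


@dataclass
class CombinedTestResult:
    """Pearson-combined evidence for one gene set (optionally one cell type)."""

    name: str
    statistic: float
    df: int
    combined_p: float
    n: int
    degenerate: bool = False  # some p_i == 1 -> statistic infinite
    cell_type: str | None = None


@dataclass
class EnrichmentSummary:
    """Fractions of a gene set significantly up/down between two groups."""

    name: str
    n_tested: int
    n_up: int
    n_down: int
    table: pd.DataFrame  # per gene: statistic, p, q, direction

    @property
    def frac_up(self) -> float:
        return self.n_up / self.n_tested if self.n_tested else 0.0

    @property
    def frac_down(self) -> float:
        return self.n_down / self.n_tested if self.n_tested else 0.0


# ---------------------------------------------------------------------------
# QC

def qc_filter(adata, min_counts: float = 500, min_genes: int = 400, min_gene_counts: float = 50):
    """Remove low-quality cells, then low-abundance genes.

    Cells with total counts < ``min_counts`` or fewer than ``min_genes``
    expressed (nonzero) genes are removed first; genes with total counts
    < ``min_gene_counts`` across the remaining cells are removed second.
    Returns a filtered copy.
    """
    X = adata.X
    if sparse.issparse(X):
        cell_tot = np.asarray(X.sum(axis=1)).ravel()
        cell_ngene = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        cell_tot = X.sum(axis=1)
        cell_ngene = (X > 0).sum(axis=1)
    keep_cells = (cell_tot >= min_counts) & (cell_ngene >= min_genes)
    out = adata[keep_cells].copy()
    Xc = out.X
    gene_tot = (np.asarray(Xc.sum(axis=0)).ravel() if sparse.issparse(Xc)
                else np.asarray(Xc).sum(axis=0))
    keep_genes = gene_tot >= min_gene_counts
    out = out[:, keep_genes].copy()
    logger.info("qc_filter: kept %d/%d cells and %d/%d genes",
                int(keep_cells.sum()), adata.n_obs, int(keep_genes.sum()), adata.n_vars)
    if out.n_obs == 0 or out.n_vars == 0:
        raise ValueError("qc_filter removed all cells or all genes")
    return out


# ---------------------------------------------------------------------------
# Rank-sum test

def rank_sum_test(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Two-sided (by default) Wilcoxon rank-sum / Mann-Whitney U test.

    Returns ``(statistic, p)`` where the statistic is the Mann-Whitney U of
    the first sample. Exact enumeration is used for tie-free pooled samples
    with n+m <= 20; otherwise the normal approximation with tie and
    continuity corrections. If every pooled value is identical the test is
    degenerate and p = 1 is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    n = x.size + y.size
    tie_free = np.unique(pooled).size == n
    method = "exact" if (n <= EXACT_MAX_N and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def rank_sum_matrix(X_a, X_b, alternative: str = "two-sided"):
    """Column-wise rank-sum tests between two matrices (cells x genes).

    Vectorized over genes with the same method-selection rule as
    :func:`rank_sum_test`, so scalar and matrix paths agree exactly.
    Returns ``(U, p, delta)`` arrays where ``delta`` is the difference of
    column means (group a minus group b), used for direction calls.
    """
    X_a = np.asarray(X_a.todense()) if sparse.issparse(X_a) else np.asarray(X_a, dtype=float)
    X_b = np.asarray(X_b.todense()) if sparse.issparse(X_b) else np.asarray(X_b, dtype=float)
    n_genes = X_a.shape[1]
    U = np.empty(n_genes)
    p = np.empty(n_genes)
    for j in range(n_genes):
        U[j], p[j] = rank_sum_test(X_a[:, j], X_b[:, j], alternative=alternative)
    delta = X_a.mean(axis=0) - X_b.mean(axis=0)
    return U, p, delta


# ---------------------------------------------------------------------------
# Multiple testing and p-value combination

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_combine(pvals, name: str = "", cell_type: str | None = None) -> CombinedTestResult:
    """Combine p-values with Pearson's method.

    P = -2 * sum_i log(1 - p_i) follows chi-squared with 2n degrees of
    freedom under the null; the combined p is the lower-tail probability at
    P, so uniformly small p_i yield a small combined p. Any p_i exactly 1
    makes P infinite; the result is flagged degenerate with combined p = 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if np.any(p == 1.0):
        return CombinedTestResult(name=name, statistic=float("inf"), df=2 * n,
                                  combined_p=1.0, n=n, degenerate=True, cell_type=cell_type)
    P = -2.0 * np.sum(np.log1p(-p))
    combined = float(sps.chi2.cdf(P, df=2 * n))
    return CombinedTestResult(name=name, statistic=float(P), df=2 * n,
                              combined_p=combined, n=n, cell_type=cell_type)


# ---------------------------------------------------------------------------
# Gene-set enrichment between two groups of cells

def _dense_expr(adata, genes, mask):
    sub = adata[mask, genes].X
    return np.asarray(sub.todense()) if sparse.issparse(sub) else np.asarray(sub, dtype=float)


def geneset_enrichment(adata, gene_set, group_a, group_b, fdr: float = 0.05,
                       name: str = "") -> EnrichmentSummary:
    """Per-gene rank-sum tests of a gene set between two cell groups.

    ``group_a``/``group_b`` are boolean masks over cells. BH adjustment is
    applied within the set; a gene is called up (down) if q <= fdr and its
    mean expression is higher (lower) in group a.
    """
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    if not group_a.any() or not group_b.any():
        raise ValueError("both groups must contain at least one cell")
    genes = [g for g in gene_set if g in set(adata.var_names)]
    if not genes:
        raise ValueError("gene set does not intersect the measured genes")
    Xa = _dense_expr(adata, genes, group_a)
    Xb = _dense_expr(adata, genes, group_b)
    U, p, delta = rank_sum_matrix(Xa, Xb)
    q = bh_adjust(p)
    sig = q <= fdr
    direction = np.where(~sig, "ns", np.where(delta > 0, "up", np.where(delta < 0, "down", "ns")))
    table = pd.DataFrame({"gene": genes, "statistic": U, "p": p, "q": q,
                          "direction": direction}).set_index("gene")
    return EnrichmentSummary(name=name, n_tested=len(genes),
                             n_up=int((direction == "up").sum()),
                             n_down=int((direction == "down").sum()),
                             table=table)


def celltype_combined_enrichment(adata, gene_sets, condition_col: str = "condition",
                                 control: str = "control",
                                 celltype_col: str = "cell_type",
                                 treatments: list[str] | None = None,
                                 alpha: float = 0.05) -> pd.DataFrame:
    """Pearson-combined per-gene evidence for each cell type x gene set.

    Within each cell type, every gene of a set is tested (rank-sum) between
    treated and control cells; the per-gene p-values are combined with
    Pearson's method. All non-control conditions are pooled into one treated
    group by default (``treatments`` restricts the pool to the named
    conditions). Cell types missing either condition are skipped with a log
    entry. Returns a tidy frame with one row per (cell type, gene set).
    """
    sets = gene_sets.as_dict() if hasattr(gene_sets, "as_dict") else {k: set(v) for k, v in gene_sets.items()}
    cond = adata.obs[condition_col].astype(str).to_numpy()
    ct = adata.obs[celltype_col].astype(str).to_numpy()
    is_control = cond == control
    is_treated = np.isin(cond, treatments) if treatments is not None else ~is_control
    rows = []
    for cell_type in pd.unique(ct):
        m_type = ct == cell_type
        m_a = m_type & is_treated
        m_b = m_type & is_control
        if not m_a.any() or not m_b.any():
            logger.info("celltype_combined_enrichment: %r missing a condition, skipped", cell_type)
            continue
        for set_name, symbols in sets.items():
            genes = [g for g in symbols if g in set(adata.var_names)]
            if not genes:
                continue
            Xa = _dense_expr(adata, genes, m_a)
            Xb = _dense_expr(adata, genes, m_b)
            _, p, _ = rank_sum_matrix(Xa, Xb)
            res = pearson_combine(p, name=set_name, cell_type=str(cell_type))
            rows.append({"cell_type": str(cell_type), "gene_set": set_name,
                         "n_genes": res.n, "statistic": res.statistic, "df": res.df,
                         "combined_p": res.combined_p,
                         "significant": res.combined_p <= alpha})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distribution shift

def wasserstein_shift(adata, group_a, group_b, celltype_col: str = "cell_type",
                      max_cells: int = 5000, seed: int = 0) -> pd.Series:
    """Mean per-gene 1-D Wasserstein-1 distance between two groups, per cell type.

    For each cell type present in both groups the expression distribution of
    every gene is compared with the empirical Wasserstein-1 distance and the
    distances are averaged over genes. Groups larger than ``max_cells`` are
    subsampled without replacement with the given seed. Cell types absent
    from either group are skipped.
    """
    rng = np.random.default_rng(seed)
    group_a = np.asarray(group_a, dtype=bool)
    group_b = np.asarray(group_b, dtype=bool)
    ct = adata.obs[celltype_col].astype(str).to_numpy()
    out = {}
    for cell_type in pd.unique(ct):
        m_type = ct == cell_type
        idx_a = np.flatnonzero(m_type & group_a)
        idx_b = np.flatnonzero(m_type & group_b)
        if idx_a.size == 0 or idx_b.size == 0:
            continue
        if idx_a.size > max_cells:
            idx_a = rng.choice(idx_a, size=max_cells, replace=False)
        if idx_b.size > max_cells:
            idx_b = rng.choice(idx_b, size=max_cells, replace=False)
        Xa = adata.X[idx_a]
        Xb = adata.X[idx_b]
        Xa = np.asarray(Xa.todense()) if sparse.issparse(Xa) else np.asarray(Xa, dtype=float)
        Xb = np.asarray(Xb.todense()) if sparse.issparse(Xb) else np.asarray(Xb, dtype=float)
        d = [sps.wasserstein_distance(Xa[:, j], Xb[:, j]) for j in range(Xa.shape[1])]
        out[str(cell_type)] = float(np.mean(d))
    return pd.Series(out, name="wasserstein", dtype=float)
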