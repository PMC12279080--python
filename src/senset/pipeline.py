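"""Signature derivation pipeline.

Orchestrates the discovery of a senescence gene signature from an
age-structured cohort: partition cells into age groups Y (< 30), M (30-50)
and A (>= 50); keep cell types with enough cells in every group; per cell
type, project onto the top principal components of the prior-knowledge gene
union U and call senescent cells in the aged group with the PUc classifier
(positives = Y, unlabeled train = M, unlabeled test = A); run rank-sum
differential expression between called-senescent and healthy aged cells,
restricted to U; select genes significant in at least k cell types.

Two distinct reporting thresholds apply downstream of the calls: cell types
with fewer than 10 negative calls are flagged not reportable in summaries,
and cell types with fewer than 20 negatives are excluded from differential
expression altogether.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import puc as puc_mod
from .gene_sets import restrict_to_measured
from .stats import bh_adjust, rank_sum_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "AgeGroupPartition",
    "SenescenceCallTable",
    "SenSetResult",
    "partition_by_age",
    "filter_cell_types",
    "call_senescent_cells",
    "de_senescent_vs_healthy",
    "assemble_senset",
    "summarize_fractions",
    "derive_signature",
]


@dataclass
class AgeGroupPartition:
    """Per-cell age-group labels: Y = [0, b0), M = [b0, b1), A = [b1, inf)."""

    labels: pd.Series  # values in {"Y", "M", "A"}, indexed by cell id
    boundaries: tuple[float, float] = (30.0, 50.0)

    def mask(self, group: str) -> np.ndarray:
        return (self.labels == group).to_numpy()


@dataclass
class SenescenceCallTable:
    """Per-cell +1/-1 calls (aged group only) with per-cell-type summaries."""

    calls: pd.DataFrame    # cell_id (index), cell_type, call in {+1, -1}
    summary: pd.DataFrame  # cell_type (index), n_cells, n_negative, fraction_negative, reportable
    min_report: int = 10


@dataclass
class SenSetResult:
    """Genes significant in >= k cell types, with per-cell-type directions."""

    genes: list[str]
    counts: pd.Series          # per gene: number of cell types significant
    directions: pd.DataFrame   # genes x cell types: "up"/"down"/"ns"
    k: int = 6
    fdr: float = 0.05


def partition_by_age(metadata: pd.DataFrame, boundaries: tuple[float, float] = (30.0, 50.0),
                     age_col: str = "age") -> AgeGroupPartition:
    """Assign cells to age groups by half-open intervals.

    Y = age < b0, M = b0 <= age < b1, A = age >= b1 (defaults 30, 50: a
    30-year-old is M, a 50-year-old is A). Cells with missing age are
    excluded with a warning; all ages missing is an error.
    """
    b0, b1 = boundaries
    if not b0 < b1:
        raise ValueError("age boundaries must be increasing")
    age = pd.to_numeric(metadata[age_col], errors="coerce")
    missing = age.isna()
    if len(metadata) > 0 and missing.all():
        raise ValueError("all cells have missing age")
    if missing.any():
        logger.warning("partition_by_age: excluding %d cell(s) with missing age",
                       int(missing.sum()))
    if (age.dropna() < 0).any():
        raise ValueError("ages must be nonnegative")
    labels = pd.Series(pd.NA, index=metadata.index, dtype="object")
    labels[age < b0] = "Y"
    labels[(age >= b0) & (age < b1)] = "M"
    labels[age >= b1] = "A"
    return AgeGroupPartition(labels=labels.dropna(), boundaries=(float(b0), float(b1)))


def filter_cell_types(adata, partition: AgeGroupPartition, min_cells: int = 50,
                      celltype_col: str = "cell_type") -> list[str]:
    """Cell types with at least ``min_cells`` cells in each of Y, M and A."""
    ct = adata.obs.loc[partition.labels.index, celltype_col].astype(str)
    counts = pd.crosstab(ct, partition.labels)
    eligible = []
    for cell_type, row in counts.iterrows():
        if all(row.get(g, 0) >= min_cells for g in ("Y", "M", "A")):
            eligible.append(str(cell_type))
        else:
            logger.info("filter_cell_types: dropping %r (Y/M/A counts %s)",
                        cell_type, row.to_dict())
    if not eligible:
        raise ValueError(f"no cell type has >= {min_cells} cells in every age group")
    return sorted(eligible)


def _nonsmoker_mask(adata, exclude_smokers: bool) -> np.ndarray:
    if not exclude_smokers or "smoking_status" not in adata.obs:
        return np.ones(adata.n_obs, dtype=bool)
    return adata.obs["smoking_status"].astype(str).isin(["never", "unknown"]).to_numpy()


def call_senescent_cells(adata, partition: AgeGroupPartition, union_genes, *,
                         alpha: float = 0.9, n_components: int = 10,
                         min_cells: int = 50, min_report: int = 10,
                         exclude_smokers: bool = True,
                         celltype_col: str = "cell_type",
                         puc_options: dict | None = None,
                         seed: int = 0) -> SenescenceCallTable:
    """Call senescent cells in the aged group, independently per cell type.

    Per eligible cell type: PCA (top ``n_components``) is fit on the pooled
    cells of that type across all age groups, restricted to the measured
    part of the prior-gene union; the PUc classifier is trained with
    positives = Y, unlabeled train = M, unlabeled test = A; the sign of the
    decision function labels each aged cell healthy (+1) or senescent (-1).
    Cell types with fewer than ``min_report`` negative calls are flagged as
    not reportable.
    """
    keep = _nonsmoker_mask(adata, exclude_smokers)
    sub = adata[keep].copy()
    part = AgeGroupPartition(labels=partition.labels[partition.labels.index.isin(sub.obs_names)],
                             boundaries=partition.boundaries)
    genes = restrict_to_measured(union_genes, sub)
    eligible = filter_cell_types(sub, part, min_cells=min_cells, celltype_col=celltype_col)
    rng = np.random.default_rng(seed)

    call_frames, summary_rows = [], []
    for cell_type in eligible:
        m_type = (sub.obs[celltype_col].astype(str) == cell_type).to_numpy()
        m_type &= sub.obs_names.isin(part.labels.index)
        type_view = sub[m_type]
        labels = part.labels[type_view.obs_names]
        try:
            proj = puc_mod.fit_pca(type_view, genes=genes, n_components=n_components)
            scores = proj.transform(type_view)
            Z = {g: scores[(labels == g).to_numpy()] for g in ("Y", "M", "A")}
            model = puc_mod.fit_puc(Z["Y"], Z["M"], Z["A"], alpha=alpha,
                                    seed=int(rng.integers(2**31)),
                                    **(puc_options or {}))
            calls = puc_mod.classify(model, Z["A"])
        except Exception as err:
            raise RuntimeError(f"PUc failed for cell type {cell_type!r}: {err}") from err
        a_cells = type_view.obs_names[(labels == "A").to_numpy()]
        call_frames.append(pd.DataFrame({"cell_type": cell_type, "call": calls}, index=a_cells))
        n_cells = int(calls.size)
        n_neg = int((calls == -1).sum())
        summary_rows.append({"cell_type": cell_type, "n_cells": n_cells,
                             "n_negative": n_neg,
                             "fraction_negative": n_neg / n_cells,
                             "reportable": n_neg >= min_report})
        logger.info("call_senescent_cells: %s: %d/%d negative (%.1f%%)",
                    cell_type, n_neg, n_cells, 100 * n_neg / n_cells)
    calls = pd.concat(call_frames)
    calls.index.name = "cell_id"
    summary = pd.DataFrame(summary_rows).set_index("cell_type")
    return SenescenceCallTable(calls=calls, summary=summary, min_report=min_report)


def de_senescent_vs_healthy(adata, calls: SenescenceCallTable, union_genes,
                            fdr: float = 0.05, min_snc: int = 20) -> pd.DataFrame:
    """Rank-sum differential expression between called-senescent and healthy aged cells.

    Only genes of the prior union are tested; BH adjustment is applied
    within each cell type. Cell types with fewer than ``min_snc`` negative
    calls are skipped with a log entry. Returns a tidy frame with columns
    gene, cell_type, statistic, p, q, direction. Comparisons use only cells
    present in the call table (i.e. aged-group cells).
    """
    genes = restrict_to_measured(union_genes, adata)
    frames = []
    for cell_type, grp in calls.calls.groupby("cell_type", sort=True, observed=True):
        n_neg = int((grp["call"] == -1).sum())
        n_pos = int((grp["call"] == 1).sum())
        if n_neg < min_snc or n_pos == 0:
            logger.info("de_senescent_vs_healthy: skipping %r (%d negatives, %d positives)",
                        cell_type, n_neg, n_pos)
            continue
        neg_ids = grp.index[grp["call"] == -1]
        pos_ids = grp.index[grp["call"] == 1]
        X_neg = adata[neg_ids, genes].X
        X_pos = adata[pos_ids, genes].X
        U, p, delta = rank_sum_matrix(X_neg, X_pos)
        q = bh_adjust(p)
        sig = q <= fdr
        direction = np.where(~sig, "ns",
                             np.where(delta > 0, "up", np.where(delta < 0, "down", "ns")))
        frames.append(pd.DataFrame({"gene": genes, "cell_type": cell_type, "statistic": U,
                                    "p": p, "q": q, "direction": direction}))
    if not frames:
        return pd.DataFrame(columns=["gene", "cell_type", "statistic", "p", "q", "direction"])
    return pd.concat(frames, ignore_index=True)


def assemble_senset(de_table: pd.DataFrame, k: int = 6, fdr: float = 0.05) -> SenSetResult:
    """Select genes significant (q <= fdr) in at least k cell types.

    Up- and downregulation both count toward the tally; directional
    consistency across cell types is not required. Per-cell-type directions
    are retained in the result.
    """
    if de_table.empty:
        return SenSetResult(genes=[], counts=pd.Series(dtype=int),
                            directions=pd.DataFrame(), k=k, fdr=fdr)
    sig = de_table[(de_table["q"] <= fdr) & (de_table["direction"] != "ns")]
    counts = sig.groupby("gene", observed=True).size().sort_values(ascending=False)
    selected = sorted(counts.index[counts >= k])
    directions = de_table.pivot_table(index="gene", columns="cell_type", values="direction",
                                      aggfunc="first", fill_value="ns")
    return SenSetResult(genes=selected, counts=counts,
                        directions=directions.loc[directions.index.intersection(selected)].reindex(selected),
                        k=k, fdr=fdr)


def summarize_fractions(calls: SenescenceCallTable) -> pd.DataFrame:
    """Per-cell-type negative-call tallies sorted by percentage (descending)."""
    s = calls.summary.copy()
    s["percentage"] = 100.0 * s["fraction_negative"]
    return s.sort_values("percentage", ascending=False)


@dataclass
class DerivationResult:
    """Everything a derivation run produces."""

    partition: AgeGroupPartition
    calls: SenescenceCallTable
    de_table: pd.DataFrame
    senset: SenSetResult
    union: list[str] = field(default_factory=list)


def derive_signature(adata, prior_lists, *, boundaries=(30.0, 50.0), alpha: float = 0.9,
                     n_components: int = 10, min_cells: int = 50, min_report: int = 10,
                     min_snc: int = 20, fdr: float = 0.05, k: int = 6,
                     exclude_smokers: bool = True, puc_options: dict | None = None,
                     seed: int = 0) -> DerivationResult:
    """Run the full derivation: age partition -> PUc calls -> DE -> selection."""
    from .gene_sets import union_genes as _union

    U = _union(prior_lists) if hasattr(prior_lists, "sets") else sorted(set().union(
        *[set(v) for v in prior_lists.values()]))
    partition = partition_by_age(adata.obs, boundaries=boundaries)
    calls = call_senescent_cells(adata, partition, U, alpha=alpha,
                                 n_components=n_components, min_cells=min_cells,
                                 min_report=min_report, exclude_smokers=exclude_smokers,
                                 puc_options=puc_options, seed=seed)
    de_table = de_senescent_vs_healthy(adata, calls, U, fdr=fdr, min_snc=min_snc)
    senset = assemble_senset(de_table, k=k, fdr=fdr)
    return DerivationResult(partition=partition, calls=calls, de_table=de_table,
                            senset=senset, union=list(U))
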