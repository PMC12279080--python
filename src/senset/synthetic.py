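"""Synthetic age-structured single-cell cohorts with planted ground truth.

The generator emulates the statistical structure the discovery pipeline
assumes, so that every downstream stage can be tested against known truth:

* three age groups (Y < 30, M 30-50, A >= 50) with several donors each;
* multiple cell types with distinct negative-binomial expression baselines;
* a minority senescent subpopulation (default 10%) whose expression is
  shifted on a planted marker subset (signed, log scale). It is present in
  the aged group and, by default at the same rate, in the middle group:
  positive-unlabeled learning models the unlabeled populations as mixtures
  of healthy and senescent cells, so the unlabeled training group must
  itself contain negatives for the problem to be identifiable (only the
  youngest, labeled-positive group is senescence-free);
* a disjoint "aging-program" covariate shift applied to every aged cell,
  healthy and senescent alike, emulating non-senescence aging hallmarks
  (inflammation, epigenetic drift) that belong to the aged donor. Because
  the program is shared by both aged subpopulations it cancels in the
  within-aged-group comparison — exactly the confounder the discovery
  design controls for by never comparing across age groups;
* several noisy, partially overlapping prior gene lists whose union forms
  the search space the pipeline is restricted to.

Counts are drawn from a negative-binomial model with per-cell-type lognormal
gene baselines, then library-size normalized to the median depth and log1p
transformed. All effects are additive on the log-mean scale, matching the
rank-based tests used downstream. All randomness flows from a single seed;
substreams are derived from it by fixed offsets, so identical seeds yield
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "PriorListSpec",
    "CohortConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_prior_lists",
    "generate_treatment_experiment",
]

_AGE_RANGES = {"Y": (18, 30), "M": (30, 50), "A": (50, 85)}


@dataclass(frozen=True)
class PriorListSpec:
    """One noisy prior gene list: size, true-marker recall, the rest decoys."""

    name: str
    n_genes: int = 120
    marker_recall: float = 0.6

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("prior list size must be positive")
        if not (0.0 <= self.marker_recall <= 1.0):
            raise ValueError(f"marker recall must lie in [0, 1], got {self.marker_recall}")

    def n_true(self, n_markers: int) -> int:
        return int(round(self.marker_recall * n_markers))

    def decoy_fraction(self, n_markers: int) -> float:
        return 1.0 - self.n_true(n_markers) / self.n_genes


def _default_lists() -> tuple[PriorListSpec, ...]:
    return tuple(PriorListSpec(name=f"prior_{c}") for c in "ABCD")


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort; defaults are the study conditions."""

    n_donors_per_group: int = 4
    n_cell_types: int = 8
    cells_per_type_per_group: int = 1000
    n_genes: int = 2000
    n_true_markers: int = 50
    marker_effect: float = 1.0          # log-scale shift magnitude, signed per gene
    marker_up_fraction: float = 0.7     # fraction of markers planted upregulated
    senescent_fraction_aged: float = 0.1
    senescent_fraction_mid: float | None = None  # None: same as the aged group
    aging_shift_genes: int = 100
    aging_shift_magnitude: float = 0.5  # log-scale shift on healthy aged cells
    dispersion: float = 0.3             # NB overdispersion: var = mu + dispersion * mu^2
    baseline_log_mean: float = -1.0
    baseline_log_sd: float = 1.0
    planted_gene_quantile: float = 0.5  # plant effects only on genes above this baseline quantile
    celltype_log_sd: float = 0.3
    cell_size_log_sd: float = 0.3
    treatment_regulation_prob: float = 0.8
    prior_list_specs: tuple[PriorListSpec, ...] = field(default_factory=_default_lists)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_donors_per_group", "n_cell_types", "cells_per_type_per_group",
                     "n_genes", "n_true_markers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.senescent_fraction_aged <= 1.0):
            raise ValueError("senescent_fraction_aged must lie in [0, 1]")
        if self.senescent_fraction_mid is not None and not (0.0 <= self.senescent_fraction_mid <= 1.0):
            raise ValueError("senescent_fraction_mid must lie in [0, 1] or be None")
        if self.n_true_markers + self.aging_shift_genes > self.n_genes:
            raise ValueError("marker and aging-shift gene demand exceeds n_genes")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a synthetic cohort."""

    senescent: pd.Series                 # boolean, indexed by cell id
    markers: pd.DataFrame                # index: gene; column "direction" in {+1, -1}
    aging_genes: list[str]
    treatment_directions: pd.DataFrame | None = None  # genes x cell types, {+1, 0, -1}

    @property
    def marker_genes(self) -> list[str]:
        return list(self.markers.index)

    def to_tsv(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.senescent.rename("senescent").to_frame().to_csv(outdir / "truth_cells.tsv", sep="\t")
        self.markers.to_csv(outdir / "truth_markers.tsv", sep="\t")
        pd.Series(self.aging_genes, name="gene").to_csv(outdir / "truth_aging_genes.tsv",
                                                        sep="\t", index=False)
        if self.treatment_directions is not None:
            self.treatment_directions.to_csv(outdir / "truth_treatment_directions.tsv", sep="\t")


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    # fixed-offset substreams: one global seed, independent generators per purpose
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _plant_genes(config: CohortConfig, base_log_mean: np.ndarray):
    # markers and aging genes are planted on expressed genes only: an effect on
    # a gene at the detection floor would be no effect at all in the measured data
    rng = _rng(config, 1)
    genes = np.array(_gene_names(config.n_genes))
    floor = np.quantile(base_log_mean, config.planted_gene_quantile)
    eligible = np.flatnonzero(base_log_mean >= floor)
    n_demand = config.n_true_markers + config.aging_shift_genes
    if n_demand > eligible.size:
        raise ValueError("marker and aging-shift gene demand exceeds the expressed genes")
    chosen = rng.choice(eligible, size=n_demand, replace=False)
    marker_idx = chosen[:config.n_true_markers]
    aging_idx = chosen[config.n_true_markers:]
    n_up = int(round(config.marker_up_fraction * config.n_true_markers))
    directions = np.ones(config.n_true_markers, dtype=int)
    directions[n_up:] = -1
    rng.shuffle(directions)
    markers = pd.DataFrame({"direction": directions}, index=genes[marker_idx])
    markers.index.name = "gene"
    return genes, markers, marker_idx, aging_idx


def _baselines(config: CohortConfig):
    rng = _rng(config, 2)
    base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=config.n_genes)
    type_eff = rng.normal(0.0, config.celltype_log_sd,
                          size=(config.n_cell_types, config.n_genes))
    return base, base[None, :] + type_eff  # gene baselines, (cell types, genes) log means


def _nb_counts(rng, log_mu, dispersion):
    mu = np.exp(log_mu)
    if dispersion <= 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


def _normalize_log1p(counts: np.ndarray) -> np.ndarray:
    depth = counts.sum(axis=1, keepdims=True).astype(float)
    depth[depth == 0] = 1.0
    target = np.median(counts.sum(axis=1))
    if target == 0:
        target = 1.0
    return np.log1p(counts / depth * target).astype(np.float32)


def generate_cohort(config: CohortConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Generate an age-structured cohort with a planted senescent subpopulation.

    Returns a cells x genes AnnData (library-size normalized, log1p; raw
    counts in ``layers["counts"]``) and the accompanying truth. Cells in the
    aged group are senescent with probability ``senescent_fraction_aged``
    (middle group: ``senescent_fraction_mid``, defaulting to the same rate;
    the young group is senescence-free) and receive the signed marker effect
    on the true markers; every aged cell additionally receives the aging
    shift on the (disjoint) aging-program genes — the covariate shift.
    """
    base, log_mu_types = _baselines(config)
    genes, markers, marker_idx, aging_idx = _plant_genes(config, base)
    rng_age = _rng(config, 3)
    rng_state = _rng(config, 4)
    rng_counts = _rng(config, 5)
    rng_size = _rng(config, 6)

    marker_dir = markers["direction"].to_numpy()
    sen_frac = {"Y": 0.0, "A": config.senescent_fraction_aged,
                "M": (config.senescent_fraction_mid
                      if config.senescent_fraction_mid is not None
                      else config.senescent_fraction_aged)}
    blocks, obs_rows, sen_flags = [], [], []
    donor_ages = {}
    for group in ("Y", "M", "A"):
        lo, hi = _AGE_RANGES[group]
        for d in range(config.n_donors_per_group):
            donor_ages[f"{group}{d}"] = int(rng_age.integers(lo, hi))
    for t in range(config.n_cell_types):
        cell_type = f"CT{t:02d}"
        for group in ("Y", "M", "A"):
            n = config.cells_per_type_per_group
            log_mu = np.tile(log_mu_types[t], (n, 1))
            senescent = np.zeros(n, dtype=bool)
            if sen_frac[group] > 0:
                senescent = rng_state.random(n) < sen_frac[group]
            if senescent.any():
                log_mu[np.ix_(senescent, marker_idx)] += marker_dir * config.marker_effect
            if group == "A":
                log_mu[:, aging_idx] += config.aging_shift_magnitude
            log_mu += rng_size.normal(0.0, config.cell_size_log_sd, size=n)[:, None]
            counts = _nb_counts(rng_counts, log_mu, config.dispersion)
            blocks.append(counts)
            donors = np.array([f"{group}{i % config.n_donors_per_group}" for i in range(n)])
            for i in range(n):
                obs_rows.append({"donor_id": donors[i], "age": donor_ages[donors[i]],
                                 "smoking_status": "never", "cell_type": cell_type,
                                 "condition": "none", "sample_id": donors[i]})
            sen_flags.append(senescent)

    counts = np.vstack(blocks)
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell{i:06d}" for i in range(len(obs))]
    adata = ad.AnnData(X=_normalize_log1p(counts), obs=obs,
                       var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.layers["counts"] = counts.astype(np.int32)
    truth = SyntheticTruth(senescent=pd.Series(np.concatenate(sen_flags), index=adata.obs_names),
                           markers=markers, aging_genes=list(genes[aging_idx]))
    return adata, truth


def generate_prior_lists(config: CohortConfig, truth: SyntheticTruth):
    """Build noisy prior gene lists around the planted markers.

    Each list contains ``round(recall * n_true_markers)`` true markers
    sampled without replacement plus decoy genes drawn from the non-marker
    genes (decoys may include aging-program genes, so part of the covariate
    shift is visible inside the union — as with real prior lists).
    """
    from .gene_sets import GeneSetCollection

    rng = _rng(config, 7)
    genes = np.array(_gene_names(config.n_genes))
    marker_arr = np.array(truth.marker_genes)
    non_markers = genes[~np.isin(genes, marker_arr)]
    coll = GeneSetCollection()
    for spec in config.prior_list_specs:
        n_true = spec.n_true(len(marker_arr))
        if n_true > len(marker_arr):
            raise ValueError(f"list {spec.name!r}: recall demands more markers than exist")
        n_decoy = max(spec.n_genes - n_true, 0)
        picked = list(rng.choice(marker_arr, size=n_true, replace=False)) + \
                 list(rng.choice(non_markers, size=n_decoy, replace=False))
        rng.shuffle(picked)
        coll.add(spec.name, picked,
                 provenance=f"synthetic prior list (recall={spec.marker_recall}, "
                            f"decoy_fraction={spec.decoy_fraction(len(marker_arr)):.2f})")
    return coll


def generate_treatment_experiment(config: CohortConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Generate a paired control/treatment experiment with cell-type-specific effects.

    Donors contribute cells to a control arm and three senescence-induction
    treatment arms (labeled so downstream validation can pool the
    treatments). Per cell type, each planted marker gene is regulated under
    treatment with probability ``treatment_regulation_prob``, direction
    random, magnitude ``marker_effect`` on the log scale; the planted
    direction table is recorded in the truth.
    """
    base, log_mu_types = _baselines(config)
    genes, markers, marker_idx, _ = _plant_genes(config, base)
    rng_dir = _rng(config, 8)
    rng_counts = _rng(config, 9)
    rng_size = _rng(config, 10)
    rng_age = _rng(config, 11)

    conditions = ("control", "bleomycin", "doxorubicin", "irradiation")
    cell_types = [f"CT{t:02d}" for t in range(config.n_cell_types)]
    reg = rng_dir.random((config.n_genes, config.n_cell_types))
    sign = np.where(rng_dir.random((config.n_genes, config.n_cell_types)) < 0.5, 1, -1)
    direction = np.zeros((config.n_genes, config.n_cell_types), dtype=int)
    is_marker = np.isin(np.arange(config.n_genes), marker_idx)
    direction[is_marker] = np.where(reg[is_marker] < config.treatment_regulation_prob,
                                    sign[is_marker], 0)
    if config.marker_effect == 0:
        direction[:] = 0
    dir_table = pd.DataFrame(direction, index=genes, columns=cell_types)
    dir_table.index.name = "gene"

    donor_ages = {f"D{d}": int(rng_age.integers(50, 80))
                  for d in range(config.n_donors_per_group)}
    blocks, obs_rows = [], []
    for t, cell_type in enumerate(cell_types):
        shift = direction[:, t] * config.marker_effect
        for condition in conditions:
            n = config.cells_per_type_per_group
            log_mu = np.tile(log_mu_types[t], (n, 1))
            if condition != "control":
                log_mu += shift[None, :]
            log_mu += rng_size.normal(0.0, config.cell_size_log_sd, size=n)[:, None]
            blocks.append(_nb_counts(rng_counts, log_mu, config.dispersion))
            for i in range(n):
                donor = f"D{i % config.n_donors_per_group}"
                obs_rows.append({"donor_id": donor, "age": donor_ages[donor],
                                 "smoking_status": "never", "cell_type": cell_type,
                                 "condition": condition,
                                 "sample_id": f"{donor}_{condition}"})

    counts = np.vstack(blocks)
    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell{i:06d}" for i in range(len(obs))]
    adata = ad.AnnData(X=_normalize_log1p(counts), obs=obs,
                       var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.layers["counts"] = counts.astype(np.int32)
    truth = SyntheticTruth(senescent=pd.Series(False, index=adata.obs_names),
                           markers=markers, aging_genes=[],
                           treatment_directions=dir_table)
    return adata, truth
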