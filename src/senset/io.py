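"""Cohort readers/writers, run configuration, and result manifests.

A cohort is a cells x genes AnnData with gene symbols in ``var_names`` and
per-cell metadata columns ``donor_id``, ``age``, ``smoking_status``,
``cell_type``, ``condition``, ``sample_id`` in ``obs``. Two on-disk layouts
are supported: an MTX+TSV triplet (``matrix.mtx`` cells x genes,
``genes.tsv`` one symbol per line, ``cells.tsv`` metadata table) and an
h5ad container.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import io as spio, sparse

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_cohort", "write_cohort", "write_results", "validate_cohort"]

REQUIRED_OBS = ("donor_id", "age", "cell_type")
OPTIONAL_OBS = {"smoking_status": "unknown", "condition": "none", "sample_id": "unknown"}


@dataclass
class RunConfig:
    """All pipeline thresholds and options; loadable from a YAML file."""

    age_boundaries: tuple[float, float] = (30.0, 50.0)
    alpha: float = 0.9
    n_components: int = 10
    min_cells: int = 50
    min_report: int = 10
    min_snc: int = 20
    fdr: float = 0.05
    k: int = 6
    max_cells_wasserstein: int = 5000
    exclude_smokers: bool = True
    normalized: bool = True
    seed: int = 0

    def __post_init__(self):
        self.age_boundaries = tuple(float(b) for b in self.age_boundaries)
        if len(self.age_boundaries) != 2 or self.age_boundaries[0] >= self.age_boundaries[1]:
            raise ValueError("age_boundaries must be two increasing values")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")
        for name in ("n_components", "min_cells", "min_report", "min_snc", "k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["age_boundaries"] = list(self.age_boundaries)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d["age_boundaries"] = list(self.age_boundaries)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def validate_cohort(adata: ad.AnnData) -> ad.AnnData:
    """Check required metadata, fill optional columns, enforce invariants."""
    missing = [c for c in REQUIRED_OBS if c not in adata.obs.columns]
    if missing:
        raise ValueError(f"cohort metadata is missing required column(s): {missing}")
    for col, default in OPTIONAL_OBS.items():
        if col not in adata.obs.columns:
            adata.obs[col] = default
    if adata.var_names.duplicated().any():
        dups = adata.var_names[adata.var_names.duplicated()].unique().tolist()
        logger.warning("duplicate gene symbols disambiguated by suffixing: %s", dups[:5])
        adata.var_names_make_unique()
    X = adata.X
    mn = X.min() if not sparse.issparse(X) else X.data.min() if X.nnz else 0.0
    if mn < 0 or not np.isfinite(float(mn)):
        raise ValueError("expression values must be nonnegative and finite")
    return adata


def read_cohort(path, format: str = "auto") -> ad.AnnData:
    """Read a cohort from an MTX+TSV triplet directory or an h5ad file."""
    path = Path(path)
    if format == "auto":
        format = "h5ad" if path.suffix == ".h5ad" else "mtx"
    if format == "h5ad":
        if not path.exists():
            raise FileNotFoundError(path)
        adata = ad.read_h5ad(path)
    elif format == "mtx":
        mtx, genes_f, cells_f = path / "matrix.mtx", path / "genes.tsv", path / "cells.tsv"
        for f in (mtx, genes_f, cells_f):
            if not f.exists():
                raise FileNotFoundError(f)
        X = spio.mmread(mtx)
        if X.shape[0] == 0 or X.shape[1] == 0:
            raise ValueError(f"empty expression matrix in {mtx}")
        genes = pd.read_csv(genes_f, sep="\t", header=None)[0].astype(str)
        obs = pd.read_csv(cells_f, sep="\t", index_col=0)
        if X.shape[0] != len(obs):
            raise ValueError(f"matrix has {X.shape[0]} cells but metadata has {len(obs)} rows")
        if X.shape[1] != len(genes):
            raise ValueError(f"matrix has {X.shape[1]} genes but gene file has {len(genes)}")
        adata = ad.AnnData(X=sparse.csr_matrix(X, dtype=np.float32), obs=obs,
                           var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    else:
        raise ValueError(f"unknown cohort format {format!r}")
    return validate_cohort(adata)


def write_cohort(adata: ad.AnnData, path, format: str = "mtx") -> Path:
    """Write a cohort as an MTX+TSV triplet directory or an h5ad file."""
    path = Path(path)
    if format == "h5ad":
        path.parent.mkdir(parents=True, exist_ok=True)
        adata.write_h5ad(path)
    elif format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(np.asarray(adata.X))
        spio.mmwrite(path / "matrix.mtx", X)
        (path / "genes.tsv").write_text("\n".join(adata.var_names) + "\n")
        adata.obs.to_csv(path / "cells.tsv", sep="\t")
    else:
        raise ValueError(f"unknown cohort format {format!r}")
    return path


def write_results(tables: dict[str, pd.DataFrame], outdir, config: RunConfig | None = None,
                  extra: dict | None = None) -> dict:
    """Write tidy TSV tables plus a manifest (files, config hash, seed, version).

    Returns the manifest dict; it is also written to ``manifest.json``.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, table in tables.items():
        fname = f"{name}.tsv"
        table.to_csv(outdir / fname, sep="\t")
        files[name] = fname
    if config is not None:
        config.to_yaml(outdir / "config.yaml")
        files["config"] = "config.yaml"
    manifest = {"version": __version__, "files": files,
                "config_hash": config.hash() if config else None,
                "seed": config.seed if config else None}
    if extra:
        manifest.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
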