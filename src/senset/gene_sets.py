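"""Gene-symbol set handling: reading, algebra, and the packaged signature.

Gene identity is the symbol string, matched exactly and case-sensitively;
no alias resolution or ID mapping is attempted. Sets preserve the order in
which symbols were first seen but compare as mathematical sets.

The packaged lung senescence signature (106 genes) ships as a TSV fixture
with per-gene direction flags for alveolar type 1 fibroblasts and
respiratory basal cells; see :func:`load_signature`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "AnnotatedSignature",
    "read_gene_lists",
    "write_gene_lists",
    "union_genes",
    "overlap_count",
    "restrict_to_measured",
    "load_signature",
]


def _dedupe(symbols: Iterable[str], name: str) -> list[str]:
    seen: dict[str, None] = {}
    n_dup = 0
    for s in symbols:
        if not isinstance(s, str) or not s:
            raise ValueError(f"gene list {name!r} contains an empty or non-string symbol")
        if s in seen:
            n_dup += 1
        else:
            seen[s] = None
    if n_dup:
        logger.warning("gene list %r: dropped %d duplicate symbol(s)", name, n_dup)
    return list(seen)


@dataclass
class GeneSetCollection:
    """Named, ordered, deduplicated gene-symbol sets with provenance notes."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, symbols: Iterable[str], provenance: str = "") -> None:
        self.sets[name] = _dedupe(symbols, name)
        self.provenance[name] = provenance

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def as_dict(self) -> dict[str, set[str]]:
        return {k: set(v) for k, v in self.sets.items()}


def read_gene_lists(paths: Iterable[str | Path], format: str = "auto") -> GeneSetCollection:
    """Read gene lists from GMT or plain one-symbol-per-line files.

    Parameters
    ----------
    paths
        Files to read. A GMT file may contribute several named sets (one per
        row); a plain file contributes one set named after its stem.
    format
        ``"gmt"``, ``"plain"``, or ``"auto"`` (by extension: ``.gmt`` is GMT,
        anything else plain).

    Duplicate symbols within a list are dropped with a logged warning.
    Empty files and malformed GMT rows raise ``ValueError``.
    """
    if format not in ("gmt", "plain", "auto"):
        raise ValueError(f"unknown gene-list format {format!r}")
    coll = GeneSetCollection()
    for path in paths:
        path = Path(path)
        fmt = format
        if fmt == "auto":
            fmt = "gmt" if path.suffix.lower() == ".gmt" else "plain"
        text = path.read_text()
        if not text.strip():
            raise ValueError(f"gene list file {path} is empty")
        if fmt == "gmt":
            for lineno, line in enumerate(text.splitlines(), start=1):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"malformed GMT row at {path}:{lineno}: expected "
                        f"name<TAB>description<TAB>symbols..., got {len(fields)} field(s)"
                    )
                name, desc = fields[0], fields[1]
                symbols = [s for s in fields[2:] if s]
                if not name or not symbols:
                    raise ValueError(f"malformed GMT row at {path}:{lineno}: empty name or symbol list")
                coll.add(name, symbols, provenance=f"{path} (GMT): {desc}")
        else:
            symbols = [ln.strip() for ln in text.splitlines() if ln.strip()]
            coll.add(path.stem, symbols, provenance=f"{path} (plain text)")
    return coll


def write_gene_lists(collection: GeneSetCollection, path: str | Path, format: str = "gmt") -> Path:
    """Write a collection as a GMT file or a directory of plain-text lists."""
    path = Path(path)
    if format == "gmt":
        lines = []
        for name, symbols in collection.sets.items():
            desc = collection.provenance.get(name, "") or "na"
            lines.append("\t".join([name, desc.replace("\t", " ").replace("\n", " ")] + symbols))
        path.write_text("\n".join(lines) + "\n")
    elif format == "plain":
        path.mkdir(parents=True, exist_ok=True)
        for name, symbols in collection.sets.items():
            (path / f"{name}.txt").write_text("\n".join(symbols) + "\n")
    else:
        raise ValueError(f"unknown gene-list format {format!r}")
    return path


def union_genes(collection: GeneSetCollection | Mapping[str, Iterable[str]]) -> list[str]:
    """Exact union of all sets in the collection, in lexicographic order.

    This is the prior-knowledge gene universe U that downstream dimension
    reduction and differential expression are restricted to.
    """
    sets = collection.sets if isinstance(collection, GeneSetCollection) else collection
    if not sets:
        raise ValueError("cannot take the union of an empty collection")
    out: set[str] = set()
    for symbols in sets.values():
        out.update(symbols)
    return sorted(out)


def overlap_count(set_a: Iterable[str], set_b: Iterable[str]) -> int:
    """|A ∩ B| for two gene sets (symmetric)."""
    return len(set(set_a) & set(set_b))


def restrict_to_measured(geneset: Iterable[str], cohort) -> list[str]:
    """Intersect a gene set with the genes measured in a cohort.

    ``cohort`` may be an AnnData (gene symbols in ``var_names``) or any
    iterable of symbols. Order of the input set is preserved. Raises if the
    intersection is empty, since the pipeline cannot proceed without genes.
    """
    measured = set(cohort.var_names) if hasattr(cohort, "var_names") else set(cohort)
    geneset = list(geneset)
    kept = [g for g in geneset if g in measured]
    if not kept:
        raise ValueError("no gene of the set is measured in the cohort")
    logger.info("restrict_to_measured: retained %d/%d genes", len(kept), len(geneset))
    return kept


@dataclass
class AnnotatedSignature:
    """A gene signature with per-gene direction flags for two cell types."""

    table: pd.DataFrame  # index: symbol; columns: full_name, fib_up, fib_down, basal_up, basal_down

    def __post_init__(self) -> None:
        t = self.table
        for a, b in (("fib_up", "fib_down"), ("basal_up", "basal_down")):
            both = t[a].astype(bool) & t[b].astype(bool)
            if both.any():
                raise ValueError(f"{a}/{b} flags must be mutually exclusive; offending genes: "
                                 f"{list(t.index[both])}")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def flagged(self, flag: str) -> list[str]:
        return list(self.table.index[self.table[flag].astype(bool)])

    def __len__(self) -> int:
        return len(self.table)


def load_signature() -> AnnotatedSignature:
    """Load the packaged 106-gene lung senescence signature fixture."""
    with resources.files("senset.data").joinpath("senset_signature.tsv").open() as fh:
        table = pd.read_csv(fh, sep="\t", comment="#", index_col="symbol")
    return AnnotatedSignature(table=table)
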