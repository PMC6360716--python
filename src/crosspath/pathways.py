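"""Pathway collections: GMT I/O, size filtering and redundancy pruning.

A pathway is a named set of gene symbols from one of the curated databases
(KEGG, Reactome, BioCarta) or elsewhere.  Downstream analysis treats
pathways as approximately independent functional units, which only holds if
heavily overlapping annotations are removed first.  The redundancy rule is
pairwise: two pathways are redundant when the fraction

    |A ∩ B| / max(|A|, |B|)

exceeds a threshold (default 0.30, strict), in which case the smaller
pathway is removed and the larger retained.  Pairs are resolved
highest-overlap first with deterministic tie-breaks, iterated to a fixed
point, so the result does not depend on input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

logger = logging.getLogger(__name__)

KNOWN_SOURCES = ("KEGG", "Reactome", "BioCarta", "OTHER")


def _normalize_gene(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class Pathway:
    name: str
    genes: frozenset
    source: str = "OTHER"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"pathway {self.name!r} has no genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class PathwayCollection:
    pathways: list
    provenance: str = ""
    _by_name: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_name = {}
        for p in self.pathways:
            if p.name in self._by_name:
                raise ValueError(f"duplicate pathway name {p.name!r}")
            self._by_name[p.name] = p

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.pathways)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Pathway:
        return self._by_name[name]

    @property
    def names(self) -> list:
        return [p.name for p in self.pathways]

    def gene_universe(self) -> frozenset:
        out = set()
        for p in self.pathways:
            out |= p.genes
        return frozenset(out)


# ------------------------------------------------------------------ GMT IO


def read_gmt(path: str | Path, provenance: str | None = None) -> PathwayCollection:
    """Read a GMT file (name, description, then tab-separated gene symbols).

    Duplicate genes within a line are deduplicated; empty gene fields are
    dropped.  Gene symbols are uppercased and whitespace-stripped.  The
    description field is used as the source tag when it names a known
    database.
    """
    path = Path(path)
    pathways = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, desc = fields[0], fields[1]
            genes = frozenset(
                _normalize_gene(g) for g in fields[2:] if g.strip()
            )
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {name!r} has no genes")
            source = desc if desc in KNOWN_SOURCES else "OTHER"
            pathways.append(Pathway(name=name, genes=genes, source=source, description=desc))
    return PathwayCollection(pathways, provenance=provenance or str(path))


def write_gmt(coll: PathwayCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for p in coll:
            genes = "\t".join(sorted(p.genes))
            fh.write(f"{p.name}\t{p.description or p.source}\t{genes}\n")
    return path


# ------------------------------------------------------- filtering/pruning


def filter_by_size(
    coll: PathwayCollection, min_size: int = 10, max_size: int = 200
) -> PathwayCollection:
    """Keep pathways with min_size <= |genes| <= max_size (inclusive bounds)."""
    if min_size > max_size:
        raise ValueError(f"min_size {min_size} > max_size {max_size}")
    kept = [p for p in coll if min_size <= len(p) <= max_size]
    logger.info("size filter %d-%d: %d of %d pathways kept", min_size, max_size, len(kept), len(coll))
    return PathwayCollection(kept, provenance=coll.provenance)


def overlap_fraction(a: Pathway, b: Pathway) -> float:
    """|A ∩ B| / max(|A|, |B|); symmetric, in [0, 1]."""
    if not a.genes or not b.genes:
        raise ValueError("overlap_fraction undefined for empty pathways")
    return len(a.genes & b.genes) / max(len(a), len(b))


def prune_redundant(
    coll: PathwayCollection, threshold: float = 0.30
) -> tuple[PathwayCollection, pd.DataFrame]:
    """Remove redundant pathways until no pair overlaps by more than ``threshold``.

    Resolution order: the violating pair with the highest overlap fraction is
    resolved first; the pathway with fewer genes is removed (ties on size are
    broken by removing the lexicographically later name).  Returns the pruned
    collection (input order preserved) and a removal log with columns
    ``removed kept overlap_fraction``.
    """
    alive = {p.name: p for p in coll}
    log_rows = []
    while True:
        worst = None
        for a, b in combinations(sorted(alive), 2):
            f = overlap_fraction(alive[a], alive[b])
            if f > threshold and (worst is None or f > worst[0]):
                worst = (f, a, b)
        if worst is None:
            break
        f, a, b = worst
        pa, pb = alive[a], alive[b]
        if len(pa) != len(pb):
            removed, kept = (a, b) if len(pa) < len(pb) else (b, a)
        else:
            removed, kept = (max(a, b), min(a, b))
        del alive[removed]
        log_rows.append({"removed": removed, "kept": kept, "overlap_fraction": f})
        logger.debug("pruned %s (overlap %.3f with %s)", removed, f, kept)
    pruned = PathwayCollection(
        [p for p in coll if p.name in alive], provenance=coll.provenance
    )
    log = pd.DataFrame(log_rows, columns=["removed", "kept", "overlap_fraction"])
    return pruned, log


def write_removal_log(log: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    log.to_csv(path, sep="\t", index=False)
    return path
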