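"""Reading, validating and writing gene-set collections (GMT format).

Immune-cell signatures, stromal/immune microenvironment signatures and
pathway sets all travel through :class:`GeneSetCollection`, a thin ordered
mapping of set name -> (description, gene list) backed by the tab-separated
GMT convention (name, description, member genes; one set per line).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)


class GmtParseError(ValueError):
    """Raised for malformed GMT content (short lines, duplicate names)."""


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets.

    ``sets`` maps set name -> (description, tuple of unique gene ids).
    Set names are unique, genes within a set are unique (first occurrence
    kept), and no set is empty after construction.
    """

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")
            for g in genes:
                if not g or "\t" in g:
                    raise ValueError(f"invalid gene id {g!r} in set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out.update(genes)
        return out

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        """Build a collection from name -> genes, with empty descriptions."""
        sets = {}
        for name, genes in mapping.items():
            deduped = tuple(dict.fromkeys(genes))
            sets[name] = ("", deduped)
        return cls(sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each line must have >= 3 tab-separated fields (name, description,
    genes...). Duplicate genes within a line are collapsed keeping the
    first occurrence; a duplicate set name or a short line is an error
    naming the offending line. An empty file yields an empty collection
    with a logged warning.
    """
    path = Path(path)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise GmtParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise GmtParseError(f"{path}: line {lineno}: set {name!r} has no genes")
            sets[name] = (description, genes)
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection to GMT; round-trips bit-exactly through read_gmt."""
    path = Path(path)
    with path.open("w") as fh:
        for name, (description, genes) in collection.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def restrict_to_matrix(
    collection: GeneSetCollection,
    gene_ids: Iterable[str],
    min_size: int = 5,
) -> tuple[GeneSetCollection, dict[str, int]]:
    """Intersect every set with the genes measured in an expression matrix.

    Sets left with fewer than ``min_size`` genes are dropped with a logged
    warning; the returned dict reports dropped set names and their
    surviving gene counts. Matching is exact, case-sensitive string
    equality. Raises ``ValueError`` if every set is dropped. Idempotent.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    universe = set(gene_ids)
    if not universe:
        raise ValueError("gene_ids is empty")
    kept: dict[str, tuple[str, tuple[str, ...]]] = {}
    dropped: dict[str, int] = {}
    for name, (description, genes) in collection.sets.items():
        surviving = tuple(g for g in genes if g in universe)
        if len(surviving) < min_size:
            dropped[name] = len(surviving)
            logger.warning(
                "dropping gene set %r: %d of %d genes in matrix (min_size=%d)",
                name, len(surviving), len(genes), min_size,
            )
        else:
            kept[name] = (description, surviving)
    if not kept:
        raise ValueError(
            f"all {len(collection)} gene sets dropped after restriction "
            f"(min_size={min_size}); nothing to score"
        )
    return GeneSetCollection(kept), dropped
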