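"""GMT gene-set library container and reader/writer.

The GMT dialect used throughout the package is one set per line,
tab-separated: term, description, then the member genes.  Files are UTF-8
with no trailing tab; writing then reading then writing again is
byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator


@dataclass
class GeneSet:
    """A named, annotated collection of gene symbols.

    ``term`` is the unique identifier within a library (for extracted sets it
    is derived from provenance), ``description`` free-text annotation, and
    ``genes`` the deduplicated member symbols in first-seen order.
    """

    term: str
    description: str
    genes: list[str]
    article_id: str | None = None

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            if g and g not in seen:
                seen[g] = None
        self.genes = list(seen)

    @property
    def membership(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass
class GeneSetLibrary:
    """An ordered collection of :class:`GeneSet` with unique terms."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        terms = [s.term for s in self.sets]
        if len(terms) != len(set(terms)):
            dupes = sorted({t for t in terms if terms.count(t) > 1})
            raise ValueError(f"duplicate terms in library: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, term: str) -> GeneSet:
        for s in self.sets:
            if s.term == term:
                return s
        raise KeyError(term)

    @property
    def terms(self) -> list[str]:
        return [s.term for s in self.sets]

    def universe(self) -> set[str]:
        """Union of all member genes across the library."""
        out: set[str] = set()
        for s in self.sets:
            out.update(s.genes)
        return out


def format_gmt_line(gene_set: GeneSet) -> str:
    fields = [gene_set.term, gene_set.description, *gene_set.genes]
    return "\t".join(fields)


def write_gmt(library: GeneSetLibrary | Iterable[GeneSet], path: str | os.PathLike) -> None:
    sets = library.sets if isinstance(library, GeneSetLibrary) else list(library)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in sets:
            fh.write(format_gmt_line(s) + "\n")


def read_gmt(path: str | os.PathLike) -> GeneSetLibrary:
    sets: list[GeneSet] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line (need term and description): {line[:80]!r}")
            term, description, *genes = fields
            sets.append(GeneSet(term=term, description=description, genes=genes))
    return GeneSetLibrary(sets)
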