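"""Resolution of arbitrary strings to official human gene symbols.

The registry is loaded from an NCBI ``gene_info``-style TSV (tab-separated;
pipe-delimited synonyms; ``-`` for "none") and builds a single normalized
lookup token -> official symbol.  Matching is case-insensitive with
surrounding whitespace stripped; this is also what lets mouse/rat symbols
(``Trp53``) fall through to the human symbol without extra logic.

Collision policy (precedence): an official symbol always resolves to itself;
a synonym that collides with another gene's official symbol loses to the
official symbol; a synonym shared by two or more genes is ambiguous and
resolves to nothing; numeric gene identifiers have the lowest precedence.
All dropped or overridden tokens are kept in ``GeneRegistry.collisions``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

_NONE = "-"

# precedence classes, lower wins
_OFFICIAL = 0
_SYNONYM = 1
_NUMERIC = 2


def normalize_token(token: str) -> str:
    """Normalization applied to every lookup token: strip + casefold."""
    return token.strip().casefold()


@dataclass
class GeneRecord:
    official_symbol: str
    synonyms: list[str]
    numeric_id: int
    description: str = ""

    def __post_init__(self) -> None:
        if not self.official_symbol:
            raise ValueError("official_symbol must be non-empty")
        norm_off = normalize_token(self.official_symbol)
        self.synonyms = [s for s in self.synonyms if s and normalize_token(s) != norm_off]


@dataclass
class MappingSummary:
    mapped_symbols: list[str]
    mapped_fraction: float
    unmapped: list[str]


@dataclass
class GeneRegistry:
    records: list[GeneRecord]
    _index: dict[str, str] = field(default_factory=dict, repr=False)
    collisions: list[tuple[str, str]] = field(default_factory=list, repr=False)

    def __len__(self) -> int:
        return len(self.records)

    def resolve(self, token: str) -> str | None:
        """Resolve a string to an official symbol, or None on no match.

        Pure function of the registry: empty/blank tokens and tokens dropped
        as ambiguous return None.
        """
        key = normalize_token(token)
        if not key:
            return None
        return self._index.get(key)

    def map_tokens(self, tokens: list[str]) -> MappingSummary:
        """Resolve a multiset of tokens; fraction is over UNIQUE non-blank tokens."""
        unique: list[str] = []
        seen: set[str] = set()
        for t in tokens:
            key = normalize_token(t)
            if not key or key in seen:
                continue
            seen.add(key)
            unique.append(t)
        mapped: list[str] = []
        mapped_set: set[str] = set()
        unmapped: list[str] = []
        n_resolved = 0
        for t in unique:
            sym = self.resolve(t)
            if sym is None:
                unmapped.append(t)
            else:
                n_resolved += 1
                if sym not in mapped_set:
                    mapped_set.add(sym)
                    mapped.append(sym)
        fraction = n_resolved / len(unique) if unique else 0.0
        return MappingSummary(mapped_symbols=mapped, mapped_fraction=fraction, unmapped=unmapped)


def _find_column(columns: list[str], candidates: tuple[str, ...]) -> str | None:
    lowered = {c.lower().lstrip("#"): c for c in columns}
    for cand in candidates:
        if cand in lowered:
            return lowered[cand]
    return None


def build_registry(records: list[GeneRecord]) -> GeneRegistry:
    """Build the resolution index from records, applying the precedence rules."""
    if not records:
        raise ValueError("cannot build a registry from zero gene records")
    # candidate lists per normalized token: (precedence, symbol)
    candidates: dict[str, list[tuple[int, str]]] = {}

    def add(token: str, prec: int, symbol: str) -> None:
        key = normalize_token(token)
        if key:
            candidates.setdefault(key, []).append((prec, symbol))

    for rec in records:
        add(rec.official_symbol, _OFFICIAL, rec.official_symbol)
        for syn in rec.synonyms:
            add(syn, _SYNONYM, rec.official_symbol)
        add(str(rec.numeric_id), _NUMERIC, rec.official_symbol)

    index: dict[str, str] = {}
    collisions: list[tuple[str, str]] = []
    for key, cands in candidates.items():
        best = min(p for p, _ in cands)
        winners = sorted({s for p, s in cands if p == best})
        losers = sorted({s for p, s in cands if p > best})
        if len(winners) == 1:
            index[key] = winners[0]
            for s in losers:
                collisions.append((key, f"token of {s} overridden by {winners[0]}"))
        else:
            # same precedence class claimed by >=2 genes: ambiguous, unresolvable
            collisions.append((key, "ambiguous between " + ", ".join(winners) + "; dropped"))
    return GeneRegistry(records=records, _index=index, collisions=collisions)


def load_registry(gene_info_path: str | os.PathLike) -> GeneRegistry:
    """Load a gene_info-style TSV into a :class:`GeneRegistry`.

    Required columns (case-insensitive, leading ``#`` tolerated): ``Symbol``,
    ``Synonyms`` (pipe-delimited, ``-`` = none), ``GeneID``.  ``description``
    is optional.
    """
    table = pd.read_csv(gene_info_path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(table.columns)
    symbol_col = _find_column(cols, ("symbol",))
    syn_col = _find_column(cols, ("synonyms",))
    id_col = _find_column(cols, ("geneid", "gene_id", "id"))
    missing = [name for name, col in
               (("Symbol", symbol_col), ("Synonyms", syn_col), ("GeneID", id_col)) if col is None]
    if missing:
        raise ValueError(f"gene_info table missing required columns: {missing}")
    desc_col = _find_column(cols, ("description",))
    if len(table) == 0:
        raise ValueError("gene_info table has no rows; refusing to build an empty registry")

    records: list[GeneRecord] = []
    for _, row in table.iterrows():
        syn_raw = row[syn_col].strip()
        synonyms = [] if syn_raw in ("", _NONE) else [s.strip() for s in syn_raw.split("|") if s.strip()]
        records.append(
            GeneRecord(
                official_symbol=row[symbol_col].strip(),
                synonyms=synonyms,
                numeric_id=int(row[id_col]),
                description=row[desc_col] if desc_col else "",
            )
        )
    return build_registry(records)
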