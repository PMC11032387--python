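"""Functional-term annotation of gene-set titles and consensus libraries.

Column titles are split on dashes, underscores, and periods; tokens that
are pure integers, or an ``S`` followed by an integer (supplementary-table
numbering), are dropped with a recorded reason.  Remaining tokens are
checked against the gene registry (synonyms are converted to official
symbols), against transcription-factor and kinase vocabularies, against a
tissue/cell-line ontology (exact match after lowercasing, hyphen-joined
when a title hits several terms), and against the direction markers
``up`` / ``down`` / ``dn``.

Consensus libraries give one set per named entity: the union of the genes
of every library set whose term or description mentions the entity as a
whole token.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field

from .gene_registry import GeneRegistry
from .gmt import GeneSet, GeneSetLibrary

logger = logging.getLogger(__name__)

_SPLIT_RE = re.compile(r"[-_.]")
_INT_RE = re.compile(r"^\d+$")
_SUPP_RE = re.compile(r"^[Ss]\d+$")
_WORD_RE = re.compile(r"[A-Za-z0-9]+")

DIRECTION_TOKENS = {"up": "up", "down": "down", "dn": "down"}


@dataclass
class Vocabulary:
    """A controlled vocabulary for one entity class.

    ``entries`` maps each canonical term to its synonyms; lookup is by exact
    match after lowercasing.
    """

    entity_class: str
    entries: dict[str, list[str]]
    _lookup: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for canonical, synonyms in self.entries.items():
            self._lookup.setdefault(canonical.lower(), canonical)
            for syn in synonyms:
                self._lookup.setdefault(syn.lower(), canonical)

    def match(self, token: str) -> str | None:
        return self._lookup.get(token.strip().lower())

    def __contains__(self, token: str) -> bool:
        return self.match(token) is not None

    @property
    def terms(self) -> list[str]:
        return list(self.entries)


def load_vocabulary(path: str | os.PathLike, entity_class: str) -> Vocabulary:
    """Read a two-column TSV (canonical term, pipe-separated synonyms)."""
    entries: dict[str, list[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            canonical = parts[0].strip()
            syn_raw = parts[1].strip() if len(parts) > 1 else ""
            synonyms = [] if syn_raw in ("", "-") else [s for s in syn_raw.split("|") if s]
            if canonical in entries:
                raise ValueError(f"duplicate canonical term {canonical!r} in {path}")
            entries[canonical] = synonyms
    return Vocabulary(entity_class=entity_class, entries=entries)


@dataclass
class TitleAnnotation:
    genes: list[str] = field(default_factory=list)
    tfs: list[str] = field(default_factory=list)
    kinases: list[str] = field(default_factory=list)
    direction: str = "none"          # up / down / none
    ontology_terms: str = ""         # hyphen-joined when multiple
    ignored_tokens: list[tuple[str, str]] = field(default_factory=list)


def tokenize_title(title: str) -> tuple[list[str], list[tuple[str, str]]]:
    """Split a column title on dash/underscore/period and filter artifacts.

    Returns (tokens, ignored) where each ignored entry carries a reason:
    pure-integer tokens ("numeric") and S-plus-integer tokens
    ("supplemental-number") are dropped; empty fragments vanish silently.
    """
    tokens: list[str] = []
    ignored: list[tuple[str, str]] = []
    for raw in _SPLIT_RE.split(title):
        tok = raw.strip()
        if not tok:
            continue
        if _INT_RE.match(tok):
            ignored.append((tok, "numeric"))
        elif _SUPP_RE.match(tok):
            ignored.append((tok, "supplemental-number"))
        else:
            tokens.append(tok)
    return tokens, ignored


def annotate_title(
    tokens: list[str],
    registry: GeneRegistry,
    tf_vocab: Vocabulary | None = None,
    kinase_vocab: Vocabulary | None = None,
    ontology_vocab: Vocabulary | None = None,
) -> TitleAnnotation:
    """Recognize genes, TFs, kinases, direction flags and ontology terms."""
    ann = TitleAnnotation()
    ontology_hits: list[str] = []
    for tok in tokens:
        low = tok.lower()
        if low in DIRECTION_TOKENS:
            ann.direction = DIRECTION_TOKENS[low]
            continue
        sym = registry.resolve(tok)
        if sym is not None:
            if sym not in ann.genes:
                ann.genes.append(sym)
            if tf_vocab is not None and sym in tf_vocab and sym not in ann.tfs:
                ann.tfs.append(sym)
            if kinase_vocab is not None and sym in kinase_vocab and sym not in ann.kinases:
                ann.kinases.append(sym)
            continue
        if ontology_vocab is not None:
            hit = ontology_vocab.match(tok)
            if hit is not None:
                if hit not in ontology_hits:
                    ontology_hits.append(hit)
                continue
        ann.ignored_tokens.append((tok, "no-match"))
    ann.ontology_terms = "-".join(ontology_hits)
    return ann


def _token_set(text: str) -> set[str]:
    return {m.group(0).lower() for m in _WORD_RE.finditer(text)}


def metadata_search(library: GeneSetLibrary, search_term: str) -> list[str]:
    """Whole-token, case-insensitive search over terms and descriptions.

    The search term matches a set when it equals (after lowercasing) one of
    the alphanumeric tokens of the set's term or description; ``STAT`` does
    not match the token ``STAT3``.  Library order is preserved.
    """
    needle = search_term.strip().lower()
    if not needle:
        raise ValueError("empty search term")
    return [s.term for s in library
            if needle in _token_set(s.term) or needle in _token_set(s.description)]


def build_consensus_library(
    library: GeneSetLibrary,
    entity_list: list[str],
    vocabulary: Vocabulary | None = None,
) -> GeneSetLibrary:
    """One consensus set per entity: the union of all metadata matches.

    Entities with zero matching sets are omitted (logged).  When a
    vocabulary is given, each entity's synonyms are searched too.  The
    consensus set's description records the contributing set ids.
    """
    out: list[GeneSet] = []
    for entity in entity_list:
        search_terms = [entity]
        if vocabulary is not None and entity in vocabulary.entries:
            search_terms += vocabulary.entries[entity]
        matched: list[str] = []
        for st in search_terms:
            for sid in metadata_search(library, st):
                if sid not in matched:
                    matched.append(sid)
        if not matched:
            logger.info("entity %s matched no sets; omitted from consensus", entity)
            continue
        genes: list[str] = []
        seen: set[str] = set()
        for sid in matched:
            for g in library[sid].genes:
                if g not in seen:
                    seen.add(g)
                    genes.append(g)
        out.append(GeneSet(term=entity,
                           description="consensus of " + ",".join(matched),
                           genes=genes))
    return GeneSetLibrary(out)
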