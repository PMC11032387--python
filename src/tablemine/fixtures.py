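"""Synthetic inputs with ground truth known by construction.

Everything the rest of the package consumes can be generated here: gene
registries in gene_info TSV form, article bundles whose planted table
columns are known in advance to pass or fail the extraction filter,
gene-set libraries with planted co-occurrence modules, named entities,
duplicate sets and abstracts with controlled vocabulary overlap, plus the
annotation gene lists used by pair discovery.  Each generator is a pure
function of its spec and seed, reproducible byte for byte, and emits a
manifest that downstream modules are tested against.

The metadata-document dialect written by :func:`make_bundle` is the same
minimal JATS-like dialect the extraction parser targets: tables inside
``table-wrap`` elements with ``label``/``caption``, supplements declared
by ``supplementary-material``, and in-text references through ``xref``.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from lxml import etree

from .extraction import ExtractionConfig
from .gene_registry import GeneRegistry, GeneRecord, build_registry
from .gmt import GeneSet, GeneSetLibrary

_LETTERS = string.ascii_lowercase


# ---------------------------------------------------------------------------
# spec types

@dataclass
class PlantedColumn:
    """One table column with a known extraction outcome.

    ``n_mappable`` cells are distinct official symbols from the registry;
    ``n_unmappable`` cells are strings that cannot resolve.  The expected
    outcome follows from the default extraction rules alone.
    """

    n_mappable: int
    n_unmappable: int = 0
    file_format: str = "csv"        # embedded / csv / tsv / txt / xlsx
    header: str = "genes"

    def expected_outcome(self, config: ExtractionConfig | None = None) -> str:
        config = config or ExtractionConfig()
        total = self.n_mappable + self.n_unmappable
        fraction = self.n_mappable / total if total else 0.0
        if fraction <= config.min_mapped_fraction:
            return "low_fraction"
        if self.n_mappable < config.min_genes:
            return "too_few"
        if self.n_mappable > config.max_genes:
            return "too_many"
        return "retained"


@dataclass
class PlantedModule:
    """A block of genes that co-occur: ``n_sets`` sets drawn from ``genes``."""

    genes: list[str]
    n_sets: int
    entity: str | None = None       # token planted into each set's title
    articles: list[str] = field(default_factory=list)
    set_size: tuple[int, int] = (8, 15)
    cover_all_genes: bool = True


@dataclass
class DuplicateItem:
    """Replicate one module set's membership: ``n_copies`` extra copies
    spread over ``articles`` (same article repeated = within-article dupes)."""

    module: int
    set_index: int
    articles: list[str]


@dataclass
class FixtureSpec:
    seed: int = 0
    n_genes: int = 100
    synonym_rate: float = 0.3
    article_id: str = "PMCA1"
    planted_columns: list[PlantedColumn] = field(default_factory=list)
    planted_modules: list[PlantedModule] = field(default_factory=list)
    duplicate_plan: list[DuplicateItem] = field(default_factory=list)
    # articles sharing a vocabulary group have overlapping abstracts;
    # articles in different groups have exactly disjoint token sets
    abstract_groups: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# registry

def registry_records(spec: FixtureSpec) -> list[GeneRecord]:
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_genes):
        symbol = f"GENE{i + 1:04d}"
        synonyms = []
        if spec.synonym_rate > 0 and rng.random() < spec.synonym_rate:
            synonyms = [f"SYN{i + 1:04d}A"]
        records.append(GeneRecord(official_symbol=symbol, synonyms=synonyms,
                                  numeric_id=1000 + i,
                                  description=f"synthetic gene {i + 1}"))
    return records


def make_registry(spec: FixtureSpec, path: str | Path) -> Path:
    """Write a gene_info-style TSV; deterministic under (spec, seed)."""
    path = Path(path)
    lines = ["GeneID\tSymbol\tSynonyms\tdescription"]
    for rec in registry_records(spec):
        syn = "|".join(rec.synonyms) if rec.synonyms else "-"
        lines.append(f"{rec.numeric_id}\t{rec.official_symbol}\t{syn}\t{rec.description}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def build_fixture_registry(spec: FixtureSpec) -> GeneRegistry:
    return build_registry(registry_records(spec))


# ---------------------------------------------------------------------------
# article bundles

def _unmappable_token(k: int) -> str:
    # letters only: never numeric, never S+integer, never a symbol/synonym
    suffix = "".join(_LETTERS[int(d)] for d in str(k))
    return f"zzq{suffix}x"


def _column_cells(col: PlantedColumn, symbols: list[str], start: int) -> list[str]:
    mapped = symbols[start:start + col.n_mappable]
    unmapped = [_unmappable_token(start * 37 + j) for j in range(col.n_unmappable)]
    return mapped + unmapped


def make_bundle(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write an article bundle realizing ``spec.planted_columns``.

    Returns (and writes next to the bundle) a manifest listing, per planted
    column, its provenance, cells, expected outcome, and — for surviving
    columns — the expected term, description and mapped genes.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        raise FileExistsError(f"bundle directory {out_dir} exists and is not empty")
    out_dir.mkdir(parents=True, exist_ok=True)

    symbols = [r.official_symbol for r in registry_records(spec)]
    need = sum(c.n_mappable for c in spec.planted_columns)
    if need > len(symbols):
        raise ValueError(f"spec needs {need} mappable symbols but registry has "
                         f"{len(symbols)} genes")

    root = etree.Element("article", id=spec.article_id)
    body = etree.SubElement(root, "body")
    # manifest entries are kept in extraction traversal order: embedded
    # tables in document order, then supplement files lexicographically
    embedded_entries: list[dict] = []
    supplement_entries: list[dict] = []
    start = 0
    used_terms: set[str] = set()

    def reserve_term(parts: list[str]) -> str:
        base = "-".join(p for p in parts if p)
        term = base
        i = 2
        while term in used_terms:
            term = f"{base}-{i}"
            i += 1
        used_terms.add(term)
        return term

    n_embedded = 0
    supplements: list[tuple[str, PlantedColumn, list[str]]] = []
    for k, col in enumerate(spec.planted_columns):
        cells = _column_cells(col, symbols, start)
        start += col.n_mappable
        if col.file_format == "embedded":
            n_embedded += 1
            table_id = f"T{n_embedded}"
            label = f"Table {n_embedded}"
            caption = f"Embedded table {n_embedded} of {spec.article_id}"
            mention = f"planted embedded column {n_embedded} appears in"
            p = etree.SubElement(body, "p")
            p.text = mention + " "
            xref = etree.SubElement(p, "xref", rid=table_id)
            xref.text = label
            xref.tail = "."
            wrap = etree.SubElement(body, "table-wrap", id=table_id)
            etree.SubElement(wrap, "label").text = label
            etree.SubElement(wrap, "caption").text = caption
            table = etree.SubElement(wrap, "table")
            for cell in [col.header, *cells]:
                tr = etree.SubElement(table, "tr")
                etree.SubElement(tr, "td").text = cell
            entry = {
                "source_file": "article.xml", "label": label, "header": col.header,
                "cells": cells, "outcome": col.expected_outcome(),
                "description": f"{caption} {label} {mention}",
            }
            if entry["outcome"] == "retained":
                entry["term"] = reserve_term([spec.article_id, "article.xml",
                                              label, col.header])
                entry["genes"] = cells[:col.n_mappable]
            embedded_entries.append(entry)
        else:
            ext = "xlsx" if col.file_format == "xlsx" else col.file_format
            fname = f"supp{k + 1:02d}.{ext}"
            caption = f"Supplementary table {k + 1} of {spec.article_id}"
            mention = f"supporting gene list {k + 1} is provided in"
            p = etree.SubElement(body, "p")
            p.text = mention + " "
            xref = etree.SubElement(p, "xref", rid=fname)
            xref.text = f"file {fname}"
            xref.tail = "."
            sm = etree.SubElement(body, "supplementary-material", id=fname, href=fname)
            etree.SubElement(sm, "caption").text = caption
            supplements.append((fname, col, cells))
            label = "Sheet1" if ext == "xlsx" else ""
            entry = {
                "source_file": fname, "label": label, "header": col.header,
                "cells": cells, "outcome": col.expected_outcome(),
                "description": " ".join(x for x in (caption, label, mention) if x),
            }
            if entry["outcome"] == "retained":
                entry["term"] = reserve_term([spec.article_id, fname, label,
                                              col.header])
                entry["genes"] = cells[:col.n_mappable]
            supplement_entries.append(entry)

    etree.ElementTree(root).write(str(out_dir / "article.xml"),
                                  xml_declaration=True, encoding="UTF-8")

    for fname, col, cells in supplements:
        rows = [col.header, *cells]
        path = out_dir / fname
        if fname.endswith(".xlsx"):
            from openpyxl import Workbook

            wb = Workbook()
            # fixed timestamps so the same spec+seed gives identical bytes
            from datetime import datetime

            wb.properties.created = datetime(2000, 1, 1)
            wb.properties.modified = datetime(2000, 1, 1)
            ws = wb.active
            ws.title = "Sheet1"
            for cell in rows:
                ws.append([cell])
            wb.save(path)
        elif fname.endswith(".tsv") or fname.endswith(".txt"):
            # single column: add a constant second column so the TXT
            # separator inference has something to vote on
            sep = "\t"
            path.write_text("".join(f"{c}{sep}note\n" for c in rows), encoding="utf-8")
        else:
            path.write_text("".join(f"{c},note\n" for c in rows), encoding="utf-8")

    supplement_entries.sort(key=lambda e: e["source_file"])
    manifest = embedded_entries + supplement_entries
    manifest_doc = {"article_id": spec.article_id, "columns": manifest}
    manifest_path = out_dir.parent / f"{out_dir.name}.manifest.json"
    manifest_path.write_text(json.dumps(manifest_doc, indent=1), encoding="utf-8")
    return manifest_doc


# ---------------------------------------------------------------------------
# libraries with planted structure

@dataclass
class LibraryFixture:
    library: GeneSetLibrary
    module_of: dict[str, int]           # set id -> module index
    entity_of: dict[str, str]           # set id -> planted entity (annotated sets)
    abstracts: dict[str, str]           # article id -> raw abstract text
    duplicate_terms: dict[str, list[str]]  # source term -> its planted copies


def _abstract_word(group: int, i: int) -> str:
    # letter-only tokens so the word tokenizer keeps them whole; the trailing
    # consonant keeps the suffix lemmatizer from touching them
    def alpha(n: int) -> str:
        out = _LETTERS[n % 26]
        while n >= 26:
            n //= 26
            out = _LETTERS[n % 26] + out
        return out

    return f"x{alpha(group)}q{alpha(i)}x"


def make_abstract(article: str, group: int, rng: np.random.Generator,
                  n_words: int = 60, vocab_size: int = 30) -> str:
    """An abstract drawn from vocabulary group ``group``; texts from
    different groups share no token after preprocessing."""
    vocab = [_abstract_word(group, i) for i in range(vocab_size)]
    words = rng.choice(vocab, size=n_words, replace=True)
    return " ".join(words)


def make_library(spec: FixtureSpec) -> LibraryFixture:
    """Realize planted modules, entities, duplicates and abstracts.

    Module sets are subsets of the module's genes, so within-module gene
    pairs co-occur while cross-module pairs never do.  Entity tokens are
    planted into the title component of each set's term.  Duplicate items
    replicate an existing set's membership under new terms/articles.
    """
    rng = np.random.default_rng(spec.seed)
    sets: list[GeneSet] = []
    module_of: dict[str, int] = {}
    entity_of: dict[str, str] = {}
    module_terms: list[list[str]] = []

    for m, module in enumerate(spec.planted_modules):
        genes = list(module.genes)
        lo, hi = module.set_size
        articles = module.articles or [f"PMCM{m + 1}"]
        terms_here: list[str] = []
        for k in range(module.n_sets):
            size = int(rng.integers(lo, hi + 1))
            members = [genes[i] for i in
                       sorted(rng.choice(len(genes), size=min(size, len(genes)),
                                         replace=False))]
            if module.cover_all_genes and k == 0:
                members = genes
            article = articles[k % len(articles)]
            title = f"{module.entity}_targets_{k + 1}" if module.entity else f"module{m + 1}_set{k + 1}"
            term = f"{article}-supp.csv-{title}"
            sets.append(GeneSet(term=term, description=f"planted module {m + 1}",
                                genes=members, article_id=article))
            module_of[term] = m
            if module.entity:
                entity_of[term] = module.entity
            terms_here.append(term)
        module_terms.append(terms_here)

    duplicate_terms: dict[str, list[str]] = {}
    for item in spec.duplicate_plan:
        src_term = module_terms[item.module][item.set_index]
        src = next(s for s in sets if s.term == src_term)
        copies = []
        for j, article in enumerate(item.articles):
            term = f"{article}-supp.csv-copy{j + 1}_of_{item.set_index + 1}"
            sets.append(GeneSet(term=term, description="planted duplicate",
                                genes=list(src.genes), article_id=article))
            module_of[term] = item.module
            if src_term in entity_of:
                entity_of[term] = entity_of[src_term]
            copies.append(term)
        duplicate_terms[src_term] = copies

    articles = sorted({s.article_id for s in sets})
    groups = dict(spec.abstract_groups)
    next_group = max(groups.values(), default=-1) + 1
    abstracts = {}
    for article in articles:
        if article not in groups:
            groups[article] = next_group
            next_group += 1
        abstracts[article] = make_abstract(article, groups[article], rng)

    return LibraryFixture(
        library=GeneSetLibrary(sets),
        module_of=module_of,
        entity_of=entity_of,
        abstracts=abstracts,
        duplicate_terms=duplicate_terms,
    )


def make_two_module_library(seed: int, genes_per_module: int = 20,
                            sets_per_module: int = 15) -> tuple[LibraryFixture, FixtureSpec]:
    """Two disjoint co-occurrence modules for function-prediction tests."""
    spec = FixtureSpec(seed=seed, n_genes=2 * genes_per_module)
    symbols = [r.official_symbol for r in registry_records(spec)]
    spec.planted_modules = [
        PlantedModule(genes=symbols[:genes_per_module], n_sets=sets_per_module),
        PlantedModule(genes=symbols[genes_per_module:], n_sets=sets_per_module),
    ]
    return make_library(spec), spec


# ---------------------------------------------------------------------------
# specialized planted fixtures

@dataclass
class PairDiscoveryFixture:
    library: GeneSetLibrary
    registry: GeneRegistry
    abstracts: dict[str, str]
    sticky_genes: list[str]
    top_cited: list[str]
    top_expressed: list[str]
    disease_terms: list[str]
    planted_pair: tuple[str, str]       # (disease-titled term, gene-titled term)
    boundary_overlap_pair: tuple[str, str]   # overlap exactly 50: excluded
    identical_pair: tuple[str, str]          # identical membership: excluded
    sticky_boundary_pair: tuple[str, str]    # sticky fraction exactly 10%: excluded


def make_pair_discovery_fixture(seed: int = 0) -> PairDiscoveryFixture:
    """A corpus with one pair that must survive every filter and three
    boundary pairs that must each fail exactly one filter.

    The surviving pair shares 60 genes (5 of them sticky: fraction 1/12),
    comes from two articles with token-disjoint abstracts, and has a
    disease name in one title and a gene symbol in the other.  The boundary
    pairs share exactly 50 genes, or have identical memberships, or carry a
    sticky fraction of exactly 10%.
    """
    spec = FixtureSpec(seed=seed, n_genes=400, synonym_rate=0.0)
    symbols = [r.official_symbol for r in registry_records(spec)]
    pool = iter(range(len(symbols)))

    def take(n: int) -> list[str]:
        return [symbols[next(pool)] for _ in range(n)]

    good_overlap = take(60)
    good_a_only = take(20)
    good_b_only = take(25)
    fifty_overlap = take(50)
    fifty_a_only = take(15)
    fifty_b_only = take(18)
    identical_members = take(55)
    sticky_overlap = take(60)
    # larger unique tails keep this pair strictly less significant than the
    # surviving pair, which must rank first
    sticky_a_only = take(40)
    sticky_b_only = take(45)

    sticky_genes = good_overlap[:5] + sticky_overlap[:6]  # 5/60 < 10% <= 6/60
    top_cited = good_overlap[5:15]
    top_expressed = good_overlap[15:25]
    gene_title_symbol = "GENE0007"
    assert gene_title_symbol in good_overlap

    sets = [
        GeneSet("PMCP1-s1.csv-melanoma_signature", "disease-titled set",
                good_overlap + good_a_only, article_id="PMCP1"),
        GeneSet(f"PMCP2-s1.csv-{gene_title_symbol}_interactome", "gene-titled set",
                good_overlap + good_b_only, article_id="PMCP2"),
        GeneSet("PMCP3-s1.csv-fifty_a", "overlap boundary a",
                fifty_overlap + fifty_a_only, article_id="PMCP3"),
        GeneSet("PMCP4-s1.csv-fifty_b", "overlap boundary b",
                fifty_overlap + fifty_b_only, article_id="PMCP4"),
        GeneSet("PMCP5-s1.csv-identical_a", "identical membership a",
                identical_members, article_id="PMCP5"),
        GeneSet("PMCP6-s1.csv-identical_b", "identical membership b",
                identical_members, article_id="PMCP6"),
        GeneSet("PMCP7-s1.csv-sticky_a", "sticky boundary a",
                sticky_overlap + sticky_a_only, article_id="PMCP7"),
        GeneSet("PMCP8-s1.csv-sticky_b", "sticky boundary b",
                sticky_overlap + sticky_b_only, article_id="PMCP8"),
    ]
    rng = np.random.default_rng(seed)
    abstracts = {f"PMCP{i}": make_abstract(f"PMCP{i}", group=i, rng=rng)
                 for i in range(1, 9)}
    return PairDiscoveryFixture(
        library=GeneSetLibrary(sets),
        registry=build_fixture_registry(spec),
        abstracts=abstracts,
        sticky_genes=sticky_genes,
        top_cited=top_cited,
        top_expressed=top_expressed,
        disease_terms=["melanoma", "glioma", "hypoxia"],
        planted_pair=(sets[0].term, sets[1].term),
        boundary_overlap_pair=(sets[2].term, sets[3].term),
        identical_pair=(sets[4].term, sets[5].term),
        sticky_boundary_pair=(sets[6].term, sets[7].term),
    )


@dataclass
class BenchmarkFixture:
    benchmark_library: GeneSetLibrary
    entity_of: dict[str, str]
    entities: list[str]


def make_benchmark_fixture(seed: int = 0, n_entities: int = 8,
                           sets_per_entity: int = 3,
                           pool_size: int = 30, set_size: int = 15) -> BenchmarkFixture:
    """Entity-labeled benchmark sets over disjoint per-entity gene pools.

    Each entity (a synthetic regulator name planted as a title token) gets
    ``sets_per_entity`` sets of ``set_size`` genes from its private pool,
    so a consensus library built from the benchmark separates entities
    perfectly; shuffling the labels destroys the signal.
    """
    spec = FixtureSpec(seed=seed, n_genes=n_entities * pool_size)
    symbols = [r.official_symbol for r in registry_records(spec)]
    rng = np.random.default_rng(seed)
    sets, entity_of = [], {}
    entities = [f"REG{_LETTERS[k].upper()}" for k in range(n_entities)]
    for k, entity in enumerate(entities):
        pool = symbols[k * pool_size:(k + 1) * pool_size]
        for j in range(sets_per_entity):
            members = [pool[i] for i in
                       sorted(rng.choice(pool_size, size=set_size, replace=False))]
            term = f"PMCB{k + 1}{_LETTERS[j]}-s1.csv-{entity}_targets_{j + 1}"
            sets.append(GeneSet(term, f"benchmark set for {entity}", members,
                                article_id=f"PMCB{k + 1}{_LETTERS[j]}"))
            entity_of[term] = entity
    return BenchmarkFixture(benchmark_library=GeneSetLibrary(sets),
                            entity_of=entity_of, entities=entities)


def spec_to_dict(spec: FixtureSpec) -> dict:
    return asdict(spec)


def spec_from_dict(data: dict) -> FixtureSpec:
    data = dict(data)
    data["planted_columns"] = [PlantedColumn(**c) for c in data.get("planted_columns", [])]
    data["planted_modules"] = [
        PlantedModule(**{**m, "set_size": tuple(m.get("set_size", (8, 15)))})
        for m in data.get("planted_modules", [])
    ]
    data["duplicate_plan"] = [DuplicateItem(**d) for d in data.get("duplicate_plan", [])]
    return FixtureSpec(**data)
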