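"""Extraction of gene sets from article bundles.

An article bundle is a directory holding one structured-markup metadata
document (tables embedded in ``table-wrap`` elements with ``label`` and
``caption``, supplements declared via ``supplementary-material``, in-text
references via ``xref``) plus any number of supplementary tables in
XLSX/CSV/TSV/TXT.  Every column of every table is considered: a column
becomes a gene set when strictly more than half of its unique non-blank
cells map to official gene symbols and the number of mapped genes lies
within the configured size bounds (default 5..2500 inclusive; fewer than 5
or more than 2500 are rejected).

The set's term is built from its provenance — article id, file name,
sheet/table label, and the column's first (header) cell — with a sequential
numeric suffix only on collision.  The description concatenates any
available caption, label, and in-text mention (at most the 15 words
preceding the reference to the table or file).
"""

from __future__ import annotations

import csv
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .gene_registry import GeneRegistry
from .gmt import GeneSet, format_gmt_line

logger = logging.getLogger(__name__)

SUPPORTED_EXTENSIONS = {".xlsx", ".xls", ".csv", ".tsv", ".txt"}
_TXT_SEPARATORS = ("\t", ",", ";")
_MENTION_WORDS = 15


class UnsupportedFormatError(ValueError):
    """Raised when no table extractor is registered for a file extension."""


class BundleError(ValueError):
    """Raised when the bundle's metadata document cannot be read."""


@dataclass
class ExtractionConfig:
    min_genes: int = 5
    max_genes: int = 2500
    min_mapped_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.min_genes < self.max_genes):
            raise ValueError("require 0 < min_genes < max_genes")
        if not (0 < self.min_mapped_fraction < 1):
            raise ValueError("require 0 < min_mapped_fraction < 1")


@dataclass
class Provenance:
    article_id: str
    filename: str
    label: str
    header_cell: str


@dataclass
class TableColumn:
    source_file: str
    sheet_or_table_label: str
    header_cell: str
    cells: list[str]


@dataclass
class Rejection:
    reason: str  # one of low_fraction, too_few, too_many
    column: TableColumn


@dataclass
class ExtractedGeneSet:
    term: str
    description: str
    raw_items: list[str]
    genes: list[str]
    provenance: Provenance

    def to_gene_set(self) -> GeneSet:
        return GeneSet(term=self.term, description=self.description,
                       genes=list(self.genes), article_id=self.provenance.article_id)


@dataclass
class EmbeddedTable:
    table_id: str
    label: str
    caption: str
    rows: list[list[str]]


@dataclass
class ArticleBundle:
    article_id: str
    bundle_path: Path
    metadata_filename: str
    tables: list[EmbeddedTable]
    supplement_files: list[tuple[str, str]]  # (filename, extension)
    supplement_meta: dict[str, tuple[str, str]]  # filename -> (label, caption)
    text_mentions: dict[str, str] = field(default_factory=dict)  # ref id -> <=15 words


# ---------------------------------------------------------------------------
# bundle parsing

def _element_text(el: etree._Element | None) -> str:
    if el is None:
        return ""
    return " ".join("".join(el.itertext()).split())


def _collect_mentions(root: etree._Element) -> dict[str, str]:
    """For every in-text reference, the (at most 15) words preceding it."""
    mentions: dict[str, str] = {}

    for para in root.iter("p"):
        buf: list[str] = []

        def visit(el: etree._Element) -> None:
            if el.text:
                buf.extend(el.text.split())
            for child in el:
                if child.tag == "xref":
                    rid = child.get("rid", "")
                    if rid and rid not in mentions:
                        mentions[rid] = " ".join(buf[-_MENTION_WORDS:])
                    if child.text:
                        buf.extend(child.text.split())
                else:
                    visit(child)
                if child.tail:
                    buf.extend(child.tail.split())

        visit(para)
    return mentions


def _parse_embedded_table(wrap: etree._Element) -> EmbeddedTable:
    rows: list[list[str]] = []
    table_el = wrap.find("table")
    if table_el is not None:
        for tr in table_el.iter("tr"):
            rows.append([_element_text(td) for td in tr if td.tag in ("td", "th")])
    return EmbeddedTable(
        table_id=wrap.get("id", ""),
        label=_element_text(wrap.find("label")),
        caption=_element_text(wrap.find("caption")),
        rows=_rectangularize(rows),
    )


def parse_bundle(bundle_path: str | os.PathLike) -> ArticleBundle:
    """Parse a bundle directory into an :class:`ArticleBundle`."""
    bundle_path = Path(bundle_path)
    xml_files = sorted(p.name for p in bundle_path.iterdir() if p.suffix == ".xml")
    if not xml_files:
        raise BundleError(f"no metadata XML document in bundle {bundle_path}")
    metadata_filename = xml_files[0]
    try:
        root = etree.parse(str(bundle_path / metadata_filename)).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise BundleError(f"unreadable metadata document {metadata_filename}: {exc}") from exc

    article_id = root.get("id", "")
    if not article_id:
        raise BundleError(f"metadata document {metadata_filename} lacks an article id")

    tables = [_parse_embedded_table(w) for w in root.iter("table-wrap")]
    supplement_meta: dict[str, tuple[str, str]] = {}
    for sm in root.iter("supplementary-material"):
        fname = sm.get("href", sm.get("id", ""))
        if fname:
            supplement_meta[fname] = (_element_text(sm.find("label")),
                                      _element_text(sm.find("caption")))

    supplement_files: list[tuple[str, str]] = []
    for p in sorted(bundle_path.iterdir()):
        if p.name == metadata_filename or not p.is_file():
            continue
        supplement_files.append((p.name, p.suffix.lower()))

    return ArticleBundle(
        article_id=article_id,
        bundle_path=bundle_path,
        metadata_filename=metadata_filename,
        tables=tables,
        supplement_files=supplement_files,
        supplement_meta=supplement_meta,
        text_mentions=_collect_mentions(root),
    )


# ---------------------------------------------------------------------------
# table extraction

def _rectangularize(rows: list[list[str]]) -> list[list[str]]:
    width = max((len(r) for r in rows), default=0)
    return [r + [""] * (width - len(r)) for r in rows]


def _infer_txt_separator(lines: list[str]) -> str:
    """Majority vote over the first lines: each line votes for the candidate
    separator it contains most often (ties broken tab > comma > semicolon)."""
    votes = {sep: 0 for sep in _TXT_SEPARATORS}
    for line in lines[:10]:
        counts = [(line.count(sep), -i) for i, sep in enumerate(_TXT_SEPARATORS)]
        best = max(range(len(_TXT_SEPARATORS)), key=lambda i: counts[i])
        if line.count(_TXT_SEPARATORS[best]) > 0:
            votes[_TXT_SEPARATORS[best]] += 1
    return max(_TXT_SEPARATORS, key=lambda s: votes[s])


def _read_delimited(path: Path, delimiter: str) -> list[list[str]]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return [list(row) for row in csv.reader(fh, delimiter=delimiter)]


def extract_tables(path: str | os.PathLike) -> list[tuple[str, list[list[str]]]]:
    """Load every table from a supplementary file.

    Returns (sheet_or_table_label, rectangular rows of strings) per table;
    one per workbook sheet, one (unlabeled) for delimited text files.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext in (".xlsx", ".xls"):
        from openpyxl import load_workbook

        wb = load_workbook(path, read_only=True, data_only=True)
        out = []
        for ws in wb.worksheets:
            rows = [["" if c is None else str(c) for c in row] for row in ws.iter_rows(values_only=True)]
            out.append((ws.title, _rectangularize(rows)))
        wb.close()
        return out
    if ext == ".csv":
        return [("", _rectangularize(_read_delimited(path, ",")))]
    if ext == ".tsv":
        return [("", _rectangularize(_read_delimited(path, "\t")))]
    if ext == ".txt":
        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()
        sep = _infer_txt_separator(lines)
        return [("", _rectangularize([line.split(sep) for line in lines]))]
    raise UnsupportedFormatError(f"no table extractor for extension {ext!r}")


def table_columns(source_file: str, label: str, rows: list[list[str]]) -> list[TableColumn]:
    """Split a rectangular table into columns; the first row is the header."""
    if not rows:
        return []
    header, *body = rows
    return [
        TableColumn(
            source_file=source_file,
            sheet_or_table_label=label,
            header_cell=header[j],
            cells=[row[j] for row in body],
        )
        for j in range(len(header))
    ]


# ---------------------------------------------------------------------------
# column filtering and naming

def column_to_gene_set(
    column: TableColumn,
    registry: GeneRegistry,
    config: ExtractionConfig | None = None,
) -> ExtractedGeneSet | Rejection:
    """Apply the retention filter to one table column.

    Retained iff mapped_fraction > min_mapped_fraction (strict) and the
    number of mapped genes is within [min_genes, max_genes].  Rejection is a
    value, with reason low_fraction / too_few / too_many.
    """
    config = config or ExtractionConfig()
    summary = registry.map_tokens(column.cells)
    if summary.mapped_fraction <= config.min_mapped_fraction:
        return Rejection("low_fraction", column)
    n = len(summary.mapped_symbols)
    if n < config.min_genes:
        return Rejection("too_few", column)
    if n > config.max_genes:
        return Rejection("too_many", column)
    raw_items = [c for c in column.cells if c.strip()]
    return ExtractedGeneSet(
        term="",
        description="",
        raw_items=raw_items,
        genes=summary.mapped_symbols,
        provenance=Provenance(article_id="", filename=column.source_file,
                              label=column.sheet_or_table_label,
                              header_cell=column.header_cell),
    )


def make_term(provenance: Provenance, already_used_terms: set[str]) -> str:
    """Provenance-derived term, suffixed with a sequential number on collision."""
    parts = [provenance.article_id, provenance.filename, provenance.label,
             provenance.header_cell]
    base = "-".join(p for p in parts if p)
    if base not in already_used_terms:
        return base
    i = 2
    while f"{base}-{i}" in already_used_terms:
        i += 1
    return f"{base}-{i}"


def make_description(caption: str | None, label: str | None, mention: str | None) -> str:
    """Concatenate available caption, label, and text mention, in that order."""
    return " ".join(p for p in (caption, label, mention) if p)


# ---------------------------------------------------------------------------
# whole-article extraction

def extract_article(
    bundle: ArticleBundle,
    registry: GeneRegistry,
    config: ExtractionConfig | None = None,
    used_terms: set[str] | None = None,
) -> list[ExtractedGeneSet]:
    """Extract all qualifying gene sets from one bundle.

    Traversal is deterministic: embedded tables in document order, then
    supplement files lexicographically, sheets in declared order, columns
    left to right.  ``used_terms`` (mutated in place) guarantees term
    uniqueness across a multi-article run.
    """
    config = config or ExtractionConfig()
    used = used_terms if used_terms is not None else set()
    out: list[ExtractedGeneSet] = []

    def emit(column: TableColumn, filename: str, label: str, caption: str,
             mention_key: str) -> None:
        result = column_to_gene_set(column, registry, config)
        if isinstance(result, Rejection):
            return
        result.provenance = Provenance(
            article_id=bundle.article_id, filename=filename,
            label=label, header_cell=column.header_cell)
        result.term = make_term(result.provenance, used)
        used.add(result.term)
        result.description = make_description(
            caption, label, bundle.text_mentions.get(mention_key, ""))
        out.append(result)

    for table in bundle.tables:
        for col in table_columns(bundle.metadata_filename, table.label, table.rows):
            emit(col, bundle.metadata_filename, table.label, table.caption,
                 table.table_id)

    for filename, ext in bundle.supplement_files:
        try:
            sheets = extract_tables(bundle.bundle_path / filename)
        except UnsupportedFormatError:
            logger.info("skipping %s: unsupported format %s", filename, ext)
            continue
        except Exception as exc:  # corrupt supplement: log and move on
            logger.warning("skipping unreadable supplement %s: %s", filename, exc)
            continue
        sup_label, sup_caption = bundle.supplement_meta.get(filename, ("", ""))
        for sheet_label, rows in sheets:
            for col in table_columns(filename, sheet_label, rows):
                emit(col, filename, sheet_label or sup_label, sup_caption, filename)

    return out


# ---------------------------------------------------------------------------
# resumable GMT appending

def _load_ledger(ledger_path: Path) -> dict:
    if ledger_path.exists():
        with open(ledger_path, "r", encoding="utf-8") as fh:
            return json.load(fh)
    return {"articles": [], "terms": []}


def load_used_terms(ledger_path: str | os.PathLike) -> set[str]:
    return set(_load_ledger(Path(ledger_path)).get("terms", []))


def processed_articles(ledger_path: str | os.PathLike) -> set[str]:
    return set(_load_ledger(Path(ledger_path)).get("articles", []))


def _atomic_write(path: Path, content: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), prefix=path.name + ".")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(content)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def append_gmt(
    sets: list[ExtractedGeneSet],
    gmt_path: str | os.PathLike,
    ledger_path: str | os.PathLike,
    article_ids: set[str] | None = None,
) -> int:
    """Append sets from not-yet-processed articles to the GMT; returns the count.

    The ledger records processed article ids and all used terms, so re-running
    on the same input appends nothing and leaves the GMT byte-identical.
    ``article_ids`` may name articles covered by this batch even when they
    produced zero sets, so they are not re-scanned on resume.
    """
    gmt_path, ledger_path = Path(gmt_path), Path(ledger_path)
    ledger = _load_ledger(ledger_path)
    done = set(ledger["articles"])
    fresh = [s for s in sets if s.provenance.article_id not in done]
    covered = {s.provenance.article_id for s in sets} | (article_ids or set())
    new_articles = sorted(covered - done)
    if not new_articles:
        return 0

    existing = gmt_path.read_text(encoding="utf-8") if gmt_path.exists() else ""
    added = "".join(format_gmt_line(s.to_gene_set()) + "\n" for s in fresh)
    _atomic_write(gmt_path, existing + added)

    ledger["articles"] = sorted(done | set(new_articles))
    ledger["terms"] = sorted(set(ledger["terms"]) | {s.term for s in fresh})
    _atomic_write(ledger_path, json.dumps(ledger, indent=1))
    return len(fresh)


def run_extraction(
    bundle_dirs: list[str | os.PathLike],
    registry: GeneRegistry,
    gmt_path: str | os.PathLike,
    ledger_path: str | os.PathLike,
    config: ExtractionConfig | None = None,
) -> int:
    """Extract every bundle and append to the GMT, resuming from the ledger."""
    config = config or ExtractionConfig()
    done = processed_articles(ledger_path)
    used = load_used_terms(ledger_path)
    total = 0
    for bundle_dir in bundle_dirs:
        bundle = parse_bundle(bundle_dir)
        if bundle.article_id in done:
            continue
        sets = extract_article(bundle, registry, config, used_terms=used)
        total += append_gmt(sets, gmt_path, ledger_path,
                            article_ids={bundle.article_id})
    return total
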