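import csv

import pytest

from tablemine import fixtures as fx
from tablemine.extraction import (
    ExtractionConfig,
    Provenance,
    Rejection,
    TableColumn,
    append_gmt,
    column_to_gene_set,
    extract_article,
    extract_tables,
    make_description,
    make_term,
    parse_bundle,
    run_extraction,
    table_columns,
)
from tablemine.gene_registry import GeneRecord, build_registry


@pytest.fixture(scope="module")
def wide_registry():
    """3000 resolvable symbols for the size-boundary columns."""
    return build_registry([GeneRecord(f"GENE{i:04d}", [], i, "") for i in range(1, 3001)])


def _column(cells, header="genes"):
    return TableColumn(source_file="f.csv", sheet_or_table_label="",
                       header_cell=header, cells=cells)


class TestBundleParsing:
    def test_embedded_table_caption_and_mention(self, tmp_path):
        spec = fx.FixtureSpec(seed=0, n_genes=20,
                              planted_columns=[fx.PlantedColumn(8, 2, "embedded")])
        fx.make_bundle(spec, tmp_path / "b")
        bundle = parse_bundle(tmp_path / "b")
        assert bundle.article_id == "PMCA1"
        assert len(bundle.tables) == 1
        table = bundle.tables[0]
        assert table.label == "Table 1"
        assert "Embedded table 1" in table.caption
        assert len(table.rows) == 11  # header + 10 cells
        mention = bundle.text_mentions[table.table_id]
        assert mention == "planted embedded column 1 appears in"
        assert len(mention.split()) <= 15

    def test_mention_truncated_to_fifteen_words(self, tmp_path):
        bundle_dir = tmp_path / "b"
        bundle_dir.mkdir()
        words = " ".join(f"w{i}" for i in range(30))
        (bundle_dir / "article.xml").write_text(
            f'<article id="PMCX"><body><p>{words} <xref rid="s.csv">S1</xref></p>'
            "</body></article>")
        bundle = parse_bundle(bundle_dir)
        mention = bundle.text_mentions["s.csv"]
        assert mention.split() == [f"w{i}" for i in range(15, 30)]

    def test_bundle_without_supplements(self, tmp_path):
        bundle_dir = tmp_path / "b"
        bundle_dir.mkdir()
        (bundle_dir / "article.xml").write_text('<article id="PMCX"><body/></article>')
        bundle = parse_bundle(bundle_dir)
        assert bundle.supplement_files == []
        assert bundle.tables == []

    def test_unreadable_metadata_is_a_bundle_error(self, tmp_path):
        bundle_dir = tmp_path / "b"
        bundle_dir.mkdir()
        (bundle_dir / "article.xml").write_text("<article id='x'")
        with pytest.raises(Exception, match="unreadable metadata"):
            parse_bundle(bundle_dir)


class TestTableReaders:
    def test_two_sheet_workbook_gives_two_labeled_tables(self, tmp_path):
        from openpyxl import Workbook

        wb = Workbook()
        ws1 = wb.active
        ws1.title = "first"
        ws1.append(["h1"])
        ws1.append(["a"])
        ws2 = wb.create_sheet("second")
        ws2.append(["h2", "x"])
        path = tmp_path / "t.xlsx"
        wb.save(path)
        tables = extract_tables(path)
        assert [label for label, _ in tables] == ["first", "second"]
        assert tables[0][1] == [["h1"], ["a"]]

    def test_quoted_commas_respected_in_csv(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text('h1,h2\n"a,b",c\n')
        _, rows = extract_tables(path)[0]
        assert rows[1] == ["a,b", "c"]

    def test_ragged_rows_padded(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("h1\th2\th3\na\nb\tc\n")
        _, rows = extract_tables(path)[0]
        assert rows == [["h1", "h2", "h3"], ["a", "", ""], ["b", "c", ""]]

    def test_unknown_extension_signals_unsupported(self, tmp_path):
        path = tmp_path / "t.docx"
        path.write_text("hello")
        from tablemine.extraction import UnsupportedFormatError

        with pytest.raises(UnsupportedFormatError):
            extract_tables(path)

    @pytest.mark.parametrize("seed", range(8))
    def test_txt_separator_inference_matches_modal_column_oracle(self, tmp_path, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        sep = ["\t", ",", ";"][seed % 3]
        n_cols = int(rng.integers(2, 6))
        lines = [sep.join(f"c{r}x{c}" for c in range(n_cols)) for r in range(8)]
        path = tmp_path / "t.txt"
        path.write_text("\n".join(lines) + "\n")
        _, rows = extract_tables(path)[0]
        # oracle: parse with each candidate, pick max modal column count
        best, best_cols = None, 0
        for cand in ("\t", ",", ";"):
            counts = [len(line.split(cand)) for line in lines]
            modal = max(set(counts), key=counts.count)
            if modal > best_cols:
                best, best_cols = cand, modal
        expected = [line.split(best) for line in lines]
        assert rows == expected


class TestColumnFilter:
    def test_six_of_ten_is_retained(self, wide_registry):
        cells = [f"GENE{i:04d}" for i in range(1, 7)] + ["q1x", "q2x", "q3x", "q4x"]
        result = column_to_gene_set(_column(cells), wide_registry)
        assert not isinstance(result, Rejection)
        assert result.genes == [f"GENE{i:04d}" for i in range(1, 7)]
        assert result.raw_items == cells

    def test_exactly_half_is_rejected(self, wide_registry):
        cells = [f"GENE{i:04d}" for i in range(1, 6)] + ["q1x", "q2x", "q3x", "q4x", "q5x"]
        result = column_to_gene_set(_column(cells), wide_registry)
        assert isinstance(result, Rejection)
        assert result.reason == "low_fraction"

    @pytest.mark.parametrize("n,reason", [(4, "too_few"), (2501, "too_many")])
    def test_size_bounds(self, wide_registry, n, reason):
        cells = [f"GENE{i:04d}" for i in range(1, n + 1)]
        result = column_to_gene_set(_column(cells), wide_registry)
        assert isinstance(result, Rejection) and result.reason == reason

    @pytest.mark.parametrize("n", [5, 2500])
    def test_inclusive_bounds_retained(self, wide_registry, n):
        cells = [f"GENE{i:04d}" for i in range(1, n + 1)]
        result = column_to_gene_set(_column(cells), wide_registry)
        assert not isinstance(result, Rejection)
        assert len(result.genes) == n

    def test_duplicate_cells_collapse_before_counting(self, wide_registry):
        # 6 unique of 10 unique resolve; duplicates must not change that
        cells = (["GENE0001"] * 5 + [f"GENE{i:04d}" for i in range(2, 7)]
                 + ["q1x", "q2x", "q3x", "q4x"])
        result = column_to_gene_set(_column(cells), wide_registry)
        assert not isinstance(result, Rejection)
        assert len(result.genes) == 6


class TestNaming:
    def test_first_occurrence_has_no_suffix(self):
        prov = Provenance("PMC1", "f.xlsx", "S1", "targets")
        assert make_term(prov, set()) == "PMC1-f.xlsx-S1-targets"

    def test_collisions_get_distinct_sequential_suffixes(self):
        prov = Provenance("PMC1", "f.xlsx", "S1", "targets")
        used = set()
        terms = []
        for _ in range(4):
            t = make_term(prov, used)
            used.add(t)
            terms.append(t)
        assert len(set(terms)) == 4
        assert terms[0] == "PMC1-f.xlsx-S1-targets"
        assert terms[1] != terms[0]

    def test_empty_components_are_skipped(self):
        prov = Provenance("PMC1", "s.csv", "", "genes")
        assert make_term(prov, set()) == "PMC1-s.csv-genes"

    @pytest.mark.parametrize("caption,label,mention,expected", [
        (None, None, None, ""),
        ("cap", None, None, "cap"),
        ("cap", None, "men", "cap men"),
        ("cap", "lab", "men", "cap lab men"),
        (None, "lab", "", "lab"),
    ])
    def test_description_concatenation(self, caption, label, mention, expected):
        assert make_description(caption, label, mention) == expected


class TestArticleExtraction:
    @pytest.mark.parametrize("seed", range(5))
    def test_extraction_matches_manifest_on_mixed_bundles(self, tmp_path, seed):
        rng_formats = ["csv", "tsv", "txt", "xlsx", "embedded"]
        columns = [
            fx.PlantedColumn(6, 4, rng_formats[seed % 5]),          # retained
            fx.PlantedColumn(5, 5, rng_formats[(seed + 1) % 5]),    # low_fraction
            fx.PlantedColumn(4, 0, rng_formats[(seed + 2) % 5]),    # too_few
            fx.PlantedColumn(10, 0, rng_formats[(seed + 3) % 5]),   # retained
        ]
        spec = fx.FixtureSpec(seed=seed, n_genes=40, article_id=f"PMCS{seed}",
                              planted_columns=columns)
        manifest = fx.make_bundle(spec, tmp_path / "b")
        registry = fx.build_fixture_registry(spec)
        sets = extract_article(parse_bundle(tmp_path / "b"), registry)
        expected = [c for c in manifest["columns"] if c["outcome"] == "retained"]
        assert [s.term for s in sets] == [c["term"] for c in expected]
        assert [s.genes for s in sets] == [c["genes"] for c in expected]
        assert [s.description for s in sets] == [c["description"] for c in expected]

    def test_numeric_measurement_column_yields_nothing(self, tmp_path, small_registry):
        bundle_dir = tmp_path / "b"
        bundle_dir.mkdir()
        (bundle_dir / "article.xml").write_text('<article id="PMCX"><body/></article>')
        with open(bundle_dir / "data.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["log2fc"])
            for i in range(20):
                writer.writerow([str(0.1 * i)])
        sets = extract_article(parse_bundle(bundle_dir), small_registry)
        assert sets == []

    def test_raw_items_appear_verbatim_in_source(self, tmp_path):
        spec = fx.FixtureSpec(seed=3, n_genes=30,
                              planted_columns=[fx.PlantedColumn(7, 3, "csv")])
        fx.make_bundle(spec, tmp_path / "b")
        registry = fx.build_fixture_registry(spec)
        sets = extract_article(parse_bundle(tmp_path / "b"), registry)
        source = (tmp_path / "b" / "supp01.csv").read_text()
        for item in sets[0].raw_items:
            assert item in source


class TestAppendLedger:
    def _extract(self, tmp_path, seed, article_id, used=None):
        spec = fx.FixtureSpec(seed=seed, n_genes=40, article_id=article_id,
                              planted_columns=[fx.PlantedColumn(8, 0, "csv"),
                                               fx.PlantedColumn(6, 2, "tsv")])
        fx.make_bundle(spec, tmp_path / article_id)
        registry = fx.build_fixture_registry(spec)
        return extract_article(parse_bundle(tmp_path / article_id), registry,
                               used_terms=used)

    def test_fresh_ledger_appends_all(self, tmp_path):
        sets = self._extract(tmp_path, 1, "PMCL1")
        n = append_gmt(sets, tmp_path / "lib.gmt", tmp_path / "ledger.json")
        assert n == len(sets) == 2

    def test_rerun_appends_zero_and_gmt_is_byte_identical(self, tmp_path):
        sets = self._extract(tmp_path, 1, "PMCL1")
        gmt, ledger = tmp_path / "lib.gmt", tmp_path / "ledger.json"
        append_gmt(sets, gmt, ledger)
        before = gmt.read_bytes()
        assert append_gmt(sets, gmt, ledger) == 0
        assert gmt.read_bytes() == before

    def test_only_unseen_articles_appended(self, tmp_path):
        gmt, ledger = tmp_path / "lib.gmt", tmp_path / "ledger.json"
        used = set()
        sets1 = self._extract(tmp_path, 1, "PMCL1", used)
        append_gmt(sets1, gmt, ledger)
        sets2 = self._extract(tmp_path, 2, "PMCL2", used)
        n = append_gmt(sets1 + sets2, gmt, ledger)
        assert n == len(sets2)

    def test_run_extraction_resumes_from_ledger(self, tmp_path):
        for seed, art in ((1, "PMCR1"), (2, "PMCR2")):
            spec = fx.FixtureSpec(seed=seed, n_genes=40, article_id=art,
                                  planted_columns=[fx.PlantedColumn(8, 0, "csv")])
            fx.make_bundle(spec, tmp_path / art)
        spec = fx.FixtureSpec(seed=9, n_genes=4000)
        registry = fx.build_fixture_registry(spec)
        gmt, ledger = tmp_path / "lib.gmt", tmp_path / "ledger.json"
        dirs = [tmp_path / "PMCR1", tmp_path / "PMCR2"]
        n1 = run_extraction(dirs, registry, gmt, ledger)
        assert n1 == 2
        content = gmt.read_bytes()
        assert run_extraction(dirs, registry, gmt, ledger) == 0
        assert gmt.read_bytes() == content
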