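from itertools import combinations

import numpy as np
import pytest

from oracles import understudied_flags
from tablemine import fixtures as fx
from tablemine.analytics import (
    benchmark_consensus,
    duplicate_fraction,
    find_duplicates,
    jaccard_index,
    shared_entity_similarity,
    understudied_sets,
)
from tablemine.annotation import build_consensus_library
from tablemine.gmt import GeneSet, GeneSetLibrary


class TestDuplicates:
    def test_triplicate_within_one_article(self):
        lib = GeneSetLibrary([
            GeneSet("PMC1-a.csv-t1", "", ["A", "B"], article_id="PMC1"),
            GeneSet("PMC1-a.csv-t2", "", ["B", "A"], article_id="PMC1"),
            GeneSet("PMC1-b.csv-t1", "", ["A", "B"], article_id="PMC1"),
        ])
        groups = find_duplicates(lib)
        assert len(groups) == 1
        assert groups[0].within_article_multiplicity == 3
        assert groups[0].cross_article_count == 1

    def test_cross_article_duplicate(self):
        lib = GeneSetLibrary([
            GeneSet("PMC1-a.csv-t", "", ["A", "B"], article_id="PMC1"),
            GeneSet("PMC2-a.csv-t", "", ["A", "B"], article_id="PMC2"),
        ])
        groups = find_duplicates(lib)
        assert groups[0].cross_article_count == 2
        assert groups[0].within_article_multiplicity == 1

    def test_groups_match_canonical_membership_oracle_and_partition(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(12)]
        sets = []
        for k in range(40):
            members = sorted(rng.choice(genes, size=rng.integers(2, 6), replace=False))
            sets.append(GeneSet(f"PMC{k % 7}-f.csv-s{k}", "", members,
                                article_id=f"PMC{k % 7}"))
        lib = GeneSetLibrary(sets)
        groups = find_duplicates(lib)
        oracle = {}
        for s in sets:
            oracle.setdefault(tuple(sorted(s.membership)), []).append(s.term)
        assert {frozenset(g.set_ids) for g in groups} == {
            frozenset(ids) for ids in oracle.values()}
        all_ids = [sid for g in groups for sid in g.set_ids]
        assert sorted(all_ids) == sorted(lib.terms)  # a partition

    def test_duplicate_fraction(self):
        lib = GeneSetLibrary([
            GeneSet("a", "", ["A"]), GeneSet("b", "", ["A"]),
            GeneSet("c", "", ["B"]), GeneSet("d", "", ["C"]),
        ])
        assert duplicate_fraction(lib) == pytest.approx(0.25)


def _citation_fixture(seed=0, n_orphan_sets=5, n_normal_sets=45):
    """Universe with well-cited genes plus citation-free orphans; sets made
    of orphans must be flagged, ordinary random sets must not."""
    rng = np.random.default_rng(seed)
    cited = {f"G{i:03d}": 40.0 + (i % 100) for i in range(200)}
    orphans = {f"ORF{i:02d}": 0.0 for i in range(15)}
    citations = {**cited, **orphans}
    genes = list(citations)
    sets = []
    for k in range(n_normal_sets):
        members = list(rng.choice(list(cited), size=rng.integers(5, 16), replace=False))
        sets.append(GeneSet(f"PMCN-{k}", "", members, article_id="PMCN"))
    for k in range(n_orphan_sets):
        members = list(rng.choice(list(orphans), size=8, replace=False))
        sets.append(GeneSet(f"PMCO-{k}", "", members, article_id="PMCO"))
    # anchor set so the universe contains every gene
    sets.append(GeneSet("PMCU-all", "", genes, article_id="PMCU"))
    return GeneSetLibrary(sets), citations


class TestUnderstudied:
    def test_zero_citation_sets_flagged(self):
        lib, citations = _citation_fixture()
        calls = understudied_sets(lib, citations, n_random=500, seed=1)
        flags = {c.set_id: c.flagged for c in calls}
        for k in range(5):
            assert flags[f"PMCO-{k}"]

    def test_null_drawn_sets_rarely_flagged(self):
        lib, citations = _citation_fixture(n_orphan_sets=0)
        n_flagged = 0
        for seed in range(5):
            calls = understudied_sets(lib, citations, n_random=400, seed=seed)
            n_flagged += sum(c.flagged for c in calls if c.set_id.startswith("PMCN"))
        assert n_flagged <= 2  # 3-sigma rule: flagging the null itself is rare

    def test_flags_match_independent_resampling_oracle(self):
        lib, citations = _citation_fixture()
        sizes = np.array([len(s.genes) for s in lib])
        bins = np.array([float(sizes.min()), float(sizes.max()) + 1.0])
        calls = understudied_sets(lib, citations, n_random=2000, bins=bins, seed=3)
        oracle = understudied_flags(
            {s.term: s.genes for s in lib}, sorted(lib.universe()), citations,
            bins.tolist(), n_random=4000, seed=99)
        for c in calls:
            assert c.flagged == oracle[c.set_id], c.set_id


class TestSharedEntityJaccard:
    def test_jaccard_basics(self):
        assert jaccard_index({"A", "B"}, {"A", "B"}) == 1.0
        assert jaccard_index({"A"}, {"B"}) == 0.0
        assert jaccard_index(set(), set()) == 0.0

    def test_identical_cross_article_same_entity_pair(self):
        lib = GeneSetLibrary([
            GeneSet("PMC1-a-KLF4", "", ["A", "B"], article_id="PMC1"),
            GeneSet("PMC2-a-KLF4", "", ["A", "B"], article_id="PMC2"),
            GeneSet("PMC3-a-SOX2", "", ["C", "D"], article_id="PMC3"),
        ])
        entity_of = {"PMC1-a-KLF4": "KLF4", "PMC2-a-KLF4": "KLF4",
                     "PMC3-a-SOX2": "SOX2"}
        same, diff, t, p = shared_entity_similarity(lib, entity_of)
        assert list(same) == [1.0]
        assert list(diff) == [0.0, 0.0]

    def test_planted_separation_is_significant(self):
        rng = np.random.default_rng(4)
        shared_pool = {e: [f"{e}G{i}" for i in range(10)] for e in ("TFA", "TFB", "TFC")}
        sets, entity_of = [], {}
        housekeeping = [f"HKG{i}" for i in range(4)]
        for e, pool in shared_pool.items():
            for k in range(6):
                private = [f"{e}P{k}x{i}" for i in range(10)]
                # a few housekeeping genes shared by everything keep the
                # different-entity Jaccard values positive and non-constant
                common = list(rng.choice(housekeeping, size=rng.integers(1, 4),
                                         replace=False))
                term = f"PMC{e}{k}-f.csv-{e}"
                sets.append(GeneSet(term, "", pool + private + common,
                                    article_id=f"PMC{e}{k}"))
                entity_of[term] = e
        lib = GeneSetLibrary(sets)
        same, diff, t, p = shared_entity_similarity(lib, entity_of)
        assert same.mean() > diff.mean()
        assert p < 0.05
        # permutation oracle: the observed mean difference is extreme
        values = np.concatenate([same, diff])
        observed = same.mean() - diff.mean()
        exceed = 0
        for _ in range(200):
            perm = rng.permutation(values)
            exceed += (perm[:len(same)].mean() - perm[len(same):].mean()) >= observed
        assert exceed / 200 < 0.05

    def test_empty_side_is_an_error(self):
        lib = GeneSetLibrary([
            GeneSet("PMC1-a-KLF4", "", ["A"], article_id="PMC1"),
            GeneSet("PMC2-a-KLF4", "", ["A", "B"], article_id="PMC2"),
        ])
        with pytest.raises(ValueError):
            shared_entity_similarity(lib, {"PMC1-a-KLF4": "KLF4",
                                           "PMC2-a-KLF4": "KLF4"})


@pytest.fixture(scope="module", name="fixture")
def _benchmark_fixture():
    return fx.make_benchmark_fixture(seed=2)


class TestBenchmark:
    def test_self_benchmark_near_perfect(self, fixture):
        consensus = build_consensus_library(fixture.benchmark_library, fixture.entities)
        report = benchmark_consensus(consensus, fixture.benchmark_library,
                                     fixture.entity_of, n_boot=300, seed=0)
        assert report.mean_auroc >= 0.95
        assert (report.scaled_ranks["scaled_rank"] <= 0.1).all()

    def test_shuffled_labels_near_chance(self, fixture):
        consensus = build_consensus_library(fixture.benchmark_library, fixture.entities)
        rng = np.random.default_rng(1)
        labels = list(fixture.entity_of.values())
        rng.shuffle(labels)
        shuffled = dict(zip(fixture.entity_of, labels))
        report = benchmark_consensus(consensus, fixture.benchmark_library,
                                     shuffled, n_boot=300, seed=0)
        assert 0.35 <= report.mean_auroc <= 0.65

    def test_mean_auroc_matches_exhaustive_downsample_oracle(self):
        """3 positives, 6 negatives: every C(6,3)=20 downsample can be
        enumerated and the bootstrap mean must sit within Monte-Carlo error."""
        from sklearn.metrics import roc_auc_score

        small = fx.make_benchmark_fixture(seed=5, n_entities=3, sets_per_entity=1)
        consensus = build_consensus_library(small.benchmark_library, small.entities)
        report = benchmark_consensus(consensus, small.benchmark_library,
                                     small.entity_of, n_boot=2000, seed=7)
        # rebuild the score matrix the same way the harness does
        from tablemine.enrichment import build_index, query

        index = build_index(consensus)
        y, x = [], []
        for s in small.benchmark_library:
            res = {r.set_id: r.p_value for r in query(index, s.genes)}
            for e in small.entities:
                y.append(e == small.entity_of[s.term])
                x.append(-np.log(max(res.get(e, 1.0), 1e-300)))
        y, x = np.array(y), np.array(x)
        pos, neg = np.flatnonzero(y), np.flatnonzero(~y)
        aucs = [roc_auc_score(y[list(pos) + list(c)], x[list(pos) + list(c)])
                for c in combinations(neg, len(pos))]
        assert report.mean_auroc == pytest.approx(float(np.mean(aucs)), abs=0.02)

    def test_seed_stability(self, fixture):
        consensus = build_consensus_library(fixture.benchmark_library, fixture.entities)
        aucs = [benchmark_consensus(consensus, fixture.benchmark_library,
                                    fixture.entity_of, n_boot=1000, seed=s).mean_auroc
                for s in (10, 11)]
        assert abs(aucs[0] - aucs[1]) <= 0.02

    def test_disjoint_entities_is_an_error(self, fixture):
        consensus = build_consensus_library(fixture.benchmark_library, ["REGA"])
        with pytest.raises(ValueError):
            benchmark_consensus(consensus, fixture.benchmark_library,
                                {t: "OTHER" for t in fixture.entity_of}, n_boot=10)
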