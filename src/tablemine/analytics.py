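"""Corpus-level statistics over a gene-set library.

Covers four analyses: profiling of membership-identical duplicate sets
(within- and cross-article multiplicities); detection of understudied sets
(per-gene median citation count more than 3 standard deviations below the
mean of medians of size-matched random sets); comparison of cross-article
Jaccard similarities between sets annotated with the same vs a different
named entity (Welch's t-test); and a bootstrap ROC harness for consensus
TF/kinase libraries with the negative class downsampled to class balance
on every iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ttest_ind
from sklearn.metrics import roc_auc_score, roc_curve

from .enrichment import build_index, query
from .gmt import GeneSetLibrary

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# duplicate profiling

@dataclass
class DuplicateProfile:
    set_ids: list[str]
    membership: frozenset[str]
    within_article_multiplicity: int   # max repeats inside a single article
    cross_article_count: int           # number of distinct articles


def _articles(library: GeneSetLibrary) -> dict[str, str]:
    return {s.term: (s.article_id if s.article_id else s.term.split("-", 1)[0])
            for s in library}


def find_duplicates(library: GeneSetLibrary) -> list[DuplicateProfile]:
    """Group sets by exact membership; every set lands in exactly one group."""
    article_of = _articles(library)
    groups: dict[frozenset[str], list[str]] = {}
    for s in library:
        groups.setdefault(s.membership, []).append(s.term)
    out = []
    for membership, ids in groups.items():
        per_article: dict[str, int] = {}
        for sid in ids:
            per_article[article_of[sid]] = per_article.get(article_of[sid], 0) + 1
        out.append(DuplicateProfile(
            set_ids=ids, membership=membership,
            within_article_multiplicity=max(per_article.values()),
            cross_article_count=len(per_article)))
    return out


def duplicate_fraction(library: GeneSetLibrary) -> float:
    """Fraction of library sets that are redundant copies of another set."""
    if len(library) == 0:
        return 0.0
    n_unique = len({s.membership for s in library})
    return (len(library) - n_unique) / len(library)


# ---------------------------------------------------------------------------
# understudied sets

@dataclass
class UnderstudiedCall:
    set_id: str
    median_citations: float
    size_bin: int
    null_mean: float
    null_sd: float
    flagged: bool


def _default_bins(sizes: np.ndarray, n_bins: int = 5) -> np.ndarray:
    lo, hi = sizes.min(), sizes.max()
    if lo == hi:
        return np.array([lo, hi + 1.0])
    return np.geomspace(lo, hi + 1.0, n_bins + 1)


def understudied_sets(
    library: GeneSetLibrary,
    citations: dict[str, float],
    n_random: int = 1000,
    bins: np.ndarray | None = None,
    seed: int | None = None,
) -> list[UnderstudiedCall]:
    """Flag sets whose per-gene citation median falls more than 3 SD below
    the mean of medians of randomly assembled size-matched sets.

    Sets are binned by size (log-spaced by default).  Per bin, ``n_random``
    random sets are drawn from the library universe, each with a size
    sampled from the real sizes in the bin; the null mean and SD are over
    their citation medians.  Genes missing from the citation table count as
    0 citations (logged).
    """
    universe = sorted(library.universe())
    missing = [g for g in universe if g not in citations]
    if missing:
        logger.info("%d universe genes missing from citations table; counted as 0",
                    len(missing))
    cite = np.array([float(citations.get(g, 0.0)) for g in universe])
    gene_idx = {g: i for i, g in enumerate(universe)}

    sizes = np.array([len(s.genes) for s in library])
    if bins is None:
        bins = _default_bins(sizes)
    bin_of = np.clip(np.digitize(sizes, bins) - 1, 0, len(bins) - 2)

    rng = np.random.default_rng(seed)
    null_stats: dict[int, tuple[float, float]] = {}
    for b in sorted(set(bin_of.tolist())):
        bin_sizes = sizes[bin_of == b]
        draw_sizes = rng.choice(bin_sizes, size=n_random, replace=True)
        medians = np.array([
            float(np.median(cite[rng.choice(len(universe), size=int(k), replace=False)]))
            for k in draw_sizes
        ])
        if medians.size < 2:
            raise ValueError(f"size bin {b} has fewer than 2 random medians")
        null_stats[b] = (float(medians.mean()), float(medians.std(ddof=1)))

    out = []
    for s, b in zip(library, bin_of.tolist()):
        med = float(np.median([cite[gene_idx[g]] for g in s.genes]))
        mean, sd = null_stats[b]
        out.append(UnderstudiedCall(
            set_id=s.term, median_citations=med, size_bin=int(b),
            null_mean=mean, null_sd=sd, flagged=med < mean - 3.0 * sd))
    return out


# ---------------------------------------------------------------------------
# shared-entity Jaccard comparison

def jaccard_index(x: frozenset[str] | set[str], y: frozenset[str] | set[str]) -> float:
    union = len(x | y)
    return len(x & y) / union if union else 0.0


def shared_entity_similarity(
    library: GeneSetLibrary,
    entity_of: dict[str, str],
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Cross-article pairwise Jaccard values split by same vs different entity.

    ``entity_of`` maps each set id to its single annotated entity.  Returns
    (same_entity_values, different_entity_values, Welch t, p).
    """
    article_of = _articles(library)
    annotated = [s for s in library if s.term in entity_of]
    same, diff = [], []
    for i, sa in enumerate(annotated):
        for sb in annotated[i + 1:]:
            if article_of[sa.term] == article_of[sb.term]:
                continue
            j = jaccard_index(sa.membership, sb.membership)
            (same if entity_of[sa.term] == entity_of[sb.term] else diff).append(j)
    if not same or not diff:
        raise ValueError("need at least one same-entity and one different-entity "
                         "cross-article pair")
    same_arr, diff_arr = np.array(same), np.array(diff)
    t, p = ttest_ind(same_arr, diff_arr, equal_var=False)
    return same_arr, diff_arr, float(t), float(p)


# ---------------------------------------------------------------------------
# consensus-library benchmarking

@dataclass
class BenchmarkReport:
    scaled_ranks: pd.DataFrame      # benchmark set id, entity, scaled rank
    fpr_grid: np.ndarray
    mean_roc: np.ndarray            # mean TPR on the grid
    mean_auroc: float
    per_iteration_auroc: np.ndarray


def benchmark_consensus(
    consensus_library: GeneSetLibrary,
    benchmark_library: GeneSetLibrary,
    entity_of: dict[str, str],
    n_boot: int = 5000,
    fpr_grid: np.ndarray | None = None,
    seed: int | None = None,
) -> BenchmarkReport:
    """Recovery of the true entity when benchmark sets are enriched against
    the consensus library.

    Each benchmark set is queried with Fisher's exact test against all
    consensus sets; the score of a (benchmark set, entity) pair is its
    -log p.  Pairs whose entity matches the benchmark set's true entity are
    positives.  Per bootstrap iteration the negative class is downsampled
    to the positive-class size, the ROC computed and linearly interpolated
    onto ``fpr_grid``; the mean curve and mean AUROC over ``n_boot``
    iterations are reported, along with each entity's scaled rank
    (rank - 1) / (n - 1) with average tie handling.
    """
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    entities = consensus_library.terms
    covered = [s for s in benchmark_library if entity_of.get(s.term) in entities]
    if not covered:
        raise ValueError("no benchmark set's entity appears in the consensus library")

    index = build_index(consensus_library)
    scores = np.zeros((len(covered), len(entities)))
    labels = np.zeros((len(covered), len(entities)), dtype=bool)
    rank_rows = []
    for i, bset in enumerate(covered):
        in_bg = [g for g in bset.genes if g in index.gene_to_int]
        results = {r.set_id: r.p_value for r in query(index, in_bg)} if in_bg else {}
        p = np.array([results.get(e, 1.0) for e in entities])
        scores[i] = -np.log(np.maximum(p, 1e-300))
        labels[i] = [e == entity_of[bset.term] for e in entities]
        ranks = rankdata(p, method="average")
        true_rank = float(ranks[entities.index(entity_of[bset.term])])
        scaled = (true_rank - 1) / (len(entities) - 1) if len(entities) > 1 else 0.0
        rank_rows.append({"set_id": bset.term, "entity": entity_of[bset.term],
                          "scaled_rank": scaled})

    y = labels.ravel()
    x = scores.ravel()
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    n_pos = pos_idx.size
    if n_pos == 0 or neg_idx.size == 0:
        raise ValueError("benchmark produced no positive or no negative pairs")

    rng = np.random.default_rng(seed)
    tprs = np.empty((n_boot, fpr_grid.size))
    aucs = np.empty(n_boot)
    for it in range(n_boot):
        neg_sample = (rng.choice(neg_idx, size=n_pos, replace=False)
                      if neg_idx.size > n_pos else neg_idx)
        idx = np.concatenate([pos_idx, neg_sample])
        fpr, tpr, _ = roc_curve(y[idx], x[idx])
        tprs[it] = np.interp(fpr_grid, fpr, tpr)
        aucs[it] = roc_auc_score(y[idx], x[idx])

    return BenchmarkReport(
        scaled_ranks=pd.DataFrame(rank_rows),
        fpr_grid=fpr_grid,
        mean_roc=tprs.mean(axis=0),
        mean_auroc=float(aucs.mean()),
        per_iteration_auroc=aucs,
    )
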