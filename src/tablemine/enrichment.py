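"""Fast overlap-based gene-set search with Fisher's exact test.

The index integer-encodes a GMT library against the background universe
formed by the union of all member genes.  Sets with identical membership
are encoded once and fanned back out to all of their ids at query time.
Each query set is scored against every library set with the one-sided
(over-representation) Fisher exact test; Benjamini-Hochberg adjusted
p-values are computed across all scored sets and results are returned
sorted ascending by p-value (ties broken by descending overlap, then id).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .gmt import GeneSetLibrary


class EmptyQueryError(ValueError):
    """Raised when no query gene is present in the index background."""


@dataclass
class SetIndex:
    background: list[str]                 # sorted universe of all library genes
    gene_to_int: dict[str, int]
    unique_members: list[np.ndarray]      # sorted integer codes, one per unique membership
    unique_to_set_ids: list[list[str]]    # fan-out from unique membership to set ids
    set_ids: list[str]
    set_to_unique: dict[str, int] = field(repr=False, default_factory=dict)
    _fold_to_int: dict[str, int] = field(repr=False, default_factory=dict)

    @property
    def n_background(self) -> int:
        return len(self.background)

    @property
    def dedup_map(self) -> dict[str, list[str]]:
        """Representative set id -> all set ids sharing its exact membership."""
        return {ids[0]: list(ids) for ids in self.unique_to_set_ids}

    def members_of(self, set_id: str) -> np.ndarray:
        return self.unique_members[self.set_to_unique[set_id]]


@dataclass
class EnrichmentResult:
    set_id: str
    overlap_size: int
    overlap_genes: list[str]
    set_size: int
    p_value: float
    adj_p: float
    odds_ratio: float


def build_index(library: GeneSetLibrary) -> SetIndex:
    """Integer-encode a library; deduplicate identical-content sets."""
    if len(library) == 0:
        raise ValueError("cannot index an empty library")
    background = sorted(library.universe())
    gene_to_int = {g: i for i, g in enumerate(background)}
    fold_to_int: dict[str, int] = {}
    for g, i in gene_to_int.items():
        fold_to_int.setdefault(g.casefold(), i)

    unique_members: list[np.ndarray] = []
    unique_to_set_ids: list[list[str]] = []
    membership_key: dict[frozenset[str], int] = {}
    set_to_unique: dict[str, int] = {}
    for s in library:
        key = s.membership
        if key not in membership_key:
            membership_key[key] = len(unique_members)
            codes = np.array(sorted(gene_to_int[g] for g in s.genes), dtype=np.int64)
            unique_members.append(codes)
            unique_to_set_ids.append([])
        idx = membership_key[key]
        unique_to_set_ids[idx].append(s.term)
        set_to_unique[s.term] = idx

    return SetIndex(
        background=background,
        gene_to_int=gene_to_int,
        unique_members=unique_members,
        unique_to_set_ids=unique_to_set_ids,
        set_ids=library.terms,
        set_to_unique=set_to_unique,
        _fold_to_int=fold_to_int,
    )


def encode_query(index: SetIndex, genes: list[str]) -> tuple[np.ndarray, int]:
    """Map query symbols onto background codes.

    Returns (sorted codes, number of unique query genes absent from the
    background).  Matching is case-insensitive; duplicates collapse; an
    entirely unknown query raises :class:`EmptyQueryError`.
    """
    fold = index._fold_to_int
    unique = list(dict.fromkeys(g.strip().casefold() for g in genes if g.strip()))
    codes = sorted({fold[g] for g in unique if g in fold})
    n_dropped = len(unique) - len(codes)
    if not codes:
        raise EmptyQueryError("no query gene found in the library background")
    return np.array(codes, dtype=np.int64), n_dropped


def fisher_overlap(a: int, b: int, c: int, d: int,
                   alternative: str = "greater") -> tuple[float, float]:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    a = overlap, b = query-only, c = set-only, d = neither; a+b+c+d is the
    background size.  Default alternative is the one-sided
    over-representation tail P(X >= a) under the hypergeometric null.
    The odds ratio is the exact cross-product (a*d)/(b*c): +inf when
    b*c = 0 with a*d > 0, and 0 when a*d = 0.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be nonnegative")
    if a * d == 0:
        odds = 0.0
    elif b * c == 0:
        odds = float("inf")
    else:
        odds = (a * d) / (b * c)
    if alternative == "greater":
        n = a + b + c + d
        p = float(hypergeom.sf(a - 1, n, a + b, a + c))
    elif alternative == "two-sided":
        p = float(_scipy_fisher([[a, b], [c, d]], alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return min(p, 1.0), odds


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def query(
    index: SetIndex,
    genes: list[str],
    alternative: str = "greater",
    max_adj_p: float | None = None,
    min_overlap: int = 0,
) -> list[EnrichmentResult]:
    """Score a query gene list against every set in the index.

    Overlaps are computed once per unique membership and fanned out to all
    set ids sharing it; BH adjustment spans all scored sets.  Results come
    back sorted ascending by p-value, ties broken by descending overlap and
    then set id.  Optional filters (``max_adj_p``, ``min_overlap``) apply
    after adjustment.
    """
    q_codes, _ = encode_query(index, genes)
    n_bg = index.n_background
    k_query = len(q_codes)
    q_mask = np.zeros(n_bg, dtype=bool)
    q_mask[q_codes] = True

    n_unique = len(index.unique_members)
    overlaps = np.empty(n_unique, dtype=np.int64)
    sizes = np.empty(n_unique, dtype=np.int64)
    for i, codes in enumerate(index.unique_members):
        sizes[i] = codes.size
        overlaps[i] = int(q_mask[codes].sum())

    if alternative == "greater":
        p_unique = hypergeom.sf(overlaps - 1, n_bg, sizes, k_query)
        p_unique = np.minimum(np.asarray(p_unique, dtype=float), 1.0)
    else:
        p_unique = np.array([
            fisher_overlap(int(a), k_query - int(a), int(s) - int(a),
                           n_bg - k_query - int(s) + int(a),
                           alternative=alternative)[0]
            for a, s in zip(overlaps, sizes)
        ])

    int_to_gene = index.background
    results: list[EnrichmentResult] = []
    for i, ids in enumerate(index.unique_to_set_ids):
        a = int(overlaps[i])
        s = int(sizes[i])
        b, c = k_query - a, s - a
        d = n_bg - a - b - c
        if a * d == 0:
            odds = 0.0
        elif b * c == 0:
            odds = float("inf")
        else:
            odds = (a * d) / (b * c)
        overlap_genes = [int_to_gene[code] for code in index.unique_members[i] if q_mask[code]]
        for set_id in ids:
            results.append(EnrichmentResult(
                set_id=set_id, overlap_size=a, overlap_genes=overlap_genes,
                set_size=s, p_value=float(p_unique[i]), adj_p=np.nan, odds_ratio=odds))

    adj = bh_adjust([r.p_value for r in results])
    for r, ap in zip(results, adj):
        r.adj_p = float(ap)

    # rank on p rounded to 12 significant digits: mathematically equal
    # tails computed from different tables can differ in the last float
    # ulp, and the overlap/id tie-break must apply to such ties
    results.sort(key=lambda r: (float(f"{r.p_value:.12e}"),
                                -r.overlap_size, r.set_id))
    if max_adj_p is not None:
        results = [r for r in results if r.adj_p <= max_adj_p]
    if min_overlap:
        results = [r for r in results if r.overlap_size >= min_overlap]
    return results
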