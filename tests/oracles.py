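"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exact rational arithmetic,
plain-python loops — and shares no code path with the package
implementations it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def hypergeom_tail(a: int, b: int, c: int, d: int) -> Fraction:
    """P(X >= a) for the overlap of a 2x2 table with fixed margins.

    Exhaustively sums the hypergeometric pmf with exact rationals: draw
    n = a + c items (the set) from N = a+b+c+d, count successes among the
    K = a + b query genes.
    """
    n_total = a + b + c + d
    k_query = a + b
    n_set = a + c
    hi = min(k_query, n_set)
    total = comb(n_total, n_set)
    acc = 0
    for x in range(a, hi + 1):
        acc += comb(k_query, x) * comb(n_total - k_query, n_set - x)
    return Fraction(acc, total)


def bh_stepup(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg by hand: p * m / rank with a running minimum."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = running
    return adjusted


def naive_enrichment(sets: dict[str, frozenset[str]], query_genes: set[str]):
    """Per-set Fisher overlap scoring without the index machinery.

    Returns {set_id: (overlap, p, odds_ratio, adj_p, p_exact)} using the
    exact rational tail (kept as a Fraction) and hand BH over all sets.
    """
    universe = set().union(*sets.values())
    q = query_genes & universe
    n_total = len(universe)
    rows = {}
    for sid, members in sets.items():
        a = len(q & members)
        b = len(q) - a
        c = len(members) - a
        d = n_total - a - b - c
        p_exact = hypergeom_tail(a, b, c, d)
        if a * d == 0:
            odds = 0.0
        elif b * c == 0:
            odds = float("inf")
        else:
            odds = (a * d) / (b * c)
        rows[sid] = [a, float(p_exact), odds, p_exact]
    adj = bh_stepup([rows[sid][1] for sid in sets])
    return {sid: (rows[sid][0], rows[sid][1], rows[sid][2], ap, rows[sid][3])
            for sid, ap in zip(sets, adj)}


def triple_loop_cooccurrence(A) -> list[list[int]]:
    """Phi by explicit gene-pair-by-set counting; zero diagonal."""
    n_genes = len(A)
    n_sets = len(A[0]) if n_genes else 0
    phi = [[0] * n_genes for _ in range(n_genes)]
    for i in range(n_genes):
        for j in range(n_genes):
            if i == j:
                continue
            for k in range(n_sets):
                if A[i][k] and A[j][k]:
                    phi[i][j] += 1
    return phi


def understudied_flags(
    set_members: dict[str, list[str]],
    universe: list[str],
    citations: dict[str, float],
    bin_edges: list[float],
    n_random: int,
    seed: int,
) -> dict[str, bool]:
    """Flagging oracle with its own RNG and plain loops.

    Same statistic (mean of medians of random size-matched sets minus three
    sample SDs) but an entirely separate implementation; with a large
    ``n_random`` the flags are stable wherever the margin is wide.
    """
    import random
    import statistics

    rng = random.Random(seed)
    sizes = {sid: len(g) for sid, g in set_members.items()}

    def bin_of(size: int) -> int:
        b = 0
        for e in bin_edges[1:-1]:
            if size >= e:
                b += 1
        return b

    bins: dict[int, list[int]] = {}
    for sid, size in sizes.items():
        bins.setdefault(bin_of(size), []).append(size)

    null: dict[int, tuple[float, float]] = {}
    for b, bin_sizes in bins.items():
        medians = []
        for _ in range(n_random):
            k = rng.choice(bin_sizes)
            sample = rng.sample(universe, k)
            medians.append(statistics.median(citations.get(g, 0.0) for g in sample))
        null[b] = (statistics.mean(medians), statistics.stdev(medians))

    flags = {}
    for sid, genes in set_members.items():
        med = statistics.median(citations.get(g, 0.0) for g in genes)
        mean, sd = null[bin_of(sizes[sid])]
        flags[sid] = med < mean - 3.0 * sd
    return flags
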