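"""Gene-gene co-occurrence similarity and gene-function prediction.

From a binary membership matrix A (genes x sets) the co-occurrence counts
are Phi = A @ A.T with the diagonal zeroed.  With phi0 the total number of
(ordered) co-occurrences, the joint probability of a gene pair is
P(a, b) = Phi(a, b) / phi0 and the marginal P(a) = sum_{b != a} Phi(a, b) / phi0,
so the marginals sum to 1 exactly.  Three similarity metrics are supported:

    Cosine(a, b)  = P(a, b) / sqrt(P(a) P(b))
    Jaccard(a, b) = P(a, b) / (P(a) + P(b) - P(a, b))
    NPWMI(a, b)   = (-1 / ln P(a, b)) * max{0, ln(P(a, b) / (P(a) P(b)))}

NPWMI lies in [0, 1]: 0 under exact independence or a never-co-occurring
pair, 1 under perfect dependence (defined by continuity at P(a, b) = 1).
The diagonal of every similarity matrix is set to 0.

Gene/term association scores are G = (D @ L) / (L column counts), i.e.
G(i, j) is the mean similarity of gene i to the genes annotated to term j
(the zero diagonal makes self-similarity contribute 0).  Prediction quality
is evaluated per term with the AUROC of the G column against the L column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .gmt import GeneSetLibrary

logger = logging.getLogger(__name__)

METRICS = ("cosine", "jaccard", "npwmi")

DEFAULT_MAX_SET_SIZE = 2000
DEFAULT_SAMPLE_SIZE = 50_000


@dataclass
class MembershipMatrix:
    A: np.ndarray               # genes x sets, binary
    gene_order: list[str]
    set_order: list[str]


@dataclass
class CooccurrenceModel:
    Phi: np.ndarray             # co-occurrence counts, zero diagonal
    phi0: float                 # total (ordered) co-occurrences
    P_joint: np.ndarray
    P_marginal: np.ndarray
    gene_order: list[str]


@dataclass
class SimilarityMatrix:
    D: np.ndarray
    metric: str
    gene_order: list[str]


@dataclass
class AssociationScores:
    G: pd.DataFrame             # genes x terms
    L: pd.DataFrame             # binary annotation matrix, same shape
    set_sizes: pd.Series


def build_membership(
    library: GeneSetLibrary,
    max_set_size: int = DEFAULT_MAX_SET_SIZE,
    sample_size: int | None = None,
    seed: int | None = None,
) -> MembershipMatrix:
    """Binary gene x set matrix from a library.

    Sets with ``max_set_size`` or more genes are removed (strictly smaller
    sets are retained); when ``sample_size`` is given, that many of the
    remaining sets are drawn uniformly without replacement under ``seed``.
    Rows cover exactly the genes appearing in the retained sets.
    """
    kept = [s for s in library if len(s.genes) < max_set_size]
    if not kept:
        raise ValueError("no sets remain after the size filter")
    if sample_size is not None and sample_size < len(kept):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(kept), size=sample_size, replace=False)
        kept = [kept[i] for i in sorted(idx)]

    genes = sorted({g for s in kept for g in s.genes})
    gene_idx = {g: i for i, g in enumerate(genes)}
    A = np.zeros((len(genes), len(kept)), dtype=np.int64)
    for j, s in enumerate(kept):
        for g in s.genes:
            A[gene_idx[g], j] = 1
    return MembershipMatrix(A=A, gene_order=genes, set_order=[s.term for s in kept])


def cooccurrence_probabilities(membership: MembershipMatrix | np.ndarray,
                               gene_order: list[str] | None = None) -> CooccurrenceModel:
    """Counts, joint and marginal co-occurrence probabilities from A."""
    if isinstance(membership, MembershipMatrix):
        A = membership.A
        gene_order = membership.gene_order
    else:
        A = np.asarray(membership)
        gene_order = gene_order or [f"g{i}" for i in range(A.shape[0])]
    if not np.isin(A, (0, 1)).all():
        raise ValueError("membership matrix must be binary")

    Phi = (A @ A.T).astype(float)
    np.fill_diagonal(Phi, 0.0)
    phi0 = float(Phi.sum())
    if phi0 == 0:
        raise ValueError("no gene pair ever co-occurs; co-occurrence model undefined")
    P_joint = Phi / phi0
    P_marginal = Phi.sum(axis=1) / phi0
    return CooccurrenceModel(Phi=Phi, phi0=phi0, P_joint=P_joint,
                             P_marginal=P_marginal, gene_order=list(gene_order))


def similarity(model: CooccurrenceModel, metric: str) -> SimilarityMatrix:
    """One of cosine / jaccard / npwmi on the co-occurrence probabilities."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    Pj = model.P_joint
    Pm = model.P_marginal
    with np.errstate(divide="ignore", invalid="ignore"):
        if metric == "cosine":
            denom = np.sqrt(np.outer(Pm, Pm))
            D = np.where(denom > 0, Pj / np.where(denom > 0, denom, 1.0), 0.0)
        elif metric == "jaccard":
            denom = Pm[:, None] + Pm[None, :] - Pj
            D = np.where(denom > 0, Pj / np.where(denom > 0, denom, 1.0), 0.0)
        else:
            D = np.zeros_like(Pj)
            pos = Pj > 0
            denom = np.outer(Pm, Pm)
            ratio = np.where(pos & (denom > 0), Pj / np.where(denom > 0, denom, 1.0), 1.0)
            pmi = np.maximum(0.0, np.log(ratio))
            log_pj = np.log(np.where(pos, Pj, 1.0))
            # P = 1 would divide by ln(1) = 0; by continuity NPWMI -> 1 there
            saturated = pos & (Pj >= 1.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                D = np.where(pos & ~saturated, -pmi / np.where(log_pj != 0, log_pj, 1.0), D)
            D = np.where(saturated, 1.0, D)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # symmetrize against floating-point asymmetry
    return SimilarityMatrix(D=D, metric=metric, gene_order=model.gene_order)


def annotation_matrix(annotation_library: GeneSetLibrary,
                      gene_order: list[str]) -> pd.DataFrame:
    """Binary gene x term matrix L restricted to ``gene_order``."""
    gene_idx = {g: i for i, g in enumerate(gene_order)}
    L = np.zeros((len(gene_order), len(annotation_library)), dtype=np.int64)
    for j, s in enumerate(annotation_library):
        for g in s.genes:
            i = gene_idx.get(g)
            if i is not None:
                L[i, j] = 1
    return pd.DataFrame(L, index=gene_order, columns=annotation_library.terms)


def association_scores(D: SimilarityMatrix | np.ndarray, L: pd.DataFrame) -> AssociationScores:
    """G = (D @ L) / column counts of L, elementwise.

    G(i, j) is the mean similarity of gene i to all genes annotated to term
    j.  A term annotated to zero genes has no mean and is an error.
    """
    if isinstance(D, SimilarityMatrix):
        Dm = D.D
        if list(L.index) != D.gene_order:
            L = L.reindex(D.gene_order, fill_value=0)
    else:
        Dm = np.asarray(D, dtype=float)
    counts = L.to_numpy().sum(axis=0)
    empty = [t for t, c in zip(L.columns, counts) if c == 0]
    if empty:
        raise ValueError(f"terms with no annotated genes: {empty[:5]}")
    G = (Dm @ L.to_numpy()) / counts[None, :]
    return AssociationScores(
        G=pd.DataFrame(G, index=L.index, columns=L.columns),
        L=L,
        set_sizes=pd.Series(counts, index=L.columns),
    )


def evaluate_prediction(scores: AssociationScores) -> pd.DataFrame:
    """Per-term AUROC of the association scores against the annotations.

    Terms whose genes are all positive or all negative have no ROC and are
    skipped (logged).  Returns a table with term, n_pos and auroc.
    """
    rows = []
    y_all = scores.L.to_numpy()
    g_all = scores.G.to_numpy()
    for j, term in enumerate(scores.L.columns):
        y = y_all[:, j]
        n_pos = int(y.sum())
        if n_pos == 0 or n_pos == len(y):
            logger.info("term %s degenerate (n_pos=%d); skipped", term, n_pos)
            continue
        rows.append({"term": term, "n_pos": n_pos,
                     "auroc": float(roc_auc_score(y, g_all[:, j]))})
    return pd.DataFrame(rows, columns=["term", "n_pos", "auroc"])


def predict_functions(
    library: GeneSetLibrary,
    annotation_library: GeneSetLibrary,
    metric: str = "npwmi",
    max_set_size: int = DEFAULT_MAX_SET_SIZE,
    sample_size: int | None = None,
    seed: int | None = None,
) -> tuple[AssociationScores, pd.DataFrame]:
    """End-to-end gene-function prediction: membership -> similarity -> G -> AUROC."""
    membership = build_membership(library, max_set_size=max_set_size,
                                  sample_size=sample_size, seed=seed)
    model = cooccurrence_probabilities(membership)
    D = similarity(model, metric)
    L = annotation_matrix(annotation_library, D.gene_order)
    L = L.loc[:, L.sum(axis=0) > 0]
    scores = association_scores(D, L)
    return scores, evaluate_prediction(scores)
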