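"""Discovery of gene-set pairs that overlap strongly but whose source
abstracts share no vocabulary.

Abstracts are tokenized, stop-word-cleaned and lemmatized, converted to
TF-IDF vectors, and compared pairwise with the cosine (linear kernel on
normalized vectors).  A candidate pair must come from two different
articles whose abstracts have exactly zero cosine similarity, overlap with
Fisher p < 0.05, have non-identical memberships, and share strictly more
than 50 genes.  Zero similarity is decided on the exact integer count
vectors (two abstracts sharing no processed token), so floating-point
noise can neither create nor destroy a zero.

Retained pairs are annotated with the fraction of overlap genes appearing
in supplied "sticky protein", top-cited and top-expressed lists, plus gene
and disease entities recognized in the two column titles; the gene/disease
analysis stream keeps the top 10,000 most significant pairs with a sticky
fraction strictly below 10%.  For each such pair a hypothesis prompt for a
language-model client can be composed; the shipped client is a recording
mock, so no network call is ever made.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import TfidfVectorizer

from ._textproc import preprocess_text
from .annotation import Vocabulary, annotate_title, tokenize_title
from .enrichment import SetIndex, fisher_overlap
from .gene_registry import GeneRegistry
from .gmt import GeneSetLibrary

logger = logging.getLogger(__name__)

MAX_PAIR_P = 0.05
MIN_OVERLAP_GENES = 50          # strictly more than this many shared genes
MAX_STICKY_FRACTION = 0.10      # strictly below
TOP_PAIRS = 10_000

USER_PROMPT_TEMPLATE = (
    "Based on the pair of extracted gene sets from two research publications, "
    "hypothesize why there might be a connection between these gene sets based "
    "on the two abstracts, and the provided gene and disease terms: "
    "Gene set term 1: [term1], disease from gene set 1 term: [disease], "
    "abstract of publication for gene set term 1: [term1_abstract], "
    "Gene set term 2: [term2], gene(s) from gene set 2 term: [gene], "
    "abstract of publication for gene set term 2: [term2_abstract]."
)

SYSTEM_PROMPT = (
    "You are a biologist who attempts to generate a hypothesis about why two "
    "gene sets, which are lists of genes, may have a high overlap despite "
    "being extracted from two publications that have dissimilar abstracts. "
    "The gene set/paper pairs you will be given have one gene set with a "
    "disease term and the other with a gene name, so you should include "
    "reasoning as to a possible connection between the disease and the gene "
    "and explain this possible connection. Such a connection should be "
    "related to the abstracts."
)


@dataclass
class AbstractCorpus:
    """Processed abstracts keyed by article id."""

    tokens: dict[str, list[str]]

    @classmethod
    def from_texts(cls, texts: dict[str, str],
                   stopword_list: set[str] | None = None) -> "AbstractCorpus":
        return cls({aid: preprocess_text(t, stopword_list) for aid, t in texts.items()})

    @classmethod
    def from_directory(cls, directory: str | os.PathLike,
                       stopword_list: set[str] | None = None) -> "AbstractCorpus":
        texts = {p.stem: p.read_text(encoding="utf-8")
                 for p in sorted(Path(directory).glob("*.txt"))}
        return cls.from_texts(texts, stopword_list)

    @property
    def article_ids(self) -> list[str]:
        return list(self.tokens)


def preprocess_abstract(text: str, stopword_list: set[str] | None = None) -> list[str]:
    """Tokenize, remove stop-words, lemmatize."""
    return preprocess_text(text, stopword_list)


def abstract_similarity(corpus: AbstractCorpus) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise TF-IDF cosine similarity plus an exact zero mask.

    Returns (cosine, shares_token): ``cosine`` is the TF-IDF linear-kernel
    similarity matrix; ``shares_token`` is a boolean matrix computed from the
    integer count vectors, True iff the two documents share at least one
    processed token.  The similarity of a pair is exactly zero iff
    ``shares_token`` is False there, and the cosine matrix is forced to an
    exact 0.0 on those entries.
    """
    ids = corpus.article_ids
    if len(ids) < 2:
        raise ValueError("need at least two abstracts")
    docs = [corpus.tokens[aid] for aid in ids]
    if not any(docs):
        raise ValueError("empty vocabulary: all abstracts reduce to no tokens")
    vectorizer = TfidfVectorizer(analyzer=lambda doc: doc, norm="l2")
    # documents with no tokens yield all-zero rows only if the vectorizer saw
    # them; TfidfVectorizer handles empty token lists fine.
    X = vectorizer.fit_transform(docs)
    cosine = (X @ X.T).toarray()

    counts = (X > 0).astype(np.int64)
    shares = (counts @ counts.T).toarray() > 0
    cosine = np.where(shares, cosine, 0.0)
    return (pd.DataFrame(cosine, index=ids, columns=ids),
            pd.DataFrame(shares, index=ids, columns=ids))


@dataclass
class PairCandidate:
    set_id_a: str
    set_id_b: str
    article_a: str
    article_b: str
    overlap_genes: list[str]
    fisher_p: float
    abstract_cosine: float
    sticky_fraction: float = np.nan
    cited_fraction: float = np.nan
    expressed_fraction: float = np.nan
    title_gene_terms: list[str] = field(default_factory=list)
    title_disease_terms: list[str] = field(default_factory=list)
    adj_p: float = np.nan

    @property
    def overlap_size(self) -> int:
        return len(self.overlap_genes)


def _article_of(library: GeneSetLibrary) -> dict[str, str]:
    out = {}
    for s in library:
        out[s.term] = s.article_id if s.article_id else s.term.split("-", 1)[0]
    return out


def find_disjoint_pairs(
    library: GeneSetLibrary,
    corpus: AbstractCorpus,
    index: SetIndex,
    max_p: float = MAX_PAIR_P,
    min_overlap: int = MIN_OVERLAP_GENES,
) -> list[PairCandidate]:
    """All cross-article pairs passing the five retention filters.

    Retained iff: different articles; abstracts share no processed token
    (exact-zero cosine); Fisher overlap p < ``max_p``; memberships not
    identical; overlap strictly greater than ``min_overlap`` genes.
    Sets whose article has no abstract are excluded (logged).
    """
    article_of = _article_of(library)
    with_abstract = []
    for s in library:
        if article_of[s.term] in corpus.tokens:
            with_abstract.append(s)
        else:
            logger.info("set %s has no abstract for article %s; excluded",
                        s.term, article_of[s.term])

    _, shares = abstract_similarity(corpus)
    n_bg = index.n_background
    out: list[PairCandidate] = []
    for sa, sb in combinations(with_abstract, 2):
        art_a, art_b = article_of[sa.term], article_of[sb.term]
        if art_a == art_b:
            continue
        if bool(shares.loc[art_a, art_b]):
            continue
        mem_a, mem_b = sa.membership, sb.membership
        if mem_a == mem_b:
            continue
        overlap = sorted(mem_a & mem_b)
        if len(overlap) <= min_overlap:
            continue
        a = len(overlap)
        b = len(mem_a) - a
        c = len(mem_b) - a
        d = n_bg - a - b - c
        p, _ = fisher_overlap(a, b, c, d)
        if p >= max_p:
            continue
        out.append(PairCandidate(
            set_id_a=sa.term, set_id_b=sb.term,
            article_a=art_a, article_b=art_b,
            overlap_genes=overlap, fisher_p=p, abstract_cosine=0.0))
    out.sort(key=lambda pc: (pc.fisher_p, pc.set_id_a, pc.set_id_b))
    return out


def _fraction_in(genes: list[str], pool: set[str]) -> float:
    if not genes:
        return 0.0
    return sum(g in pool for g in genes) / len(genes)


def _title_component(set_id: str) -> str:
    # the column title is the last provenance component of the term
    return set_id.rsplit("-", 1)[-1]


def annotate_pairs(
    candidates: list[PairCandidate],
    sticky_genes: list[str],
    top_cited: list[str],
    top_expressed: list[str],
    registry: GeneRegistry | None = None,
    disease_vocab: Vocabulary | None = None,
    max_sticky_fraction: float = MAX_STICKY_FRACTION,
    top_n: int = TOP_PAIRS,
) -> list[PairCandidate]:
    """Annotate candidates with list fractions and title entities, then
    filter the gene/disease analysis stream.

    Each candidate gets the fraction of its overlap genes found in the
    sticky / top-cited / top-expressed lists, and any gene or disease
    entities recognized in the two sets' column titles.  The returned list
    keeps pairs with sticky fraction strictly below ``max_sticky_fraction``,
    ranked by p-value and truncated to the ``top_n`` most significant.
    """
    from .enrichment import bh_adjust

    if not (sticky_genes and top_cited and top_expressed):
        logger.warning("one or more annotation gene lists is empty; "
                       "the corresponding fractions will be 0")
    sticky, cited, expressed = set(sticky_genes), set(top_cited), set(top_expressed)

    adj = bh_adjust([c.fisher_p for c in candidates]) if candidates else []
    for cand, ap in zip(candidates, adj):
        cand.adj_p = float(ap)
        cand.sticky_fraction = _fraction_in(cand.overlap_genes, sticky)
        cand.cited_fraction = _fraction_in(cand.overlap_genes, cited)
        cand.expressed_fraction = _fraction_in(cand.overlap_genes, expressed)
        if registry is not None or disease_vocab is not None:
            genes: list[str] = []
            diseases: list[str] = []
            for sid in (cand.set_id_a, cand.set_id_b):
                tokens, _ = tokenize_title(_title_component(sid))
                if registry is not None:
                    ann = annotate_title(tokens, registry)
                    genes.extend(g for g in ann.genes if g not in genes)
                if disease_vocab is not None:
                    for tok in tokens:
                        hit = disease_vocab.match(tok)
                        if hit is not None and hit not in diseases:
                            diseases.append(hit)
            cand.title_gene_terms = genes
            cand.title_disease_terms = diseases

    kept = [c for c in candidates if c.sticky_fraction < max_sticky_fraction]
    kept.sort(key=lambda c: (c.fisher_p, c.set_id_a, c.set_id_b))
    return kept[:top_n]


@dataclass
class PromptBundle:
    system_message: str
    user_message: str
    pair: PairCandidate


class PromptCompositionError(ValueError):
    """A required template slot has no value."""


def compose_hypothesis_prompt(
    pair: PairCandidate,
    abstracts: dict[str, str],
) -> PromptBundle:
    """Fill the hypothesis prompt templates for a gene/disease-titled pair.

    Convention: set A carries the disease-titled term, set B the gene-titled
    term.  Raises :class:`PromptCompositionError` naming the first missing
    slot.  No language-model call is performed.
    """
    slots = {
        "[term1]": pair.set_id_a,
        "[disease]": ", ".join(pair.title_disease_terms),
        "[term1_abstract]": abstracts.get(pair.article_a, ""),
        "[term2]": pair.set_id_b,
        "[gene]": ", ".join(pair.title_gene_terms),
        "[term2_abstract]": abstracts.get(pair.article_b, ""),
    }
    for slot, value in slots.items():
        if not value:
            raise PromptCompositionError(f"missing value for slot {slot}")
    user = USER_PROMPT_TEMPLATE
    for slot, value in slots.items():
        user = user.replace(slot, value)
    return PromptBundle(system_message=SYSTEM_PROMPT, user_message=user, pair=pair)


class RecordingLLMClient:
    """Default injected language-model client: records prompts, returns a
    fixed placeholder response, performs no network access."""

    def __init__(self) -> None:
        self.calls: list[PromptBundle] = []

    def complete(self, bundle: PromptBundle) -> str:
        self.calls.append(bundle)
        return "[no hypothesis generated: offline recording client]"
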