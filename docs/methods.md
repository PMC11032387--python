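# Methods

## Scope and model of the data

`tablemine` treats a publication corpus as a collection of *article
bundles*: one directory per article containing a structured-markup
metadata document (tables in `table-wrap` elements with `label` and
`caption`, supplements declared by `supplementary-material`, in-text
references through `xref`) plus supplementary files in XLSX/CSV/TSV/TXT.
The markup dialect the parser targets is deliberately minimal and is
co-specified with the fixture generator; it captures the semantics that
matter for extraction (tables, captions, labels, and the words preceding a
reference) rather than the full richness of production article XML.

The package assumes one header row per table (the column's first cell is
its title and is excluded from the mapping denominator), and that gene
identity is adequately captured by case-insensitive matching of official
symbols, synonyms and numeric ids from a single gene_info-style registry.
Case-insensitivity is also what lets mouse/rat orthographic variants of
human symbols resolve without any cross-species machinery.

## Extraction

A column survives iff

* mapped fraction strictly above 0.5, where the denominator is the number
  of **unique non-blank** cell strings and a cell counts as mapped when it
  resolves to an official symbol;
* the number of distinct mapped genes is between `min_genes = 5` and
  `max_genes = 2500` inclusive (columns with fewer than 5 or more than
  2500 mapped genes are rejected — very large columns are usually the
  full measured gene universe, not a finding).

Resolution precedence on colliding tokens is official symbol > synonym >
numeric id; a synonym claimed by two or more genes is ambiguous and
resolves to nothing. This is a deliberately conservative, deterministic
choice; every collision is recorded on the registry for audit.

Terms are `article-file-label-header` joined with `-` (empty components
skipped) with a sequential numeric suffix appended only on collision; the
delimiter and suffix format are package conventions. Descriptions join
caption, label and mention with single spaces. The TXT separator is
inferred by majority vote over the first ten lines among tab, comma and
semicolon. The appender is resumable: a JSON ledger records processed
article ids and used terms, appends are atomic (write-temp-then-replace),
and re-running over the same bundles is a byte-level no-op. A PDF table
extractor is a plug-in point with no default implementation.

## Enrichment search

The index encodes the library against the background universe defined as
the union of all library genes — p-values therefore depend only on the
library, never on an external gene catalogue. Sets with identical
membership are encoded once and fanned back out to all their ids. The
test is the one-sided over-representation Fisher exact test (the
convention in enrichment analysis; a `two-sided` alternative is available
as a flag), computed as the hypergeometric survival function. Odds ratios
are the exact cross-product (a·d)/(b·c), reported as 0 when a·d = 0 and
+∞ when only b·c = 0 — no Haldane correction, so the statistic stays
exact. BH adjustment spans all scored sets of the query.

Results are ranked ascending by p with ties broken by descending overlap
then set id. Ranking compares p rounded to 12 significant digits:
mathematically equal tails arising from different tables (e.g. by the
margin symmetry of the hypergeometric) can differ in the last float ulp,
and the tie-break must treat them as the ties they are. Twelve digits is
far below any scientifically meaningful difference and far above
double-precision noise.

## Title annotation and consensus libraries

Column titles are split on dashes, underscores and periods; pure-integer
tokens and `S`+integer tokens (supplementary-table numbering) are dropped
with recorded reasons. Gene tokens are resolved to official symbols;
transcription factors and kinases are flagged by membership in
user-supplied vocabularies; `up`/`down`/`dn` set the direction; ontology
terms (e.g. tissue/cell-line vocabularies) match exactly after
lowercasing and are hyphen-joined in title order when a title hits
several. Metadata search is whole-token and case-insensitive over term
and description — substring matching would let `ERK` match unrelated
tokens. A consensus library contains, per named entity, the union of the
genes of every set whose metadata mentions the entity; entities with no
match are omitted and logged.

## Gene-function prediction

Membership matrices keep sets with strictly fewer than 2000 genes and can
subsample the library uniformly without replacement under a seed (the
corpus-scale configuration is a 50,000-set sample; desk-scale fixtures
use the whole library). φ₀ counts ordered pairs — the sum over the full
off-diagonal of Φ — which makes the marginals sum to exactly 1; the
factor-2 convention cancels inside all three similarity ratios. The Φ
diagonal is zeroed before normalization and the similarity diagonal is
forced to 0, so in G = (D·L)/(L·1ᵀ) a gene's self-similarity contributes
nothing: scoring a gene for its own term is automatically a held-out
evaluation. NPWMI is defined 0 at P(α,β) = 0 (the limit of the max-branch)
and 1 at P(α,β) = 1 (by continuity; ln 1 = 0 would divide by zero).
Similarity matrices are explicitly symmetrized ((D + Dᵀ)/2) to remove
floating-point asymmetry. Per-term AUROC uses the rank statistic; terms
with no positives or no negatives are skipped and logged. The ROC harness
accepts any externally supplied gene×gene matrix in place of D, so a
co-expression baseline can be evaluated through the identical pipeline.

## Pair discovery

Abstract preprocessing is lowercase word tokenization, removal of the
scikit-learn English stop-word list, and a small deterministic rule-based
suffix lemmatizer (plural, `-ing`, `-ed` reduction with a
double-consonant rule). The lemmatizer is intentionally simple: the
pair-retention decision depends only on whether two processed abstracts
share *any* token, which is robust to lemma quality, and determinism is
the property that matters. TF-IDF cosine uses the standard smoothed IDF
and l2 normalization; whether a pair's similarity is exactly zero is
decided on the integer count vectors (do the documents share a token at
all?), so float noise can neither create nor destroy a zero, and the
cosine matrix is forced to exact 0.0 on those entries.

Retention requires: different articles, exact-zero abstract cosine,
Fisher overlap p < 0.05 (computed against the library-union background —
the natural universe for sets drawn from the same library), non-identical
memberships, and strictly more than 50 shared genes. The five filters
commute, which the tests verify against an independent predicate oracle.
The gene/disease analysis stream further requires a sticky-protein
fraction strictly below 10% of the overlap and keeps the 10,000 most
significant pairs; raw p is reported alongside a BH-adjusted column since
pair-level multiplicity treatment is a reporting choice. The
hypothesis-prompt composer fills fixed system/user templates (slots:
terms, disease, gene, both abstracts) and raises naming the first missing
slot; the default language-model client records prompts and performs no
network access.

## Corpus statistics and benchmarking

*Duplicates* are grouped by exact membership (order-insensitive); each
group records its maximum within-article multiplicity and the number of
distinct contributing articles, and the redundant fraction is
(sets − unique memberships)/sets.

*Understudied sets* compare each set's per-gene citation median with the
distribution of medians of randomly assembled size-matched sets: per
log-spaced size bin, `n_random` (default 1000) random sets are drawn from
the library universe with sizes sampled from the real sizes in the bin,
and a set is flagged when its median falls more than 3 sample standard
deviations below the **mean** of the null medians (the mean-of-medians
anchor, matching the boundary-line construction the statistic mirrors).
Genes missing from the citation table count as zero citations, logged.

*Shared-entity similarity* compares cross-article pairwise Jaccard
indices between sets annotated with the same entity versus different
entities, with Welch's unequal-variance t-test.

*Consensus benchmarking* queries each truth-labeled benchmark set against
the consensus library; a (set, entity) pair scores −log p and is positive
when the entity is the set's true label. Because negatives vastly
outnumber positives, each bootstrap iteration downsamples the negative
class to the positive-class size, computes the ROC, and linearly
interpolates it onto a fixed false-positive grid (101 points); the mean
curve and mean AUROC over the iterations are reported (5000 iterations at
corpus scale; 1000 on fixtures, where the seed-to-seed spread of the mean
AUROC is within 0.02). Scaled ranks are (rank − 1)/(n − 1) with
average-rank tie handling.

## The synthetic-data generator

The `fixtures` module generates every input: registries (symbols
`GENE0001…`, collision-free synonyms at a configurable rate), article
bundles realizing planted columns with known outcomes across all file
formats, libraries with planted co-occurrence modules (sets are subsets
of a module's genes, so cross-module pairs never co-occur), planted
entity tokens, duplicate plans, and abstracts built from per-group
letter-only vocabularies so that different groups are token-disjoint by
construction. Every fixture is byte-reproducible from (spec, seed) —
workbook timestamps are pinned — and each generator emits a manifest that
serves as the test oracle.

What the generator does *not* emulate: production article-XML edge cases
(multi-row headers, merged cells, footnotes), natural-language abstracts
(vocabulary overlap is controlled, not Zipfian), realistic gene-set size
and overlap distributions, or scanned/PDF tables. Passing tests therefore
demonstrate that the algorithms implement their contracts exactly on
inputs with known truth — not that real-corpus figures (duplicate
percentages, understudied-set counts, corpus-wide AUROC distributions)
would be reproduced, since those depend on the full literature corpus and
external catalogues.

## Problem sizes

The test suite and acceptance script run at desk scale by design: exact
Fisher enumeration over all 2×2 tables with N ≤ 12; enrichment oracle
comparisons on libraries up to 500 sets over ≤ 60-gene universes;
100-bundle extraction runs covering every filter boundary (fraction
exactly 0.5 vs 0.6; 4/5/2500/2501 mapped genes); two-module prediction
fixtures of 40 genes × 30 sets over 20 seeds; benchmark fixtures of 8
entities × 3 sets at 1000 bootstrap iterations. These sizes make every
oracle exhaustive or near-exhaustive while keeping the whole suite in
well under a minute per component.

## Known limitations

* The extraction dialect is the fixture dialect; pointing the parser at
  real archive XML would need an adapter (and a PDF extractor plug-in for
  scanned tables).
* The lemmatizer is rule-based English; token-level outputs differ from
  dictionary lemmatizers, though pair decisions do not depend on that.
* Numeric-id resolution covers plain integer ids only; probe ids,
  Ensembl ids and cross-species orthology are out of scope.
* Corpus-scale quantities (e.g. duplicate percentage of a real library)
  are functions of the corpus; the package computes them but ships no
  corpus.
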