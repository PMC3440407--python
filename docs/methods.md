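# Methods

## Problem and pipeline

Gene name normalization links gene/protein mentions in abstracts to unique
database identifiers. The package decomposes the problem into four stages —
recognition, entity mapping, disambiguation, filtering — each of which can
be run, configured and tested independently; `run_pipeline` composes them in
that order and deduplicates the output to document-level
(doc&nbsp;id, gene&nbsp;id) pairs, the unit the gold standard annotates.

## Text normalization

All string comparison goes through one tokenizer: split on punctuation and
whitespace and at every alphabetic↔numeric boundary (both directions), then
lowercase. `"NF-kappaB2"` → `nf · kappab · 2`. Mixed-case boundaries
(`kappaB`) are not split, and there is no stemming — `homologue` and
`homolog` stay distinct surface forms. Hyphens adjacent to digits are
treated like any other delimiter, so `IL-2R` yields three tokens.

Two stop lists are used, shipped as replaceable one-term-per-line data
files: a general English list (495 words, a standard common-word list) and
a 27-entry list of common biological terms (*gene*, *receptor*, *human*,
*family*, …) that occur in many synonyms without distinguishing genes. The
indexing/approximate-matching stage removes both; the disambiguation stage
removes only the English list, because terms like *receptor* are exactly
what distinguishes one gene profile from another.

## Recognition

The tagger consumes a TSV dictionary of surface forms with real-valued
confidence scores (higher = more likely a genuine gene name; typical range
−1.6…+1.0). Surface forms are normalized into token sequences and stored in
a token trie; duplicate normalized forms keep the maximum score. Tagging
scans the document's token stream and takes non-overlapping
leftmost-longest matches; character offsets refer to the original text.
Score filtering happens *after* match selection, so tightening `min_score`
removes mentions but never changes the segmentation (the monotonicity the
threshold sweep relies on). By default no score threshold is applied at
tagging time; confidence filtering is the filtering stage's job.

Deliberate limitation: enumerations ("ORP-1 to ORP-6", "cofactors A, D, E,
and C") are not expanded. Only surface forms literally present in the
dictionary can be found, and error analyses of dictionary taggers report
exactly this class of miss.

## Entity mapping

**Exact route.** For each mention, spelling variants are generated: every
space may stay or be deleted; every hyphen may stay, become a space, or be
deleted; a slash splits the mention and each side is varied independently.
Variants are compared to synonyms case-insensitively with runs of
whitespace collapsed. Inputs with more than 8 delimiter positions fall back
to {original, all-deleted, all-spaced} so variant generation always
terminates in bounded time. One candidate per distinct gene id is returned,
with an infinite sentinel score (an exact hit outranks any retrieval
score).

**Approximate route** (only when the exact route returns nothing). Every
synonym string is one "document" of an inverted index, tokenized and
stop-filtered; synonyms consisting entirely of stop words are not indexed.
The mention, stop-filtered the same way, is a Boolean query: duplicate
tokens are deduplicated, which makes scores exactly invariant under word
permutation. Scoring is canonical Okapi BM25 with k₁ = 2.0, b = 0.75 and
the Robertson–Spärck Jones idf `ln((N − n + 0.5)/(n + 0.5))` (natural log;
the base only rescales rankings uniformly). Negative idf for terms in more
than half the lexicon is kept by default; a `clamp_negative_idf` flag
zeroes it for users who prefer the clamped convention. Candidates scoring
at or above `score_threshold` are returned in descending order, ties broken
by shorter synonym then smaller document id for determinism; a `top1` mode
restricts the result to the single best synonym. The default
`score_threshold` of 1.0 was calibrated on the synthetic fixtures: it is
low enough that any single informative shared token clears it in a
realistic lexicon, while zero-overlap synonyms (score 0) never do.

## Disambiguation

Each gene's profile — database description, GO term names, linked abstract
texts — is flattened into one pseudo-document (one "relevant information
vector" per gene, not three). The vector space is built per batch over all
profile pseudo-documents plus the batch's abstracts; weights are raw term
frequency times `idf = ln(n_docs/df)` (the plain TF-IDF schema; no
sublinear tf, no smoothing). Candidates are ranked by cosine similarity
between the mention's whole abstract and each profile; ties break toward
the larger profile (more evidence), then the smallest gene id, making the
result independent of candidate order. A candidate with no profile scores
0. The winning similarity is retained rather than treated as a commitment:
the similarity filter may still reject the pair, so an apparent gene
mention that matches no candidate's profile can be dropped entirely.

## Filtering

Three filters applied as a pure set intersection (order-independent,
contractive, idempotent):

| filter | rule | default |
|---|---|---|
| confidence | keep score ≥ t (ties kept: "under t" is removed) | t = −0.8 |
| blocklist | drop mentions whose normalized text names a family/complex/cell line | on |
| similarity | keep cosine > t (strict: must "exceed") | t = 0.1 |

The asymmetric tie handling (confidence keeps ties, similarity drops them)
follows the two rules' definitions literally. The blocklist is a plain text
file consumed as data. After filtering, records collapse to unique
(doc, gene) pairs keeping the max-similarity exemplar mention. Because the
confidence filter's survivor sets are nested as the threshold rises, recall
is non-increasing along a sweep; precision usually rises but is not
guaranteed monotone and is not asserted as an invariant.

Both confidence knobs exist — a tagging-time `min_score` and the filter
threshold — because applying the dictionary's legacy −0.2 cutoff at tag
time and sweeping a separate cutoff at filter time are different policies;
the default applies no tag-time cutoff so the sweep sees every mention.

## Evaluation

`evaluate` is a set comparison of (doc, gene) pairs: TP = |pred ∩ gold|,
FP = |pred \ gold|, FN = |gold \ pred|; precision, recall, F1 with the 0/0
conventions (no predictions → precision 0). Reports round to 3 decimals.
`sweep` re-applies the filters at each grid point on retained, unfiltered
records — it never re-runs tagging or mapping, which the thresholds do not
affect.

## Synthetic corpora

The generator emulates the data regime of a gene-normalization benchmark at
desk scale, one seeded RNG driving everything (byte-identical bundles per
seed). Design choices and what they emulate:

- **Names** come from a syllable grammar plus numeric suffixes, as one- to
  three-word surfaces with hyphen/space variation — enough morphology for
  the variant rules and BM25 to have real work. Name, profile and filler
  vocabularies use disjoint syllable sets so mentions never collide with
  ordinary prose.
- **Ambiguity**: a configurable fraction of synonyms is additionally
  assigned to a decoy gene, so the same surface maps to ≥ 2 identifiers.
- **Profiles**: each gene owns a distinct profile vocabulary (default 20
  words). The description, GO terms and linked abstracts are built from it,
  and one linked abstract covers the whole vocabulary so every profile word
  has frequency ≥ 1 — a gene's profile reliably contains its own
  terminology, as curated database records do.
- **Abstracts** plant mentions (optionally noised by hyphenation changes,
  case changes, word-order permutation — which only the BM25 route survives
  — and stop-word insertion) in filler sentences together with context
  terms sampled from the true gene's profile vocabulary (default 8 per
  mention, each written twice: abstracts dwell on the annotations of the
  gene they discuss, and the doubled term frequency keeps the correct-pair
  cosine well clear of the 0.1 similarity threshold even when a document
  mentions several genes).
- **Negatives**: a configurable fraction of plants are family names
  (excluded from the gold standard, present in the blocklist). Dictionary
  confidences are Gaussian around +1.0 for gene names and −1.0 for family
  names (sd 0.3), mimicking a learned score that separates the two
  populations.

By construction, a corpus with `ambiguity_fraction=0` and no variant noise
is solved exactly by the pipeline (P = R = 1), which the acceptance run
verifies end to end. The "high-signal" ambiguous corpus used to measure
disambiguation accuracy plants one mention per abstract so each context
belongs to a single gene; with several genes per abstract, accuracy
degrades not because the method fails but because the context genuinely
discusses multiple candidates — a real phenomenon the generator can also
reproduce.

What the generator does **not** emulate: real MEDLINE language (filler is a
small word pool, not a language model), realistic synonym morphology beyond
the grammar above, abbreviation definitions ("oxysterol binding protein
(OSBP)"), enumerations, or genes discussed without their profile
terminology. Passing on synthetic corpora therefore demonstrates the
machinery is correct and calibrated, not that benchmark-level accuracy
transfers to real abstracts.

## Problem sizes and numerical choices

Default corpora are 40 genes / 60 abstracts (≈ 150 gold pairs); the
high-signal disambiguation corpus uses 250 single-mention abstracts
(≥ 100 ambiguous cases); oracle cross-checks run lexicons up to ~10³
synonyms. The whole test suite and the acceptance run each complete in a
few seconds on one CPU. All arithmetic is double precision; BM25 and
cosine ties are broken deterministically as described above; degenerate
inputs (empty documents, all-stop-word queries, empty candidate lists,
zero-norm vectors) return empty results or raise early, as documented per
function.
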