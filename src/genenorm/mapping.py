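"""Mapping gene mentions to candidate identifiers in a synonym lexicon.

Two strategies are combined.  Exact lookup first: simple spelling variants of
the mention (hyphen/space deletion or substitution, splitting at a slash) are
compared case-insensitively against every synonym.  Only when no variant
hits does the approximate route run: the lexicon is treated as a document
collection with one "document" per synonym string, indexed after stop-word
removal, and the mention is issued as a Boolean bag-of-words query ranked by
Okapi BM25 (k1 = 2.0, b = 0.75 by default).  Because queries are Boolean
(duplicate tokens deduplicated), word-order permutations of a mention score
identically — "the human homologue of mouse Ly9" retrieves the synonym
"ly9, mouse, homolog of".

The IDF weight is the Robertson–Spärck Jones form
``ln((N - n + 0.5) / (n + 0.5))`` with N the number of indexed synonym
documents and n the number containing the term; it goes negative for terms
in more than half the lexicon and is kept unclamped by default.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .tagger import Mention
from .textnorm import StopList, Token, remove_stops, tokenize

__all__ = [
    "SynonymLexicon",
    "InvertedIndex",
    "BM25Params",
    "Candidate",
    "load_lexicon",
    "generate_variants",
    "exact_lookup",
    "build_index",
    "idf",
    "bm25_score",
    "approximate_search",
    "map_mention",
]

# above this many space/hyphen positions, only coarse variants are generated
_MAX_VARIANT_POSITIONS = 8

_WS_RE = re.compile(r"\s+")


def _canon(s: str) -> str:
    """Whitespace-normalized, casefolded comparison form for exact matching."""
    return _WS_RE.sub(" ", s.strip()).casefold()


@dataclass
class SynonymLexicon:
    """gene_id -> verbatim synonym strings; the normalization target space."""

    records: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._exact: dict[str, set[str]] | None = None

    def add(self, gene_id: str, synonyms: Iterable[str]) -> None:
        if not gene_id:
            raise ValueError("gene_id must be non-empty")
        syns = [s for s in synonyms if s.strip()]
        if not syns:
            raise ValueError(f"gene {gene_id!r} has no synonyms")
        self.records.setdefault(gene_id, []).extend(syns)
        self._exact = None

    def __len__(self) -> int:
        return len(self.records)

    def exact_table(self) -> dict[str, set[str]]:
        """Canonical synonym string -> gene_ids, built lazily."""
        if self._exact is None:
            table: dict[str, set[str]] = {}
            for gid, syns in self.records.items():
                for syn in syns:
                    table.setdefault(_canon(syn), set()).add(gid)
            self._exact = table
        return self._exact


def load_lexicon(path: str | Path) -> SynonymLexicon:
    """Read a BioCreative-style lexicon TSV: ``gene_id<TAB>syn<TAB>syn...``."""
    lex = SynonymLexicon()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: need gene_id and >=1 synonym")
            lex.add(parts[0].strip(), parts[1:])
    return lex


@dataclass(frozen=True)
class BM25Params:
    k1: float = 2.0
    b: float = 0.75
    score_threshold: float = 1.0
    clamp_negative_idf: bool = False

    def __post_init__(self) -> None:
        if self.k1 <= 0:
            raise ValueError("k1 must be positive")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError("b must lie in [0, 1]")


@dataclass(frozen=True)
class Candidate:
    """One candidate gene identifier for a mention.

    ``score`` is the BM25 score for approximate candidates and +inf for exact
    ones (an exact hit outranks any retrieval score by construction).
    """

    gene_id: str
    matched_synonym: str
    method: str  # "exact" | "approximate"
    score: float


def generate_variants(mention_text: str) -> set[str]:
    """Spelling variants of a mention for exact lookup.

    Every space may stay or be deleted; every hyphen may stay, become a
    space, or be deleted ("NF-Kappa B" yields "NF Kappa B", "NF-KappaB",
    "NFKappaB", ...).  A slash splits the mention into the pieces on either
    side, each varied the same way.  Inputs with many delimiters fall back to
    the three coarse forms {original, all-deleted, all-spaced} to bound the
    combinatorics.
    """
    if not mention_text:
        return set()
    pieces = [p.strip() for p in mention_text.split("/") if p.strip()]
    out: set[str] = {mention_text}
    for piece in pieces:
        out |= _delimiter_variants(piece)
    return out


def _delimiter_variants(text: str) -> set[str]:
    positions = [i for i, ch in enumerate(text) if ch == "-" or ch.isspace()]
    if not positions:
        return {text}
    if len(positions) > _MAX_VARIANT_POSITIONS:
        deleted = "".join(ch for ch in text if ch != "-" and not ch.isspace())
        spaced = _WS_RE.sub(" ", text.replace("-", " ")).strip()
        return {text, deleted, spaced}
    variants = {""}
    prev = 0
    for pos in positions:
        seg = text[prev:pos]
        reps = (" ", "") if text[pos].isspace() else (text[pos], " ", "")
        variants = {v + seg + r for v in variants for r in reps}
        prev = pos + 1
    tail = text[prev:]
    return {_WS_RE.sub(" ", (v + tail)).strip() for v in variants}


def exact_lookup(mention_text: str, lexicon: SynonymLexicon) -> list[Candidate]:
    """Match every generated variant of the mention against every synonym,
    case-insensitively and whitespace-normalized; one candidate per gene."""
    table = lexicon.exact_table()
    hits: dict[str, str] = {}
    for variant in generate_variants(mention_text):
        for gid in table.get(_canon(variant), ()):
            hits.setdefault(gid, variant)
    return [
        Candidate(gene_id=gid, matched_synonym=syn, method="exact", score=math.inf)
        for gid, syn in sorted(hits.items())
    ]


@dataclass
class InvertedIndex:
    """Inverted index over lexicon synonyms, one index document per synonym.

    ``postings`` maps a term to (doc_id, term frequency) pairs; ``doc_len``
    is the stop-filtered token count |D|; ``avgdl`` its mean; ``N`` the number
    of indexed synonym documents; ``doc_meta`` recovers (gene_id, verbatim
    synonym) from a doc id.
    """

    postings: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    doc_len: dict[int, int] = field(default_factory=dict)
    avgdl: float = 0.0
    N: int = 0
    doc_meta: dict[int, tuple[str, str]] = field(default_factory=dict)

    def doc_freq(self, term: str) -> int:
        return len(self.postings.get(term, ()))


def build_index(lexicon: SynonymLexicon, stops: StopList) -> InvertedIndex:
    """Index every synonym after tokenization and stop removal.

    Synonyms whose tokens are all stop words ("the gene") are not indexed;
    if nothing survives, the index would be useless and an error is raised.
    """
    index = InvertedIndex()
    doc_id = 0
    for gid in sorted(lexicon.records):
        for syn in lexicon.records[gid]:
            toks = remove_stops(tokenize(syn), stops)
            if not toks:
                continue
            tf: dict[str, int] = {}
            for t in toks:
                tf[t.text] = tf.get(t.text, 0) + 1
            for term, f in tf.items():
                index.postings.setdefault(term, []).append((doc_id, f))
            index.doc_len[doc_id] = len(toks)
            index.doc_meta[doc_id] = (gid, syn)
            doc_id += 1
    if doc_id == 0:
        raise ValueError("index would be empty: every synonym reduced to stop words")
    index.N = doc_id
    index.avgdl = sum(index.doc_len.values()) / doc_id
    return index


def idf(term: str, index: InvertedIndex) -> float:
    """RSJ inverse document frequency: ln((N - n + 0.5)/(n + 0.5))."""
    n = index.doc_freq(term)
    return math.log((index.N - n + 0.5) / (n + 0.5))


def bm25_score(
    query_tokens: list[Token],
    synonym_doc_id: int,
    index: InvertedIndex,
    params: BM25Params = BM25Params(),
) -> float:
    """Okapi BM25 score of one indexed synonym against a Boolean query.

    Duplicate query tokens are deduplicated (Boolean query), which makes the
    score exactly invariant under token permutation.
    """
    dlen = index.doc_len.get(synonym_doc_id)
    if dlen is None:
        return 0.0
    norm = params.k1 * (1.0 - params.b + params.b * dlen / index.avgdl)
    score = 0.0
    for term in {t.text for t in query_tokens}:
        f = 0
        for did, tf in index.postings.get(term, ()):
            if did == synonym_doc_id:
                f = tf
                break
        if f == 0:
            continue
        w = idf(term, index)
        if params.clamp_negative_idf and w < 0.0:
            w = 0.0
        score += w * f * (params.k1 + 1.0) / (f + norm)
    return score


def approximate_search(
    mention_text: str,
    index: InvertedIndex,
    params: BM25Params,
    stops: StopList,
    top1: bool = False,
) -> list[Candidate]:
    """BM25-rank indexed synonyms against the stop-filtered mention query.

    Returns candidates scoring >= ``params.score_threshold`` in descending
    score order (ties: shorter document, then smaller doc id); with ``top1``
    only the single best synonym is considered.  An all-stop-word query
    returns nothing.
    """
    query = remove_stops(tokenize(mention_text), stops)
    if not query:
        return []
    terms = {t.text for t in query}
    doc_ids: set[int] = set()
    for term in terms:
        doc_ids.update(did for did, _ in index.postings.get(term, ()))
    scored = [
        (bm25_score(query, did, index, params), did) for did in doc_ids
    ]
    scored.sort(key=lambda s_d: (-s_d[0], index.doc_len[s_d[1]], s_d[1]))
    if top1:
        scored = scored[:1]
    out: list[Candidate] = []
    seen_genes: set[str] = set()
    for score, did in scored:
        if score < params.score_threshold:
            break
        gid, syn = index.doc_meta[did]
        if gid in seen_genes:
            continue
        seen_genes.add(gid)
        out.append(Candidate(gene_id=gid, matched_synonym=syn,
                             method="approximate", score=score))
    return out


def map_mention(
    mention: Mention,
    lexicon: SynonymLexicon,
    index: InvertedIndex,
    params: BM25Params,
    stops: StopList,
    top1: bool = False,
) -> list[Candidate]:
    """Exact lookup first; fall back to approximate search only when no
    variant of the mention matches any synonym."""
    exact = exact_lookup(mention.text, lexicon)
    if exact:
        return exact
    return approximate_search(mention.text, index, params, stops, top1=top1)
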