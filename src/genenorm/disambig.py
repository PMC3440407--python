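"""Word-sense disambiguation of ambiguous gene mentions.

A surface form like "ORP-1" can be the synonym of several unrelated genes.
Each candidate identifier is represented by a *gene profile* — the database
description, the names of its GO annotations, and the texts of abstracts the
database links to the gene — flattened into one pseudo-document.  The
mention's surrounding abstract and each profile are embedded as TF-IDF
vectors in a shared space (general English stop words removed; raw term
frequency times ln(n_docs/df)), and the candidate whose profile is most
cosine-similar to the context wins.

The winning similarity is *not* a commitment: it travels with the result so
the filtering stage can still reject the pair when the context matches no
candidate well.  This avoids the assumption that one of the candidates is
always the correct answer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .mapping import Candidate
from .tagger import Mention
from .textnorm import StopList, tokenize

__all__ = [
    "GeneProfile",
    "VectorSpace",
    "TfIdfVector",
    "load_profiles",
    "build_space",
    "vectorize",
    "cosine",
    "disambiguate",
]


@dataclass(frozen=True)
class GeneProfile:
    """Aggregated textual knowledge about one gene identifier."""

    gene_id: str
    description: str = ""
    go_terms: tuple[str, ...] = ()
    linked_abstracts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not (self.description or self.go_terms or self.linked_abstracts):
            raise ValueError(f"profile {self.gene_id!r} has no text in any source")

    def pseudo_document(self) -> str:
        """Description + GO terms + linked abstracts as one text blob."""
        parts = [self.description, *self.go_terms, *self.linked_abstracts]
        return " ".join(p for p in parts if p)


def load_profiles(path: str | Path) -> dict[str, GeneProfile]:
    """Read gene profiles from a JSON-lines file (one record per gene with
    fields gene_id, description, go_terms, linked_abstracts)."""
    profiles: dict[str, GeneProfile] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            try:
                rec = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: invalid JSON record") from exc
            prof = GeneProfile(
                gene_id=str(rec["gene_id"]),
                description=rec.get("description", ""),
                go_terms=tuple(rec.get("go_terms", ())),
                linked_abstracts=tuple(rec.get("linked_abstracts", ())),
            )
            profiles[prof.gene_id] = prof
    return profiles


@dataclass
class VectorSpace:
    """Shared vocabulary and idf weights for one disambiguation batch."""

    vocabulary: tuple[str, ...]
    idf_weights: dict[str, float]
    n_docs: int


@dataclass(frozen=True)
class TfIdfVector:
    """Sparse nonnegative term->weight map over an owning space's vocabulary."""

    weights: Mapping[str, float]

    def norm(self) -> float:
        return math.sqrt(sum(w * w for w in self.weights.values()))


def _doc_terms(text: str, stops: StopList) -> list[str]:
    # only general English stops are removed for disambiguation vectors;
    # biological terms like "receptor" are informative here
    return [t.text for t in tokenize(text) if t.text not in stops.english_terms]


def build_space(
    profiles: Iterable[GeneProfile],
    context_docs: Iterable[str],
    stops: StopList,
) -> VectorSpace:
    """Build the vocabulary and idf table over all profile pseudo-documents
    plus the batch's context documents; idf(term) = ln(n_docs / df)."""
    docs = [_doc_terms(p.pseudo_document(), stops) for p in profiles]
    docs += [_doc_terms(c, stops) for c in context_docs]
    if not docs:
        raise ValueError("cannot build a vector space from an empty collection")
    df: dict[str, int] = {}
    for terms in docs:
        for term in set(terms):
            df[term] = df.get(term, 0) + 1
    n_docs = len(docs)
    vocab = tuple(sorted(df))
    idf = {term: math.log(n_docs / df[term]) for term in vocab}
    return VectorSpace(vocabulary=vocab, idf_weights=idf, n_docs=n_docs)


def vectorize(text_or_profile: str | GeneProfile, space: VectorSpace,
              stops: StopList) -> TfIdfVector:
    """TF-IDF embed a text (or a profile's flattened pseudo-document):
    weight(term) = count(term) * idf(term); out-of-vocabulary terms ignored."""
    text = (
        text_or_profile.pseudo_document()
        if isinstance(text_or_profile, GeneProfile)
        else text_or_profile
    )
    tf: dict[str, int] = {}
    for term in _doc_terms(text, stops):
        tf[term] = tf.get(term, 0) + 1
    weights = {
        term: count * space.idf_weights[term]
        for term, count in tf.items()
        if term in space.idf_weights
    }
    return TfIdfVector(weights=weights)


def cosine(v1: TfIdfVector, v2: TfIdfVector) -> float:
    """Cosine similarity; 0 when either vector has zero norm."""
    if len(v1.weights) > len(v2.weights):
        v1, v2 = v2, v1
    dot = sum(w * v2.weights.get(t, 0.0) for t, w in v1.weights.items())
    n1, n2 = v1.norm(), v2.norm()
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    return dot / (n1 * n2)


def disambiguate(
    mention: Mention,
    context_text: str,
    candidates: list[Candidate],
    profiles: Mapping[str, GeneProfile],
    space: VectorSpace,
    stops: StopList,
) -> tuple[str, float]:
    """Pick the candidate whose profile best matches the mention's context.

    Returns (gene_id, cosine similarity).  A candidate without a profile
    scores 0.  Ties break toward the larger profile (more evidence), then the
    lexicographically smallest gene_id, so the result is independent of
    candidate order.  A single candidate still gets its similarity computed —
    the similarity filter needs it.
    """
    if not candidates:
        raise ValueError("disambiguate requires at least one candidate")
    ctx_vec = vectorize(context_text, space, stops)
    best: tuple[float, int, str] | None = None
    for cand in candidates:
        prof = profiles.get(cand.gene_id)
        if prof is None:
            sim, size = 0.0, 0
        else:
            sim = cosine(ctx_vec, vectorize(prof, space, stops))
            size = len(_doc_terms(prof.pseudo_document(), stops))
        key = (-sim, -size, cand.gene_id)
        if best is None or key < (-best[0], -best[1], best[2]):
            best = (sim, size, cand.gene_id)
    assert best is not None
    return best[2], best[0]
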