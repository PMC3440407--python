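"""Removal of spurious mention->identifier pairs.

Three independent filters, applied as a pure intersection (so their order
never matters):

* **confidence** — drop records whose NER dictionary score is *under* a
  threshold (ties kept; default -0.8, the setting that maximizes F on the
  reference corpus sweep);
* **blocklist** — drop mentions whose normalized text names a protein
  family, complex, or cell line ("CapZ Actin Capping Protein", "PC3",
  "MCF-7"): such names denote groups, not single genes;
* **similarity** — keep a pair only if its disambiguation cosine *exceeds*
  a threshold (strict; default 0.1), rejecting mappings the context does not
  support at all.

After filtering, results are deduplicated to document-level
(doc_id, gene_id) pairs — the unit the gold standard annotates — keeping the
max-similarity exemplar mention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from .mapping import _canon
from .tagger import Mention

__all__ = [
    "FilterConfig",
    "Blocklist",
    "NormalizationResult",
    "load_blocklist",
    "filter_by_confidence",
    "filter_by_blocklist",
    "filter_by_similarity",
    "apply_filters",
    "dedupe_results",
    "write_results",
    "read_results",
]


@dataclass(frozen=True)
class FilterConfig:
    conf_threshold: float = -0.8
    sim_threshold: float = 0.1
    use_blocklist: bool = True
    use_confidence: bool = True
    use_similarity: bool = True


@dataclass(frozen=True)
class Blocklist:
    """Normalized family/complex/cell-line names that must never be
    normalized to a single gene identifier."""

    names: frozenset[str] = frozenset()

    def __contains__(self, mention_text: str) -> bool:
        return _canon(mention_text) in self.names

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "Blocklist":
        return cls(names=frozenset(_canon(n) for n in names if n.strip()))


def load_blocklist(path: str | Path) -> Blocklist:
    """Plain text, one name per line; '#' comments and blanks ignored."""
    names = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.append(line)
    return Blocklist.from_names(names)


@dataclass(frozen=True)
class NormalizationResult:
    """One surviving (document, mention, gene) triple with the scores the
    filters consume."""

    doc_id: str
    gene_id: str
    mention: Mention
    similarity: float
    confidence: float


def filter_by_confidence(
    results: Iterable[NormalizationResult], threshold: float
) -> list[NormalizationResult]:
    """Keep records whose NER confidence is >= threshold (ties kept)."""
    return [r for r in results if r.confidence >= threshold]


def filter_by_blocklist(
    results: Iterable[NormalizationResult], blocklist: Blocklist
) -> list[NormalizationResult]:
    """Drop records whose mention text is a blocklisted family/cell-line name."""
    return [r for r in results if r.mention.text not in blocklist]


def filter_by_similarity(
    results: Iterable[NormalizationResult], threshold: float
) -> list[NormalizationResult]:
    """Keep records whose disambiguation cosine strictly exceeds threshold."""
    return [r for r in results if r.similarity > threshold]


def dedupe_results(
    results: Iterable[NormalizationResult],
) -> list[NormalizationResult]:
    """Collapse to one record per (doc_id, gene_id), keeping the
    max-similarity exemplar mention (earliest span on ties)."""
    best: dict[tuple[str, str], NormalizationResult] = {}
    for r in results:
        key = (r.doc_id, r.gene_id)
        cur = best.get(key)
        if (
            cur is None
            or r.similarity > cur.similarity
            or (r.similarity == cur.similarity and r.mention.start < cur.mention.start)
        ):
            best[key] = r
    return sorted(best.values(), key=lambda r: (r.doc_id, r.gene_id))


def apply_filters(
    results: Iterable[NormalizationResult],
    config: FilterConfig = FilterConfig(),
    blocklist: Blocklist | None = None,
) -> list[NormalizationResult]:
    """Intersect the survivors of every enabled filter, then deduplicate to
    document-level pairs."""
    results = list(results)
    survivors = set(range(len(results)))
    if config.use_confidence:
        survivors &= {
            i for i, r in enumerate(results) if r.confidence >= config.conf_threshold
        }
    if config.use_blocklist:
        bl = blocklist if blocklist is not None else Blocklist()
        survivors &= {i for i, r in enumerate(results) if r.mention.text not in bl}
    if config.use_similarity:
        survivors &= {
            i for i, r in enumerate(results) if r.similarity > config.sim_threshold
        }
    return dedupe_results(results[i] for i in sorted(survivors))


def write_results(results: Iterable[NormalizationResult], path: str | Path) -> None:
    """TSV: doc_id, gene_id, mention text, start, end, confidence, similarity."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\tgene_id\tmention\tstart\tend\tconfidence\tsimilarity\n")
        for r in results:
            fh.write(
                f"{r.doc_id}\t{r.gene_id}\t{r.mention.text}\t{r.mention.start}\t"
                f"{r.mention.end}\t{r.confidence:.6f}\t{r.similarity:.6f}\n"
            )


def read_results(path: str | Path) -> list[NormalizationResult]:
    out: list[NormalizationResult] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("doc_id\t"):
            raise ValueError(f"{path}: missing results header")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            doc_id, gene_id, text, start, end, conf, sim = parts
            m = Mention(doc_id=doc_id, start=int(start), end=int(end),
                        text=text, score=float(conf))
            out.append(
                NormalizationResult(
                    doc_id=doc_id, gene_id=gene_id, mention=m,
                    similarity=float(sim), confidence=float(conf),
                )
            )
    return out
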