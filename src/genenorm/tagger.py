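"""Dictionary-based gene mention tagging.

The recognizer consumes a pre-built dictionary of gene-name surface forms,
each carrying a real-valued confidence score produced upstream by a
semi-supervised learner (higher = more likely a genuine gene name; observed
scores range roughly -1.6 to +1.0).  Tagging is a longest-match scan of the
document's token stream against a token trie of the normalized surface
forms: matches are anchored at token boundaries, non-overlapping, and
resolved leftmost-longest.  Confidence thresholding normally happens later,
in the filtering stage, but ``tag`` accepts a ``min_score`` for callers that
want to prune early.

Known limitation, kept by design: enumerations such as "ORP-1 to ORP-6" or
"cofactors A, D, E, and C" are not expanded — only surface forms literally
present in the dictionary can be found.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .textnorm import normalize_key, tokenize_with_spans

__all__ = ["ScoredDictionary", "Mention", "load_dictionary", "tag", "write_mentions"]


@dataclass
class ScoredDictionary:
    """Normalized surface form -> confidence score, plus a token trie.

    Keys are canonical token strings (lowercased, single-spaced); duplicate
    surface forms collapse to the maximum score seen.
    """

    entries: dict[str, float] = field(default_factory=dict)
    # trie over token sequences: nested dicts; _SCORE marks an accepting node
    _trie: dict = field(default_factory=dict, repr=False)

    _SCORE = object()  # sentinel trie key

    def add(self, surface: str, score: float) -> None:
        key = normalize_key(surface)
        if not key:
            raise ValueError(f"surface form {surface!r} has no tokens")
        if not math.isfinite(score):
            raise ValueError(f"non-finite score for {surface!r}")
        if key in self.entries:
            score = max(score, self.entries[key])
        self.entries[key] = score
        node = self._trie
        for tok in key.split(" "):
            node = node.setdefault(tok, {})
        node[self._SCORE] = score

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, surface: str) -> bool:
        return normalize_key(surface) in self.entries

    @classmethod
    def from_items(cls, items: Iterable[tuple[str, float]]) -> "ScoredDictionary":
        d = cls()
        for surface, score in items:
            d.add(surface, score)
        return d


@dataclass(frozen=True)
class Mention:
    """A located gene-name span: 0-based half-open character offsets into the
    source document, the verbatim slice, and the dictionary confidence."""

    doc_id: str
    start: int
    end: int
    text: str
    score: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


def load_dictionary(path: str | Path) -> ScoredDictionary:
    """Load a two-column TSV (surface form, confidence score).

    Surface forms are normalized before keying; duplicate normalized keys keep
    the maximum score.  A malformed line (wrong column count, non-numeric
    score) raises ``ValueError`` naming the line number.
    """
    d = ScoredDictionary()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            surface, score_text = parts
            try:
                # tolerate U+2212 minus as printed in some tables
                score = float(score_text.strip().replace("−", "-"))
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric confidence score {score_text!r}"
                ) from exc
            d.add(surface, score)
    return d


def tag(
    doc_id: str,
    text: str,
    dictionary: ScoredDictionary,
    min_score: float = -math.inf,
) -> list[Mention]:
    """Find dictionary matches in *text* as non-overlapping leftmost-longest
    token-anchored spans.

    The scan walks the token stream; at each position the trie yields the
    longest entry whose normalized token sequence matches.  Matches are
    selected before score filtering, so raising ``min_score`` only removes
    mentions and never changes the segmentation (monotone pruning).
    """
    spans = tokenize_with_spans(text)
    mentions: list[Mention] = []
    i = 0
    n = len(spans)
    SCORE = ScoredDictionary._SCORE
    while i < n:
        node = dictionary._trie
        best_end = -1  # token index past last token of best match
        best_score = 0.0
        j = i
        while j < n:
            nxt = node.get(spans[j][0].text)
            if nxt is None:
                break
            node = nxt
            j += 1
            if SCORE in node:
                best_end = j
                best_score = node[SCORE]
        if best_end > 0:
            start = spans[i][1]
            end = spans[best_end - 1][2]
            if best_score >= min_score:
                mentions.append(
                    Mention(doc_id=doc_id, start=start, end=end,
                            text=text[start:end], score=best_score)
                )
            i = best_end
        else:
            i += 1
    return mentions


def write_mentions(mentions: Iterable[Mention], path: str | Path) -> None:
    """Serialize mentions as TSV: doc_id, start, end, text, score."""
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(f"{m.doc_id}\t{m.start}\t{m.end}\t{m.text}\t{m.score:.6f}\n")
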