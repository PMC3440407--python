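"""Tokenization, case folding, and the stop lists shared by mapping and
disambiguation.

Gene names in text and in lexicons differ in punctuation, spacing, and the
placement of numeric suffixes ("NF-kappaB2" vs "NF kappa B 2").  All string
comparison in this package therefore goes through a single tokenizer that
splits on punctuation/whitespace and at every alphabetic<->numeric boundary,
and lowercases.  Mixed-case boundaries ("kappaB") are deliberately NOT split,
and no stemming is performed ("homologue" and "homolog" stay distinct).

Two stop lists are used: a general English list (~500 common words) and a
small manually curated list of 27 common biological terms ("gene",
"receptor", "human", ...) that carry no information about *which* gene is
meant.  Both ship as packaged data files and can be replaced by any
one-term-per-line text file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Token",
    "StopList",
    "tokenize",
    "tokenize_with_spans",
    "remove_stops",
    "load_stop_file",
    "default_stops",
    "normalize_key",
]

# runs of letters or of digits; everything else is a delimiter
_TOKEN_RE = re.compile(r"[^\W\d_]+|\d+", re.UNICODE)


@dataclass(frozen=True)
class Token:
    """A lowercased tokenizer output unit: a pure-alpha or pure-numeric run."""

    text: str
    kind: str  # "alpha" | "numeric"

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("Token text must be non-empty")


def tokenize_with_spans(text: str) -> list[tuple[Token, int, int]]:
    """Tokenize *text*, returning each token with its half-open character span
    in the original string.

    Splits on punctuation and whitespace and at alpha<->numeric boundaries in
    both directions; token text is lowercased.  Character offsets refer to the
    untouched input so callers can recover verbatim slices.
    """
    out: list[tuple[Token, int, int]] = []
    for m in _TOKEN_RE.finditer(text):
        piece = m.group(0)
        kind = "numeric" if piece[0].isdigit() else "alpha"
        out.append((Token(piece.lower(), kind), m.start(), m.end()))
    return out


def tokenize(text: str) -> list[Token]:
    """Tokenize *text* into lowercased alpha/numeric tokens.

    >>> [t.text for t in tokenize("NF-kappaB2")]
    ['nf', 'kappab', '2']
    """
    return [tok for tok, _, _ in tokenize_with_spans(text)]


def normalize_key(text: str) -> str:
    """Canonical single-spaced lowercase token form used as a lookup key."""
    return " ".join(t.text for t in tokenize(text))


@dataclass(frozen=True)
class StopList:
    """The two term sets removed before indexing and approximate matching.

    ``english_terms`` is the general English list; ``bio_terms`` the 27
    curated biological terms.  Disambiguation removes only the English set,
    so the two are kept separate.
    """

    english_terms: frozenset[str] = field(default_factory=frozenset)
    bio_terms: frozenset[str] = field(default_factory=frozenset)

    @property
    def all_terms(self) -> frozenset[str]:
        return self.english_terms | self.bio_terms

    def __contains__(self, term: str) -> bool:
        return term in self.english_terms or term in self.bio_terms


def load_stop_file(path: str | Path) -> frozenset[str]:
    """Load a one-term-per-line stop file; '#' comments and blanks ignored."""
    terms: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.add(line.lower())
    return frozenset(terms)


def _packaged(name: str) -> frozenset[str]:
    ref = resources.files("genenorm.data").joinpath(name)
    terms: set[str] = set()
    for line in ref.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.add(line.lower())
    return frozenset(terms)


def default_stops(
    english_path: str | Path | None = None,
    bio_path: str | Path | None = None,
) -> StopList:
    """Build the default :class:`StopList` from the packaged data files,
    optionally overriding either list with a user-supplied file."""
    english = load_stop_file(english_path) if english_path else _packaged("english_stops.txt")
    bio = load_stop_file(bio_path) if bio_path else _packaged("bio_stops.txt")
    return StopList(english_terms=english, bio_terms=bio)


def remove_stops(tokens: Iterable[Token], stops: StopList) -> list[Token]:
    """Order-preserving removal of tokens whose text is in either stop set."""
    return [t for t in tokens if t.text not in stops]
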