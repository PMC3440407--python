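"""Scoring against a gene-normalization gold standard.

The unit of evaluation is the unique (document id, gene identifier) pair —
the gold standard annotates which genes each abstract discusses, not where.
Precision, recall and F1 follow the usual definitions
P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R).

``sweep`` re-applies the filtering stage over a grid of NER-confidence
thresholds and evaluates each, tracing the precision/recall trade-off a user
can tune: as the threshold rises the survivor sets are nested decreasing, so
recall never increases.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .filtering import Blocklist, FilterConfig, NormalizationResult, apply_filters

__all__ = ["GoldStandard", "EvalCounts", "load_gold", "evaluate", "sweep",
           "write_sweep_csv"]


@dataclass(frozen=True)
class GoldStandard:
    """The expert-annotated (doc_id, gene_id) pairs."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if any(not d or not g for d, g in self.pairs):
            raise ValueError("gold pairs must have non-empty doc and gene ids")

    def __len__(self) -> int:
        return len(self.pairs)


def load_gold(path: str | Path) -> GoldStandard:
    """Gold TSV: ``doc_id<TAB>gene_id[<TAB>mention excerpt]``; the optional
    excerpt column is ignored for scoring."""
    pairs: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: need doc_id and gene_id")
            pairs.add((parts[0].strip(), parts[1].strip()))
    return GoldStandard(pairs=frozenset(pairs))


@dataclass(frozen=True)
class EvalCounts:
    TP: int
    FP: int
    FN: int
    precision: float
    recall: float
    f1: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "EvalCounts":
        if min(tp, fp, fn) < 0:
            raise ValueError("counts must be non-negative")
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (
            2.0 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        return cls(TP=tp, FP=fp, FN=fn, precision=precision, recall=recall, f1=f1)

    def summary(self) -> str:
        """Report line rounded to 3 decimal places."""
        return (
            f"P={self.precision:.3f} R={self.recall:.3f} F1={self.f1:.3f} "
            f"(TP={self.TP} FP={self.FP} FN={self.FN})"
        )


def evaluate(
    predictions: Iterable[tuple[str, str]], gold: GoldStandard
) -> EvalCounts:
    """Set comparison of predicted vs gold (doc_id, gene_id) pairs."""
    if not gold.pairs:
        raise ValueError("evaluation against an empty gold standard is undefined")
    pred = set(predictions)
    tp = len(pred & gold.pairs)
    return EvalCounts.from_counts(tp=tp, fp=len(pred) - tp, fn=len(gold.pairs) - tp)


def sweep(
    results: Sequence[NormalizationResult],
    thresholds: Iterable[float],
    gold: GoldStandard,
    config: FilterConfig = FilterConfig(),
    blocklist: Blocklist | None = None,
) -> list[tuple[float, EvalCounts]]:
    """Re-filter the (unfiltered, confidence-carrying) pipeline output at each
    confidence threshold and evaluate; output ordered as the input grid."""
    out: list[tuple[float, EvalCounts]] = []
    for t in thresholds:
        cfg = replace(config, conf_threshold=t, use_confidence=True)
        kept = apply_filters(results, cfg, blocklist)
        pairs = {(r.doc_id, r.gene_id) for r in kept}
        out.append((t, evaluate(pairs, gold)))
    return out


def write_sweep_csv(
    rows: Iterable[tuple[float, EvalCounts]], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["threshold", "precision", "recall", "f1", "TP", "FP", "FN"])
        for t, c in rows:
            w.writerow([t, f"{c.precision:.6f}", f"{c.recall:.6f}",
                        f"{c.f1:.6f}", c.TP, c.FP, c.FN])
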