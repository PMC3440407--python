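"""End-to-end orchestration: tag -> map -> disambiguate -> filter -> dedupe.

``run_pipeline`` wires the stages together in order and logs per-stage
counters (mentions found, exact vs approximate hits, records removed per
filter) to the ``genenorm`` logger.  All resources are loaded and validated
before any document is processed; a missing or malformed resource is a hard
error up front.

A *gold-mention mode* accepts pre-specified mention spans instead of running
the tagger, for measuring the downstream stages free of NER errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import disambig, mapping, tagger
from .disambig import GeneProfile, build_space, disambiguate
from .filtering import (
    Blocklist,
    FilterConfig,
    NormalizationResult,
    apply_filters,
    load_blocklist,
)
from .mapping import BM25Params, SynonymLexicon, build_index, load_lexicon, map_mention
from .synthetic import CorpusBundle
from .tagger import Mention, ScoredDictionary, load_dictionary
from .textnorm import StopList, default_stops

logger = logging.getLogger("genenorm")

__all__ = [
    "PipelineConfig",
    "PipelineResources",
    "run_pipeline",
    "load_abstracts",
    "measure_disambiguation_accuracy",
]


@dataclass(frozen=True)
class PipelineConfig:
    """File paths plus the tunables of every stage; parsed from one YAML file
    by the CLI or built directly in code."""

    lexicon_path: str = ""
    dictionary_path: str = ""
    profiles_path: str = ""
    blocklist_path: str = ""
    english_stops_path: str | None = None
    bio_stops_path: str | None = None
    bm25: BM25Params = BM25Params()
    filters: FilterConfig = FilterConfig()
    approximate_top1: bool = False
    disambiguation: bool = True
    tag_min_score: float = float("-inf")
    output_path: str = "results.tsv"

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        bm = d.get("bm25", {})
        fl = d.get("filters", {})
        return cls(
            lexicon_path=d.get("lexicon", ""),
            dictionary_path=d.get("dictionary", ""),
            profiles_path=d.get("profiles", ""),
            blocklist_path=d.get("blocklist", ""),
            english_stops_path=d.get("english_stops"),
            bio_stops_path=d.get("bio_stops"),
            bm25=BM25Params(
                k1=float(bm.get("k1", 2.0)),
                b=float(bm.get("b", 0.75)),
                score_threshold=float(bm.get("score_threshold", 1.0)),
                clamp_negative_idf=bool(bm.get("clamp_negative_idf", False)),
            ),
            filters=FilterConfig(
                conf_threshold=float(fl.get("conf_threshold", -0.8)),
                sim_threshold=float(fl.get("sim_threshold", 0.1)),
                use_blocklist=bool(fl.get("use_blocklist", True)),
                use_confidence=bool(fl.get("use_confidence", True)),
                use_similarity=bool(fl.get("use_similarity", True)),
            ),
            approximate_top1=bool(d.get("approximate_top1", False)),
            disambiguation=bool(d.get("disambiguation", True)),
            tag_min_score=float(d.get("tag_min_score", float("-inf"))),
            output_path=d.get("output", "results.tsv"),
        )


@dataclass
class PipelineResources:
    """In-memory resources for one run; load from files or adopt a synthetic
    bundle directly."""

    lexicon: SynonymLexicon
    dictionary: ScoredDictionary
    profiles: dict[str, GeneProfile]
    blocklist: Blocklist
    stops: StopList
    index: mapping.InvertedIndex = field(init=False)

    def __post_init__(self) -> None:
        self.index = build_index(self.lexicon, self.stops)

    @classmethod
    def from_config(cls, config: PipelineConfig) -> "PipelineResources":
        try:
            lexicon = load_lexicon(config.lexicon_path)
            dictionary = load_dictionary(config.dictionary_path)
            profiles = disambig.load_profiles(config.profiles_path)
            blocklist = (
                load_blocklist(config.blocklist_path)
                if config.blocklist_path
                else Blocklist()
            )
            stops = default_stops(config.english_stops_path, config.bio_stops_path)
        except (OSError, ValueError) as exc:
            raise RuntimeError(f"failed to load pipeline resources: {exc}") from exc
        return cls(lexicon=lexicon, dictionary=dictionary, profiles=profiles,
                   blocklist=blocklist, stops=stops)

    @classmethod
    def from_bundle(cls, bundle: CorpusBundle) -> "PipelineResources":
        return cls(
            lexicon=bundle.lexicon,
            dictionary=bundle.dictionary,
            profiles=bundle.profiles,
            blocklist=bundle.blocklist,
            stops=default_stops(),
        )


def load_abstracts(path: str | Path) -> dict[str, str]:
    """Abstracts TSV: ``doc_id<TAB>text``, one document per line."""
    docs: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t", 1)
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected doc_id<TAB>text")
            docs[parts[0]] = parts[1]
    return docs


def run_pipeline(
    config: PipelineConfig,
    abstracts: Mapping[str, str],
    resources: PipelineResources | None = None,
    gold_mentions: Sequence[Mention] | None = None,
) -> list[NormalizationResult]:
    """Run the full normalization pipeline over *abstracts*.

    With ``gold_mentions`` the tagger is bypassed and the given spans are
    mapped/disambiguated/filtered instead (their ``score`` fields are used as
    confidences).  Returns deduplicated document-level results.
    """
    res = resources if resources is not None else PipelineResources.from_config(config)

    # stage 1: mention detection
    if gold_mentions is None:
        mentions: list[Mention] = []
        for doc_id in sorted(abstracts):
            mentions.extend(
                tagger.tag(doc_id, abstracts[doc_id], res.dictionary,
                           min_score=config.tag_min_score)
            )
    else:
        mentions = list(gold_mentions)
    logger.info("tagger: %d mentions in %d documents", len(mentions), len(abstracts))

    # stage 2: entity mapping
    mapped: list[tuple[Mention, list[mapping.Candidate]]] = []
    n_exact = n_approx = 0
    for m in mentions:
        cands = map_mention(m, res.lexicon, res.index, config.bm25, res.stops,
                            top1=config.approximate_top1)
        if not cands:
            continue
        if cands[0].method == "exact":
            n_exact += 1
        else:
            n_approx += 1
        mapped.append((m, cands))
    logger.info("mapping: %d exact, %d approximate, %d unmapped",
                n_exact, n_approx, len(mentions) - len(mapped))

    # stage 3: disambiguation (shared vector space for the whole batch)
    results: list[NormalizationResult] = []
    if config.disambiguation and mapped:
        space = build_space(res.profiles.values(), abstracts.values(), res.stops)
        n_ambiguous = 0
        for m, cands in mapped:
            if len(cands) > 1:
                n_ambiguous += 1
            gid, sim = disambiguate(m, abstracts[m.doc_id], cands, res.profiles,
                                    space, res.stops)
            results.append(
                NormalizationResult(doc_id=m.doc_id, gene_id=gid, mention=m,
                                    similarity=sim, confidence=m.score)
            )
        logger.info("disambiguation: %d of %d mentions were ambiguous",
                    n_ambiguous, len(mapped))
    else:
        # no disambiguation: keep the top candidate with a neutral similarity
        for m, cands in mapped:
            results.append(
                NormalizationResult(doc_id=m.doc_id, gene_id=cands[0].gene_id,
                                    mention=m, similarity=1.0, confidence=m.score)
            )

    # stage 4: filtering + document-level deduplication
    kept = apply_filters(results, config.filters, res.blocklist)
    logger.info("filtering: %d of %d records kept (%d document-level pairs)",
                len(kept), len(results), len({(r.doc_id, r.gene_id) for r in kept}))
    return kept


def measure_disambiguation_accuracy(
    bundle: CorpusBundle,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[int, float]:
    """Fraction of genuinely ambiguous planted mentions (>= 2 candidate
    genes after mapping) that disambiguation resolves to the generator's
    true gene.  Returns (number of ambiguous cases, accuracy)."""
    from .textnorm import normalize_key

    res = PipelineResources.from_bundle(bundle)
    space = build_space(res.profiles.values(), bundle.abstracts.values(), res.stops)
    n_ambiguous = n_correct = 0
    for doc_id, surface, true_gid in bundle.planted:
        if true_gid is None:
            continue
        key = normalize_key(surface)
        found = [
            m for m in tagger.tag(doc_id, bundle.abstracts[doc_id], res.dictionary)
            if normalize_key(m.text) == key
        ]
        if not found:
            continue
        cands = map_mention(found[0], res.lexicon, res.index, config.bm25,
                            res.stops, top1=config.approximate_top1)
        if len(cands) < 2:
            continue
        n_ambiguous += 1
        chosen, _ = disambiguate(found[0], bundle.abstracts[doc_id], cands,
                                 res.profiles, space, res.stops)
        if chosen == true_gid:
            n_correct += 1
    accuracy = n_correct / n_ambiguous if n_ambiguous else float("nan")
    return n_ambiguous, accuracy
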