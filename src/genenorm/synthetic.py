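"""Self-contained synthetic corpora for exercising every pipeline stage.

The generator emulates the data regime of a gene-normalization benchmark at
desk scale: a synonym lexicon, a confidence-scored NER dictionary, per-gene
textual profiles, abstracts with planted mentions, a family-name blocklist,
and a document-level gold standard — all derived deterministically from one
seed, with no download.

Surface forms are built from a syllable grammar plus numeric suffixes so
that the hyphen/space variant rules have something to chew on; configurable
noise perturbs the planted mentions (hyphenation changes, case changes, word
order permutation — which only approximate matching survives — and stop-word
insertion).  Ambiguous synonyms are shared between a true gene and decoys;
abstracts embed context terms from the *true* gene's profile vocabulary, so
disambiguation is solvable, mimicking how real abstracts discuss a gene's
annotations.  A configurable fraction of planted surfaces are blocklisted
family names: negatives that the filters must remove and the gold standard
excludes.  Dictionary confidences are base score plus Gaussian noise, with
family-name entries centered below zero the way a learned gene-name score
separates the two populations.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .disambig import GeneProfile
from .filtering import Blocklist
from .mapping import SynonymLexicon
from .tagger import ScoredDictionary
from .textnorm import normalize_key

__all__ = ["GeneratorConfig", "CorpusBundle", "generate_corpus"]

_NOISE_KINDS = frozenset({"hyphenation", "case_change", "word_order", "stop_insertion"})

_NAME_SYLLABLES = [
    "bak", "dor", "fim", "gal", "hep", "jun", "kor", "lim", "mav", "nol",
    "pir", "quz", "rin", "sov", "tul", "vex", "wos", "yan", "zeb", "cru",
]
_PROFILE_SYLLABLES = [
    "ost", "eryl", "bind", "oxis", "terol", "plasm", "cyt", "mito", "chond",
    "nucle", "kinas", "phos", "lig", "glyc", "regul", "sign", "path", "metab",
    "membr", "transp",
]
_FILLER_WORDS = [
    "study", "analysis", "experiments", "observed", "measured", "levels",
    "cells", "tissue", "samples", "increase", "decrease", "expression",
    "activity", "role", "effect", "pathway", "interaction", "mechanism",
    "localization", "phenotype",
]
_STOP_INSERTS = ["the", "a", "gene", "human"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus; all sampling flows from ``seed``."""

    n_genes: int = 40
    synonyms_per_gene: tuple[int, int] = (2, 4)
    ambiguity_fraction: float = 0.2
    profile_vocab_size: int = 20
    n_docs: int = 60
    mentions_per_doc: tuple[int, int] = (2, 4)
    variant_noise: frozenset[str] = frozenset({"hyphenation", "case_change"})
    family_name_fraction: float = 0.1
    confidence_noise_sd: float = 0.3
    context_terms_per_mention: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_docs < 1 or self.profile_vocab_size < 1:
            raise ValueError("counts must be >= 1")
        for lo, hi in (self.synonyms_per_gene, self.mentions_per_doc):
            if not 1 <= lo <= hi:
                raise ValueError("ranges must satisfy 1 <= lo <= hi")
        for frac in (self.ambiguity_fraction, self.family_name_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.ambiguity_fraction > 0.0 and self.n_genes < 2:
            raise ValueError("ambiguity requires at least 2 genes")
        unknown = self.variant_noise - _NOISE_KINDS
        if unknown:
            raise ValueError(f"unknown variant noise kinds: {sorted(unknown)}")
        if self.confidence_noise_sd < 0.0:
            raise ValueError("confidence_noise_sd must be >= 0")


@dataclass
class CorpusBundle:
    """Everything a pipeline run needs, plus the generator's truth labels."""

    config: GeneratorConfig
    lexicon: SynonymLexicon
    dictionary: ScoredDictionary
    profiles: dict[str, GeneProfile]
    abstracts: dict[str, str]
    blocklist: Blocklist
    blocklist_names: list[str]
    gold_pairs: set[tuple[str, str]]
    # (doc_id, planted surface, true gene_id or None for family-name negatives)
    planted: list[tuple[str, str, str | None]] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the bundle as the pipeline's input files; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "lexicon": out / "lexicon.tsv",
            "dictionary": out / "dictionary.tsv",
            "profiles": out / "profiles.jsonl",
            "abstracts": out / "abstracts.tsv",
            "blocklist": out / "blocklist.txt",
            "gold": out / "gold.tsv",
            "manifest": out / "manifest.json",
        }
        with open(paths["lexicon"], "w", encoding="utf-8") as fh:
            for gid in sorted(self.lexicon.records):
                fh.write("\t".join([gid, *self.lexicon.records[gid]]) + "\n")
        with open(paths["dictionary"], "w", encoding="utf-8") as fh:
            for key in sorted(self.dictionary.entries):
                fh.write(f"{key}\t{self.dictionary.entries[key]:.6f}\n")
        with open(paths["profiles"], "w", encoding="utf-8") as fh:
            for gid in sorted(self.profiles):
                p = self.profiles[gid]
                fh.write(json.dumps({
                    "gene_id": p.gene_id,
                    "description": p.description,
                    "go_terms": list(p.go_terms),
                    "linked_abstracts": list(p.linked_abstracts),
                }, sort_keys=True) + "\n")
        with open(paths["abstracts"], "w", encoding="utf-8") as fh:
            for doc_id in sorted(self.abstracts):
                fh.write(f"{doc_id}\t{self.abstracts[doc_id]}\n")
        with open(paths["blocklist"], "w", encoding="utf-8") as fh:
            for name in sorted(self.blocklist_names):
                fh.write(name + "\n")
        with open(paths["gold"], "w", encoding="utf-8") as fh:
            for doc_id, gid in sorted(self.gold_pairs):
                fh.write(f"{doc_id}\t{gid}\n")
        manifest = {"seed": self.config.seed, "config": _config_dict(self.config)}
        paths["manifest"].write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return paths


def _config_dict(cfg: GeneratorConfig) -> dict:
    return {
        "n_genes": cfg.n_genes,
        "synonyms_per_gene": list(cfg.synonyms_per_gene),
        "ambiguity_fraction": cfg.ambiguity_fraction,
        "profile_vocab_size": cfg.profile_vocab_size,
        "n_docs": cfg.n_docs,
        "mentions_per_doc": list(cfg.mentions_per_doc),
        "variant_noise": sorted(cfg.variant_noise),
        "family_name_fraction": cfg.family_name_fraction,
        "confidence_noise_sd": cfg.confidence_noise_sd,
        "context_terms_per_mention": cfg.context_terms_per_mention,
        "seed": cfg.seed,
    }


def _make_word(rng: random.Random, syllables: list[str], n: int) -> str:
    return "".join(rng.choice(syllables) for _ in range(n))


def _make_synonym(rng: random.Random, used_keys: set[str]) -> str:
    """A fresh synonym surface, unique under token normalization."""
    for _ in range(1000):
        n_words = rng.choice([1, 1, 2, 2, 3])
        words = [_make_word(rng, _NAME_SYLLABLES, rng.choice([2, 2, 3]))
                 for _ in range(n_words)]
        surface = " ".join(words)
        style = rng.random()
        suffix = str(rng.randrange(1, 10))
        if style < 0.4:
            surface = f"{surface}-{suffix}"
        elif style < 0.7:
            surface = f"{surface} {suffix}"
        key = normalize_key(surface)
        if key and key not in used_keys:
            used_keys.add(key)
            return surface
    raise RuntimeError("could not generate a fresh synonym surface")


def _apply_noise(rng: random.Random, surface: str, noise: frozenset[str]) -> str:
    s = surface
    if "hyphenation" in noise and rng.random() < 0.5:
        if "-" in s:
            s = s.replace("-", " " if rng.random() < 0.5 else "")
        elif " " in s:
            parts = s.split(" ")
            i = rng.randrange(len(parts) - 1)
            parts[i] = parts[i] + "-" + parts[i + 1]
            del parts[i + 1]
            s = " ".join(parts)
    if "word_order" in noise and rng.random() < 0.5:
        parts = s.replace("-", " ").split(" ")
        if len(parts) > 1:
            rng.shuffle(parts)
            s = " ".join(parts)
    if "stop_insertion" in noise and rng.random() < 0.5:
        s = f"{rng.choice(_STOP_INSERTS)} {s}"
    if "case_change" in noise and rng.random() < 0.5:
        s = rng.choice([s.upper(), s.lower(), s.title()])
    return s


def generate_corpus(config: GeneratorConfig) -> CorpusBundle:
    """Build a deterministic fixture bundle from ``config``.

    Guarantees: gold pairs reference only genes actually planted; no
    blocklisted negative appears in gold; with ``ambiguity_fraction`` 0 and
    no variant noise every planted mention maps uniquely to its gene.
    """
    rng = random.Random(config.seed)
    gene_ids = [str(100001 + i) for i in range(config.n_genes)]

    used_keys: set[str] = set()
    lexicon = SynonymLexicon()
    primary: dict[str, str] = {}
    all_synonyms: list[tuple[str, str]] = []  # (gene_id, surface)
    for gid in gene_ids:
        lo, hi = config.synonyms_per_gene
        n_syn = rng.randint(lo, hi)
        syns = [_make_synonym(rng, used_keys) for _ in range(n_syn)]
        lexicon.add(gid, syns)
        primary[gid] = syns[0]
        all_synonyms.extend((gid, s) for s in syns)

    # share a fraction of synonyms with a second ("decoy") gene
    shared_of: dict[str, list[str]] = {}  # normalized synonym -> gene_ids
    n_shared = int(round(config.ambiguity_fraction * len(all_synonyms)))
    if n_shared:
        for gid, surface in rng.sample(all_synonyms, n_shared):
            others = [g for g in gene_ids if g != gid]
            decoy = rng.choice(others)
            lexicon.records[decoy].append(surface)
            shared_of[normalize_key(surface)] = [gid, decoy]
        lexicon._exact = None

    # distinct per-gene profile vocabulary, then profiles from it
    profile_words: dict[str, list[str]] = {}
    used_pw: set[str] = set()
    for gid in gene_ids:
        words: list[str] = []
        while len(words) < config.profile_vocab_size:
            w = _make_word(rng, _PROFILE_SYLLABLES, rng.choice([2, 3]))
            if w not in used_pw:
                used_pw.add(w)
                words.append(w)
        profile_words[gid] = words

    profiles: dict[str, GeneProfile] = {}
    for gid in gene_ids:
        words = profile_words[gid]
        desc = f"{primary[gid]} protein involved in " + " ".join(words[:6])
        go_terms = tuple(
            " ".join(rng.sample(words, 2)) for _ in range(3)
        )
        # first linked abstract covers the whole vocabulary so every profile
        # word has frequency >= 1; the second adds realistic uneven usage
        linked = (
            " ".join(words),
            " ".join(rng.choices(words, k=12)),
        )
        profiles[gid] = GeneProfile(
            gene_id=gid, description=desc, go_terms=go_terms,
            linked_abstracts=linked,
        )

    # family-name blocklist entries (negatives)
    n_family = max(3, config.n_genes // 4)
    family_names: list[str] = []
    for _ in range(n_family):
        surface = _make_synonym(rng, used_keys)
        family_names.append(surface + " family")
    blocklist = Blocklist.from_names(family_names)

    # abstracts with planted mentions and context terms
    abstracts: dict[str, str] = {}
    gold_pairs: set[tuple[str, str]] = set()
    planted: list[tuple[str, str, str | None]] = []
    surfaces_in_text: set[str] = set()
    for d in range(config.n_docs):
        doc_id = f"doc{d:04d}"
        lo, hi = config.mentions_per_doc
        sentences: list[str] = []
        for _ in range(rng.randint(lo, hi)):
            filler = rng.choices(_FILLER_WORDS, k=4)
            if rng.random() < config.family_name_fraction:
                surface = rng.choice(family_names)
                sentences.append(
                    f"The {surface} was {filler[0]} in {filler[1]} {filler[2]}."
                )
                planted.append((doc_id, surface, None))
                surfaces_in_text.add(surface)
                continue
            gid, base_surface = rng.choice(all_synonyms)
            surface = _apply_noise(rng, base_surface, config.variant_noise)
            ctx = rng.sample(
                profile_words[gid],
                min(config.context_terms_per_mention, len(profile_words[gid])),
            )
            # each context term appears twice: abstracts dwell on the
            # annotations of the gene they discuss, and the doubled term
            # frequency keeps the correct-pair cosine well clear of the
            # similarity filter regardless of how many genes share the doc
            sentences.append(
                f"Our {filler[0]} of {surface} {filler[1]} "
                + " ".join(ctx) + " " + " ".join(ctx)
                + f" and {filler[2]} {filler[3]}."
            )
            gold_pairs.add((doc_id, gid))
            planted.append((doc_id, surface, gid))
            surfaces_in_text.add(surface)
        abstracts[doc_id] = " ".join(sentences)

    # the NER dictionary knows every planted surface, scored by population
    dictionary = ScoredDictionary()
    family_keys = {normalize_key(n) for n in family_names}
    for surface in sorted(surfaces_in_text):
        base = -1.0 if normalize_key(surface) in family_keys else 1.0
        dictionary.add(surface, base + rng.gauss(0.0, config.confidence_noise_sd))

    return CorpusBundle(
        config=config,
        lexicon=lexicon,
        dictionary=dictionary,
        profiles=profiles,
        abstracts=abstracts,
        blocklist=blocklist,
        blocklist_names=family_names,
        gold_pairs=gold_pairs,
        planted=planted,
    )
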