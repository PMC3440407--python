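"""Exact variant matching, the inverted index, and BM25 approximate search."""

import math
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from genenorm.mapping import (
    BM25Params,
    SynonymLexicon,
    approximate_search,
    build_index,
    exact_lookup,
    generate_variants,
    idf,
    load_lexicon,
    map_mention,
)
from genenorm.tagger import Mention
from genenorm.textnorm import StopList, remove_stops, tokenize


def brute_force_bm25(query_text, lexicon, stops, params):
    """Independent oracle evaluating the Okapi BM25 sum term by term over a
    flat list of (gene_id, synonym, tokens) documents."""
    docs = []
    for gid in sorted(lexicon.records):
        for syn in lexicon.records[gid]:
            toks = [t.text for t in remove_stops(tokenize(syn), stops)]
            if toks:
                docs.append((gid, syn, toks))
    N = len(docs)
    avgdl = sum(len(t) for _, _, t in docs) / N
    qterms = {t.text for t in remove_stops(tokenize(query_text), stops)}
    scores = []
    for gid, syn, toks in docs:
        s = 0.0
        for q in qterms:
            f = toks.count(q)
            if f == 0:
                continue
            n = sum(1 for _, _, d in docs if q in d)
            w = math.log((N - n + 0.5) / (n + 0.5))
            s += w * f * (params.k1 + 1) / (f + params.k1 * (1 - params.b + params.b * len(toks) / avgdl))
        scores.append((gid, syn, s))
    return scores


class TestGenerateVariants:
    def test_hyphen_space_variants(self):
        got = {v.casefold() for v in generate_variants("NF-Kappa B")}
        assert {"nf kappa b", "nf kappab", "nfkappab"} <= got

    def test_slash_splits_both_sides(self):
        got = generate_variants("Lef/tcf")
        assert {"Lef", "tcf"} <= got

    def test_no_delimiters_identity(self):
        assert generate_variants("BRCA1") == {"BRCA1"}

    def test_empty_string(self):
        assert generate_variants("") == set()

    def test_many_delimiters_capped(self):
        name = "-".join(["aa"] * 15)
        got = generate_variants(name)
        assert name in got
        assert "aa" * 15 in got  # all-deleted
        assert " ".join(["aa"] * 15) in got  # all-spaced
        assert len(got) < 10


class TestExactLookup:
    def test_hyphen_and_case_rules(self):
        lex = SynonymLexicon()
        lex.add("G1", ["NF kappa B"])
        (c,) = exact_lookup("nf-kappa b", lex)
        assert (c.gene_id, c.method) == ("G1", "exact")

    def test_slash_rule(self, toy_lexicon):
        got = {c.gene_id for c in exact_lookup("Lef/tcf", toy_lexicon)}
        assert got == {"G2", "G3"}

    def test_no_match(self, toy_lexicon):
        assert exact_lookup("xyz", toy_lexicon) == []

    def test_whitespace_normalized_comparison(self):
        lex = SynonymLexicon()
        lex.add("G1", ["NF  kappa   B"])
        assert [c.gene_id for c in exact_lookup("NF kappa B", lex)] == ["G1"]


class TestBuildIndex:
    def test_stop_removal_and_lengths(self, stops):
        lex = SynonymLexicon()
        lex.add("G1", ["PRNP gene"])
        idx = build_index(lex, stops)
        assert idx.N == 1
        assert idx.doc_len == {0: 1}
        assert idx.avgdl == 1.0
        assert "prnp" in idx.postings and "gene" not in idx.postings

    def test_avgdl_is_mean(self, stops):
        lex = SynonymLexicon()
        lex.add("G1", ["abcx defy"])
        lex.add("G2", ["pqrs tuvw wxyz mnop"])
        idx = build_index(lex, stops)
        assert idx.avgdl == 3.0

    def test_stop_only_synonym_not_indexed(self, stops):
        lex = SynonymLexicon()
        lex.add("G1", ["the gene", "PRNP"])
        idx = build_index(lex, stops)
        assert idx.N == 1

    def test_all_stop_lexicon_errors(self, stops):
        lex = SynonymLexicon()
        lex.add("G1", ["the gene"])
        with pytest.raises(ValueError, match="empty"):
            build_index(lex, stops)


class TestIdf:
    def _index_with(self, N, n, stops):
        lex = SynonymLexicon()
        for i in range(N):
            syns = ["term filler%d" % i] if i < n else ["filler%d" % i]
            lex.add("G%03d" % i, syns)
        return build_index(lex, stops)

    def test_symmetry_point_zero(self, stops):
        idx = self._index_with(10, 5, stops)
        assert idf("term", idx) == pytest.approx(0.0)

    def test_eq2_direct_value(self, stops):
        idx = self._index_with(100, 10, stops)
        assert idf("term", idx) == pytest.approx(math.log(90.5 / 10.5), abs=1e-12)
        assert idf("term", idx) == pytest.approx(2.1542, abs=5e-4)

    def test_unseen_term(self, stops):
        idx = self._index_with(100, 0, stops)
        assert idf("zzzz", idx) == pytest.approx(math.log(100.5 / 0.5), abs=1e-12)
        assert idf("zzzz", idx) == pytest.approx(5.3033, abs=5e-4)

    def test_strictly_decreasing_in_df(self, stops):
        vals = [idf("term", self._index_with(50, n, stops)) for n in range(0, 50, 7)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestApproximateSearch:
    @pytest.fixture(scope="class")
    @staticmethod
    def ly9_lexicon():
        lex = SynonymLexicon()
        lex.add("G5", ["ly9, mouse, homolog of"])
        lex.add("D1", ["zeta chain kinase"])
        lex.add("D2", ["catalase beta subunit"])
        lex.add("D3", ["ferritin light polypeptide"])
        return lex

    def test_ly9_full_match_ranks_first(self, ly9_lexicon, stops):
        idx = build_index(ly9_lexicon, stops)
        params = BM25Params(score_threshold=0.0)
        cands = approximate_search("the human homologue of mouse Ly9", idx, params, stops)
        assert cands and cands[0].gene_id == "G5"
        assert cands[0].matched_synonym == "ly9, mouse, homolog of"

    def test_word_order_irrelevant(self, ly9_lexicon, stops):
        idx = build_index(ly9_lexicon, stops)
        params = BM25Params(score_threshold=0.0)
        a = approximate_search("the human homologue of mouse Ly9", idx, params, stops)
        b = approximate_search("Ly9 mouse homologue human the of", idx, params, stops)
        assert [(c.gene_id, c.score) for c in a] == [(c.gene_id, c.score) for c in b]

    def test_all_stop_query_empty(self, ly9_lexicon, stops):
        idx = build_index(ly9_lexicon, stops)
        assert approximate_search("the gene", idx, BM25Params(), stops) == []

    def test_threshold_monotone_pruning(self, ly9_lexicon, stops):
        idx = build_index(ly9_lexicon, stops)
        prev = None
        for thr in (0.0, 1.0, 2.0, 5.0, 50.0):
            got = {c.gene_id for c in approximate_search(
                "mouse ly9 kinase", idx, BM25Params(score_threshold=thr), stops)}
            if prev is not None:
                assert got <= prev
            prev = got

    def test_top1_mode_returns_single_best(self, ly9_lexicon, stops):
        idx = build_index(ly9_lexicon, stops)
        params = BM25Params(score_threshold=0.0)
        got = approximate_search("mouse ly9 kinase", idx, params, stops, top1=True)
        assert len(got) == 1 and got[0].gene_id == "G5"

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_on_random_lexicons(self, seed, stops):
        rng = random.Random(seed)
        vocab = ["alphax", "betay", "gammaz", "deltaw", "epsv", "zetau", "etat", "thetas"]
        lex = SynonymLexicon()
        for i in range(40):
            syns = [" ".join(rng.choices(vocab, k=rng.randint(1, 4)))
                    for _ in range(rng.randint(1, 3))]
            lex.add("G%03d" % i, syns)
        idx = build_index(lex, stops)
        params = BM25Params(score_threshold=-math.inf)
        query = " ".join(rng.choices(vocab, k=3))
        got = approximate_search(query, idx, params, stops)
        oracle = brute_force_bm25(query, lex, stops, params)
        best_by_gene = {}
        for gid, syn, s in oracle:
            best_by_gene[gid] = max(best_by_gene.get(gid, -math.inf), s)
        for c in got:
            assert c.score == pytest.approx(best_by_gene[c.gene_id], abs=1e-9)
        # ranking agrees with the oracle's best score per gene
        scores = [c.score for c in got]
        assert scores == sorted(scores, reverse=True)


@given(st.permutations(["mouse", "ly", "9", "homolog", "ly"]))
def test_bm25_permutation_invariance(perm):
    lex = SynonymLexicon()
    lex.add("G5", ["ly9, mouse, homolog of"])
    lex.add("D1", ["zeta chain kinase"])
    lex.add("D2", ["ferritin light polypeptide"])
    stops = StopList()
    idx = build_index(lex, stops)
    base = approximate_search("mouse ly 9 homolog ly", idx, BM25Params(score_threshold=0.0), stops)
    got = approximate_search(" ".join(perm), idx, BM25Params(score_threshold=0.0), stops)
    assert [(c.gene_id, c.score) for c in got] == [(c.gene_id, c.score) for c in base]


class TestMapMention:
    def _mention(self, text):
        return Mention(doc_id="d", start=0, end=len(text), text=text, score=1.0)

    def test_exact_hit_skips_approximate(self, toy_lexicon, stops):
        idx = build_index(toy_lexicon, stops)
        cands = map_mention(self._mention("NF-kappa B"), toy_lexicon, idx,
                            BM25Params(score_threshold=0.0), stops)
        assert all(c.method == "exact" for c in cands)
        assert {c.gene_id for c in cands} == {"G1"}

    def test_fallback_to_approximate(self, toy_lexicon, stops):
        idx = build_index(toy_lexicon, stops)
        cands = map_mention(self._mention("the human homologue of mouse Ly9"),
                            toy_lexicon, idx, BM25Params(score_threshold=0.0), stops)
        assert cands and cands[0].method == "approximate"
        assert cands[0].gene_id == "G5"

    def test_neither_route_matches(self, toy_lexicon, stops):
        idx = build_index(toy_lexicon, stops)
        assert map_mention(self._mention("zzz qqq"), toy_lexicon, idx,
                           BM25Params(), stops) == []


def test_lexicon_tsv_roundtrip(tmp_path):
    p = tmp_path / "lex.tsv"
    p.write_text("G1\tNF kappa B\tnuclear factor\nG2\tLEF\n")
    lex = load_lexicon(p)
    assert lex.records == {"G1": ["NF kappa B", "nuclear factor"], "G2": ["LEF"]}


def test_lexicon_rejects_missing_synonyms(tmp_path):
    p = tmp_path / "lex.tsv"
    p.write_text("G1\n")
    with pytest.raises(ValueError):
        load_lexicon(p)


def test_bm25params_validation():
    with pytest.raises(ValueError):
        BM25Params(k1=0.0)
    with pytest.raises(ValueError):
        BM25Params(b=1.5)
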