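"""Tokenization, n-grams, hypergeometric enrichment, and entropy scoring."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from envclust.annotate import (
    TermUniverse,
    annotate_cluster,
    categorical_universe,
    entropy_score,
    hypergeom_pvalue,
    literature_universes,
    parse_hetatm_codes,
)
from envclust.synthdata import CorpusGenSpec, gen_corpus
from envclust.text import ngrams, tokenize


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Zinc-binding in proteins", ["zinc-binding", "proteins"]),
            ("", []),
            ("Copper binding, blue copper proteins.", ["copper", "binding", "blue", "copper", "proteins"]),
            ("EF-hand Ca2+ site", ["ef-hand", "ca2", "site"]),
        ],
    )
    def test_examples(self, text, expected):
        assert tokenize(text) == expected

    @given(st.text(max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_tokens_lowercase_and_stopword_free(self, text):
        from envclust.text import stop_words

        toks = tokenize(text)
        for t in toks:
            assert t == t.lower()
            assert t not in stop_words()
            assert not t.startswith("-") and not t.endswith("-")


class TestNgrams:
    def test_bigrams_are_consecutive_pairs(self):
        uni, bi = ngrams(["a", "b", "c"])
        assert uni == {"a", "b", "c"}
        assert bi == {"a b", "b c"}

    def test_single_token_has_no_bigrams(self):
        uni, bi = ngrams(["solo"])
        assert uni == {"solo"} and bi == set()

    def test_worked_example(self):
        toks = tokenize("Copper binding, blue copper proteins.")
        _, bi = ngrams(toks)
        assert bi == {"copper binding", "binding blue", "blue copper", "copper proteins"}


def exact_hypergeom_tail(k, n, K, M):
    """Independent oracle: exact combinatorial enumeration with rationals."""
    total = Fraction(0)
    denom = math.comb(M, n)
    for i in range(k, min(n, K) + 1):
        total += Fraction(math.comb(K, i) * math.comb(M - K, n - i), denom)
    return float(total)


class TestHypergeomPvalue:
    def test_k_zero_is_one(self):
        assert hypergeom_pvalue(0, 4, 5, 10) == 1.0

    def test_universal_term_is_one(self):
        for k in range(5):
            assert hypergeom_pvalue(k, 5, 12, 12) == pytest.approx(1.0)

    def test_worked_example(self):
        # M=10, K=5, n=4, k=3: (C(5,3)C(5,1)+C(5,4)C(5,0))/C(10,4) = 55/210
        assert hypergeom_pvalue(3, 4, 5, 10) == pytest.approx(55 / 210, rel=1e-12)

    def test_matches_exact_enumeration_small_universe(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            M = int(rng.integers(1, 26))
            K = int(rng.integers(0, M + 1))
            n = int(rng.integers(0, M + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            assert hypergeom_pvalue(k, n, K, M) == pytest.approx(
                exact_hypergeom_tail(k, n, K, M), rel=1e-9, abs=1e-12
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(5, 4, 10, 20)
        with pytest.raises(ValueError):
            hypergeom_pvalue(1, 25, 10, 20)


class TestEntropyScore:
    def test_single_protein_term_scores_zero(self):
        assert entropy_score("t", {"p1": 3}, idf=2.0) == 0.0

    def test_uniform_spread_maximizes_entropy(self):
        h = entropy_score("t", {f"p{i}": 1 for i in range(4)}, idf=1.0)
        assert h == pytest.approx(math.log(4))
        skew = entropy_score("t", {"p0": 3, "p1": 1, "p2": 1, "p3": 1}, idf=1.0)
        assert skew < h

    def test_three_protein_worked_fixture(self):
        # term A: doc counts 2/1/1 → D = (0.5, 0.25, 0.25), H ≈ 1.0397
        # term B: 4/0/0 → H = 0
        h_a = entropy_score("A", {"p1": 2, "p2": 1, "p3": 1}, idf=1.0)
        assert h_a == pytest.approx(-(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25)))
        assert h_a == pytest.approx(1.0397, abs=1e-4)
        h_b = entropy_score("B", {"p1": 4, "p2": 0, "p3": 0}, idf=1.0)
        assert h_b == 0.0
        # normalization by the cluster max (h_a) then idf weighting
        idf = math.log(100 / 5)
        assert entropy_score("A", {"p1": 2, "p2": 1, "p3": 1}, idf, max_entropy=h_a) == pytest.approx(idf)

    def test_permutation_invariant(self):
        a = entropy_score("t", {"p1": 2, "p2": 5, "p3": 1}, idf=1.3)
        b = entropy_score("t", {"p3": 1, "p1": 2, "p2": 5}, idf=1.3)
        assert a == b

    def test_absent_term_rejected(self):
        with pytest.raises(ValueError):
            entropy_score("t", {"p1": 0}, idf=1.0)


@pytest.fixture(scope="module")
def implanted_corpus():
    """200 proteins; the first 8 share an implanted keyword absent elsewhere."""
    cluster = [f"s{i:03d}" for i in range(8)]
    spec = CorpusGenSpec(
        n_proteins=200,
        clusters={0: cluster},
        implants={"keyword": {"zinc-implant": cluster, "common": [f"s{i:03d}" for i in range(150)]}},
        seed=9,
    )
    corpus, truth = gen_corpus(spec)
    return corpus, cluster


class TestAnnotateCluster:
    def test_implanted_keyword_ranks_first(self, implanted_corpus):
        corpus, cluster = implanted_corpus
        results = annotate_cluster(cluster, corpus)
        kw = results["keyword"]
        assert kw and kw[0].term == "zinc-implant"
        assert kw[0].k == 8 and kw[0].K == 8 and kw[0].M == 200
        assert kw[0].p_corrected < 0.01

    def test_ubiquitous_term_not_significant(self, implanted_corpus):
        corpus, cluster = implanted_corpus
        results = annotate_cluster(cluster, corpus, keep_all=True)
        common = [t for t in results["keyword"] if t.term == "common"]
        assert common and common[0].p_raw > 0.01

    def test_correction_factor_and_bounds(self, implanted_corpus):
        corpus, cluster = implanted_corpus
        results = annotate_cluster(cluster, corpus, keep_all=True)
        for cat in results:
            n_terms = len(results[cat])
            for t in results[cat]:
                assert 0.0 <= t.p_raw <= t.p_corrected <= 1.0

    def test_literature_terms_carry_entropy_scores(self, implanted_corpus):
        corpus, cluster = implanted_corpus
        results = annotate_cluster(cluster, corpus, keep_all=True)
        assert results["unigram"]
        for t in results["unigram"][:20]:
            assert t.entropy_score is not None and t.entropy_score >= 0

    def test_single_protein_term_has_zero_entropy_score(self, implanted_corpus):
        corpus, cluster = implanted_corpus
        results = annotate_cluster(cluster, corpus, keep_all=True)
        for t in results["unigram"]:
            if len(t.contributors) == 1 and t.k == 1:
                # contributed by one protein only → entropy 0 unless the
                # same term appears via multiple proteins' documents
                docs_per_protein = 1
                assert t.entropy_score == pytest.approx(0.0, abs=1e-12)
                break

    def test_background_duplication_only_via_M_and_K(self, implanted_corpus):
        corpus, cluster = implanted_corpus
        uni = categorical_universe(corpus, "keyword")
        r1 = annotate_cluster(cluster, corpus, universes={
            "keyword": uni, **literature_universes(corpus)})
        bigger = TermUniverse("keyword", dict(uni.counts), uni.M + 1)
        r2 = annotate_cluster(cluster, corpus, universes={
            "keyword": bigger, **literature_universes(corpus)})
        t1 = {t.term: t for t in r1["keyword"]}
        t2 = {t.term: t for t in r2["keyword"]}
        assert set(t1) == set(t2)
        for term in t1:
            assert t1[term].k == t2[term].k
            assert t1[term].p_raw != t2[term].p_raw  # only M changed

    def test_empty_cluster_rejected(self, implanted_corpus):
        corpus, _ = implanted_corpus
        with pytest.raises(ValueError):
            annotate_cluster([], corpus)


class TestHetatmParsing:
    def test_codes_extracted_waters_skipped(self, tmp_path):
        path = tmp_path / "het.pdb"
        path.write_text(
            "HETATM    1 ZN    ZN A 101      10.000  10.000  10.000  1.00  0.00          ZN\n"
            "HETATM    2  O   HOH A 201       5.000   5.000   5.000  1.00  0.00           O\n"
            "HETATM    3 FE   HEM A 301       1.000   2.000   3.000  1.00  0.00          FE\n"
        )
        assert parse_hetatm_codes(path) == {"ZN", "HEM"}
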