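"""Document index, fractional references, document scores, and the
functional-coherence statistic."""

import numpy as np
import pytest

from envclust.coherence import (
    KnowledgeCorpus,
    _kl_vs_poisson,
    build_index,
    document_score,
    fractional_reference,
    functional_coherence,
)
from envclust.synthdata import CorpusGenSpec, gen_corpus


def tiny_corpus(documents, protein_docs, large_scale=()):
    proteins = sorted(protein_docs)
    return KnowledgeCorpus(
        proteins=proteins,
        documents=dict(documents),
        protein_docs={p: set(d) for p, d in protein_docs.items()},
        large_scale_docs=set(large_scale),
    )


class TestBuildIndex:
    def test_two_documents_are_mutual_neighbors(self):
        c = tiny_corpus(
            {"d1": "zinc binding protein", "d2": "copper transport"},
            {"p1": ["d1"], "p2": ["d2"]},
        )
        index = build_index(c, m=20)
        assert index.m == 1
        assert [nb for nb, _ in index.neighbors["d1"]] == ["d2"]
        assert [nb for nb, _ in index.neighbors["d2"]] == ["d1"]

    def test_identical_documents_rank_first_with_similarity_one(self):
        c = tiny_corpus(
            {
                "d1": "zinc finger domain zinc",
                "d2": "zinc finger domain zinc",
                "d3": "unrelated membrane lipid transporter",
            },
            {"p1": ["d1"], "p2": ["d2"], "p3": ["d3"]},
        )
        index = build_index(c, m=2)
        top, sim = index.neighbors["d1"][0]
        assert top == "d2"
        assert sim == pytest.approx(1.0)

    def test_topic_corpus_neighbors_stay_within_topic(self):
        clusters = {0: [f"s{i:03d}" for i in range(5)], 1: [f"s{i:03d}" for i in range(5, 10)]}
        corpus, truth = gen_corpus(
            CorpusGenSpec(n_proteins=10, clusters=clusters, docs_per_protein=3, seed=1)
        )
        index = build_index(corpus, m=5)
        doc_topic = {}
        for p, docs in corpus.protein_docs.items():
            for d in docs:
                doc_topic[d] = truth["topic_of"][p]
        same = total = 0
        for d, nbs in index.neighbors.items():
            for nb, _ in nbs:
                total += 1
                same += doc_topic[nb] == doc_topic[d]
        assert same / total >= 0.9

    def test_never_own_neighbor_and_sorted(self, reference_index):
        for d, nbs in list(reference_index.neighbors.items())[:50]:
            assert d not in [nb for nb, _ in nbs]
            sims = [s for _, s in nbs]
            assert sims == sorted(sims, reverse=True)
            assert len(nbs) == reference_index.m

    def test_empty_corpus_rejected(self):
        c = tiny_corpus({"d1": "one document"}, {"p1": ["d1"]})
        with pytest.raises(ValueError):
            build_index(c, m=5)


class TestFractionalReference:
    def test_proportion_examples(self):
        c = tiny_corpus(
            {"d1": "x", "d2": "y"},
            {"p1": ["d1"], "p2": ["d1"], "p3": ["d1"], "p4": ["d1", "d2"]},
        )
        assert fractional_reference("d1", {"p1"}, c) == pytest.approx(0.25)
        assert fractional_reference("d1", {"p1", "p2", "p3", "p4"}, c) == 1.0
        assert fractional_reference("d1", {"other"}, c) == 0.0
        with pytest.raises(ValueError):
            fractional_reference("d9", {"p1"}, c)


class TestDocumentScore:
    def test_hand_built_corpus(self):
        # 5 docs: d1's neighbors will be d2 (identical text) then others.
        docs = {
            "d1": "alpha beta gamma",
            "d2": "alpha beta gamma",
            "d3": "alpha beta delta",
            "d4": "epsilon zeta eta",
            "d5": "epsilon zeta theta",
        }
        pd = {"p1": ["d1"], "p2": ["d2"], "p3": ["d3"], "p4": ["d4"], "p5": ["d5"]}
        c = tiny_corpus(docs, pd)
        index = build_index(c, m=2)
        nbs = [nb for nb, _ in index.neighbors["d1"]]
        assert nbs == ["d2", "d3"]
        # cluster {p2}: only d2 contributes 1/1
        assert document_score("d1", {"p2"}, index, c) == pytest.approx(1.0)
        # cluster {p2, p3}: both neighbors fully inside
        assert document_score("d1", {"p2", "p3"}, index, c) == pytest.approx(2.0)
        # cluster {p4}: no neighbor maps inside
        assert document_score("d1", {"p4"}, index, c) == 0.0

    def test_bounds(self, reference_corpus, reference_index):
        corpus, _, clusters = reference_corpus
        for d in list(reference_index.neighbors)[:20]:
            s = document_score(d, clusters[0], reference_index, corpus)
            assert 0.0 <= s <= reference_index.m


class TestFunctionalCoherence:
    def test_kl_kernel_zero_against_itself(self):
        # Poisson-distributed integers with rate equal to their own mean
        # would give KL→0 in the infinite-sample limit; the kernel itself
        # must return exactly 0 when observed equals reference pointwise.
        # Degenerate single-bin-at-zero case: lambda floored, KL ≈ 0.
        assert _kl_vs_poisson(np.zeros(10)) == pytest.approx(0.0, abs=1e-3)

    def test_all_zero_scores_give_near_zero_coherence(self):
        clusters = {0: [f"s{i:03d}" for i in range(5)]}
        corpus, _ = gen_corpus(CorpusGenSpec(n_proteins=40, clusters=clusters, seed=2))
        index = build_index(corpus, m=20)
        # a single background protein shares no topic: scores all ~0
        res = functional_coherence(["s030"], index, corpus)
        assert res.F >= 0.0

    def test_invariant_to_order(self, reference_corpus, reference_index):
        corpus, _, clusters = reference_corpus
        f1 = functional_coherence(clusters[3], reference_index, corpus).F
        f2 = functional_coherence(list(reversed(clusters[3])), reference_index, corpus).F
        assert f1 == f2

    def test_planted_cluster_beats_random(self, reference_corpus, reference_index):
        corpus, _, clusters = reference_corpus
        coherent = functional_coherence(clusters[0], reference_index, corpus).F
        rng = np.random.default_rng(0)
        random_f = [
            functional_coherence(
                list(rng.choice(corpus.proteins, 10, replace=False)),
                reference_index, corpus,
            ).F
            for _ in range(30)
        ]
        assert coherent > np.percentile(random_f, 95)

    def test_unscorable_cluster_raises(self):
        c = tiny_corpus(
            {"d1": "alpha beta", "d2": "gamma delta"},
            {"p1": ["d1"], "p2": ["d2"], "p3": []},
        )
        index = build_index(c, m=1)
        with pytest.raises(ValueError, match="unscorable"):
            functional_coherence(["p3"], index, c)

    def test_excluded_proteins_tallied(self):
        c = tiny_corpus(
            {"d1": "alpha beta", "d2": "alpha gamma"},
            {"p1": ["d1"], "p2": ["d2"], "p3": []},
        )
        index = build_index(c, m=1)
        res = functional_coherence(["p1", "p2", "p3"], index, c)
        assert res.n_scored_proteins == 2
        assert res.n_excluded_proteins == 1
        assert all(v >= 0 for v in res.per_protein_kl.values())


class TestLargeScaleFiltering:
    def test_flagged_documents_dropped_everywhere(self):
        c = tiny_corpus(
            {"d1": "alpha beta", "d2": "alpha gamma", "d3": "big survey"},
            {"p1": ["d1", "d3"], "p2": ["d2", "d3"]},
            large_scale=["d3"],
        )
        assert "d3" not in c.documents
        assert "d3" not in c.protein_docs["p1"]
        assert "d3" not in c.doc_proteins
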