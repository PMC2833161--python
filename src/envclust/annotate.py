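"""Term extraction and enrichment scoring for selected clusters.

Each cluster is described by terms from two kinds of sources:

* categorical tables (Swiss-Prot-style keywords, GO-like terms, PDB
  HETATM ligand codes) attached per protein, and
* literature terms — unigrams and bigrams of the cluster's documents.

Every term receives an upper-tail hypergeometric p-value against its
background universe, Bonferroni-corrected by the number of distinct
terms tested for that category in the cluster (corrected cutoff 0.01).
Literature terms additionally receive an entropy×idf score that rewards
terms whose supporting documents are spread evenly across the cluster's
proteins rather than concentrated in one heavily published protein
(cutoff 2.7).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .coherence import KnowledgeCorpus
from .text import ngrams, tokenize

DEFAULT_P_CUTOFF = 0.01
DEFAULT_ENTROPY_CUTOFF = 2.7
LITERATURE_CATEGORIES = ("unigram", "bigram")


@dataclass
class TermUniverse:
    """Background counts for one term category over M entities."""

    category: str
    counts: dict[str, int]  # term → number of entities carrying it
    M: int  # total entities

    def __post_init__(self):
        if self.counts and max(self.counts.values()) > self.M:
            raise ValueError("a term count exceeds the universe size")


@dataclass
class TermScore:
    category: str
    term: str
    k: int  # cluster entities with the term
    n: int  # cluster size (entities)
    K: int  # background entities with the term
    M: int  # universe size
    p_raw: float
    p_corrected: float
    entropy_score: float | None = None
    contributors: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "category": self.category, "term": self.term,
            "k": self.k, "n": self.n, "K": self.K, "M": self.M,
            "p_raw": self.p_raw, "p_corrected": self.p_corrected,
            "entropy_score": self.entropy_score,
            "contributors": self.contributors,
        }


def hypergeom_pvalue(k: int, n: int, K: int, M: int) -> float:
    """Upper-tail enrichment p-value P(X ≥ k), X ~ Hypergeometric(M, K, n).

    Drawing n cluster entities from a universe of M in which K carry the
    term, the p-value is the probability of seeing k or more carriers.
    Computed via the log-space survival function for stability.
    """
    if not (0 <= k <= min(n, K) and n <= M and K <= M):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, M={M}")
    if k == 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(k - 1, M, K, n)))


def entropy_score(term: str, cluster_doc_counts: dict[str, int],
                  idf: float, max_entropy: float | None = None) -> float:
    """Entropy×idf literature-term score.

    ``cluster_doc_counts`` maps each cluster protein to the number of its
    documents containing the term; D_tp is each protein's share of the
    cluster total, H_t = −Σ_p D_tp·ln(D_tp).  The entropy is normalized
    by ``max_entropy`` (the maximum raw H over all terms in the cluster,
    supplied by the caller; pre-idf) and then weighted by the term's idf.
    A term confined to one protein has H = 0 and hence score 0.
    """
    total = sum(cluster_doc_counts.values())
    if total <= 0:
        raise ValueError(f"term {term!r} occurs in no cluster document")
    h = 0.0
    for c in cluster_doc_counts.values():
        if c > 0:
            d = c / total
            h -= d * math.log(d)
    if max_entropy is not None and max_entropy > 0:
        h = h / max_entropy
    return h * idf


def categorical_universe(corpus: KnowledgeCorpus, category: str) -> TermUniverse:
    """Background counts for a categorical term table: one count per
    protein carrying the term; M = number of corpus proteins."""
    table = corpus.term_tables.get(category, {})
    counts: dict[str, int] = {}
    for _p, terms in table.items():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return TermUniverse(category=category, counts=counts, M=len(corpus.proteins))


def literature_universes(corpus: KnowledgeCorpus) -> dict[str, TermUniverse]:
    """Unigram/bigram backgrounds: a protein carries a term when any of
    its documents contains it; M = number of corpus proteins."""
    uni_counts: dict[str, int] = {}
    bi_counts: dict[str, int] = {}
    doc_terms = {d: ngrams(tokenize(text)) for d, text in corpus.documents.items()}
    for p in corpus.proteins:
        uni, bi = set(), set()
        for d in corpus.protein_docs.get(p, ()):
            u, b = doc_terms[d]
            uni |= u
            bi |= b
        for t in uni:
            uni_counts[t] = uni_counts.get(t, 0) + 1
        for t in bi:
            bi_counts[t] = bi_counts.get(t, 0) + 1
    M = len(corpus.proteins)
    return {
        "unigram": TermUniverse("unigram", uni_counts, M),
        "bigram": TermUniverse("bigram", bi_counts, M),
    }


def _term_doc_frequency(corpus: KnowledgeCorpus) -> tuple[dict[str, int], dict[str, int], dict]:
    """Document frequency of each unigram/bigram over the whole corpus,
    plus the per-document term sets (reused by annotate_cluster)."""
    doc_terms = {d: ngrams(tokenize(text)) for d, text in corpus.documents.items()}
    uni_df: dict[str, int] = {}
    bi_df: dict[str, int] = {}
    for u, b in doc_terms.values():
        for t in u:
            uni_df[t] = uni_df.get(t, 0) + 1
        for t in b:
            bi_df[t] = bi_df.get(t, 0) + 1
    return uni_df, bi_df, doc_terms


def annotate_cluster(cluster_proteins, corpus: KnowledgeCorpus,
                     universes: dict[str, TermUniverse] | None = None,
                     p_cutoff: float = DEFAULT_P_CUTOFF,
                     entropy_cutoff: float = DEFAULT_ENTROPY_CUTOFF,
                     keep_all: bool = False) -> dict[str, list[TermScore]]:
    """Score every term of every category for one cluster.

    The counting entity is the protein throughout: for categorical terms
    k is the number of cluster proteins carrying the term, and for
    literature terms a protein counts once if any of its documents
    contains the term.  The Bonferroni factor is the number of distinct
    terms observed in the cluster for that category.  Results are sorted
    by corrected p-value then term; only terms with p_corrected <
    ``p_cutoff`` are kept unless ``keep_all``.  Literature terms also
    carry the entropy×idf score (significance flagged at
    ``entropy_cutoff`` by the caller/report layer).
    """
    cluster = sorted(dict.fromkeys(cluster_proteins))
    if not cluster:
        raise ValueError("cluster has no proteins")
    if universes is None:
        universes = {c: categorical_universe(corpus, c) for c in corpus.term_tables}
        universes.update(literature_universes(corpus))

    uni_df, bi_df, doc_terms = _term_doc_frequency(corpus)
    n_docs = len(corpus.documents)
    results: dict[str, list[TermScore]] = {}

    # --- categorical categories ---------------------------------------
    for category, table in corpus.term_tables.items():
        universe = universes[category]
        cluster_terms: dict[str, list[str]] = {}
        for p in cluster:
            for t in table.get(p, ()):
                cluster_terms.setdefault(t, []).append(p)
        scored = _score_terms(category, cluster_terms, len(cluster), universe, p_cutoff, keep_all)
        results[category] = scored

    # --- literature categories ----------------------------------------
    cluster_docs: dict[str, list[str]] = {
        p: sorted(corpus.protein_docs.get(p, ())) for p in cluster
    }
    for category, df_map in (("unigram", uni_df), ("bigram", bi_df)):
        universe = universes[category]
        pos = 0 if category == "unigram" else 1
        # protein → terms in any of its documents; term → per-protein doc counts
        cluster_terms: dict[str, list[str]] = {}
        term_doc_counts: dict[str, dict[str, int]] = {}
        for p, docs in cluster_docs.items():
            seen: set[str] = set()
            for d in docs:
                terms = doc_terms[d][pos]
                seen |= terms
                for t in terms:
                    term_doc_counts.setdefault(t, {}).setdefault(p, 0)
                    term_doc_counts[t][p] += 1
            for t in seen:
                cluster_terms.setdefault(t, []).append(p)
        scored = _score_terms(category, cluster_terms, len(cluster), universe, p_cutoff, keep_all)
        # entropy scores: normalize by the cluster's max raw entropy pre-idf
        raw_h = {}
        for t, counts in term_doc_counts.items():
            total = sum(counts.values())
            raw_h[t] = -sum(
                (c / total) * math.log(c / total) for c in counts.values() if c > 0
            )
        max_h = max(raw_h.values()) if raw_h else 0.0
        for ts in scored:
            idf = math.log(n_docs / df_map[ts.term])
            ts.entropy_score = entropy_score(
                ts.term, term_doc_counts[ts.term], idf, max_entropy=max_h or None
            )
        results[category] = scored
    return results


def _score_terms(category, cluster_terms: dict[str, list[str]], n: int,
                 universe: TermUniverse, p_cutoff: float, keep_all: bool) -> list[TermScore]:
    n_tested = len(cluster_terms)
    scored = []
    for term, carriers in cluster_terms.items():
        k = len(set(carriers))
        K = universe.counts.get(term, k)
        p_raw = hypergeom_pvalue(k, n, K, universe.M)
        p_corr = min(1.0, p_raw * n_tested)
        if keep_all or p_corr < p_cutoff:
            scored.append(
                TermScore(category=category, term=term, k=k, n=n, K=K, M=universe.M,
                          p_raw=p_raw, p_corrected=p_corr,
                          contributors=sorted(set(carriers)))
            )
    scored.sort(key=lambda t: (t.p_corrected, t.term))
    return scored


def parse_hetatm_codes(structure_file) -> set[str]:
    """HETATM residue codes (ligands/ions) present in a PDB-format file;
    waters excluded."""
    codes = set()
    with open(structure_file) as fh:
        for line in fh:
            if line.startswith("HETATM"):
                code = line[17:20].strip()
                if code and code != "HOH":
                    codes.add(code)
    return codes


def scores_to_tsv(results: dict[str, list[TermScore]], path) -> None:
    with open(path, "w") as fh:
        fh.write("category\tterm\tk\tn\tK\tM\tp_raw\tp_corrected\tentropy_score\tcontributors\n")
        for category in sorted(results):
            for t in results[category]:
                es = "" if t.entropy_score is None else f"{t.entropy_score:.6f}"
                fh.write(
                    f"{t.category}\t{t.term}\t{t.k}\t{t.n}\t{t.K}\t{t.M}\t"
                    f"{t.p_raw:.6g}\t{t.p_corrected:.6g}\t{es}\t{';'.join(t.contributors)}\n"
                )


def scores_to_json(results: dict[str, list[TermScore]], path) -> None:
    with open(path, "w") as fh:
        json.dump({c: [t.to_dict() for t in ts] for c, ts in results.items()}, fh, indent=1)
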