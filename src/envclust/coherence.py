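"""Literature-based functional coherence (neighbor divergence per gene).

A cluster of proteins is biologically coherent when its members share
similar literature.  The statistic implemented here works over a corpus
of documents (title + abstract) mapped to proteins:

1. Documents become weighted word vectors (log(1+tf)·idf) compared by
   cosine similarity; each document's m (default 20) most similar
   documents are its *semantic neighbors*.
2. A document's *fractional reference* with respect to a cluster is the
   proportion of its mapped proteins that lie in the cluster.
3. Each document mapped to a cluster protein receives a *score*: the sum
   of the fractional references of its semantic neighbors.
4. Per protein, the document scores (floored to integer bins) form an
   observed distribution that is compared to a Poisson with rate equal
   to the protein's mean score via Kullback-Leibler divergence; the
   cluster's functional coherence F is the mean KL over scorable
   proteins.

Random protein sets yield scores piled near zero and F ≈ 0; sets whose
members share literature produce heavy, over-dispersed score
distributions and large F.  Documents flagged as large-scale studies are
excluded from all maps at corpus construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .text import tokenize

DEFAULT_M_NEIGHBORS = 20
LAMBDA_FLOOR = 1e-6


@dataclass
class KnowledgeCorpus:
    """Proteins, documents, their mapping, and categorical term tables.

    ``documents`` maps document id → raw text (title + abstract already
    concatenated).  Documents flagged large-scale are dropped from
    ``documents``/``protein_docs``/``doc_proteins`` on construction and
    remembered in ``large_scale_docs``.  ``term_tables`` maps a category
    name (e.g. "keyword") to {protein id → set of terms}.
    """

    proteins: list[str]
    documents: dict[str, str]
    protein_docs: dict[str, set[str]]
    doc_proteins: dict[str, set[str]] = field(default_factory=dict)
    term_tables: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    large_scale_docs: set[str] = field(default_factory=set)

    def __post_init__(self):
        # drop large-scale documents everywhere
        for d in self.large_scale_docs:
            self.documents.pop(d, None)
        self.protein_docs = {
            p: {d for d in docs if d in self.documents}
            for p, docs in self.protein_docs.items()
        }
        self.doc_proteins = {}
        for p, docs in self.protein_docs.items():
            for d in docs:
                self.doc_proteins.setdefault(d, set()).add(p)
        unknown = set(self.protein_docs) - set(self.proteins)
        if unknown:
            raise ValueError(f"protein_docs references unknown proteins {sorted(unknown)[:5]}")

    @classmethod
    def from_files(cls, map_path, docs_path, term_paths: dict | None = None) -> "KnowledgeCorpus":
        """Build from a protein↔document TSV (protein_id, document_id,
        large_scale 0/1), a JSON-lines document file (id, title, abstract)
        and optional per-category term TSVs (protein_id, category, term)."""
        import pandas as pd

        m = pd.read_csv(map_path, sep="\t", dtype=str)
        required = {"protein_id", "document_id", "large_scale"}
        if not required <= set(m.columns):
            raise ValueError(f"map file needs columns {sorted(required)}")
        documents: dict[str, str] = {}
        with open(docs_path) as fh:
            for line in fh:
                if line.strip():
                    rec = json.loads(line)
                    documents[str(rec["id"])] = f"{rec.get('title', '')} {rec.get('abstract', '')}".strip()
        large = set(m.loc[m["large_scale"].astype(int) == 1, "document_id"])
        protein_docs: dict[str, set[str]] = {}
        for p, d in zip(m["protein_id"], m["document_id"]):
            protein_docs.setdefault(p, set()).add(d)
        proteins = sorted(protein_docs)
        term_tables = {}
        if term_paths:
            for _, path in term_paths.items():
                t = pd.read_csv(path, sep="\t", dtype=str)
                for p, cat, term in zip(t["protein_id"], t["category"], t["term"]):
                    term_tables.setdefault(cat, {}).setdefault(p, set()).add(term)
        return cls(
            proteins=proteins,
            documents=documents,
            protein_docs=protein_docs,
            term_tables=term_tables,
            large_scale_docs=large,
        )


@dataclass
class DocumentIndex:
    """tf-idf document vectors and the m-nearest-neighbor lists."""

    doc_ids: list[str]
    vocabulary: dict[str, int]
    vectors: sp.csr_matrix  # unit-normalized rows
    neighbors: dict[str, list[tuple[str, float]]]  # sorted by similarity desc
    m: int


def build_index(corpus: KnowledgeCorpus, m: int = DEFAULT_M_NEIGHBORS) -> DocumentIndex:
    """Index the corpus: log(1+tf)·idf word vectors (idf = ln(n_docs/df)),
    cosine similarity, top-m neighbor lists (m capped at n_docs − 1; a
    document is never its own neighbor; ties broken by document id)."""
    doc_ids = sorted(corpus.documents)
    n_docs = len(doc_ids)
    if n_docs < 2:
        raise ValueError("need at least 2 documents to build an index")
    m = min(m, n_docs - 1)

    token_lists = [tokenize(corpus.documents[d]) for d in doc_ids]
    vocabulary: dict[str, int] = {}
    rows, cols, tfs = [], [], []
    for i, toks in enumerate(token_lists):
        counts: dict[str, int] = {}
        for t in toks:
            counts[t] = counts.get(t, 0) + 1
        for t, c in counts.items():
            j = vocabulary.setdefault(t, len(vocabulary))
            rows.append(i)
            cols.append(j)
            tfs.append(c)
    mat = sp.csr_matrix(
        (np.log1p(tfs), (rows, cols)), shape=(n_docs, len(vocabulary))
    )
    df = np.asarray((mat > 0).sum(axis=0)).ravel()
    idf = np.log(n_docs / df)
    mat = mat.multiply(idf[None, :]).tocsr()
    norms = np.sqrt(np.asarray(mat.multiply(mat).sum(axis=1)).ravel())
    norms[norms == 0] = 1.0
    mat = sp.diags(1.0 / norms) @ mat

    sims = (mat @ mat.T).toarray()
    np.fill_diagonal(sims, -np.inf)
    neighbors: dict[str, list[tuple[str, float]]] = {}
    for i, d in enumerate(doc_ids):
        # sort by similarity desc, ties by document id asc
        order = sorted(range(n_docs), key=lambda j: (-sims[i, j], doc_ids[j]))[:m]
        neighbors[d] = [(doc_ids[j], float(sims[i, j])) for j in order]
    return DocumentIndex(doc_ids=doc_ids, vocabulary=vocabulary, vectors=mat,
                         neighbors=neighbors, m=m)


def fractional_reference(doc: str, cluster_proteins, corpus: KnowledgeCorpus) -> float:
    """Proportion of the document's mapped proteins present in the cluster."""
    mapped = corpus.doc_proteins.get(doc, set())
    if not mapped:
        raise ValueError(f"document {doc} maps to no proteins")
    cluster = set(cluster_proteins)
    return len(mapped & cluster) / len(mapped)


def document_score(doc: str, cluster_proteins, index: DocumentIndex,
                   corpus: KnowledgeCorpus) -> float:
    """Sum of fractional references over the document's semantic neighbors.

    Neighbors mapping to no proteins contribute 0.  The score is bounded
    by m (all neighbors fully inside the cluster)."""
    if doc not in index.neighbors:
        raise KeyError(f"document {doc} not in index")
    cluster = set(cluster_proteins)
    total = 0.0
    for nb, _sim in index.neighbors[doc]:
        mapped = corpus.doc_proteins.get(nb)
        if mapped:
            total += len(mapped & cluster) / len(mapped)
    return total


@dataclass
class CoherenceResult:
    cluster_proteins: list[str]
    per_protein_kl: dict[str, float]
    F: float
    n_scored_proteins: int
    n_excluded_proteins: int  # cluster proteins with no surviving documents

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "cluster_proteins": self.cluster_proteins,
                    "per_protein_kl": self.per_protein_kl,
                    "F": self.F,
                    "n_scored_proteins": self.n_scored_proteins,
                    "n_excluded_proteins": self.n_excluded_proteins,
                },
                fh,
            )


def _kl_vs_poisson(scores: np.ndarray) -> float:
    """KL divergence of floored document scores against a Poisson whose
    rate is the mean observed score (floored at LAMBDA_FLOOR)."""
    bins = np.floor(scores).astype(int)
    lam = max(float(np.mean(scores)), LAMBDA_FLOOR)
    values, counts = np.unique(bins, return_counts=True)
    p_obs = counts / counts.sum()
    kl = 0.0
    for b, p in zip(values, p_obs):
        log_pois = -lam + b * math.log(lam) - math.lgamma(b + 1)
        kl += p * (math.log(p) - log_pois)
    return max(kl, 0.0)


def functional_coherence(cluster_proteins, index: DocumentIndex,
                         corpus: KnowledgeCorpus) -> CoherenceResult:
    """Functional coherence F of a protein cluster: mean per-protein KL
    divergence of document-score distributions against their Poisson
    references.  Proteins without documents are excluded from the mean
    and tallied in the result."""
    cluster = list(dict.fromkeys(cluster_proteins))  # dedupe, keep order
    per_protein: dict[str, float] = {}
    excluded = 0
    for p in cluster:
        docs = sorted(corpus.protein_docs.get(p, set()) & set(index.neighbors))
        if not docs:
            excluded += 1
            continue
        scores = np.array([document_score(d, cluster, index, corpus) for d in docs])
        per_protein[p] = _kl_vs_poisson(scores)
    if not per_protein:
        raise ValueError("no cluster protein has any mapped document; cluster unscorable")
    return CoherenceResult(
        cluster_proteins=cluster,
        per_protein_kl=per_protein,
        F=float(np.mean(list(per_protein.values()))),
        n_scored_proteins=len(per_protein),
        n_excluded_proteins=excluded,
    )
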