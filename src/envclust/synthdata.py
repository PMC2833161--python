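"""Deterministic generators for synthetic study data.

Two generators make every pipeline stage testable without external
databases:

* ``gen_vectors`` plants clusters of unit vectors on the sphere —
  cluster centers at a guaranteed pairwise angular separation, members
  perturbed with isotropic Gaussian noise and re-normalized, plus
  optional uniform background points (label −1).  This emulates a
  microenvironment feature matrix with known group structure.
* ``gen_corpus`` builds a protein↔document corpus with topic structure:
  proteins in the same planted cluster draw their documents' vocabulary
  mostly from a shared topic word list (within-topic overlap, default
  0.8) with only slight leakage across topics (default 0.05), so that
  planted clusters are functionally coherent by construction.
  Categorical terms can be implanted into chosen protein sets.

Both generators are pure functions of (spec, seed); ground-truth labels
and implant records are first-class outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coherence import KnowledgeCorpus
from .microenv import MicroenvironmentSet, SiteId

DEFAULT_DIM = 264


@dataclass
class VectorGenSpec:
    """Planted-cluster vector generation parameters.

    ``noise`` is the expected norm of the isotropic Gaussian perturbation
    added to the unit center before re-normalization (per-coordinate
    sigma = noise/sqrt(dim)), so the expected cosine of a member to its
    center is about 1/sqrt(1 + noise²) regardless of dimension: noise 0.1
    gives concentration ≈ 0.995, noise 1.0 gives ≈ 0.71.
    """

    sizes: list[int]
    dim: int = DEFAULT_DIM
    separation_deg: float = 60.0
    noise: float = 0.1
    n_background: int = 0
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def _random_unit(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def _planted_centers(rng: np.random.Generator, n: int, dim: int,
                     separation_deg: float) -> np.ndarray:
    """Rejection-sample unit centers with pairwise angle ≥ separation."""
    if n > dim and separation_deg >= 90:
        raise ValueError(f"cannot place {n} centers at ≥{separation_deg}° in dim {dim}")
    max_cos = math.cos(math.radians(separation_deg))
    centers: list[np.ndarray] = []
    for _ in range(10000):
        c = _random_unit(rng, dim)
        if all(float(c @ other) <= max_cos + 1e-12 for other in centers):
            centers.append(c)
            if len(centers) == n:
                return np.array(centers)
    raise ValueError(
        f"could not place {n} centers at ≥{separation_deg}° separation in dim {dim}"
    )


def _site_id(i: int) -> SiteId:
    # synthetic 4-char structure codes s000, s001, ... (one site per structure)
    return SiteId(f"s{i:03d}" if i < 1000 else f"t{i - 1000:03d}", "A", 1, "CYS")


def gen_vectors(spec: VectorGenSpec) -> tuple[MicroenvironmentSet, np.ndarray]:
    """Generate a raw-space set of planted unit vectors plus true labels.

    Returns (set, labels); cluster members get labels 0..n_clusters−1 in
    block order, background points get −1.
    """
    if any(s <= 0 for s in spec.sizes):
        raise ValueError("cluster sizes must be positive")
    rng = np.random.default_rng(spec.seed)
    centers = _planted_centers(rng, spec.n_clusters, spec.dim, spec.separation_deg)
    rows, labels = [], []
    sigma = spec.noise / math.sqrt(spec.dim)
    for label, size in enumerate(spec.sizes):
        for _ in range(size):
            v = centers[label] + sigma * rng.standard_normal(spec.dim)
            rows.append(v / np.linalg.norm(v))
            labels.append(label)
    for _ in range(spec.n_background):
        rows.append(_random_unit(rng, spec.dim))
        labels.append(-1)
    features = np.array(rows)
    sites = [_site_id(i) for i in range(len(rows))]
    names = [f"f{j}" for j in range(spec.dim)]
    ms = MicroenvironmentSet(sites=sites, features=features, feature_names=names)
    return ms, np.array(labels)


@dataclass
class CorpusGenSpec:
    """Topic-structured corpus generation parameters.

    ``clusters`` maps a topic label to the list of protein ids assigned
    to it; proteins not listed belong to the background topic.  Each
    document mixes words from its protein's topic vocabulary (with
    probability ``within_overlap``) and from the shared background
    vocabulary; a fraction ``cross_overlap`` of each topic's vocabulary
    is shared with every other topic.
    """

    n_proteins: int = 200
    clusters: dict[int, list[str]] = field(default_factory=dict)
    vocab_size: int = 2000
    topic_vocab_size: int = 60
    within_overlap: float = 0.8
    cross_overlap: float = 0.05
    docs_per_protein: int = 5
    doc_length: int = 60
    implants: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    # implants: category → term → protein ids to tag
    large_scale_fraction: float = 0.0
    #: mean number of extra proteins (uniform over the universe) each
    #: document is additionally mapped to, Poisson-distributed.  0 keeps
    #: the strict docs-per-protein accounting; positive values emulate
    #: publications referencing several proteins, which spreads the
    #: fractional references of semantic neighbors below 1 and lets the
    #: coherence statistic's score distributions disperse as in real
    #: corpora.
    shared_doc_rate: float = 0.0
    seed: int = 0


def default_protein_ids(n: int) -> list[str]:
    return [f"s{i:03d}" if i < 1000 else f"t{i - 1000:03d}" for i in range(n)]


def gen_corpus(spec: CorpusGenSpec) -> tuple[KnowledgeCorpus, dict]:
    """Generate a KnowledgeCorpus with planted topic structure.

    Returns (corpus, truth) where truth records per-protein topic labels
    and the implanted categorical terms.  Same spec + seed yields a
    byte-identical corpus.
    """
    rng = np.random.default_rng(spec.seed)
    proteins = default_protein_ids(spec.n_proteins)
    topic_of = {p: -1 for p in proteins}
    for topic, members in spec.clusters.items():
        for p in members:
            if p not in topic_of:
                raise ValueError(f"cluster protein {p} outside the protein universe")
            topic_of[p] = topic

    n_topics = len(spec.clusters)
    shared_per_topic = int(round(spec.cross_overlap * spec.topic_vocab_size))
    own_per_topic = spec.topic_vocab_size - shared_per_topic
    needed = n_topics * own_per_topic + shared_per_topic + 1
    if spec.vocab_size < needed + 50:
        raise ValueError(
            f"vocab_size {spec.vocab_size} too small for {n_topics} topics "
            f"of {spec.topic_vocab_size} words (need ≥ {needed + 50})"
        )
    words = [f"w{i:05d}" for i in range(spec.vocab_size)]
    shared = words[:shared_per_topic]
    topic_vocab: dict[int, list[str]] = {}
    cursor = shared_per_topic
    for topic in sorted(spec.clusters):
        topic_vocab[topic] = shared + words[cursor:cursor + own_per_topic]
        cursor += own_per_topic
    background = words[cursor:]

    documents: dict[str, str] = {}
    protein_docs: dict[str, set[str]] = {p: set() for p in proteins}
    large_scale: set[str] = set()
    doc_counter = 0
    for p in proteins:
        topic = topic_of[p]
        vocab = topic_vocab.get(topic)
        for _ in range(spec.docs_per_protein):
            doc_id = f"d{doc_counter:05d}"
            doc_counter += 1
            toks = []
            for _ in range(spec.doc_length):
                if vocab is not None and rng.random() < spec.within_overlap:
                    toks.append(vocab[rng.integers(len(vocab))])
                else:
                    toks.append(background[rng.integers(len(background))])
            documents[doc_id] = " ".join(toks)
            protein_docs[p].add(doc_id)
            if spec.shared_doc_rate > 0:
                for _ in range(rng.poisson(spec.shared_doc_rate)):
                    protein_docs[proteins[rng.integers(len(proteins))]].add(doc_id)
            if spec.large_scale_fraction > 0 and rng.random() < spec.large_scale_fraction:
                large_scale.add(doc_id)

    term_tables: dict[str, dict[str, set[str]]] = {}
    for category, terms in spec.implants.items():
        table: dict[str, set[str]] = {}
        for term, members in terms.items():
            for p in members:
                table.setdefault(p, set()).add(term)
        term_tables[category] = table

    corpus = KnowledgeCorpus(
        proteins=proteins,
        documents=documents,
        protein_docs=protein_docs,
        term_tables=term_tables,
        large_scale_docs=large_scale,
    )
    truth = {
        "topic_of": topic_of,
        "topic_vocab": topic_vocab,
        "implants": spec.implants,
    }
    return corpus, truth


def linked_corpus_spec(labels: np.ndarray, **kwargs) -> CorpusGenSpec:
    """Corpus spec whose topic clusters mirror planted vector labels.

    Protein ids follow the synthetic SiteId convention (one structure per
    site), so pipeline site→protein mapping is the identity on
    structure_id.
    """
    labels = np.asarray(labels)
    proteins = default_protein_ids(len(labels))
    clusters: dict[int, list[str]] = {}
    for p, lab in zip(proteins, labels):
        if lab >= 0:
            clusters.setdefault(int(lab), []).append(p)
    return CorpusGenSpec(n_proteins=len(labels), clusters=clusters, **kwargs)
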