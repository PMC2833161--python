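"""End-to-end functional-site discovery pipeline.

standardize → PCA → spherical k-means → per-coarse-cluster single-linkage
trees → literature coherence → optimal cluster selection → size/coherence
filters → term annotation → HTML reports.  Every intermediate artifact is
written into the run directory together with a manifest (config, seed,
input hashes) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import annotate as annotate_mod
from . import coarse as coarse_mod
from . import reduce as reduce_mod
from . import report as report_mod
from .coherence import KnowledgeCorpus, build_index, functional_coherence
from .microenv import MicroenvironmentSet, read_vectors, standardize, write_vectors
from .select import (
    build_records,
    filter_clusters,
    records_to_json,
    records_to_tsv,
    score_tree,
    select_clusters,
)
from .tree import hac_single_cosine

logger = logging.getLogger(__name__)

REQUIRED_KEYS = ("k", "n_pc", "seed")


@dataclass
class PipelineConfig:
    """All pipeline parameters, defaults as used in the reference study
    conditions: k=40 coarse clusters on 80 principal components, 20
    semantic neighbors, clusters of ≥5 members with F > 3.0."""

    k: int = 40
    n_pc: int = 80
    m_neighbors: int = 20
    min_size: int = 5
    fc_cutoff: float = 3.0
    p_cutoff: float = 0.01
    entropy_cutoff: float = 2.7
    w_c: float = 0.5
    w_f: float = 0.5
    f_cap: float = 10.0
    n_restarts: int = 3
    seed: int = 0
    vectors: str | None = None  # TSV path (or pass objects to run_pipeline)
    corpus_map: str | None = None
    corpus_docs: str | None = None
    term_tables: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        missing = [k for k in REQUIRED_KEYS if k not in d]
        if missing:
            raise ValueError(f"config missing required keys: {missing}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, out_dir,
                 ms: MicroenvironmentSet | None = None,
                 corpus: KnowledgeCorpus | None = None) -> Path:
    """Execute the full pipeline into ``out_dir`` and return it.

    Inputs come either from the config's file paths or directly as
    in-memory objects.  Any stage failure aborts with the stage name;
    partial outputs are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "inputs": {}}

    stage = "load"
    try:
        if ms is None:
            if not config.vectors:
                raise ValueError("no vector input: set config.vectors or pass ms")
            manifest["inputs"]["vectors"] = _hash_file(config.vectors)
            ms = read_vectors(config.vectors)
        if corpus is None and config.corpus_map and config.corpus_docs:
            manifest["inputs"]["corpus_map"] = _hash_file(config.corpus_map)
            manifest["inputs"]["corpus_docs"] = _hash_file(config.corpus_docs)
            corpus = KnowledgeCorpus.from_files(
                config.corpus_map, config.corpus_docs, config.term_tables or None
            )
        logger.info("loaded %d sites, %d features", ms.n_sites, ms.n_features)

        stage = "standardize"
        std = standardize(ms) if ms.space_tag == "raw" else ms
        write_vectors(std, out / "standardized.tsv")

        stage = "reduce"
        n_pc = min(config.n_pc, std.n_sites - 1, std.n_features)
        model = reduce_mod.fit_pca(std, n_components=n_pc)
        model.to_json(out / "pca_model.json")
        red = reduce_mod.transform(model, std)

        stage = "coarse"
        k = min(config.k, red.n_sites)
        clustering = coarse_mod.restarts(
            red, k, n_restarts=config.n_restarts, base_seed=config.seed
        )
        clustering.to_tsv(red, out / "coarse_assignments.tsv")
        clustering.centroids_to_json(out / "coarse_centroids.json")
        logger.info("coarse k=%d objective=%.4f", k, clustering.objective)

        stage = "coherence-index"
        index = None
        site_to_protein = lambda s: s.structure_id
        if corpus is not None:
            index = build_index(corpus, m=config.m_neighbors)

        stage = "trees+selection"
        all_records = []
        trees_dir = out / "trees"
        trees_dir.mkdir(exist_ok=True)
        for c in range(k):
            members = clustering.members(c)
            if len(members) < 2:
                continue
            sub = red.subset(members)
            tree = hac_single_cosine(sub)
            tree.to_json(trees_dir / f"coarse{c}.json")
            coherence_fn = None
            if index is not None:
                # score_tree passes row indices into the coarse-cluster subset
                def coherence_fn(site_indices, _sub=sub):
                    proteins = sorted({site_to_protein(_sub.sites[i]) for i in site_indices})
                    return functional_coherence(proteins, index, corpus).F
            scores = score_tree(
                sub, tree, coherence_fn=coherence_fn,
                w_c=config.w_c, w_f=config.w_f, f_cap=config.f_cap,
            )
            selected = select_clusters(tree, {nid: sc.S for nid, sc in scores.items()})
            all_records.extend(
                build_records(sub, tree, selected, scores, coarse_id=c,
                              site_to_protein=site_to_protein)
            )

        stage = "filter"
        records_to_json(all_records, out / "selected_all.json")
        kept = filter_clusters(all_records, min_size=config.min_size,
                               fc_cutoff=config.fc_cutoff)
        high_c_low_f = filter_clusters(all_records, min_size=config.min_size,
                                       fc_cutoff=config.fc_cutoff, complement=True)
        records_to_json(kept, out / "clusters.json")
        records_to_tsv(kept, out / "clusters.tsv")
        records_to_json(high_c_low_f, out / "clusters_low_F.json")
        logger.info("selected %d nodes, %d pass filters", len(all_records), len(kept))

        stage = "annotate+report"
        reports_dir = out / "reports"
        reports_dir.mkdir(exist_ok=True)
        if corpus is not None:
            universes = {c: annotate_mod.categorical_universe(corpus, c)
                         for c in corpus.term_tables}
            universes.update(annotate_mod.literature_universes(corpus))
            for rec in kept:
                terms = annotate_mod.annotate_cluster(
                    rec.member_proteins, corpus, universes=universes,
                    p_cutoff=config.p_cutoff, entropy_cutoff=config.entropy_cutoff,
                )
                annotate_mod.scores_to_json(terms, reports_dir / f"{rec.cluster_id}_terms.json")
                report_mod.render_cluster_html(
                    rec, terms, corpus, reports_dir,
                    entropy_cutoff=config.entropy_cutoff,
                )
            report_mod.render_index(kept, reports_dir)
    except Exception as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
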