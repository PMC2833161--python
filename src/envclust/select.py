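"""Optimal cluster selection over a merge tree.

Every internal node of a tree is scored from its internal coherence
(node correlation C, in [0, 1]), its external coherence (functional
coherence F, unbounded above), and its size N.  A bottom-up pass then
selects a disjoint antichain of nodes: a node displaces its descendants'
selection exactly when its score strictly exceeds the sum of scores of
the selected nodes below it.  Selected clusters finally pass the size
filter (N ≥ 5) and the coherence filter (F > 3.0, strict).

The default scoring function S = N·(w_C·C + w_F·min(F, F_cap)/F_cap)
weights the two coherence measures approximately equally by capping and
normalizing F onto [0, 1]; weights, cap, and size exponent are
configurable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .microenv import MicroenvironmentSet, SiteId
from .tree import MergeTree, hac_single_cosine, node_correlation

logger = logging.getLogger(__name__)

DEFAULT_W_C = 0.5
DEFAULT_W_F = 0.5
DEFAULT_F_CAP = 10.0
DEFAULT_MIN_SIZE = 5
DEFAULT_FC_CUTOFF = 3.0


def score_node(C: float, F: float, N: int, w_c: float = DEFAULT_W_C,
               w_f: float = DEFAULT_W_F, f_cap: float = DEFAULT_F_CAP,
               n_exponent: float = 1.0) -> float:
    """Combined node score S = N^e · (w_C·C + w_F·min(F, F_cap)/F_cap).

    Linear in N by default, strictly increasing in C and in F below the
    cap.  S = 0 when both coherences vanish.
    """
    if F < 0:
        raise ValueError("functional coherence must be non-negative")
    if not 0.0 <= C <= 1.0:
        raise ValueError("node correlation must lie in [0, 1]")
    if N < 1:
        raise ValueError("N must be >= 1")
    return (N ** n_exponent) * (w_c * C + w_f * min(F, f_cap) / f_cap)


@dataclass
class NodeScore:
    node_id: int
    C: float
    F: float
    N: int
    S: float


@dataclass
class ClusterRecord:
    """One selected cluster: Clust<coarse>-Sub<node> with its members and scores."""

    cluster_id: str
    coarse_id: int
    node_id: int
    member_sites: list[SiteId]
    member_proteins: list[str]
    C: float
    F: float
    N: int
    S: float

    def to_dict(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "coarse_id": self.coarse_id,
            "node_id": self.node_id,
            "member_sites": [
                [s.structure_id, s.chain, s.residue_number, s.residue_name]
                for s in self.member_sites
            ],
            "member_proteins": self.member_proteins,
            "C": self.C,
            "F": self.F,
            "N": self.N,
            "S": self.S,
        }


def select_clusters(tree: MergeTree, node_scores: dict[int, float]) -> set[int]:
    """Bottom-up dynamic selection of a disjoint node set.

    For each node, best(node) = max(S(node), best(left) + best(right)),
    keeping the descendant selection unless S(node) is *strictly*
    greater.  Returns the selected antichain for the whole tree.
    Leaves default to score 0 unless present in ``node_scores``.
    """
    best: dict[int, float] = {}
    chosen: dict[int, set[int]] = {}
    for nid in range(tree.n_leaves):
        s = node_scores.get(nid, 0.0)
        if s > 0.0:
            best[nid], chosen[nid] = s, {nid}
        else:
            best[nid], chosen[nid] = 0.0, set()
    for nid in tree.internal_nodes():
        nd = tree.nodes[nid]
        if nid not in node_scores:
            raise KeyError(f"node {nid} has no score")
        below = best[nd.left] + best[nd.right]
        s = node_scores[nid]
        if s > below:
            best[nid], chosen[nid] = s, {nid}
        else:
            best[nid], chosen[nid] = below, chosen[nd.left] | chosen[nd.right]
    selected = chosen[tree.root] if tree.n_leaves > 1 else chosen[0]
    _assert_antichain(tree, selected)
    return selected


def _assert_antichain(tree: MergeTree, selected: set[int]) -> None:
    seen: set[int] = set()
    for nid in selected:
        members = set(tree.nodes[nid].members)
        if members & seen:
            raise AssertionError("selected nodes are not pairwise disjoint")
        seen |= members


def filter_clusters(records, min_size: int = DEFAULT_MIN_SIZE,
                    fc_cutoff: float = DEFAULT_FC_CUTOFF,
                    complement: bool = False) -> list[ClusterRecord]:
    """Keep records with N ≥ min_size and F strictly greater than fc_cutoff.

    With ``complement`` the high-C/low-F list is returned instead: records
    that pass the size filter but fail the coherence filter (useful for
    inspecting physically tight but literature-poor clusters).
    """
    kept, comp = [], []
    for r in records:
        if r.N < min_size:
            continue
        (kept if r.F > fc_cutoff else comp).append(r)
    return comp if complement else kept


def score_tree(ms: MicroenvironmentSet, tree: MergeTree,
               coherence_fn=None, w_c: float = DEFAULT_W_C, w_f: float = DEFAULT_W_F,
               f_cap: float = DEFAULT_F_CAP, n_exponent: float = 1.0,
               min_size: int = 2) -> dict[int, NodeScore]:
    """Score every internal node of a tree.

    ``coherence_fn(site_indices) -> F`` supplies functional coherence for
    the member sites of a node; None (or a raised unscorable condition)
    is treated as F = 0 with a warning, so selection never aborts
    mid-tree.  Nodes smaller than ``min_size`` get score 0 so they are
    never selected (but still participate in the bottom-up pass).
    """
    scores: dict[int, NodeScore] = {}
    for nid in tree.internal_nodes():
        members = tree.members(nid)
        N = len(members)
        C = node_correlation(ms, tree, nid)
        F = 0.0
        if coherence_fn is not None:
            try:
                F = float(coherence_fn(members))
            except ValueError:
                logger.warning("node %d unscorable (no documents); F treated as 0", nid)
                F = 0.0
        S = score_node(C, F, N, w_c=w_c, w_f=w_f, f_cap=f_cap, n_exponent=n_exponent)
        if N < min_size:
            S = 0.0
        scores[nid] = NodeScore(nid, C, F, N, S)
    return scores


def build_records(ms: MicroenvironmentSet, tree: MergeTree, selected: set[int],
                  scores: dict[int, NodeScore], coarse_id: int,
                  site_to_protein=None) -> list[ClusterRecord]:
    """Materialize selected nodes as ClusterRecords (Clust<k>-Sub<node>)."""
    site_to_protein = site_to_protein or (lambda s: s.structure_id)
    records = []
    for nid in sorted(selected):
        if nid < tree.n_leaves:
            continue  # leaves never form reportable clusters
        members = tree.members(nid)
        sites = [ms.sites[i] for i in members]
        proteins = sorted({site_to_protein(s) for s in sites})
        sc = scores[nid]
        records.append(
            ClusterRecord(
                cluster_id=f"Clust{coarse_id}-Sub{nid}",
                coarse_id=coarse_id,
                node_id=nid,
                member_sites=sites,
                member_proteins=proteins,
                C=sc.C,
                F=sc.F,
                N=sc.N,
                S=sc.S,
            )
        )
    return records


def records_to_json(records, path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in records], fh, indent=1)


def records_to_tsv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tsites\tproteins\tC\tF\tN\tS\n")
        for r in records:
            sites = ";".join(f"{s.structure_id}:{s.chain}:{s.residue_number}" for s in r.member_sites)
            fh.write(
                f"{r.cluster_id}\t{sites}\t{';'.join(r.member_proteins)}\t"
                f"{r.C:.6f}\t{r.F:.6f}\t{r.N}\t{r.S:.6f}\n"
            )


@dataclass
class StabilityReport:
    """Outcome of pooling selected clusters and re-running tree + selection."""

    exact_match: dict[str, bool]  # original cluster id → recovered exactly
    n_recovered: int  # sites in exactly recovered clusters
    n_changed: int  # sites whose cluster changed membership
    n_singletons: int  # sites that fell out of every selected cluster
    original_total: int

    @property
    def all_recovered(self) -> bool:
        return all(self.exact_match.values())


def recluster_stability(records: list[ClusterRecord], ms: MicroenvironmentSet,
                        coherence_fn=None, min_size: int = 2, **score_kwargs) -> StabilityReport:
    """Pool the member sites of several selected clusters, re-run
    hierarchical clustering + selection on the pooled set, and report how
    faithfully the original clusters reappear.

    Site accounting: recovered + changed + singletons = pooled size.
    """
    if len(records) < 2 and (len(records) == 0 or records[0].N < 2):
        raise ValueError("need at least 2 pooled sites from selected clusters")
    site_key = lambda s: (s.structure_id, s.chain, s.residue_number)
    pooled_keys: dict[tuple, int] = {}
    original: dict[str, set[tuple]] = {}
    for r in records:
        original[r.cluster_id] = {site_key(s) for s in r.member_sites}
        for s in r.member_sites:
            pooled_keys.setdefault(site_key(s), None)
    index_of = {site_key(s): i for i, s in enumerate(ms.sites)}
    pooled = [index_of[k] for k in pooled_keys]
    if len(pooled) < 2:
        raise ValueError("pooled set has fewer than 2 sites")
    sub = ms.subset(pooled)
    tree = hac_single_cosine(sub)
    scores = score_tree(sub, tree, coherence_fn=coherence_fn, min_size=min_size, **score_kwargs)
    selected = select_clusters(tree, {nid: sc.S for nid, sc in scores.items()})
    new_sets = [
        {site_key(sub.sites[i]) for i in tree.members(nid)}
        for nid in selected
        if nid >= tree.n_leaves
    ]
    covered = set().union(*new_sets) if new_sets else set()
    exact, recovered, changed = {}, 0, 0
    for cid, members in original.items():
        hit = any(members == ns for ns in new_sets)
        exact[cid] = hit
        if hit:
            recovered += len(members)
        else:
            changed += len(members & covered)
    singletons = len(pooled_keys) - recovered - changed
    return StabilityReport(
        exact_match=exact,
        n_recovered=recovered,
        n_changed=changed,
        n_singletons=singletons,
        original_total=len(pooled_keys),
    )
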