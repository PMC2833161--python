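"""Agglomerative hierarchical clustering within a coarse cluster.

Single-linkage agglomeration under cosine distance (1 − cosine
similarity), producing a binary merge tree.  Trees are built per coarse
cluster, never globally.  Each internal node is a candidate cluster; its
internal coherence ("node correlation" C) is the cosine similarity
between the unit-normalized mean vectors of its two branches, clamped
to [0, 1].

The implementation is written directly (distance-matrix update with an
explicit lexicographic tie-break on smallest leaf-index pairs) so that
merge order is fully deterministic even in the presence of ties.
Average and complete linkage are available behind the ``linkage``
switch for parameter-sweep experiments only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .coarse import unit_rows
from .microenv import MicroenvironmentSet


@dataclass
class TreeNode:
    node_id: int  # leaves are 0..n-1; internal nodes n..2n-2
    left: int | None
    right: int | None
    merge_distance: float  # 1 − cosine similarity at the merge (0 for leaves)
    members: list[int]  # leaf indices below this node, in leaf order

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class MergeTree:
    """Binary agglomeration tree over a list of site indices.

    ``leaves[i]`` is the site index (into the parent set) of leaf node i.
    Internal nodes are numbered n..2n−2 in merge order; the last is the
    root.  With single linkage, merge distances are non-decreasing from
    leaves to root.
    """

    leaves: list[int]
    nodes: dict[int, TreeNode] = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2 if self.n_leaves > 1 else 0

    def internal_nodes(self) -> list[int]:
        return [i for i in range(self.n_leaves, 2 * self.n_leaves - 1)]

    def members(self, node_id: int) -> list[int]:
        """Site indices (into the parent set) below a node, in leaf order."""
        if node_id not in self.nodes:
            raise KeyError(f"unknown node {node_id}")
        return [self.leaves[i] for i in self.nodes[node_id].members]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "leaves": self.leaves,
                    "nodes": [
                        {
                            "id": nd.node_id,
                            "left": nd.left,
                            "right": nd.right,
                            "distance": nd.merge_distance,
                        }
                        for nd in (self.nodes[i] for i in sorted(self.nodes))
                    ],
                },
                fh,
            )

    def to_gtr(self, path) -> None:
        """Tab format in the style of Cluster 3.0 .gtr files:
        node id, left child, right child, similarity (1 − distance)."""
        with open(path, "w") as fh:
            for i in self.internal_nodes():
                nd = self.nodes[i]
                fh.write(f"NODE{i}\t{nd.left}\t{nd.right}\t{1.0 - nd.merge_distance:.6f}\n")


def _linkage_update(d_a: np.ndarray, d_b: np.ndarray, size_a: int, size_b: int,
                    method: str) -> np.ndarray:
    if method == "single":
        return np.minimum(d_a, d_b)
    if method == "complete":
        return np.maximum(d_a, d_b)
    if method == "average":
        return (size_a * d_a + size_b * d_b) / (size_a + size_b)
    raise ValueError(f"unknown linkage {method!r}")


def hac_single_cosine(ms: MicroenvironmentSet, member_indices=None,
                      linkage: str = "single") -> MergeTree:
    """Exact agglomerative clustering of a (subset of a) set under cosine
    distance; single linkage by default.

    Ties between equal-distance candidate pairs are broken by the
    lexicographically smallest pair of minimum leaf indices, so the merge
    sequence is deterministic.
    """
    member_indices = list(member_indices) if member_indices is not None else list(range(ms.n_sites))
    n = len(member_indices)
    if n < 2:
        raise ValueError("hierarchical clustering needs at least 2 members")
    x = unit_rows(ms.features[member_indices])
    dist = np.clip(1.0 - x @ x.T, 0.0, None)
    np.fill_diagonal(dist, np.inf)

    tree = MergeTree(leaves=member_indices)
    for i in range(n):
        tree.nodes[i] = TreeNode(i, None, None, 0.0, [i])

    # active clusters: row index in dist → (node id, min leaf index, size)
    active: dict[int, tuple[int, int, int]] = {i: (i, i, 1) for i in range(n)}
    next_id = n
    for _ in range(n - 1):
        rows = sorted(active)
        sub = dist[np.ix_(rows, rows)]
        dmin = sub.min()
        # candidates at the minimum; pick smallest (min leaf of pair, max leaf of pair)
        best_key, best_pair = None, None
        ii, jj = np.nonzero(sub <= dmin)
        for a, b in zip(ii, jj):
            if a >= b:
                continue
            ra, rb = rows[a], rows[b]
            la, lb = active[ra][1], active[rb][1]
            key = (min(la, lb), max(la, lb))
            if best_key is None or key < best_key:
                best_key, best_pair = key, (ra, rb)
        ra, rb = best_pair
        id_a, leaf_a, size_a = active[ra]
        id_b, leaf_b, size_b = active[rb]
        left, right = (id_a, id_b) if leaf_a < leaf_b else (id_b, id_a)
        members = sorted(tree.nodes[id_a].members + tree.nodes[id_b].members)
        tree.nodes[next_id] = TreeNode(next_id, left, right, float(dmin), members)
        # merge rb into ra
        merged = _linkage_update(dist[ra], dist[rb], size_a, size_b, linkage)
        dist[ra], dist[:, ra] = merged, merged
        dist[ra, ra] = np.inf
        dist[rb], dist[:, rb] = np.inf, np.inf
        active[ra] = (next_id, min(leaf_a, leaf_b), size_a + size_b)
        del active[rb]
        next_id += 1
    return tree


def node_correlation(ms: MicroenvironmentSet, tree: MergeTree, node_id: int) -> float:
    """Internal coherence of a node: cosine similarity between the
    unit-normalized mean vectors of its two branches, clamped to [0, 1]."""
    nd = tree.nodes.get(node_id)
    if nd is None:
        raise KeyError(f"unknown node {node_id}")
    if nd.is_leaf:
        raise ValueError("node correlation is defined for internal nodes only")
    left_idx = [tree.leaves[i] for i in tree.nodes[nd.left].members]
    right_idx = [tree.leaves[i] for i in tree.nodes[nd.right].members]
    x = ms.features

    def branch_mean(idx):
        m = unit_rows(x[idx]).mean(axis=0)
        norm = np.linalg.norm(m)
        return m / norm if norm > 0 else m

    c = float(branch_mean(left_idx) @ branch_mean(right_idx))
    return float(np.clip(c, 0.0, 1.0))
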