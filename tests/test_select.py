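"""Node scoring, antichain selection (vs exhaustive oracle), filters, and
re-clustering stability."""

import itertools

import numpy as np
import pytest

from envclust.microenv import MicroenvironmentSet, SiteId
from envclust.select import (
    ClusterRecord,
    build_records,
    filter_clusters,
    recluster_stability,
    score_node,
    score_tree,
    select_clusters,
)
from envclust.synthdata import VectorGenSpec, gen_vectors
from envclust.tree import hac_single_cosine


class TestScoreNode:
    def test_zero_coherences_give_zero(self):
        for n in (1, 5, 100):
            assert score_node(0.0, 0.0, n) == 0.0

    def test_linear_in_n(self):
        assert score_node(0.7, 4.0, 10) == pytest.approx(2 * score_node(0.7, 4.0, 5))

    def test_default_formula_at_cap(self):
        # C=1, F at or above the cap, N=5: S = 5·(0.5·1 + 0.5·1) = 5
        assert score_node(1.0, 10.0, 5) == pytest.approx(5.0)
        assert score_node(1.0, 25.0, 5) == pytest.approx(5.0)

    def test_monotone_in_C_and_F_below_cap(self):
        assert score_node(0.9, 2.0, 4) > score_node(0.8, 2.0, 4)
        assert score_node(0.5, 3.0, 4) > score_node(0.5, 2.0, 4)

    def test_negative_F_rejected(self):
        with pytest.raises(ValueError):
            score_node(0.5, -1.0, 4)


def random_tree_and_scores(seed):
    """A random merge tree over ≤8 leaves with random node scores."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 9))
    x = rng.standard_normal((n, 3))
    ms = MicroenvironmentSet(
        [SiteId(f"s{i:03d}", "A", i + 1, "CYS") for i in range(n)], x,
        [f"f{j}" for j in range(3)],
    )
    tree = hac_single_cosine(ms)
    scores = {nid: float(rng.uniform(0, 10)) for nid in tree.internal_nodes()}
    return tree, scores


def best_antichain_total(tree, scores):
    """Exhaustive oracle: maximum total score over all antichains of
    internal nodes (leaves score 0)."""
    internal = tree.internal_nodes()
    best = 0.0
    members = {nid: set(tree.nodes[nid].members) for nid in internal}
    for r in range(1, len(internal) + 1):
        for combo in itertools.combinations(internal, r):
            ok = all(
                members[a].isdisjoint(members[b])
                for a, b in itertools.combinations(combo, 2)
            )
            if ok:
                best = max(best, sum(scores[nid] for nid in combo))
    return best


class TestSelectClusters:
    def test_root_dominates(self):
        tree, _ = random_tree_and_scores(1)
        scores = {nid: 0.1 for nid in tree.internal_nodes()}
        scores[tree.root] = 100.0
        assert select_clusters(tree, scores) == {tree.root}

    def test_children_kept_on_ties(self):
        # root score equal to descendants' sum → descendants stay (strict >)
        tree, _ = random_tree_and_scores(2)
        scores = {nid: 1.0 for nid in tree.internal_nodes()}
        root = tree.nodes[tree.root]
        below = sum(
            1.0 for nid in tree.internal_nodes() if nid != tree.root
        )
        selected = select_clusters(tree, {**scores, tree.root: 0.0})
        assert tree.root not in selected

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_antichain_oracle(self, seed):
        tree, scores = random_tree_and_scores(seed)
        selected = select_clusters(tree, scores)
        total = sum(scores[nid] for nid in selected)
        assert total == pytest.approx(best_antichain_total(tree, scores))

    def test_selected_nodes_disjoint(self):
        for seed in range(10):
            tree, scores = random_tree_and_scores(seed + 500)
            selected = select_clusters(tree, scores)
            seen = set()
            for nid in selected:
                m = set(tree.nodes[nid].members)
                assert not (m & seen)
                seen |= m

    def test_unscored_node_rejected(self):
        tree, scores = random_tree_and_scores(3)
        scores.pop(tree.root)
        with pytest.raises(KeyError):
            select_clusters(tree, scores)


def record(n, f, c=0.9, cid="Clust0-Sub1"):
    return ClusterRecord(
        cluster_id=cid, coarse_id=0, node_id=1,
        member_sites=[SiteId(f"s{i:03d}", "A", i + 1, "CYS") for i in range(n)],
        member_proteins=[f"s{i:03d}" for i in range(n)],
        C=c, F=f, N=n, S=1.0,
    )


class TestFilterClusters:
    def test_size_and_strict_coherence_thresholds(self):
        records = [record(4, 10.0), record(5, 3.0), record(5, 3.01), record(10, 0.5)]
        kept = filter_clusters(records)
        assert [r.N for r in kept] == [5] and kept[0].F == 3.01

    def test_mixed_fixture_manual_count(self):
        rng = np.random.default_rng(0)
        records = [
            record(int(n), float(f))
            for n, f in zip(rng.integers(2, 12, 10), rng.uniform(0, 8, 10))
        ]
        kept = filter_clusters(records)
        manual = [r for r in records if r.N >= 5 and r.F > 3.0]
        assert kept == manual

    def test_complement_returns_low_F_list(self):
        records = [record(6, 5.0), record(6, 1.0), record(3, 1.0)]
        low = filter_clusters(records, complement=True)
        assert len(low) == 1 and low[0].F == 1.0


class TestExternalKnowledgeOffSwitch:
    def test_all_F_zero_selection_driven_by_C_and_N(self, planted_vectors):
        ms, labels = planted_vectors
        tree = hac_single_cosine(ms)
        scores = score_tree(ms, tree, coherence_fn=None)
        assert all(sc.F == 0.0 for sc in scores.values())
        selected = select_clusters(tree, {nid: sc.S for nid, sc in scores.items()})
        assert selected  # still selects something purely from C and N


class TestReclusterStability:
    def _select_planted(self, ms, labels):
        records = []
        for lab in sorted(set(labels)):
            idx = np.flatnonzero(labels == lab)
            sub = ms.subset(idx)
            tree = hac_single_cosine(sub)
            scores = score_tree(sub, tree)
            selected = select_clusters(tree, {n: s.S for n, s in scores.items()})
            records.extend(build_records(sub, tree, selected, scores, coarse_id=int(lab)))
        return records

    def test_pooling_well_separated_clusters_recovers_both(self):
        ms, labels = gen_vectors(VectorGenSpec(sizes=[20, 20], dim=30, seed=21))
        records = self._select_planted(ms, labels)
        assert len(records) == 2  # each planted cluster selected whole
        report = recluster_stability(records, ms)
        assert report.all_recovered
        assert report.n_singletons == 0
        assert report.n_recovered == 40

    def test_pooling_cluster_with_itself(self):
        ms, labels = gen_vectors(VectorGenSpec(sizes=[20, 20], dim=30, seed=22))
        records = self._select_planted(ms, labels)
        report = recluster_stability([records[0], records[0]], ms)
        assert report.exact_match[records[0].cluster_id]

    def test_accounting_identity(self):
        ms, labels = gen_vectors(
            VectorGenSpec(sizes=[15, 15, 15], dim=20, noise=0.6, seed=23)
        )
        records = self._select_planted(ms, labels)
        report = recluster_stability(records, ms)
        assert (
            report.n_recovered + report.n_changed + report.n_singletons
            == report.original_total
        )
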