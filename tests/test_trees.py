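"""Distances, neighbor joining, bootstrap supports, monophyly."""

import dendropy
import numpy as np
import pytest

from lophopax import synthetic
from lophopax.seqio import AlignmentMatrix, ProteinRecord
from lophopax.trees import (DistanceMatrix, PhyloParams, SaturationError,
                            bootstrap, distance_matrix, monophyly_report,
                            neighbor_joining, to_newick, tree_splits)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _aln(pairs):
    return AlignmentMatrix(records=[ProteinRecord.aligned(i, s) for i, s in pairs])


# ------------------------------------------------- random additive trees --
def random_tree_distances(rng, n_leaves):
    """Random binary tree; returns (leaf labels, distance matrix, true splits).

    Built independently of the NJ code: explicit adjacency graph and BFS
    path lengths.
    """
    labels = [f"t{i:02d}" for i in range(n_leaves)]
    nodes = list(labels)
    adj = {u: [] for u in labels}
    nxt = 0
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        u = f"internal{nxt}"; nxt += 1
        adj[u] = []
        for v in (nodes[i], nodes[j]):
            w = float(rng.uniform(0.1, 1.0))
            adj[u].append((v, w))
            adj[v].append((u, w))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [u]
    w = float(rng.uniform(0.1, 1.0))
    adj[nodes[0]].append((nodes[1], w))
    adj[nodes[1]].append((nodes[0], w))

    def bfs(src):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, wt in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + wt
                    stack.append(y)
        return dist

    d = np.zeros((n_leaves, n_leaves))
    for a, la in enumerate(labels):
        dd = bfs(la)
        for b, lb in enumerate(labels):
            d[a, b] = dd[lb]
    d = (d + d.T) / 2   # exact symmetry despite float summation order

    ref = min(labels)
    splits = set()
    for u in adj:
        for v, _ in adj[u]:
            # side of edge (u, v) containing u
            seen = {u}
            stack = [u]
            while stack:
                x = stack.pop()
                for y, _ in adj[x]:
                    if y != v and y not in seen and not (x == u and y == v):
                        seen.add(y)
                        stack.append(y)
            side = frozenset(l for l in labels if l in seen)
            if ref in side:
                side = frozenset(labels) - side
            if 2 <= len(side) <= n_leaves - 2:
                splits.add(side)
    return labels, d, splits


class TestDistanceMatrix:
    def test_identical_sequences_zero(self):
        dm = distance_matrix(_aln([("a", "ACDE"), ("b", "ACDE"), ("c", "ACDE")]))
        assert np.all(dm.values == 0)

    def test_p_distance_half(self):
        dm = distance_matrix(_aln([("a", "AAAA"), ("b", "AATT"), ("c", "AAAA")]))
        assert dm.values[0, 1] == pytest.approx(0.5)

    def test_gamma_correction_closed_form(self):
        alpha = 0.716
        dm = distance_matrix(
            _aln([("a", "AAAAAAAAAA"), ("b", "AAAAAATTTT"), ("c", "AAAAAAAAAA")]),
            correction="gamma", alpha=alpha)
        p = 0.4
        expect = alpha * ((1 - p) ** (-1 / alpha) - 1)
        assert dm.values[0, 1] == pytest.approx(expect)

    def test_pairwise_deletion(self):
        dm = distance_matrix(_aln([("a", "AA--"), ("b", "AT-C"), ("c", "AAAA")]))
        assert dm.values[0, 1] == pytest.approx(0.5)  # 2 shared columns, 1 mismatch

    def test_saturation_names_pair(self):
        with pytest.raises(SaturationError, match="a.*b"):
            distance_matrix(_aln([("a", "AAAA"), ("b", "TTTT"), ("c", "AAAA")]),
                            correction="gamma")


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float))
        tree = neighbor_joining(dm)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_all_zero_matrix_gives_star_with_zero_lengths(self):
        dm = DistanceMatrix(list("abcd"), np.zeros((4, 4)))
        tree = neighbor_joining(dm)
        for e in tree.preorder_edge_iter():
            assert (e.length or 0) == 0

    def test_recovers_generating_topology_from_additive_matrices(self):
        rng = np.random.default_rng(1234)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            labels, d, true_splits = random_tree_distances(rng, n)
            tree = neighbor_joining(DistanceMatrix(labels, d))
            assert tree_splits(tree) == true_splits

    def test_agrees_with_scikit_bio_on_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(77)
        labels, d, _ = random_tree_distances(rng, 8)
        ours = tree_splits(neighbor_joining(DistanceMatrix(labels, d)))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        ref = min(labels)
        theirs = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if ref in side:
                side = frozenset(labels) - side
            if 2 <= len(side) <= len(labels) - 2:
                theirs.add(side)
        assert ours == theirs

    def test_fewer_than_three_labels_is_error(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_leaf_order_invariance_of_splits(self):
        rng = np.random.default_rng(8)
        labels, d, _ = random_tree_distances(rng, 7)
        s1 = tree_splits(neighbor_joining(DistanceMatrix(labels, d)))
        perm = list(rng.permutation(len(labels)))
        labels2 = [labels[i] for i in perm]
        d2 = d[np.ix_(perm, perm)]
        s2 = tree_splits(neighbor_joining(DistanceMatrix(labels2, d2)))
        assert s1 == s2


class TestBootstrap:
    def _dup_alignment(self):
        rng = np.random.default_rng(55)
        base = ["".join(AA[i] for i in rng.integers(0, 20, 40)) for _ in range(4)]
        pairs = []
        for k, s in enumerate(base):
            pairs.append((f"g{k}a", s))
            pairs.append((f"g{k}b", s))
        return _aln(pairs)

    def test_identical_copies_pair_with_full_support(self):
        aln = self._dup_alignment()
        tree = bootstrap(aln, PhyloParams(n_bootstrap=20, seed=3))
        splits = {}
        leaves = frozenset(f"g{k}{x}" for k in range(4) for x in "ab")
        ref = min(leaves)
        for node in tree.preorder_node_iter():
            if node is tree.seed_node or node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if ref in side:
                side = leaves - side
            splits[side] = node.label
        for k in range(4):
            pair = frozenset({f"g{k}a", f"g{k}b"})
            if ref in pair:
                continue  # normalized away: pair split shows as complement
            assert splits.get(pair) == "100"

    def test_collapse_threshold_zero_keeps_all_edges(self):
        aln = self._dup_alignment()
        t0 = bootstrap(aln, PhyloParams(n_bootstrap=10, seed=3, collapse_threshold=0))
        t1 = neighbor_joining(distance_matrix(aln))
        assert tree_splits(t0) == tree_splits(t1)

    def test_single_replicate_supports_are_0_or_100(self):
        aln = self._dup_alignment()
        tree = bootstrap(aln, PhyloParams(n_bootstrap=1, seed=9, collapse_threshold=0))
        sups = {node.label for node in tree.preorder_node_iter()
                if node.label is not None}
        assert sups <= {"0", "100"}

    def test_fixed_seed_gives_byte_identical_newick(self):
        aln = self._dup_alignment()
        n1 = to_newick(bootstrap(aln, PhyloParams(n_bootstrap=15, seed=4)))
        n2 = to_newick(bootstrap(aln, PhyloParams(n_bootstrap=15, seed=4)))
        assert n1 == n2


class TestMonophyly:
    def test_synthetic_families_all_monophyletic(self):
        recs, truths = synthetic.generate_dataset(
            synthetic.SyntheticConfig(n_per_family=5, mutation_rate=0.03, seed=11))
        aln = synthetic.prd_alignment(recs, truths)
        tree = bootstrap(aln, PhyloParams(n_bootstrap=100, seed=5))
        fams = {t.record_id: t.family for t in truths}
        report = monophyly_report(tree, fams)
        assert len(report) == 6
        assert all(r.is_monophyletic for r in report.values())

    def test_intruder_listed_for_nested_leaf(self):
        nwk = "((p1,(p2,b1)),(b2,(b3,p3)));"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        fams = {"p1": "Pax6", "p2": "Pax6", "p3": "Pax6",
                "b1": "Paxβ", "b2": "Paxβ", "b3": "Paxβ"}
        report = monophyly_report(tree, fams)
        assert not report["Pax6"].is_monophyletic
        assert not report["Paxβ"].is_monophyletic
        assert "b1" in report["Pax6"].intruders or "p3" in report["Paxβ"].intruders

    def test_single_member_family_excluded(self):
        nwk = "((a1,a2),(b1,(c1,a3)));"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        fams = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "c1": "C"}
        report = monophyly_report(tree, fams)
        assert "B" not in report and "C" not in report

    def test_uncalled_leaf_is_error(self):
        nwk = "((a1,a2),(b1,b2),x);"
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        fams = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        with pytest.raises(ValueError, match="x"):
            monophyly_report(tree, fams)
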