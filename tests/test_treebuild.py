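"""Distance, neighbor-joining, rooting and parsimony reconstruction tests."""

import itertools

import numpy as np
import pytest

from lonr import (
    DistanceMatrix,
    LineageTree,
    build_clone_tree,
    fitch_reconstruct,
    hamming_distance,
    hamming_matrix,
    neighbor_joining,
    root_at_germline,
)
from conftest import random_binary_tree


def tree_path_metric(unrooted, leaf_ids):
    """Leaf-to-leaf path lengths in an unrooted tree (independent of NJ)."""
    import networkx as nx

    g = nx.Graph()
    for a, nbrs in unrooted.adjacency.items():
        for b, ln in nbrs.items():
            g.add_edge(a, b, weight=ln)
    out = np.zeros((len(leaf_ids), len(leaf_ids)))
    for i, a in enumerate(leaf_ids):
        lengths = nx.single_source_dijkstra_path_length(g, a)
        for j, b in enumerate(leaf_ids):
            out[i, j] = lengths[b]
    return out


def rooted_leaf_metric(tree):
    """Pairwise leaf path lengths of a rooted LineageTree."""
    import networkx as nx

    g = nx.Graph()
    for nid, node in tree.nodes.items():
        if node.parent is not None:
            g.add_edge(nid, node.parent, weight=node.edge_length)
    leaves = tree.leaves()
    out = np.zeros((len(leaves), len(leaves)))
    for i, a in enumerate(leaves):
        lengths = nx.single_source_dijkstra_path_length(g, a)
        for j, b in enumerate(leaves):
            out[i, j] = lengths[b]
    return leaves, out


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACGT", "ACGT", 0), ("ACGT", "ACGA", 1), ("ACNT", "ACGA", 1), ("AAAA", "TTTT", 4)],
    )
    def test_pairwise(self, a, b, expected):
        assert hamming_distance(a, b) == expected

    def test_matrix_symmetric_zero_diagonal(self):
        m = hamming_matrix({"a": "ACGT", "b": "ACGA", "c": "ACNT"})
        assert np.allclose(m.d, m.d.T)
        assert np.all(np.diag(m.d) == 0)
        assert m.d[0, 1] == 1

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError):
            hamming_matrix({"a": "ACGT", "b": "ACG"})


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        t = neighbor_joining(DistanceMatrix(ids=["a", "b", "c"], d=d))
        (center,) = [n for n in t.adjacency if n not in ("a", "b", "c")]
        assert t.adjacency["a"][center] == pytest.approx((3 + 4 - 5) / 2)
        assert t.adjacency["b"][center] == pytest.approx((3 + 5 - 4) / 2)
        assert t.adjacency["c"][center] == pytest.approx((4 + 5 - 3) / 2)

    def test_all_zero_matrix(self):
        d = np.zeros((4, 4))
        t = neighbor_joining(DistanceMatrix(ids=list("abcd"), d=d))
        metric = tree_path_metric(t, list("abcd"))
        assert np.allclose(metric, 0)

    def test_four_taxon_additive_vs_least_squares_enumeration(self):
        # known tree: ((a:1,b:1):1,(c:1,d:1)); all branch lengths 1
        ids = list("abcd")
        d = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], dtype=float
        )
        t = neighbor_joining(DistanceMatrix(ids=ids, d=d))
        assert np.allclose(tree_path_metric(t, ids), d, atol=1e-9)
        # independent check: of the three unrooted quartet topologies, the
        # least-squares-best must be the ab|cd split NJ found
        best = None
        for split in [("ab", "cd"), ("ac", "bd"), ("ad", "bc")]:
            # fit 5 branch lengths by least squares for this topology
            pairs = list(itertools.combinations(range(4), 2))
            pos = {c: i for i, c in enumerate(ids)}
            rows, y = [], []
            for i, j in pairs:
                row = np.zeros(5)
                row[i] = 1  # leaf branches 0..3, internal branch 4
                row[j] = 1
                same_side = any(
                    ids[i] in side and ids[j] in side for side in split
                )
                if not same_side:
                    row[4] = 1
                rows.append(row)
                y.append(d[i, j])
            x, res, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
            sse = float(np.sum((np.array(rows) @ x - np.array(y)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, split)
        assert best[1] == ("ab", "cd")
        assert best[0] == pytest.approx(0, abs=1e-18)

    @pytest.mark.parametrize("trial", range(25))
    def test_recovers_random_additive_trees(self, trial):
        # a tree metric is realized by a unique tree; recovering the input
        # metric exactly proves topology and branch lengths are recovered
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(4, 9))
        true = random_binary_tree(rng, n)
        leaves, metric = rooted_leaf_metric(true)
        nj = neighbor_joining(DistanceMatrix(ids=leaves, d=metric))
        assert np.allclose(tree_path_metric(nj, leaves), metric, atol=1e-8)

    def test_agrees_with_skbio_on_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(77)
        true = random_binary_tree(rng, 7)
        leaves, metric = rooted_leaf_metric(true)
        metric = (metric + metric.T) / 2  # exact symmetry for both consumers
        nj = neighbor_joining(DistanceMatrix(ids=leaves, d=metric))
        ours = tree_path_metric(nj, leaves)
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        sk_tree = skbio_nj(SkbioDM(metric, ids=leaves))
        theirs = np.array(
            [[sk_tree.find(a).distance(sk_tree.find(b)) for b in leaves] for a in leaves]
        )
        assert np.allclose(ours, theirs, atol=1e-6)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(ids=["a", "b"], d=np.array([[0, 1], [2, 0]]))


class TestRooting:
    def test_three_members_plus_germline(self):
        seqs = {"g": "AAAA", "x": "AAAT", "y": "AATT", "z": "ATTT"}
        nj = neighbor_joining(hamming_matrix(seqs))
        tree = root_at_germline(nj, "g", sequences=seqs)
        assert tree.nodes[tree.root].sequence == "AAAA"
        assert tree.nodes[tree.root].leaf_count == 3
        assert "g" not in tree.nodes

    def test_leaf_count_sum_rule(self):
        seqs = {"g": "AAAA", "x": "AAAT", "y": "AATT", "z": "ATTT", "w": "TTTT"}
        tree = root_at_germline(neighbor_joining(hamming_matrix(seqs)), "g", sequences=seqs)
        for nid, node in tree.nodes.items():
            if node.children:
                assert node.leaf_count == sum(
                    tree.nodes[c].leaf_count for c in node.children
                )
            else:
                assert node.leaf_count == 1

    def test_germline_identical_to_member_kept_as_leaf(self):
        seqs = {"g": "AAAA", "x": "AAAA", "y": "AATT"}
        tree, _ = build_clone_tree(seqs, germline_id="g")
        assert set(tree.leaves()) == {"x", "y"}
        assert tree.nodes[tree.root].sequence == "AAAA"
        assert tree.nodes[tree.root].leaf_count == 2

    def test_missing_germline_rejected(self):
        seqs = {"x": "AAAT", "y": "AATT", "z": "ATTT"}
        nj = neighbor_joining(hamming_matrix(seqs))
        with pytest.raises(ValueError):
            root_at_germline(nj, "g", sequences=seqs)


def brute_force_parsimony(tree, root_state_by_site):
    """Exhaustive minimum substitutions over all internal-state assignments.

    The root state is fixed per site where given (the germline base).
    Tractable only for tiny trees; the independent oracle for the DP.
    """
    internal = [n for n in tree.postorder() if tree.nodes[n].children]
    L = len(next(tree.nodes[l].sequence for l in tree.leaves()))
    total = 0
    for site in range(L):
        leaf_state = {l: tree.nodes[l].sequence[site] for l in tree.leaves()}
        fixed_root = root_state_by_site[site]
        best = None
        free = [n for n in internal if not (n == tree.root and fixed_root in "ACGT")]
        for combo in itertools.product("ACGT", repeat=len(free)):
            state = dict(zip(free, combo))
            if tree.root not in state:
                state[tree.root] = fixed_root
            state.update(leaf_state)
            cost = sum(
                state[nid] != state[tree.nodes[nid].parent]
                for nid in tree.nodes
                if tree.nodes[nid].parent is not None
            )
            best = cost if best is None else min(best, cost)
        total += best
    return total


class TestFitch:
    def test_identical_leaves_zero_score(self):
        t = LineageTree()
        t.add_node("r", sequence=None)
        t.add_node("i", parent="r")
        t.add_node("a", parent="i", sequence="ACGT")
        t.add_node("b", parent="i", sequence="ACGT")
        t.add_node("c", parent="r", sequence="ACGT")
        t.update_leaf_counts()
        t, score = fitch_reconstruct(t)
        assert score == 0
        assert all(t.nodes[n].sequence == "ACGT" for n in t.nodes)

    def test_two_cherries_single_site(self):
        t = LineageTree()
        t.add_node("r")
        t.add_node("u", parent="r")
        t.add_node("v", parent="r")
        for name, parent, seq in [("a", "u", "A"), ("b", "u", "A"), ("c", "v", "T"), ("d", "v", "T")]:
            t.add_node(name, parent=parent, sequence=seq)
        t.update_leaf_counts()
        t, score = fitch_reconstruct(t)
        assert score == 1
        assert t.nodes["u"].sequence == "A"
        assert t.nodes["v"].sequence == "T"

    def test_cherry_tiebreak_prefers_germline_parent_state(self):
        t = LineageTree()
        t.add_node("r", sequence="A")
        t.add_node("i", parent="r")
        t.add_node("a", parent="i", sequence="A")
        t.add_node("b", parent="i", sequence="T")
        t.update_leaf_counts()
        t, score = fitch_reconstruct(t)
        assert score == 1
        assert t.nodes["i"].sequence == "A"

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_exhaustive_minimum(self, trial):
        rng = np.random.default_rng(5000 + trial)
        n_leaves = int(rng.integers(2, 7))
        n_sites = int(rng.integers(1, 5))
        t = random_binary_tree(rng, n_leaves)
        bases = "ACGT"
        for leaf in t.leaves():
            t.nodes[leaf].sequence = "".join(rng.choice(list(bases), size=n_sites))
        root_seq = "".join(rng.choice(list(bases), size=n_sites))
        t.nodes[t.root].sequence = root_seq
        expected = brute_force_parsimony(t, root_seq)
        _, score = fitch_reconstruct(t)
        assert score == expected

    def test_missing_leaf_sequence_rejected(self):
        t = LineageTree()
        t.add_node("r")
        t.add_node("a", parent="r", sequence="A")
        t.add_node("b", parent="r")
        t.update_leaf_counts()
        with pytest.raises(ValueError):
            fitch_reconstruct(t)


class TestNewick:
    def test_round_trip_isomorphic(self):
        seqs = {"g": "AAAA", "x": "AAAT", "y": "AATT", "z": "ATTT", "w": "GTTT"}
        tree, _ = build_clone_tree(seqs, germline_id="g")
        rebuilt = LineageTree.from_newick(
            tree.to_newick(),
            sequences={nid: n.sequence for nid, n in tree.nodes.items()},
        )
        assert set(rebuilt.leaves()) == set(tree.leaves())
        # internal labels (with underscores) must survive so reconstructed
        # sequences re-attach on import
        assert all(n.sequence is not None for n in rebuilt.nodes.values())
        ids_a, metric_a = rooted_leaf_metric(tree)
        ids_b, metric_b = rooted_leaf_metric(rebuilt)
        order = [ids_b.index(i) for i in ids_a]
        assert np.allclose(metric_a, metric_b[np.ix_(order, order)], atol=1e-9)

    def test_polytomy_resolved_to_binary(self):
        tree = LineageTree.from_newick("(a:1,b:1,c:1,d:1)root;")
        for nid, node in tree.nodes.items():
            assert len(node.children) in (0, 2)
        assert set(tree.leaves()) == {"a", "b", "c", "d"}
        # synthetic nodes carry zero-length edges
        synth = [n for n in tree.nodes if n.startswith("_poly")]
        assert synth and all(tree.nodes[s].edge_length == 0 for s in synth)
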