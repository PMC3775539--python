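import numpy as np
import pytest

from lonr import LineageTree, RegionMap


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def toy_tree():
    """Three-mutation toy tree: a root codon CTA, a synonymous change on one
    branch and two non-synonymous changes, with known subtree sizes."""
    t = LineageTree()
    t.add_node("root", sequence="CTA")
    t.add_node("A", parent="root", sequence="ATA")
    t.add_node("B", parent="root", sequence="CTA")
    t.add_node("A1", parent="A", sequence="TTA", multiplicity=30)
    t.add_node("A2", parent="A", sequence="ATA", multiplicity=40)
    t.add_node("B1", parent="B", sequence="CTG", multiplicity=20)
    t.add_node("B2", parent="B", sequence="CTA", multiplicity=10)
    t.update_leaf_counts()
    return t


@pytest.fixture
def single_region_map():
    return RegionMap([("CDR3", 0, 3)])


def random_binary_tree(rng, n_leaves, length_low=0.5, length_high=3.0):
    """Random rooted binary topology with positive branch lengths.

    Returns a LineageTree skeleton (no sequences) built by random joins.
    """
    t = LineageTree()
    # build by successive random pair joins, bottom-up
    import itertools

    counter = itertools.count()
    subtrees = [(f"L{i}", None) for i in range(n_leaves)]
    edges = {}
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        a, b = subtrees[j], subtrees[i]
        nid = f"I{next(counter)}"
        edges[a[0]] = (nid, float(rng.uniform(length_low, length_high)))
        edges[b[0]] = (nid, float(rng.uniform(length_low, length_high)))
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)] + [(nid, None)]
    root_id = subtrees[0][0]
    children = {}
    for child, (parent, ln) in edges.items():
        children.setdefault(parent, []).append((child, ln))

    def attach(nid, parent):
        if parent is None:
            t.add_node(nid)
        for child, ln in children.get(nid, []):
            t.add_node(child, parent=nid, edge_length=ln)
            attach(child, nid)

    attach(root_id, None)
    t.update_leaf_counts()
    return t
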