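"""Lineage-tree construction: distances, neighbor joining, germline rooting
and parsimony reconstruction of ancestral sequences.

Within a clonal group all sequences are equal length by construction (the
truncation window is fixed per group and somatic hypermutation is treated
as indel-free), so no alignment step is needed: pairwise distances are
Hamming counts over determined positions, the topology comes from an
internal neighbor-joining implementation, the tree is rooted at the
germline reference, and internal-node sequences are reconstructed by
minimum-change (Fitch/Sankoff) parsimony with the root pinned to the
germline where it is determined.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

_ALPHABET = "ACGTN"
_ENCODE = {c: i for i, c in enumerate(_ALPHABET)}
_N_CODE = 4
_BIG = np.int32(1 << 20)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 (A,C,G,T -> 0..3; anything else -> 4).

    Degenerate bases other than N are treated as undetermined, like N, and
    are excluded from all mutation counting.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, _N_CODE, dtype=np.uint8)
    for base, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        out[arr == ord(base)] = code
    return out


def decode_sequence(arr: np.ndarray) -> str:
    return "".join(_ALPHABET[int(b)] for b in arr)


# ---------------------------------------------------------------------------
# Distance matrix


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise Hamming distances over determined positions."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")


def hamming_distance(a: str | np.ndarray, b: str | np.ndarray) -> int:
    """Number of positions where both bases are determined (A/C/G/T) and differ."""
    ea = encode_sequence(a) if isinstance(a, str) else a
    eb = encode_sequence(b) if isinstance(b, str) else b
    if ea.shape != eb.shape:
        raise ValueError("sequences have unequal length")
    ok = (ea != _N_CODE) & (eb != _N_CODE)
    return int(np.count_nonzero((ea != eb) & ok))


def hamming_matrix(sequences: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise Hamming distances between equal-length sequences.

    Positions where either sequence is undetermined (N) are skipped.
    """
    ids = list(sequences)
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    enc = [encode_sequence(sequences[i]) for i in ids]
    lengths = {e.shape[0] for e in enc}
    if len(lengths) != 1:
        raise ValueError("sequences have unequal lengths")
    mat = np.stack(enc)
    ok = mat != _N_CODE
    # broadcast pairwise comparison; fine at within-clone scale
    diff = (mat[:, None, :] != mat[None, :, :]) & ok[:, None, :] & ok[None, :, :]
    return DistanceMatrix(ids=ids, d=diff.sum(axis=2).astype(float))


# ---------------------------------------------------------------------------
# Unrooted tree (neighbor joining output)


@dataclass
class UnrootedTree:
    """Unrooted tree as an adjacency map ``node -> {neighbor: branch length}``."""

    adjacency: dict[str, dict[str, float]]
    leaf_ids: list[str]

    def degree(self, node: str) -> int:
        return len(self.adjacency[node])


def neighbor_joining(matrix: DistanceMatrix) -> UnrootedTree:
    """Saitou-Nei neighbor joining on a distance matrix.

    Agglomerates by Q-matrix minimisation; a negative branch length is
    clamped to zero and the deficit moved to the sibling branch so that the
    pair's summed length is preserved.  Ties in Q are broken by the lowest
    (row, column) index pair, which makes the topology deterministic for a
    given input ordering.  One taxon yields a single node, two taxa a
    single edge.
    """
    ids = list(matrix.ids)
    n = len(ids)
    adjacency: dict[str, dict[str, float]] = {i: {} for i in ids}

    def connect(a: str, b: str, length: float) -> None:
        adjacency.setdefault(a, {})[b] = length
        adjacency.setdefault(b, {})[a] = length

    if n == 1:
        return UnrootedTree(adjacency=adjacency, leaf_ids=ids)
    if n == 2:
        connect(ids[0], ids[1], float(matrix.d[0, 1]))
        return UnrootedTree(adjacency=adjacency, leaf_ids=ids)

    d = matrix.d.copy()
    active = list(ids)
    counter = itertools.count()

    while len(active) > 3:
        m = len(active)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new_id = f"_nj{next(counter)}"
        connect(active[i], new_id, float(li))
        connect(active[j], new_id, float(lj))
        du = 0.5 * (d[i, :] + d[j, :] - dij)
        du = np.maximum(du, 0.0)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], du[keep][None, :]])
        d = np.hstack([d, np.append(du[keep], 0.0)[:, None]])
        active = [active[k] for k in keep] + [new_id]

    # final trifurcation: closed-form three-point lengths
    a, b, c = active
    ia, ib, ic = 0, 1, 2
    center = f"_nj{next(counter)}"
    la = 0.5 * (d[ia, ib] + d[ia, ic] - d[ib, ic])
    lb = 0.5 * (d[ia, ib] + d[ib, ic] - d[ia, ic])
    lc = 0.5 * (d[ia, ic] + d[ib, ic] - d[ia, ib])
    connect(a, center, max(float(la), 0.0))
    connect(b, center, max(float(lb), 0.0))
    connect(c, center, max(float(lc), 0.0))
    return UnrootedTree(adjacency=adjacency, leaf_ids=ids)


# ---------------------------------------------------------------------------
# Rooted lineage tree


@dataclass
class TreeNode:
    id: str
    parent: str | None = None
    children: list[str] = field(default_factory=list)
    sequence: str | None = None
    edge_length: float = 0.0
    multiplicity: int = 1
    member_ids: list[str] = field(default_factory=list)
    leaf_count: int = 0


class LineageTree:
    """Rooted tree whose nodes carry nucleotide sequences and cached leaf counts.

    Leaves are observed (possibly collapsed duplicates with a multiplicity);
    internal nodes get sequences from parsimony reconstruction.  The root
    represents the germline/founder and is not itself a counted leaf.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, TreeNode] = {}
        self.root: str | None = None

    # -- construction -----------------------------------------------------

    def add_node(
        self,
        node_id: str,
        parent: str | None = None,
        sequence: str | None = None,
        edge_length: float = 0.0,
        multiplicity: int = 1,
        member_ids: Sequence[str] | None = None,
    ) -> TreeNode:
        if node_id in self.nodes:
            raise ValueError(f"duplicate node id {node_id!r}")
        node = TreeNode(
            id=node_id,
            parent=parent,
            sequence=sequence,
            edge_length=edge_length,
            multiplicity=multiplicity,
            member_ids=list(member_ids) if member_ids else [node_id],
        )
        self.nodes[node_id] = node
        if parent is None:
            if self.root is not None:
                raise ValueError("tree already has a root")
            self.root = node_id
        else:
            self.nodes[parent].children.append(node_id)
        return node

    # -- queries ----------------------------------------------------------

    def is_leaf(self, node_id: str) -> bool:
        return not self.nodes[node_id].children

    def leaves(self) -> list[str]:
        return [n for n in self.postorder() if self.is_leaf(n)]

    def postorder(self) -> list[str]:
        if self.root is None:
            return []
        out: list[str] = []
        stack = [self.root]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(self.nodes[nid].children)
        out.reverse()
        return out

    def preorder(self) -> list[str]:
        return list(reversed(self.postorder()))

    def sibling(self, node_id: str) -> str | None:
        parent = self.nodes[node_id].parent
        if parent is None:
            return None
        sibs = [c for c in self.nodes[parent].children if c != node_id]
        return sibs[0] if len(sibs) == 1 else None

    def update_leaf_counts(self, count_duplicates: bool = True) -> None:
        """Recompute cached leaf counts bottom-up.

        With ``count_duplicates`` (default) a collapsed leaf contributes its
        read multiplicity, so counts reflect sampled reads, not unique
        sequences.
        """
        for nid in self.postorder():
            node = self.nodes[nid]
            if not node.children:
                node.leaf_count = node.multiplicity if count_duplicates else 1
            else:
                node.leaf_count = sum(self.nodes[c].leaf_count for c in node.children)

    def validate(self) -> None:
        if self.root is None:
            raise ValueError("tree has no root")
        seen = set(self.postorder())
        if seen != set(self.nodes):
            raise ValueError("tree is not connected")
        for nid, node in self.nodes.items():
            for c in node.children:
                if self.nodes[c].parent != nid:
                    raise ValueError(f"parent/child mismatch at {nid}/{c}")

    # -- Newick interchange -----------------------------------------------

    def to_newick(self) -> str:
        """Serialize with internal-node labels and branch lengths."""

        def render(nid: str) -> str:
            node = self.nodes[nid]
            if node.children:
                inner = ",".join(render(c) for c in node.children)
                body = f"({inner}){node.id}"
            else:
                body = node.id
            if node.parent is not None:
                body += f":{node.edge_length:.10g}"
            return body

        return render(self.root) + ";"

    @classmethod
    def from_newick(
        cls,
        newick: str,
        sequences: Mapping[str, str] | None = None,
        count_duplicates: bool = True,
    ) -> "LineageTree":
        """Build a lineage tree from a Newick string.

        Polytomies are resolved into left-leaning binary caterpillars with
        zero-length internal edges, so that every mutation event is a
        two-branch comparison; at the synthetic nodes the "sibling" side
        aggregates the remaining children.  Leaf (and labelled internal)
        sequences may be supplied via ``sequences``.
        """
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        tree = cls()
        counter = itertools.count()

        def label_of(dnode) -> str:
            if dnode.taxon is not None and dnode.taxon.label:
                return dnode.taxon.label.replace(" ", "_")
            if dnode.label:
                return dnode.label
            return f"_in{next(counter)}"

        def attach(dnode, parent_id: str | None) -> None:
            nid = label_of(dnode)
            length = float(dnode.edge.length or 0.0)
            seq = sequences.get(nid) if sequences else None
            tree.add_node(nid, parent=parent_id, sequence=seq, edge_length=length)
            children = list(dnode.child_nodes())
            current_parent = nid
            while len(children) > 2:
                # peel one child off; a zero-length synthetic node holds the rest
                attach(children[0], current_parent)
                synth = f"_poly{next(counter)}"
                tree.add_node(synth, parent=current_parent, edge_length=0.0)
                current_parent = synth
                children = children[1:]
            for child in children:
                attach(child, current_parent)

        attach(dtree.seed_node, None)
        tree.update_leaf_counts(count_duplicates=count_duplicates)
        return tree


# ---------------------------------------------------------------------------
# Rooting


def root_at_germline(
    tree: UnrootedTree,
    germline_id: str,
    sequences: Mapping[str, str],
    multiplicity: Mapping[str, int] | None = None,
    member_ids: Mapping[str, Sequence[str]] | None = None,
    count_duplicates: bool = True,
) -> LineageTree:
    """Root an unrooted tree on the edge leading to the germline leaf.

    The germline leaf is removed -- it is the ancestor, not a sampled
    read -- and its attachment node becomes the root, carrying the germline
    sequence.  Leaf counts therefore reflect only sampled descendants.
    """
    if germline_id not in tree.adjacency:
        raise ValueError(f"germline id {germline_id!r} not in tree")
    if tree.degree(germline_id) != 1:
        raise ValueError(f"germline id {germline_id!r} is not a leaf")
    germline_seq = sequences[germline_id]

    (anchor,) = tree.adjacency[germline_id].keys()
    rooted = LineageTree()

    def node_kwargs(nid: str) -> dict:
        return dict(
            sequence=sequences.get(nid),
            multiplicity=multiplicity.get(nid, 1) if multiplicity else 1,
            member_ids=member_ids.get(nid) if member_ids else None,
        )

    def attach(nid: str, parent: str | None, came_from: str | None, length: float) -> None:
        rooted.add_node(nid, parent=parent, edge_length=length, **node_kwargs(nid))
        for nbr, ln in tree.adjacency[nid].items():
            if nbr not in (came_from, germline_id):
                attach(nbr, nid, nid, ln)

    if anchor in tree.leaf_ids:
        # two-taxon tree: germline + one sampled sequence
        root_id = "_root"
        rooted.add_node(root_id, sequence=germline_seq, member_ids=[root_id])
        attach(anchor, root_id, germline_id, tree.adjacency[germline_id][anchor])
    else:
        attach(anchor, None, germline_id, 0.0)
        rooted.nodes[anchor].sequence = germline_seq
    rooted.update_leaf_counts(count_duplicates=count_duplicates)
    rooted.validate()
    return rooted


# ---------------------------------------------------------------------------
# Parsimony reconstruction


def fitch_reconstruct(tree: LineageTree) -> tuple[LineageTree, int]:
    """Reconstruct internal-node sequences by minimum-change parsimony.

    Per site, a bottom-up dynamic programme accumulates for every node the
    minimal number of substitutions needed below it for each nucleotide
    state (unit cost; undetermined leaf bases are free).  The root state is
    pinned to the germline sequence wherever that base is determined.  The
    top-down pass prefers the parent's state among minimal-cost states and
    otherwise takes the alphabetically first, which makes reconstruction
    deterministic.  Returns the tree (modified in place) and the parsimony
    score: the total number of substitutions implied along all edges.
    """
    if tree.root is None:
        raise ValueError("empty tree")
    order = tree.postorder()
    leaves = [n for n in order if tree.is_leaf(n)]
    for nid in leaves:
        if tree.nodes[nid].sequence is None:
            raise ValueError(f"leaf {nid!r} has no sequence")
    lengths = {len(tree.nodes[n].sequence) for n in leaves}
    if len(lengths) != 1:
        raise ValueError("leaf sequences have unequal lengths")
    (L,) = lengths

    cost: dict[str, np.ndarray] = {}
    for nid in order:
        node = tree.nodes[nid]
        if not node.children:
            enc = encode_sequence(node.sequence)
            c = np.zeros((L, 4), dtype=np.int32)
            det = enc != _N_CODE
            c[det, :] = _BIG
            c[det, enc[det]] = 0
            cost[nid] = c
        else:
            c = np.zeros((L, 4), dtype=np.int32)
            for child in node.children:
                cc = cost[child]
                c += np.minimum(cc, cc.min(axis=1, keepdims=True) + 1)
            cost[nid] = c

    root = tree.nodes[tree.root]
    root_cost = cost[tree.root]
    if root.sequence is not None:
        enc_root = encode_sequence(root.sequence)
    else:
        enc_root = np.full(L, _N_CODE, dtype=np.uint8)
    state = np.where(enc_root != _N_CODE, enc_root, root_cost.argmin(axis=1)).astype(np.uint8)
    assigned: dict[str, np.ndarray] = {tree.root: state}
    root.sequence = decode_sequence(state)

    for nid in tree.preorder():
        node = tree.nodes[nid]
        if not node.children:
            continue
        pstate = assigned[nid]
        for child in node.children:
            if tree.is_leaf(child):
                continue
            cc = cost[child]
            switch = np.ones((L, 4), dtype=np.int32)
            switch[np.arange(L), pstate] = 0
            total = cc + switch
            best = total.min(axis=1)
            cstate = total.argmin(axis=1).astype(np.uint8)
            keep_parent = total[np.arange(L), pstate] == best
            cstate[keep_parent] = pstate[keep_parent]
            assigned[child] = cstate
            tree.nodes[child].sequence = decode_sequence(cstate)

    score = 0
    for nid in order:
        node = tree.nodes[nid]
        if node.parent is not None:
            score += hamming_distance(node.sequence, tree.nodes[node.parent].sequence)
    return tree, score


# ---------------------------------------------------------------------------
# High-level builder


def build_clone_tree(
    sequences: Mapping[str, str],
    germline_id: str,
    count_duplicates: bool = True,
    collapse_identical: bool = True,
) -> tuple[LineageTree, int]:
    """Distance matrix -> neighbor joining -> germline rooting -> parsimony.

    ``sequences`` maps read ids (plus the germline id) to equal-length
    nucleotide strings.  Identical member sequences are collapsed into one
    leaf whose multiplicity is the read count (the germline is never
    collapsed into a member), then leaf counts are expanded back so that
    branch imbalance reflects reads rather than unique sequences.  Returns
    the reconstructed tree and its parsimony score.
    """
    if germline_id not in sequences:
        raise ValueError("germline id missing from sequences")
    members = {k: v for k, v in sequences.items() if k != germline_id}
    if not members:
        raise ValueError("no member sequences")

    if collapse_identical:
        by_seq: dict[str, list[str]] = {}
        for sid, seq in members.items():
            by_seq.setdefault(seq.upper(), []).append(sid)
        reps = {ids[0]: seq for seq, ids in by_seq.items()}
        mult = {ids[0]: len(ids) for ids in by_seq.values()}
        mids = {ids[0]: ids for ids in by_seq.values()}
    else:
        reps = dict(members)
        mult = {k: 1 for k in members}
        mids = {k: [k] for k in members}

    pool = dict(reps)
    pool[germline_id] = sequences[germline_id]
    if len(pool) == 2:
        (rep_id,) = reps.keys()
        unrooted = UnrootedTree(
            adjacency={
                rep_id: {germline_id: float(hamming_distance(pool[rep_id], pool[germline_id]))},
                germline_id: {rep_id: float(hamming_distance(pool[rep_id], pool[germline_id]))},
            },
            leaf_ids=[rep_id, germline_id],
        )
    else:
        unrooted = neighbor_joining(hamming_matrix(pool))
    rooted = root_at_germline(
        unrooted,
        germline_id,
        sequences=pool,
        multiplicity=mult,
        member_ids=mids,
        count_duplicates=count_duplicates,
    )
    rooted, score = fitch_reconstruct(rooted)
    rooted.update_leaf_counts(count_duplicates=count_duplicates)
    return rooted, score
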