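"""Germline V/J assignment, clonal grouping, truncation and clone parsing.

Somatic hypermutation essentially never inserts or deletes nucleotides, so
a rearranged read is modelled as an ungapped V segment, an unknowable
junction, and an ungapped J segment.  Assignment slides every germline
gene along the read without gaps and keeps the placement maximising the
fraction of matching positions; reads matching both segments above a
threshold are grouped by (V gene, J gene, V-J distance) -- members of one
clone must share all three -- and truncated to a fixed analysis window:
the last 159 nt of the aligned V, the junction, and the first 20 nt of
the aligned J.  A group's tree is finally parsed into clones by cutting
branches that carry more than a cutoff number of mutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from lonr.events import RegionMap
from lonr.treebuild import LineageTree, encode_sequence, hamming_distance

logger = logging.getLogger(__name__)

V_TAIL_LENGTH = 159
J_HEAD_LENGTH = 20


@dataclass(frozen=True)
class GermlineGene:
    """One germline gene segment with optional region annotations.

    ``region_map`` lists (label, start, end) half-open intervals in gene
    coordinates (V genes only; e.g. CDR2/FWR3/CDR3 boundaries).
    """

    name: str
    segment: str
    sequence: str
    region_map: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.segment not in ("V", "J"):
            raise ValueError("segment must be 'V' or 'J'")
        if not self.sequence:
            raise ValueError("empty gene sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        ivs = tuple((str(l), int(s), int(e)) for l, s, e in self.region_map)
        for label, s, e in ivs:
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(f"interval {label} outside gene bounds")
        for a in range(len(ivs)):
            for b in range(a + 1, len(ivs)):
                if ivs[a][1] < ivs[b][2] and ivs[b][1] < ivs[a][2]:
                    raise ValueError("gene region intervals overlap")
        object.__setattr__(self, "region_map", ivs)


@dataclass
class GermlineAssignment:
    """Best-matching V and J placement for one read.

    Read coordinates are 0-based: ``v_end_pos`` is the index of the last
    aligned V nucleotide and ``j_start_pos`` the first aligned J
    nucleotide, so ``vj_distance = j_start_pos - v_end_pos - 1``.
    ``v_gene_end``/``j_gene_start`` are the matching gene coordinates.
    """

    sequence_id: str
    v_gene: str
    j_gene: str
    v_match_fraction: float
    j_match_fraction: float
    v_start_pos: int
    v_end_pos: int
    j_start_pos: int
    j_end_pos: int
    v_gene_end: int
    j_gene_start: int

    @property
    def vj_distance(self) -> int:
        return self.j_start_pos - self.v_end_pos - 1


class AssignmentError(ValueError):
    """Raised when no valid germline placement exists for a read."""


def _best_placement(
    read: np.ndarray,
    gene: np.ndarray,
    min_overlap: int,
    first_allowed: int = 0,
) -> tuple[float, int, int] | None:
    """Best ungapped placement of ``gene`` against ``read``.

    Considers every offset whose overlap with the read (restricted to
    positions >= ``first_allowed``) spans at least ``min_overlap``
    positions.  The score is matches / compared positions, comparing only
    positions where both bases are determined.  Returns (fraction,
    read_start, gene_start) of the best placement; ties favour the
    smallest offset.  None when no placement is feasible.
    """
    L, G = read.size, gene.size
    best: tuple[float, int, int] | None = None
    for offset in range(first_allowed - G + min_overlap, L - min_overlap + 1):
        rs = max(offset, first_allowed)
        re = min(offset + G, L)
        if re - rs < min_overlap:
            continue
        gs = rs - offset
        r = read[rs:re]
        g = gene[gs : gs + (re - rs)]
        ok = (r != 4) & (g != 4)
        compared = int(ok.sum())
        if compared == 0:
            continue
        frac = float(((r == g) & ok).sum()) / compared
        if best is None or frac > best[0] + 1e-12:
            best = (frac, rs, gs)
    return best


def assign_germline(
    sequence: str,
    library: Sequence[GermlineGene],
    sequence_id: str = "read",
    min_overlap_v: int = 60,
    min_overlap_j: int = 12,
) -> GermlineAssignment:
    """Find the V gene, J gene and V-J distance maximising the match fraction.

    Every germline V is slid ungapped along the read and the placement
    with the highest fraction of non-mutated positions wins; the J search
    is then constrained to start strictly after the V end.  Ties are
    broken by library order (first gene wins), then by smaller offset.
    """
    vs = [g for g in library if g.segment == "V"]
    js = [g for g in library if g.segment == "J"]
    if not vs or not js:
        raise ValueError("library must contain at least one V and one J gene")
    read = encode_sequence(sequence)
    if read.size < min_overlap_v:
        raise AssignmentError(f"{sequence_id}: read shorter than minimum V overlap")

    best_v = None
    for gene in vs:
        hit = _best_placement(read, encode_sequence(gene.sequence), min_overlap_v)
        if hit and (best_v is None or hit[0] > best_v[1][0] + 1e-12):
            best_v = (gene, hit)
    if best_v is None:
        raise AssignmentError(f"{sequence_id}: no feasible V placement")
    v_gene, (v_frac, v_rs, v_gs) = best_v
    v_genc = encode_sequence(v_gene.sequence)
    v_re = min(v_rs - v_gs + v_genc.size, read.size)  # one past last aligned V position

    best_j = None
    for gene in js:
        hit = _best_placement(read, encode_sequence(gene.sequence), min_overlap_j, first_allowed=v_re)
        if hit and (best_j is None or hit[0] > best_j[1][0] + 1e-12):
            best_j = (gene, hit)
    if best_j is None:
        raise AssignmentError(f"{sequence_id}: no feasible J placement after the V segment")
    j_gene, (j_frac, j_rs, j_gs) = best_j
    j_genc = encode_sequence(j_gene.sequence)
    j_re = min(j_rs - j_gs + j_genc.size, read.size)

    return GermlineAssignment(
        sequence_id=sequence_id,
        v_gene=v_gene.name,
        j_gene=j_gene.name,
        v_match_fraction=v_frac,
        j_match_fraction=j_frac,
        v_start_pos=v_rs,
        v_end_pos=v_re - 1,
        j_start_pos=j_rs,
        j_end_pos=j_re - 1,
        v_gene_end=v_gs + (v_re - v_rs) - 1,
        j_gene_start=j_gs,
    )


def filter_assignments(
    assignments: Iterable[GermlineAssignment], threshold: float = 0.5
) -> list[GermlineAssignment]:
    """Keep assignments matching strictly above ``threshold`` in both segments."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    return [
        a
        for a in assignments
        if a.v_match_fraction > threshold and a.j_match_fraction > threshold
    ]


@dataclass
class CloneGroup:
    """Reads sharing (V gene, J gene, V-J distance), truncated to the
    analysis window, plus the artificial germline reference for the group.

    The reference is the germline V tail + an all-N junction (the true
    junction is unknowable from germline) + the germline J head; N
    positions are excluded from all mutation counting.  ``region_map``
    labels the truncated frame, with the junction and J included in CDR3.
    """

    v_gene: str
    j_gene: str
    vj_distance: int
    members: dict[str, str]
    germline_reference: str
    region_map: RegionMap

    @property
    def member_length(self) -> int:
        return V_TAIL_LENGTH + self.vj_distance + J_HEAD_LENGTH


@dataclass
class DropoutReport:
    """Reads excluded during grouping, keyed by reason."""

    too_short: list[str] = field(default_factory=list)
    partial_v: list[str] = field(default_factory=list)
    partial_j: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.too_short) + len(self.partial_v) + len(self.partial_j)


def _truncated_region_map(v_gene: GermlineGene, vj_distance: int) -> RegionMap:
    """Map the V gene's region annotations onto the truncated frame and
    extend/append CDR3 over the junction + J head."""
    tail_start = len(v_gene.sequence) - V_TAIL_LENGTH
    total = V_TAIL_LENGTH + vj_distance + J_HEAD_LENGTH
    intervals: list[tuple[str, int, int]] = []
    for label, s, e in v_gene.region_map:
        s2, e2 = max(s, tail_start) - tail_start, min(e, len(v_gene.sequence)) - tail_start
        if e2 > s2:
            intervals.append((label, s2, e2))
    merged = False
    for i, (label, s, e) in enumerate(intervals):
        if label == "CDR3" and e == V_TAIL_LENGTH:
            intervals[i] = (label, s, total)
            merged = True
    if not merged:
        intervals.append(("CDR3", V_TAIL_LENGTH, total))
    return RegionMap(intervals)


def group_and_truncate(
    assignments: Iterable[GermlineAssignment],
    reads: Mapping[str, str],
    library: Sequence[GermlineGene],
) -> tuple[list[CloneGroup], DropoutReport]:
    """Cluster filtered reads by (V, J, V-J distance) and truncate each to
    the analysis window.

    A read is kept only if its V alignment reaches the 3' end of the
    germline V and covers at least 159 nt, and its J alignment starts at
    the germline J 5' end and covers at least 20 nt; anything else goes to
    the dropout report.  Member sequences of one group all have length
    159 + distance + 20.
    """
    genes = {g.name: g for g in library}
    groups: dict[tuple[str, str, int], CloneGroup] = {}
    dropped = DropoutReport()
    for a in assignments:
        v = genes[a.v_gene]
        j = genes[a.j_gene]
        v_len_aligned = a.v_end_pos - a.v_start_pos + 1
        j_len_aligned = a.j_end_pos - a.j_start_pos + 1
        if a.v_gene_end != len(v.sequence) - 1 or v_len_aligned < V_TAIL_LENGTH:
            dropped.partial_v.append(a.sequence_id)
            continue
        if a.j_gene_start != 0 or j_len_aligned < J_HEAD_LENGTH:
            dropped.partial_j.append(a.sequence_id)
            continue
        read = reads[a.sequence_id].upper()
        start = a.v_end_pos - V_TAIL_LENGTH + 1
        end = a.j_start_pos + J_HEAD_LENGTH
        if start < 0 or end > len(read):
            dropped.too_short.append(a.sequence_id)
            continue
        key = (a.v_gene, a.j_gene, a.vj_distance)
        if key not in groups:
            reference = (
                v.sequence[-V_TAIL_LENGTH:]
                + "N" * a.vj_distance
                + j.sequence[:J_HEAD_LENGTH]
            )
            groups[key] = CloneGroup(
                v_gene=a.v_gene,
                j_gene=a.j_gene,
                vj_distance=a.vj_distance,
                members={},
                germline_reference=reference,
                region_map=_truncated_region_map(v, a.vj_distance),
            )
        groups[key].members[a.sequence_id] = read[start:end]
    if dropped.n_dropped:
        logger.warning("dropped %d reads during grouping", dropped.n_dropped)
    return list(groups.values()), dropped


def partition_into_clones(
    group: CloneGroup, tree: LineageTree, cutoff: int = 4
) -> list[list[str]]:
    """Parse a group's tree into clones with a mutation-distance cutoff.

    Every tree edge whose endpoint sequences differ at more than ``cutoff``
    positions is cut; each connected component of the remaining forest is
    one clone, reported as the read ids of its leaves (collapsed duplicate
    leaves expand back to all their reads).  Singleton clones are allowed.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    tree.validate()
    leaf_members = {
        nid: tree.nodes[nid].member_ids for nid in tree.nodes if tree.is_leaf(nid)
    }
    covered = {m for ids in leaf_members.values() for m in ids}
    if covered != set(group.members):
        raise ValueError("tree leaves do not match the group's members")

    parent_of: dict[str, str] = {}
    for nid, node in tree.nodes.items():
        if node.parent is None:
            continue
        n_mut = hamming_distance(node.sequence, tree.nodes[node.parent].sequence)
        if n_mut <= cutoff:
            parent_of[nid] = node.parent

    def find(nid: str) -> str:
        while nid in parent_of:
            nid = parent_of[nid]
        return nid

    components: dict[str, list[str]] = {}
    for leaf in sorted(leaf_members):
        components.setdefault(find(leaf), []).extend(leaf_members[leaf])
    return [components[k] for k in sorted(components)]
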