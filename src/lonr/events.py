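"""Per-mutation LONR scoring.

Every internal node of a reconstructed lineage tree (including the
germline root) is a two-branch comparison: if at some position exactly one
of the two children differs from the node, that substitution is a mutation
event and its Log Offspring Number Ratio is

    LONR = ln( leaves under the mutated child / leaves under the sibling )

A positive LONR means the mutated lineage left more sampled descendants
than its un-mutated sister lineage.  Each event is classified synonymous
(S) or non-synonymous (NS) on the containing codon relative to the direct
ancestor, and mapped to a sequence region (CDR2/FWR3/CDR3/other).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from lonr.treebuild import LineageTree

logger = logging.getLogger(__name__)

_VALID = set("ACGT")


@dataclass(frozen=True)
class RegionMap:
    """Non-overlapping half-open ``(label, start, end)`` intervals on the
    truncated-sequence frame; positions outside every interval are 'other'."""

    intervals: tuple[tuple[str, int, int], ...]

    def __init__(self, intervals: Iterable[Sequence]) -> None:
        ivs = tuple((str(l), int(s), int(e)) for l, s, e in intervals)
        for label, s, e in ivs:
            if s < 0 or e <= s:
                raise ValueError(f"bad interval {label}: [{s}, {e})")
        for a in range(len(ivs)):
            for b in range(a + 1, len(ivs)):
                _, s1, e1 = ivs[a]
                _, s2, e2 = ivs[b]
                if s1 < e2 and s2 < e1:
                    raise ValueError("region intervals overlap")
        object.__setattr__(self, "intervals", ivs)

    def label(self, position: int) -> str:
        for label, s, e in self.intervals:
            if s <= position < e:
                return label
        return "other"

    def labels(self) -> list[str]:
        return [l for l, _, _ in self.intervals]


def map_position_to_region(position: int, region_map: RegionMap) -> str:
    """Region label of a 0-based position (half-open intervals; else 'other')."""
    return region_map.label(position)


def classify_mutation(from_codon: str, to_codon: str) -> str:
    """'S' if the two codons translate to the same amino acid, else 'NS'.

    Stops translate to '*', so any change creating or destroying a stop is
    non-synonymous.  Codons containing undetermined bases are unclassifiable.
    """
    fc, tc = from_codon.upper(), to_codon.upper()
    if len(fc) != 3 or len(tc) != 3:
        raise ValueError("codons must be 3 nt")
    if not (set(fc) <= _VALID and set(tc) <= _VALID):
        raise ValueError(f"codon with undetermined base: {fc}->{tc}")
    if fc == tc:
        raise ValueError("codons do not differ")
    return "S" if str(Seq(fc).translate()) == str(Seq(tc).translate()) else "NS"


@dataclass
class MutationEvent:
    """One nucleotide substitution on one branch of a lineage tree."""

    clone_id: str
    node_id: str
    position: int
    from_base: str
    to_base: str
    from_codon: str
    to_codon: str
    mutation_class: str
    region: str
    n_mut: int
    n_sib: int
    lonr: float


def enumerate_mutation_events(
    tree: LineageTree,
    region_map: RegionMap,
    clone_id: str = "clone",
    frame_offset: int = 0,
) -> list[MutationEvent]:
    """Emit one event per (internal node, position) where exactly one child
    differs from the node's own sequence.

    If both children differ from the parent at the same position, neither
    has an un-mutated sibling and no event is emitted there.  Co-occurring
    substitutions in one codon on one branch are classified independently,
    each substituted alone into the ancestral codon.  Positions whose frame
    codon contains an undetermined base are skipped (logged), as are
    positions where the parent or either child is undetermined.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    events: list[MutationEvent] = []
    skipped = 0
    for nid in tree.preorder():
        node = tree.nodes[nid]
        if len(node.children) != 2:
            continue
        if node.sequence is None:
            raise ValueError(f"node {nid!r} has no sequence")
        parent_seq = node.sequence.upper()
        c1, c2 = (tree.nodes[c] for c in node.children)
        if c1.sequence is None or c2.sequence is None:
            raise ValueError(f"child of {nid!r} has no sequence")
        s1, s2 = c1.sequence.upper(), c2.sequence.upper()
        L = len(parent_seq)
        for pos in range(L):
            p, b1, b2 = parent_seq[pos], s1[pos], s2[pos]
            if p not in _VALID or b1 not in _VALID or b2 not in _VALID:
                continue
            d1, d2 = b1 != p, b2 != p
            if d1 == d2:
                continue
            child, sib = (c1, c2) if d1 else (c2, c1)
            to_base = b1 if d1 else b2
            if pos < frame_offset:
                skipped += 1
                continue
            codon_start = frame_offset + 3 * ((pos - frame_offset) // 3)
            if codon_start + 3 > L:
                skipped += 1
                continue
            from_codon = parent_seq[codon_start : codon_start + 3]
            if not set(from_codon) <= _VALID:
                skipped += 1
                continue
            k = pos - codon_start
            to_codon = from_codon[:k] + to_base + from_codon[k + 1 :]
            events.append(
                MutationEvent(
                    clone_id=clone_id,
                    node_id=child.id,
                    position=pos,
                    from_base=p,
                    to_base=to_base,
                    from_codon=from_codon,
                    to_codon=to_codon,
                    mutation_class=classify_mutation(from_codon, to_codon),
                    region=region_map.label(pos),
                    n_mut=child.leaf_count,
                    n_sib=sib.leaf_count,
                    lonr=math.log(child.leaf_count / sib.leaf_count),
                )
            )
    if skipped:
        logger.info("%s: skipped %d events with unclassifiable codons", clone_id, skipped)
    return events


_EVENT_COLUMNS = [
    "clone_id",
    "node_id",
    "position",
    "from_base",
    "to_base",
    "from_codon",
    "to_codon",
    "mutation_class",
    "region",
    "n_mut",
    "n_sib",
    "lonr",
]


def events_to_frame(events: Iterable[MutationEvent]) -> pd.DataFrame:
    """Tabulate mutation events (one row per event, stable column order)."""
    rows = [[getattr(e, c) for c in _EVENT_COLUMNS] for e in events]
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)
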