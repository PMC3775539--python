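"""File formats, run configuration and the end-to-end pipeline.

FASTA in, TSV/JSON out.  The pipeline chains germline assignment ->
grouping/truncation -> per-group tree -> clone parsing -> per-clone tree
and mutation events -> region selection report, and writes a manifest
reconciling record counts at every stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO

from lonr import __version__ as _version
from lonr.events import enumerate_mutation_events, events_to_frame
from lonr.germline import (
    AssignmentError,
    GermlineGene,
    assign_germline,
    filter_assignments,
    group_and_truncate,
    partition_into_clones,
)
from lonr.stats import region_report
from lonr.treebuild import build_clone_tree

logger = logging.getLogger(__name__)

GERMLINE_ID = "germline"


def read_fasta(path: str | Path) -> dict[str, str]:
    """Order-preserving id -> uppercase sequence mapping.

    Duplicate ids are an error (the id is named); malformed records raise.
    """
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValueError(f"duplicate sequence id {record.id!r} in {path}")
        out[record.id] = str(record.seq).upper()
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n{seq}\n")


def read_region_config(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """YAML/JSON mapping each V gene name to its region intervals.

    Expected shape::

        V1:
          - [CDR2, 111, 168]
          - [FWR3, 168, 282]
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"region config {path} must map gene names to interval lists")
    return {
        str(gene): [(str(l), int(s), int(e)) for l, s, e in intervals]
        for gene, intervals in raw.items()
    }


def load_germline_library(
    v_fasta: str | Path, j_fasta: str | Path, regions: str | Path | None = None
) -> list[GermlineGene]:
    """Build a germline library from V and J FASTA files plus a region config."""
    region_cfg = read_region_config(regions) if regions else {}
    library = [
        GermlineGene(name=n, segment="V", sequence=s, region_map=region_cfg.get(n, ()))
        for n, s in read_fasta(v_fasta).items()
    ]
    library += [
        GermlineGene(name=n, segment="J", sequence=s)
        for n, s in read_fasta(j_fasta).items()
    ]
    return library


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    """TSV with a header line, stable column order and 6-significant-digit floats."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    reads_fasta: str
    v_fasta: str
    j_fasta: str
    regions: str | None = None
    out_dir: str = "lonr_out"
    min_match: float = 0.5
    clone_cutoff: int = 4
    min_mutations_per_tree: int = 10
    significant_tree_p: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_match <= 1:
            raise ValueError("min_match must be in [0, 1]")
        if self.clone_cutoff < 0 or self.min_mutations_per_tree < 0:
            raise ValueError("thresholds must be >= 0")


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write TSV reports plus a JSON manifest.

    Returns the manifest dict.  Stages: assign -> filter -> group/truncate
    -> per-group tree -> clone parsing -> per-clone tree + mutation events
    (clones below ``min_mutations_per_tree`` substitutions are skipped and
    counted) -> pooled region report and significant-trees-only report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reads = read_fasta(config.reads_fasta)
    library = load_germline_library(config.v_fasta, config.j_fasta, config.regions)

    assignments, failed = [], []
    for sid, seq in reads.items():
        try:
            assignments.append(assign_germline(seq, library, sequence_id=sid))
        except AssignmentError as exc:
            logger.warning("assignment failed: %s", exc)
            failed.append(sid)
    kept = filter_assignments(assignments, config.min_match)
    groups, dropped = group_and_truncate(kept, reads, library)

    assignment_rows = pd.DataFrame(
        [
            {
                "sequence_id": a.sequence_id,
                "v_gene": a.v_gene,
                "j_gene": a.j_gene,
                "v_match_fraction": a.v_match_fraction,
                "j_match_fraction": a.j_match_fraction,
                "vj_distance": a.vj_distance,
            }
            for a in assignments
        ]
    )
    write_tsv(assignment_rows, out / "assignments.tsv")

    all_events = []
    n_clones = n_clones_skipped = 0
    for group in groups:
        label = f"{group.v_gene}_{group.j_gene}_{group.vj_distance}"
        write_fasta(group.members, out / f"group_{label}.fasta")
        if len(group.members) < 2:
            clones = [list(group.members)]
        else:
            sequences = dict(group.members)
            sequences[GERMLINE_ID] = group.germline_reference
            tree, _ = build_clone_tree(sequences, germline_id=GERMLINE_ID)
            clones = partition_into_clones(group, tree, config.clone_cutoff)
        for ci, clone in enumerate(clones):
            if len(clone) < 2:
                n_clones_skipped += 1
                continue
            clone_seqs = {sid: group.members[sid] for sid in clone}
            clone_seqs[GERMLINE_ID] = group.germline_reference
            clone_tree, score = build_clone_tree(clone_seqs, germline_id=GERMLINE_ID)
            if score < config.min_mutations_per_tree:
                n_clones_skipped += 1
                continue
            clone_id = f"{label}_clone{ci}"
            n_clones += 1
            all_events.extend(
                enumerate_mutation_events(clone_tree, group.region_map, clone_id=clone_id)
            )
            with open(out / f"{clone_id}.nwk", "w") as fh:
                fh.write(clone_tree.to_newick() + "\n")

    events_frame = events_to_frame(all_events)
    write_tsv(events_frame, out / "events.tsv")
    report = region_report(events_frame)
    write_tsv(report, out / "report.tsv")
    sig_report = region_report(events_frame, significant_tree_p=config.significant_tree_p)
    write_tsv(sig_report, out / "report_significant_trees.tsv")

    n_grouped = sum(len(g.members) for g in groups)
    manifest = {
        "version": _version,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "counts": {
            "reads_in": len(reads),
            "assignment_failed": len(failed),
            "filtered_out": len(assignments) - len(kept),
            "dropped_in_grouping": dropped.n_dropped,
            "grouped_reads": n_grouped,
            "groups": len(groups),
            "clones_analyzed": n_clones,
            "clones_skipped": n_clones_skipped,
            "mutation_events": len(all_events),
        },
    }
    counts = manifest["counts"]
    assert counts["reads_in"] == (
        counts["assignment_failed"]
        + counts["filtered_out"]
        + counts["dropped_in_grouping"]
        + counts["grouped_reads"]
    ), "record-count reconciliation failed"
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
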