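"""Forward-time neutral (and optionally selective) clonal-expansion simulator.

The simulator emulates germinal-center-like expansion of a single clone: a
random founder sequence divides with a constant number of offspring per
cell per generation; every child draws a Poisson number of substitutions
in each of two sequence regions with region-specific mean rates, positions
uniform within the region and the new base uniform over the three
alternatives (no transition/transversion bias, no indels, no hotspots).
Sampling mimics amplification bias: the descendants of one randomly chosen
third-generation cell are sampled with an elevated weight.

The neutral version (no fitness differences) calibrates the false-positive
rate of the NS-vs-S LONR test; a selective mode gives cells carrying at
least one non-synonymous change in a designated region a larger mean
offspring number, which is what the LONR statistic is designed to detect.

The same module provides a synthetic germline V/J library generator so the
germline-assignment pipeline can be exercised without any external
database.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from lonr.events import RegionMap, enumerate_mutation_events, events_to_frame
from lonr.germline import GermlineGene
from lonr.stats import welch_t_test
from lonr.treebuild import build_clone_tree, decode_sequence

logger = logging.getLogger(__name__)

_MAX_GENERATIONS_GUARD = 14


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one clonal-expansion run.

    Defaults reproduce the neutral calibration setup: a 348-nt founder,
    two offspring per cell, two equal-length regions with mean mutation
    rates 0.5 and 1.0 substitutions per sequence per generation, ten
    generations (1024 final cells, ~15 mutations per sequence), 300 cells
    sampled with a factor-2 weight on the descendants of one random
    third-generation cell.
    """

    founder_length: int = 348
    offspring_per_cell: int = 2
    region_boundary: int = 174
    region_mutation_rates: tuple[float, float] = (0.5, 1.0)
    generations: int = 10
    sample_size: int = 300
    bias_generation: int = 3
    bias_factor: float = 2.0
    selection_region: int | None = None
    delta_mu: float = 0.0
    per_site: bool = False
    allow_large: bool = False

    def __post_init__(self) -> None:
        if self.founder_length % 3 != 0:
            raise ValueError("founder_length must be a codon multiple")
        if not 0 < self.region_boundary < self.founder_length:
            raise ValueError("region_boundary out of range")
        if any(r < 0 for r in self.region_mutation_rates):
            raise ValueError("mutation rates must be >= 0")
        if self.bias_factor <= 0:
            raise ValueError("bias_factor must be > 0")
        if self.generations > _MAX_GENERATIONS_GUARD and not self.allow_large:
            raise ValueError(
                f"generations > {_MAX_GENERATIONS_GUARD} is intractable by default; "
                "set allow_large=True to override"
            )
        if self.generations < self.bias_generation and self.bias_factor != 1.0:
            raise ValueError("bias_generation beyond the last generation")
        if self.selection_region is not None and self.selection_region not in (0, 1):
            raise ValueError("selection_region must be 0 or 1")
        if self.delta_mu != 0.0 and self.selection_region is None:
            raise ValueError("delta_mu requires a selection_region")
        if self.delta_mu < -self.offspring_per_cell:
            raise ValueError("delta_mu would make mean offspring negative")

    @property
    def region_bounds(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (0, self.region_boundary), (self.region_boundary, self.founder_length)

    @property
    def region_map(self) -> RegionMap:
        return RegionMap(
            [
                ("R1", 0, self.region_boundary),
                ("R2", self.region_boundary, self.founder_length),
            ]
        )


@dataclass
class SimulatedLineage:
    """Complete genealogy of one simulated expansion.

    ``sequences`` holds every cell's sequence (uint8-encoded rows, in birth
    order), ``parents`` the global parent index (-1 for the founder),
    ``generation`` each cell's generation index (founder = 0), and
    ``mutation_log`` one (cell, position, from, to) row per substitution
    actually applied.
    """

    config: SimulationConfig
    sequences: np.ndarray
    parents: np.ndarray
    generation: np.ndarray
    mutation_log: pd.DataFrame

    @property
    def founder(self) -> str:
        return decode_sequence(self.sequences[0])

    @property
    def final_indices(self) -> np.ndarray:
        return np.flatnonzero(self.generation == self.generation.max())

    def cell_sequence(self, index: int) -> str:
        return decode_sequence(self.sequences[index])


# codon -> amino-acid lookup over index 16*b0 + 4*b1 + b2
def _codon_table() -> np.ndarray:
    aa = np.empty(64, dtype=np.uint8)
    for i in range(64):
        codon = "".join("ACGT"[(i >> k) & 3] for k in (4, 2, 0))
        aa[i] = ord(str(Seq(codon).translate()))
    return aa


_AA = _codon_table()


def _translate_codons(block: np.ndarray) -> np.ndarray:
    """Amino-acid codes for a (cells, 3k) uint8 base block."""
    c = block.reshape(block.shape[0], -1, 3).astype(np.int64)
    return _AA[16 * c[:, :, 0] + 4 * c[:, :, 1] + c[:, :, 2]]


def _mutate_block(
    seqs: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    log_rows: list,
    first_index: int,
) -> None:
    """Apply per-region random substitutions to a block of child sequences in place."""
    n = seqs.shape[0]
    for (start, end), rate in zip(config.region_bounds, config.region_mutation_rates):
        width = end - start
        if config.per_site:
            hits = rng.random((n, width)) < rate / width
            rows, cols = np.nonzero(hits)
            cols = cols + start
        else:
            counts = rng.poisson(rate, size=n)
            total = int(counts.sum())
            rows = np.repeat(np.arange(n), counts)
            cols = rng.integers(start, end, size=total)
        if rows.size == 0:
            continue
        old = seqs[rows, cols]
        new = (old + rng.integers(1, 4, size=rows.size).astype(np.uint8)) % 4
        seqs[rows, cols] = new  # repeated draws on one site collapse to the last
        log_rows.append(
            np.column_stack([rows + first_index, cols, old, seqs[rows, cols]])
        )


def _offspring_counts(
    seqs: np.ndarray,
    founder: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Offspring number per cell; selected NS-carriers get mean mu + delta_mu."""
    n = seqs.shape[0]
    base = np.full(n, config.offspring_per_cell, dtype=np.int64)
    if config.selection_region is None or config.delta_mu == 0.0:
        return base
    start, end = config.region_bounds[config.selection_region]
    start = 3 * ((start + 2) // 3)  # whole codons inside the region
    end = 3 * (end // 3)
    if end <= start:
        return base
    carrier = np.any(
        _translate_codons(seqs[:, start:end]) != _translate_codons(founder[None, start:end]),
        axis=1,
    )
    mean = config.offspring_per_cell + config.delta_mu
    lo = int(math.floor(mean))
    frac = mean - lo
    sel = base[carrier]
    sel = lo + (rng.random(sel.size) < frac).astype(np.int64)
    base[carrier] = sel
    return base


def _simulate(config: SimulationConfig, rng: np.random.Generator) -> SimulatedLineage:
    L = config.founder_length
    founder = rng.integers(0, 4, size=L, dtype=np.uint8)
    blocks = [founder[None, :].copy()]
    parents = [np.array([-1], dtype=np.int64)]
    generation = [np.array([0], dtype=np.int64)]
    log_rows: list[np.ndarray] = []

    first_of_gen = 0
    current = blocks[0]
    current_first = 0
    for gen in range(1, config.generations + 1):
        counts = _offspring_counts(current, founder, config, rng)
        parent_idx = np.repeat(np.arange(current.shape[0]) + current_first, counts)
        children = np.repeat(current, counts, axis=0)
        next_first = current_first + current.shape[0]
        _mutate_block(children, config, rng, log_rows, next_first)
        blocks.append(children)
        parents.append(parent_idx)
        generation.append(np.full(children.shape[0], gen, dtype=np.int64))
        current = children
        current_first = next_first
        if current.shape[0] == 0:
            raise RuntimeError("population died out")

    sequences = np.concatenate(blocks, axis=0)
    log = (
        pd.DataFrame(
            np.concatenate(log_rows) if log_rows else np.empty((0, 4), dtype=np.int64),
            columns=["cell", "position", "from_code", "to_code"],
        )
        .astype(np.int64)
    )
    return SimulatedLineage(
        config=config,
        sequences=sequences,
        parents=np.concatenate(parents),
        generation=np.concatenate(generation),
        mutation_log=log,
    )


def simulate_pool(config: SimulationConfig, rng: np.random.Generator | int) -> SimulatedLineage:
    """Simulate a neutral clonal expansion (no fitness differences).

    Fully reproducible from the random generator or integer seed.
    """
    if config.delta_mu != 0.0:
        raise ValueError("simulate_pool is the neutral model; use simulate_with_selection")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    return _simulate(config, rng)


def simulate_with_selection(
    config: SimulationConfig, rng: np.random.Generator | int
) -> SimulatedLineage:
    """Simulate an expansion where NS carriers in the selected region divide faster.

    Cells with at least one amino-acid change (relative to the founder)
    within ``config.selection_region`` draw their offspring number with
    mean ``offspring_per_cell + delta_mu`` (nearest-integer stochastic
    rounding).  With ``delta_mu = 0`` this is the neutral model.
    """
    if config.delta_mu != 0.0 and config.selection_region is None:
        raise ValueError("selection requires selection_region")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    return _simulate(config, rng)


def sample_biased(
    lineage: SimulatedLineage,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | int = 0,
    return_chosen: bool = False,
):
    """Sample final-generation cells with a lineage-specific weight.

    One cell of the bias generation (by default the third generation, one
    of the first eight siblings) is chosen uniformly; final-generation
    cells descending from it receive sampling weight ``bias_factor``, all
    others weight 1, and ``sample_size`` cells are drawn without
    replacement with probability proportional to weight.  Returns an
    ordered id -> sequence mapping with ids ``s<cell index>``.
    """
    config = config or lineage.config
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    final = lineage.final_indices
    if config.sample_size > final.size:
        raise ValueError("sample_size exceeds the final population")
    weights = np.ones(final.size, dtype=float)
    chosen = None
    if config.bias_factor != 1.0:
        gen_cells = np.flatnonzero(lineage.generation == config.bias_generation)
        chosen = int(rng.choice(gen_cells))
        # walk each final cell up to the bias generation
        anc = final.copy()
        hops = int(lineage.generation.max()) - config.bias_generation
        for _ in range(hops):
            anc = lineage.parents[anc]
        weights[anc == chosen] = config.bias_factor
    p = weights / weights.sum()
    picked = rng.choice(final, size=config.sample_size, replace=False, p=p)
    sample = {f"s{int(i)}": lineage.cell_sequence(int(i)) for i in np.sort(picked)}
    if return_chosen:
        return sample, chosen
    return sample


GERMLINE_ID = "germline"


def lineage_to_events(
    lineage: SimulatedLineage,
    sample: Mapping[str, str],
    clone_id: str = "sim",
) -> pd.DataFrame:
    """Sampled sequences -> NJ tree rooted at the founder -> mutation events."""
    sequences = dict(sample)
    sequences[GERMLINE_ID] = lineage.founder
    tree, _ = build_clone_tree(sequences, germline_id=GERMLINE_ID)
    events = enumerate_mutation_events(tree, lineage.config.region_map, clone_id=clone_id)
    return events_to_frame(events)


def run_replicates(
    config: SimulationConfig,
    n_replicates: int,
    seed: int,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulate -> sample -> tree -> events -> per-region Welch test, repeatedly.

    Returns one row per (replicate, region) with NS/S event counts, class
    means and the Welch t-test of NS vs S LONR values.  Replicate streams
    are spawned from one seed, so results are reproducible and independent
    of the replicate order.
    """
    rows = []
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        lineage = _simulate(config, rng)
        sample = sample_biased(lineage, config, rng)
        events = lineage_to_events(lineage, sample, clone_id=f"rep{rep}")
        for region in config.region_map.labels():
            sub = events[events.region == region]
            ns = sub.loc[sub.mutation_class == "NS", "lonr"].to_numpy()
            s = sub.loc[sub.mutation_class == "S", "lonr"].to_numpy()
            res = welch_t_test(ns, s)
            rows.append(
                {
                    "replicate": rep,
                    "region": region,
                    "n_ns": ns.size,
                    "n_s": s.size,
                    "mean_lonr_ns": ns.mean() if ns.size else math.nan,
                    "mean_lonr_s": s.mean() if s.size else math.nan,
                    "mean_difference": ns.mean() - s.mean() if ns.size and s.size else math.nan,
                    "t_statistic": res.t,
                    "p_value": res.p,
                    "test_valid": res.valid,
                }
            )
        if progress and (rep + 1) % 25 == 0:
            logger.info("replicate %d/%d done", rep + 1, n_replicates)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FalsePositiveResult:
    rate: float
    n_significant: int
    n_valid: int
    n_replicates: int
    alpha: float
    ci_low: float
    ci_high: float
    region: str


def false_positive_rate(
    config: SimulationConfig,
    n_replicates: int,
    alpha: float = 0.05,
    seed: int = 0,
    region: str = "R2",
    replicate_table: pd.DataFrame | None = None,
) -> FalsePositiveResult:
    """Fraction of neutral replicates whose region test is significant at ``alpha``.

    Under neutrality this should match ``alpha`` in the calibrated regime
    (hundreds of sampled sequences, 10-20 mutations per sequence).  The
    95% Clopper-Pearson interval of the observed rate is reported.
    Replicates with an undefined test (too few events in a class) count as
    non-significant.  A precomputed ``run_replicates`` table may be passed
    to re-evaluate at a different alpha without re-simulating.
    """
    if config.delta_mu != 0.0:
        raise ValueError("false_positive_rate requires the neutral model")
    table = (
        replicate_table
        if replicate_table is not None
        else run_replicates(config, n_replicates, seed)
    )
    sub = table[table.region == region]
    n = int(sub.replicate.nunique())
    valid = sub[sub.test_valid.astype(bool)]
    k = int((valid.p_value < alpha).sum())
    rate = k / n if n else math.nan
    from scipy.stats import beta

    lo = float(beta.ppf(0.025, k, n - k + 1)) if k > 0 else 0.0
    hi = float(beta.ppf(0.975, k + 1, n - k)) if k < n else 1.0
    return FalsePositiveResult(
        rate=rate,
        n_significant=k,
        n_valid=int(len(valid)),
        n_replicates=n,
        alpha=alpha,
        ci_low=lo,
        ci_high=hi,
        region=region,
    )


# ---------------------------------------------------------------------------
# Synthetic germline library and repertoire (fixtures for the full pipeline)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return decode_sequence(rng.integers(0, 4, size=length, dtype=np.uint8))


def make_germline_library(
    rng: np.random.Generator | int = 0,
    n_v: int = 3,
    n_j: int = 2,
    v_length: int = 294,
    j_length: int = 48,
) -> list[GermlineGene]:
    """Generate a synthetic germline V/J gene library.

    V genes carry CDR2/FWR3/CDR3 interval annotations laid out so that the
    final 159 nt (the analysis tail) contain the tail of CDR2, all of FWR3
    and the start of CDR3, mimicking the 3' part of a heavy-chain V gene.
    Lengths are codon multiples so the truncated frame stays in frame.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if v_length % 3 or j_length % 3:
        raise ValueError("gene lengths must be codon multiples")
    tail = v_length - 159
    genes = [
        GermlineGene(
            name=f"V{i + 1}",
            segment="V",
            sequence=_random_seq(rng, v_length),
            region_map=[
                ("CDR2", tail - 24, tail + 33),
                ("FWR3", tail + 33, tail + 147),
                ("CDR3", tail + 147, v_length),
            ],
        )
        for i in range(n_v)
    ]
    genes += [
        GermlineGene(name=f"J{i + 1}", segment="J", sequence=_random_seq(rng, j_length))
        for i in range(n_j)
    ]
    return genes


def simulate_repertoire(
    library: list[GermlineGene],
    rng: np.random.Generator | int = 0,
    n_clones: int = 4,
    reads_per_clone: int = 8,
    junction_length_range: tuple[int, int] = (3, 12),
    mutations_per_read: float = 6.0,
) -> dict[str, str]:
    """Simulate a small repertoire of mutated V-junction-J reads.

    Each clone picks a V gene, a J gene and a random junction; its reads
    are independent copies of the rearrangement with a Poisson number of
    uniform substitutions.  Junction lengths are multiples of 3 so reads
    stay in frame.  Intended as an end-to-end fixture for assignment,
    grouping and tree building.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    vs = [g for g in library if g.segment == "V"]
    js = [g for g in library if g.segment == "J"]
    reads: dict[str, str] = {}
    for c in range(n_clones):
        v = vs[int(rng.integers(len(vs)))]
        j = js[int(rng.integers(len(js)))]
        lo, hi = junction_length_range
        jl = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
        junction = _random_seq(rng, jl)
        founder = v.sequence + junction + j.sequence
        enc = np.frombuffer(founder.encode(), dtype=np.uint8)
        base = np.zeros(enc.shape, dtype=np.uint8)
        for ch, code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
            base[enc == ord(ch)] = code
        for r in range(reads_per_clone):
            seq = base.copy()
            k = int(rng.poisson(mutations_per_read))
            if k:
                pos = rng.integers(0, seq.size, size=k)
                seq[pos] = (seq[pos] + rng.integers(1, 4, size=k).astype(np.uint8)) % 4
            reads[f"c{c}r{r}"] = decode_sequence(seq)
    return reads
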