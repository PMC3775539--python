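# Methods

## The selection model

The unit of analysis is a B-cell clone: the set of sequences descending
from one V(D)J rearrangement, diversified by somatic hypermutation (SHM)
during affinity maturation. Selection *within* the clone is defined
dynamically — a mutation is positively selected if it raises the mean
number of offspring per generation from μ to μ + Δμ — rather than through
mutation counts. While both the mutated and the un-mutated sub-lineage of
an internal tree node survive, the expected ratio of their population
sizes grows like e^(Δμ·T), T being the number of generations from the
mutation to sampling. The Log Offspring Number Ratio of a mutation,

    LONR = ln(n_mut / n_sib),

with `n_mut`, `n_sib` the sampled-leaf counts below the mutated branch
and its sibling, is therefore an estimator of Δμ·T up to sampling noise.

A single LONR value cannot distinguish selection from uneven sampling.
The test aggregates: within a sequence region, the LONR values of
synonymous (S) mutations experience every confounder — tree shape,
amplification bias, position-dependent mutation rates — except the
fitness effect itself. Selection in the region is therefore declared by
an unpaired, unequal-variance (Welch) two-sample t-test between the NS
and the S LONR samples. Because no absolute NS or S counts are used, the
test needs no baseline mutation model; it would only be distorted if S
and NS rates differed by orders of magnitude.

Two aggregation variants are reported side by side: events pooled over
all clones in a scope (headline), and the mean of per-clone NS − S
differences. A secondary report restricts pooling to clones whose own
pooled test is significant at p < 0.01. No multiple-testing correction is
applied to the headline p-values; a Benjamini–Hochberg column is appended
for convenience and clearly separate.

### Assumptions

- SHM produces point substitutions only; all sequences of a clonal group
  are treated as equal length and ungapped (indel-carrying reads are
  dropped during grouping).
- Each mutation is classified S/NS on its containing codon **relative to
  the direct ancestor**, not to the germline or a consensus. Co-occurring
  substitutions in one codon on one branch are classified independently,
  each substituted alone into the ancestral codon; joint effects of
  same-codon pairs are ignored (they are rare at SHM loads and the events
  table carries the full codons, so a different rule can be applied
  downstream).
- Natural log is used; the base only rescales LONR and cannot change
  signs or test outcomes.
- Events on branches to leaves are included (`n_mut = 1` is possible),
  and the germline root is an eligible internal node like any other.

## Pipeline choices

**Germline assignment.** Exhaustive ungapped sliding placement of every
germline gene against the read, scored by matched/compared positions
(undetermined bases excluded from both counts); placements must overlap
the read by ≥ 60 nt (V) / ≥ 12 nt (J), the J search is constrained to
start after the V end, and ties fall to library order and then the
smaller offset. This is a deterministic, dependency-free proxy for a
local aligner, justified by the no-indel assumption. Both match fractions
must exceed 0.5 (strictly) for a read to be kept. For a random read the
maximised V fraction sits near 0.25–0.4 — well below the threshold —
while the short J segment's maximised fraction is noticeably inflated;
the joint threshold on both segments is what carries the filtering.

**Grouping and truncation.** Reads sharing (V gene, J gene, V–J
distance) form a group; each member is truncated to the last 159 nt of
its aligned V + the junction + the first 20 nt of its aligned J, so all
members have length 159 + distance + 20 and the frame is preserved
(159 = 53 codons). The group's artificial germline is the germline V
tail + N-filled junction + germline J head; N positions are excluded from
all mutation counting, so junction mutations relative to germline are
never called (the true junction is unknowable), while junction mutations
*within* the tree are scored normally. Region annotations are carried in
gene coordinates and mapped onto the truncated frame; the junction and J
head are included in CDR3, avoiding artifacts of D-segment length.

**Trees.** Pairwise Hamming distances over determined positions feed an
internal Saitou–Nei neighbor-joining implementation (deterministic
tie-breaks; negative branch lengths clamped to zero with the deficit
moved to the sibling so pair sums are preserved). The tree is rooted on
the germline edge; the germline leaf is removed from leaf counts because
it is the inferred ancestor, not a sampled read. Identical member
sequences are collapsed into one leaf and expanded back in leaf counts
(`count_duplicates`, default on), so branch imbalance reflects sampled
reads, not unique haplotypes. Trees imported from Newick with polytomies
are resolved into left-leaning caterpillars with zero-length edges, which
makes every LONR event a two-branch comparison in which the synthetic
sibling aggregates the remaining children.

**Ancestral reconstruction.** Internal sequences come from minimum-change
parsimony. Per site, a bottom-up unit-cost dynamic programme (the Sankoff
form of Fitch's small-parsimony problem) computes the minimal
substitution count below each node for each state; the root is pinned to
the germline base wherever determined, which keeps the reconstruction
exactly minimal *given* the known ancestor — a plain Fitch backtrace is
not, when the fixed root state lies outside the root's optimal set. The
top-down pass prefers the parent's state among minimal options and falls
back to alphabetical order, making reconstruction deterministic. The
implementation is verified against exhaustive enumeration of all
internal-state assignments on small trees.

**Clone parsing.** A group's tree is cut at every edge whose endpoint
sequences differ at more than 4 positions (edge cut, not path distance —
the ambiguity is resolved in favour of edges and tested against a
connected-components oracle); each remaining component of leaves is one
clone. Clones are then re-built as their own germline-rooted trees, and
clones whose parsimony score falls below `min_mutations_per_tree`
(default 10, matching the calibrated regime of 10–20 mutations per
sequence) are excluded from event enumeration.

## The simulator

`simulate_pool` emulates the neutral expansion used for calibration: a
uniform-random 348-nt founder; every cell leaves exactly two offspring
per generation; each child draws a Poisson number of substitutions in
each of two regions (default split 174/174 — the region boundary is a
free choice and configurable) with mean rates 0.5 and 1.0 per sequence
per generation; mutated positions are uniform within the region and the
new base uniform over the three alternatives (no transition bias, no
hotspots, no indels; a per-site Bernoulli mode is available via
`per_site`). Back-mutation is allowed, and stop codons are retained —
the neutral model has no phenotype. Two technical notes: several draws
hitting one site in one child collapse to a single substitution (a
sub-percent effect at these rates), and the founder, not a consensus, is
the tree root at analysis time, exactly as the germline would be.

Sampling emulates amplification bias: one random third-generation cell
(of eight) is chosen and its final-generation descendants get sampling
weight 2 (`bias_factor`), all others weight 1; `sample_size` cells are
drawn without replacement proportionally to weight.

Defaults place the calibration in the regime where the test is expected
to hold its size: 10 generations (1024 cells), 300 sampled sequences,
~15 substitutions per sequence (within the stated 10–20 band). The
false-positive rate is the fraction of neutral replicates whose
designated-region Welch test (NS vs S LONR) has p < 0.05; the
higher-rate region is designated because it supplies more events per
replicate, and both regions are null under neutrality. 300 replicates
run in a few minutes on one CPU; the replicate count trades Monte-Carlo
resolution against desk-scale runtime and is a command-line parameter.

**Selective mode.** `simulate_with_selection` gives every cell carrying
at least one amino-acid change (relative to the founder) inside the
selected region an offspring number with mean μ + Δμ (nearest-integer
stochastic rounding). Because carrier status is a threshold, the signal
*saturates* once most lineages carry an NS mutation in the region — with
the default region rates nearly every lineage is a carrier within a few
generations and the NS-vs-S contrast vanishes. The power check therefore
runs in a pilot-calibrated regime: selected-region rate 0.08 (so
non-carrier siblings persist into mid-tree), Δμ = 2, 10 generations,
400 sampled sequences. There, the majority of replicates show a positive
mean NS − S LONR difference in the selected region while the unselected
region's rejection rate stays at the nominal α. Per-replicate detection
is deliberately the *sign* of the mean difference: single-replicate
significance is weak because each replicate contains essentially one
selective sweep.

## What the synthetic data does and does not show

The simulator and the synthetic germline library (`make_germline_library`,
random V/J genes with CDR2/FWR3/CDR3 annotations laid out like the 3'
part of a heavy-chain V gene) exercise every pipeline stage, but they
lack real-data features: SHM hotspot motifs and transition bias, indels
and sequencing error, allelic variation in the germline library,
isotype structure, and the shallow, uneven sampling of real repertoires.
Passing tests demonstrate correctness of the machinery and calibration
under the stated model, not biological conclusions about any repertoire.
Donor-repertoire-scale results (region rankings across isotypes,
per-donor profiles, load–size correlations) depend on data that is not
shipped; the operators that would compute them (`region_report`,
`position_profile`, `ns_fraction`, `spearman_correlation`) are tested at
operator level only.

## Numerical and degenerate-input policy

- Bases outside {A, C, G, T} are treated as undetermined (N): excluded
  from distances, match fractions, and mutation calls; events whose frame
  codon contains an N are skipped and logged.
- Welch tests with a group of fewer than two values or zero pooled
  variance are flagged (`test_valid = False`, NaN statistics), never
  silently zeroed; flagged replicates count as non-significant in
  false-positive rates.
- The NS/(NS+S) fraction is flagged undefined at 0/0; Spearman's rho is
  NaN for constant vectors.
- All TSV outputs have stable column order and 6-significant-digit
  floats; re-running a pipeline with the same configuration and seed
  reproduces outputs byte-identically.
- Randomness everywhere derives from numpy Generators seeded explicitly;
  replicate streams are spawned from a single seed, so results do not
  depend on scheduling or replicate order.

## Known limitations

- NJ topology error at low mutation counts is untracked; reconstruction
  noise is part of what the neutral calibration absorbs.
- The germline-assignment maximiser can inflate match fractions of short
  segments on random sequence (partial-placement maximisation); the joint
  V-and-J threshold compensates, but segment-level fractions should not
  be read as calibrated probabilities.
- The selective mode's threshold ("carrier") fitness model saturates at
  high region mutation rates by construction; Δμ inference is out of
  scope — the package tests direction, not magnitude, of selection.
- Maximum-parsimony tree *search* is not implemented; neighbor joining is
  the single topology builder, with `build_clone_tree` as the seam where
  an alternative could be plugged in.
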