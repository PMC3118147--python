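# Methods

This note documents the models and procedures implemented in `phasemir`,
the parameters that matter, the numerical choices, what the synthetic-data
generators do and do not emulate, and the known limitations.

## Coordinates and sequence conventions

All coordinates are 0-based, half-open intervals on the 5′→3′ strand of the
sequence under consideration. DNA input is normalized to RNA (T→U) on
read. `N` is accepted only in homology-scan targets (EST/GSS-style input),
never in precursors, and never matches anything (substitution cost 1).

## Secondary structure and the built-in folder

A structure is a set of non-crossing base pairs (Watson-Crick plus G:U
wobble) with a minimum hairpin loop of 3 nt. Structures can be supplied
externally as dot-bracket strings; for self-contained operation the package
ships a deterministic folder: a Nussinov-style dynamic program maximizing a
stacking-aware score (G:C = 3, A:U = 2, G:U = 1, +1 per stacked pair), with
ties broken toward the pairing with the smaller opening index, then the
smaller closing index. This is not a thermodynamic nearest-neighbour
model; it is a reproducible stand-in whose output feeds rule-based filters
that are themselves parameterized, so boundary discrepancies against a
thermodynamic folder change rule counts, not rule definitions. The folder
is verified against exhaustive enumeration of all non-crossing structures
on sequences up to length 14.

A `Hairpin` couples a sequence, a structure, and the terminal-loop span of
the *main stem*, defined as the maximal nested pair path carrying the most
paired positions; side branches of a multiloop therefore belong entirely
to one arm. Intervals classify as 5′-arm, 3′-arm, or loop-spanning.

## miR* location and the loop distance D

Given a located miR, its star is derived from the pairing table: the
minimal interval containing all partners of paired miR positions, widened
by the number of unpaired residues at each miR end (mirroring terminal
bulges), then shifted +2 nt in the 3′ direction — the standard 2-nt
3′-overhang geometry of a Dicer duplex, applied symmetrically. A perfect
21-bp duplex therefore yields a 21-nt star offset by 2; a 2-nt star-side
bulge yields a 23-nt star. `D` is the number of nucleotides strictly
between the loop-proximal ends of the miR and the located miR*; the same
quantity is bounded by rule 7 (5 ≤ D ≤ 300) and drives the type split at
D ≤ 60.

## The seven filtering rules

Rule 1 (single-arm placement) is evaluated on the spans of the *paired
bases* of miR and miR*, not on the overhang-shifted star interval: the
overhang of a loop-adjacent duplex legitimately pokes into the terminal
loop, and the rule concerns where the pairing lives. Rules 2/3/6 count
unpaired miR positions, their maximal runs ("bulges") and the longest run.
Rule 5 counts asymmetric unpaired bases: for each unpaired run, the excess
of the run length over the number of star-side positions between the same
flanking pairs. Rule 4 bounds the miR/miR* length difference at 3; rule 7
bounds D. All thresholds are configurable (`MircheckParams`). The
original manual screen against loose structures is replaced by a
deterministic stability rule — at least 50% of miR ∪ miR* positions paired
(configurable) — reported separately from the seven rules and applied when
calling status. Status calling: rejected unless all rules pass; homolog at
edit distance ≤ 3 to a known mature miRNA; candidate at exactly 4.
"Mismatches or indels" are formalized as unit-cost Levenshtein distance
over the best-matching window; overlapping windows merge to the locally
best one (minimal distance, then leftmost, then shortest).

## Classification and partitions

Types follow the decision table: D ≤ 60 → type 2; otherwise
(sequence, structure) conservation of the loop-proximal ACRs maps
(y,y) → 1, (y,n) → 3, (n,y) → 4, (n,n) → 5. Sequence conservation is the
best ungapped window (±2 nt length slack) against a user-supplied ACR
consensus at identity ≥ 0.6; structural conservation requires the candidate
ACR windows to pair with each other at fraction ≥ 0.6 with no multiloop in
the connecting stem (no intervening position pairing outside it). When
sequence identity cannot place the ACRs, loop-abutting windows of the
consensus length serve as structural candidates. Both thresholds are
package defaults chosen so that cleanly planted synthetic cases separate,
and are explicitly tunable; the source study never quantified
"conserved". Partition schemes are built only for type-1 precursors
(conserved partitions constrained to 18–26 nt); the nine partitions tile
the precursor exactly, with zero-length space partitions permitted, and
mirror when the miR sits on the 5′ arm.

## Quantification

Reads map by exact substring match only. A read matching k > 1 precursors
contributes to each precursor's *maximum-possible* abundance at full
weight and to no *unique* abundance; a read at several positions within one
precursor splits its weight equally (mass conservation). Per-sample scale
factors are mean(total reads)/total reads, with a pre-normalized flag
(factor 1). A read is assigned to the partition covering ≥ 80% of its
nucleotides (for 21 nt: ≥ 17), implemented as an exact rational comparison;
with disjoint partitions and a threshold above 50% the assignment is
necessarily unique. Unassignable reads are *leak* — abundance inconsistent
with the phased register. Ratios average replicates first, then divide
mutant by wild-type maximum-possible values; when both sides fall below the
abundance floor (default 1.0 normalized units) the ratio reports 1.0
flagged `absent`, and a sub-floor denominator alone is replaced by the
floor and flagged `floored`. Length-class ratios apply the same
conventions per read-length bin.

## PARE profiling

Tags (minimum 18 nt) map sense-strand, exact-match, over ~1-kb contexts
with the precursor at the centre. The cleavage between nucleotides i−1
and i is recorded at index i by summing the TP10M-normalized abundances
(raw × 10⁷ / total reads) of all tags whose 5′ nucleotide sits at i.
Multi-target tags count fully in each target's maximum-possible profile.
Aggregation across samples is position-wise summation; the modal site is
the argmax with 5′-most tie-breaking.

## Consensus structure and covariation

Columns with a gap fraction strictly above 0.75 are removed (exactly 75%
is kept). Column information content is (2 − Shannon entropy in bits of
the non-gap residue distribution) scaled by the non-gap fraction, so 2.0
occurs iff the column is a single residue with no gaps; the consensus
residue requires a 0.8 majority among non-gap entries. Pair support for
columns (i, j) is the canonical-pair fraction among rows with both columns
present, eligible only when at least half the rows are present. Candidate
pairs (support ≥ 0.75) are assembled into the maximum-total-support
non-crossing set by a weighted interval DP (minimum loop 3), verified
against exhaustive subset search on small alignments. A selected pair is
*covarying* when ≥ 2 distinct canonical pair types occur among supporting
rows, else *consensus*. This is one coherent covariation-scored procedure
in the spirit of RNAalifold-style consensus methods, rather than a
re-implementation of any one historical tool.

## Phylogenetic model and inference

Unpaired columns evolve under GTR; each consensus base-pair column pair is
one 16-state doublet character whose rate matrix allows only
single-position changes, with rate = exchangeability of the changed
nucleotide pair × stationary frequency of the target doublet. Both
matrices are reversible by construction and scaled to one expected event
per unit branch length at stationarity. Site-rate heterogeneity uses four
equal-probability discrete-gamma categories (mean-of-bin rates, mean
exactly 1; median-of-bin available). Likelihoods use Felsenstein pruning
with pattern compression, gaps as missing data, per-category averaging and
(on trees above 24 nodes) per-node rescaling; correctness is checked
against exhaustive summation over internal states and, for the doublet
model, against the independent-coordinate factorization limit (uniform
frequencies: the doublet generator is a Kronecker sum of two half-rate GTR
generators).

The sampler is Metropolis-Hastings with moves: NNI on a random internal
edge (35%), branch-length multiplier (45%), gamma-shape multiplier (10%),
and Dirichlet frequency proposals for the 4- and 16-state stationary
distributions (10%). Priors: uniform topology, iid Exponential(mean 0.1)
branch lengths, Exponential(1) gamma shape, flat Dirichlet frequencies.
Exchangeabilities are fixed at their supplied values. Runs are
independently seeded; samples are pooled after discarding a 25% burn-in;
acceptance rates are logged and convergence is reported as the average
standard deviation of split frequencies (ASDSF) between runs, never
silently ignored. Identical alignment rows are collapsed to one
representative before inference and reinserted afterwards as children of
the representative's node with posterior 100 and branch length 0.001.
The desk-scale defaults (two runs, tens of thousands of generations,
6-taxon validation studies) replace production-scale multi-million-
generation runs; the configuration accepts arbitrary sizes.

Consensus trees contain exactly the splits with frequency strictly above
0.5 (mutually compatible by the majority property), annotated with their
posterior probabilities, and are cross-checked against an independent
consensus implementation.

## Reconciliation

Rooted gene trees map onto rooted species trees by the LCA map; rooting is
the caller's responsibility (e.g. by an outgroup). A gene node is a
duplication iff it maps to the same species node as one of its children;
each gene edge implies dist(M(parent), M(child)) − 1 losses after a
speciation and dist losses after a duplication, with the lost species
branches reported. The LCA map minimizes both counts, verified against a
brute-force search over all valid reconciliation maps.

## Synthetic data: what it emulates, what it does not

Generators are deterministic given their seed and return exact ground
truth. Planted hairpins realize the nine-partition anatomy with
reverse-complement duplexes and a planted structure (they are not refolded,
so ground truth is exact); violation switches plant symmetric interior
loops, miR-side bulges, star-side bulges, or a shortened stem, each
engineered to trip a single rule. Read libraries draw multinomially from
per-partition proportions whose defaults mirror the canonical phased
profile (miR 0.70, miR* 0.08, ACR5 0.05, ACR3 0.12, leak 0.05) at default
depth 10⁵ with 21±1-nt reads; leak reads straddle partition boundaries
below the 80% threshold. PARE libraries draw 20-nt tags from specified
hot-spot distributions. Alignments evolve by exact matrix-exponential
CTMC simulation down the tree, with compensatory stem evolution expressed
through doublet frequencies concentrated on canonical pairs (default 0.97
canonical mass — the regime of a deeply conserved consensus helix); the
ancestral state of a planted pair is drawn conditioned on being canonical,
since a planted pair that never paired in the ancestor is not planted.
Gene families arise by per-lineage birth–death along the species tree with
the full event log retained; reconciliation counts are parsimony lower
bounds on the logged truth.

Real data differ in ways the generators deliberately omit: sequencing
error and adapter artifacts, expression noise beyond multinomial sampling,
alignment error and indels (alignments are simulated substitution-only,
mirroring analysis downstream of a fixed alignment), heterogeneous library
chemistry, and genome-scale search space. Passing round-trip tests
therefore demonstrates correctness of the computations under their stated
models, not robustness to upstream artifacts.

## Numerical choices

Exact-boundary comparisons (80% overlap, 75% gaps, 0.8 consensus majority)
use epsilon-guarded rational comparisons so integer boundary cases are
exact. The DP tie-breaks are deterministic and documented above. Rate
matrices are diagonalized through the symmetrized similarity transform of
a reversible generator (`eigh`), and transition probabilities are clipped
at 0 against round-off. MCMC per-branch transition matrices are cached by
branch-length value and invalidated whenever rates or frequencies move.

## Limitations

- The folder ignores thermodynamics; callers with access to a
  thermodynamic folder should supply its dot-bracket output.
- ACR detection thresholds (0.6/0.6) are package conventions; sensitivity
  analyses should vary them.
- The sampler has no Metropolis-coupling; very diffuse posteriors on many
  taxa will mix slowly.
- Reconciliation assumes a correct rooted gene tree; uncertainty in the
  gene tree is not propagated into event counts.
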