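# Methods

This note documents the models and procedures implemented in `strlineage`,
the defaults they ship with, and the choices made where the design was
genuinely open.

## Problem setting

Single cells are related by a lineage tree; every cell division leaves a
faint signature in the genome as replication slippage changes the repeat
count of short tandem repeats (STRs). A targeted duplex-MIP panel measures
thousands of STR lengths per cell, but amplification stutter blurs each
measurement, and single-cell whole-genome amplification drops loci at
random. The pipeline therefore consists of: choosing loci that mutate fast
enough to be informative; modelling stutter explicitly; genotyping each
cell-locus read histogram against that model; and reconstructing and
validating a tree from the resulting genotype matrix.

## Panel design

Loci are selected by repeat-unit class: AC/AG di-repeats with more than 10
units, A/G mono-repeats with more than 6, both thresholds strict. Units
are canonicalized to their minimal rotation; by default reverse-complement
classes are unified (GT→AC, CT→AG, T→A, C→G), with a flag to disable —
whether the opposite-strand classes should count is genuinely ambiguous,
and the flag keeps both readings available. Candidate amplicons containing
`TTAA` are excluded (the upstream WGA chemistry cuts there), and amplicons
must be 150 ± `tol` bp (`tol` defaults to 30; "approximately 150" is not a
precise bound, so it is configurable).

A MIP precursor is the fixed concatenation
`Mly1_F + fw_arm + NNN + backbone + NNN + revcomp(rv_arm) + revcomp(Mly1_R)`
with the constants

```
Mly1_F   GTCTATGAGTGTGGAGTCGTTGC
Mly1_R   CTAGCTTCCTGATGAGTCCGATG
backbone AGATCGGAAGAGCACACGTCTGAACTCTTTCCCTACACGACGCTCTTCCGATCT
```

The fixed elements total 106 nt, leaving a 44 nt combined arm budget under
the 150 nt synthesis limit. MlyI recognizes `GAGTC(N5)` and cuts blunt
5 nt downstream; each adapter carries one inward-facing site positioned so
digestion removes exactly the two 23 nt adapters, giving a 104 nt active
probe for a 150 nt precursor (the expected ~105 bp product). Precursors
harboring any additional `GAGTC`/`GACTC` occurrence are rejected; the scan
is literal on the designed sequence — randomized UMI bases (`N`) are not
treated as wildcard matches, since a site completed by a random base exists
only in a fraction of synthesized molecules.

Arm selection is a deliberate simplification of thermodynamic primer
scoring: sliding windows in the flanks, length 18–25 nt, GC 30–70%, no
homopolymer ≥ 5, Wallace-rule Tm (2·AT + 4·GC) within 48–72 °C, no MlyI
site; among passing pairs the one whose implied captured amplicon is
closest to 150 bp wins, shorter arms breaking ties.

## Stutter model

A sequenced read is modelled as the endpoint of a C-step Markov chain on
repeat length: per cycle the length decreases by one unit with probability
`slip_down(unit, L)`, increases with `slip_up(unit, L)`, else stays; length
1 is an absorbing floor. `C` defaults to 17 cycles — the midpoint of the
15–20 effective-cycle band that low-noise targeted amplification
corresponds to — and is fully configurable (whole-genome-amplification
pipelines behave like substantially more cycles).

Slip probabilities follow a logistic curve in repeat length, separately
parameterized per unit-class length: mono-repeats
(p_max = 0.06, midpoint 10, scale 3), di-repeats (p_max = 0.02, midpoint
20, scale 5), longer units (p_max = 0.008). Contraction dominates
expansion (`up_ratio` = 0.35), matching the well-known asymmetry of the
n−1 stutter band. No published constants are assumed; all parameters are
plain numbers serializable to YAML/JSON. At the defaults an (AC)×13
allele at 17 cycles yields ≈ 91% on-target reads, 6% at n−1 and 2% at
n+1 — a realistic stutter ladder for low-cycle targeted data.

Deliberate simplifications: single-step slippage only (multi-step events
arise as multiple cycles); reads are i.i.d. C-step walks, ignoring the
branching structure of PCR (consistent with describing noise as
"equivalent to C cycles"); no sequencing errors inside the repeat or the
flanks. Because reads are i.i.d., sampling a histogram is implemented as
one multinomial draw from the DP-predicted distribution — exactly the
per-read walk distribution, just computed once.

## Lineage simulation

The benchmark emulates an ex vivo clonal-expansion experiment: a founding
cell is expanded, single cells are re-sampled every 12–15 divisions and
re-expanded, over nine sampling levels. `simulate_benchmark_tree` grows
`branching` new lineages per existing lineage per level until `max_leaves`
(default 2 and 32: binary splits for five levels, then single carry-over),
drawing each level's division count uniformly from 12–15. Genotyped cells
are the terminal-level samples, giving ~32 leaves; edges record both
sampling generations and divisions.

Mutation follows the stepwise mutation model: per sampling generation each
locus mutates with probability 10⁻³ (the rate at which such panels
actually mutate per sampling level), stepping ±1 unit with equal
probability, floored at one repeat. The "per generation" unit is
ambiguous between sampling level and cell division; the default is per
sampling level — the unit in which the rate is estimated on such trees —
with a `per_division` flag that divides the rate by the mean divisions per
level (13.5) and applies it at every division. Diploid simulation is
optional (two allele series per locus, configurable initial separation)
and exists to exercise biallelic splitting; haploid X/Y-style loci are the
default, matching male-donor panel policy.

`simulate_labeled_populations` attaches labeled clades to a backbone
lineage at per-group divergence depths, for enrichment testing.

## Read mapping

Rather than aligning against a genome, the mapper enumerates, per locus,
all repeat-count variants within ±10 of the reference count (floored at 1)
— assigning a read to a variant is the same thing as measuring its repeat
length. Classification uses the innermost 15 nt of each flank as anchors:
exact k-mer lookup, with an optional one-mismatch fallback scan; the
inter-anchor span must be an in-phase whole number of repeat units, else
the read is unmapped with a reason. Anchors shared between loci are
flagged ambiguous and excluded. An aligner-backed implementation could sit
behind the same contract; the anchor method keeps the package
self-contained and deterministic. Paired-end merging is upstream of this
interface: the simulator emits merged single reads.

## Genotyping

A histogram with fewer than 10 reads is not called. Otherwise candidates
are all mono-allelic genotypes within the observed support ± 2 repeat
units, plus all biallelic pairs from the same range at a fixed 0.5 mixture
(WGA allelic imbalance modelling is deferred). Each candidate is scored by
the Pearson correlation between the normalized observed histogram and the
predicted distribution, computed over the union of the two supports
including interior zero bins (predicted support truncated at 10⁻⁹). A
call is made only if the best correlation reaches 0.95 (confidence =
1 − correlation ≤ 0.05); the mono-allelic candidate is preferred unless
the best biallelic beats it by a margin of 0.01. Degenerate single-bin
comparisons score 1 when the vectors coincide. Predicted distributions
are cached per (unit, allele), and all candidates of a histogram are
scored in one masked vectorized pass, which is what makes genotyping
160,000 histograms take seconds.

Biallelic loci are split population-wide: all called allele values at a
locus are pooled and partitioned at the largest gap; if the two cluster
centers are more than 3 repeat units apart the locus becomes two
mono-allelic pseudo-locus columns, each cell's alleles assigned to the
nearer center (cells whose two alleles fall on one side are set missing
and counted as conflicts). At 3 units or less the maternal/paternal
assignment cannot be trusted, but such loci still carry signal, so the
locus is kept as a single column holding the lower allele, flagged
low-heterogeneity (a flag drops them instead).

## Tree reconstruction and rooting

The pairwise distance between cells is the number of shared genotyped
pseudo-loci with differing repeat counts, normalized by the shared count
(raw counts behind a flag; which variant the original pipelines used is
not documented, and the normalized form is robust to per-cell missingness).
Pairs sharing fewer than `min_shared` loci (default 50) are undefined and
abort reconstruction with an explicit pair list. Trees are built with
neighbor joining — deterministic lexicographic tie-breaking, negative
branch lengths clamped to zero with a warning — and the distance matrix
can be exported in square PHYLIP format for external distance-based tools.

Rooting uses the median genotype (per-locus lower median) of a designated
outgroup population, e.g. healthy blood cells, as a proxy for the zygote.
Default mode projects that genotype onto the unrooted tree: for each split
(A|B) the estimated distance from the genotype q to the path between the
sides is mean over (a∈A, b∈B) of (d(q,a) + d(q,b) − d(a,b))/2, and the
root is placed mid-edge on the minimizing split. An alternative mode
re-runs NJ with q as a synthetic outgroup taxon and roots at its
attachment. Rooting is idempotent.

## Branch support and enrichment

Bootstrap replicates re-draw ⌈2/3·L⌉ pseudo-locus columns without
replacement (about a third of the loci left out per round) and rebuild the
tree; B defaults to 100. For a branch with light-side size p, the
transfer distance to a replicate is the minimum bipartition Hamming
distance over all of the replicate's branches (both orientations; pendant
branches included, which caps it at p−1), and
TBE = 1 − (mean transfer distance)/(p−1), reported in [0,1] and percent,
with TBE > 70% the significance convention. Enrichment of each internal
branch for each population label is the upper-tail hypergeometric
probability P(X ≥ k) of drawing k labelled leaves in a subtree of n out
of N labelled leaves with K carrying the label; unlabeled leaves are
excluded from the universe. Benjamini–Hochberg adjustment is applied
across all (branch, label) tests; raw p-values are reported alongside
since no particular correction is canonical here.

## Tree comparison

The normalized triples distance between two rooted trees on the same
leaves is the fraction of leaf triples whose induced rooted topology
(which pair coalesces most recently, or unresolved) differs; triples are
enumerated exhaustively (fine to a few hundred leaves). A triple resolved
in one tree and unresolved in the other counts as differing by default; a
flag restricts to mutually resolved triples. The coverage curve
subsamples histograms without replacement to each target coverage,
re-genotypes, re-reconstructs and reports the triples distance to the
full-data tree (mean ± sd over seeded repeats).

## Validation configurations

The full benchmark (`BenchmarkConfig` defaults) is the nine-level,
32-cell, 5,000-locus, μ = 10⁻³, C = 17, 30× configuration; one run takes
roughly half a minute on a single CPU, and the acceptance script reports
the median TBE over the true level-1/level-2 splits together with the
mutation-rate estimate obtained by inverting d = 1 − (1−μ)^g per cell
against the founder genotype.

The noise-free oracle (`ZERO_NOISE_CONFIG`) checks that the pipeline is
exact when its assumptions hold: zero stutter, full coverage, 8 cells,
4,000 loci at μ = 5·10⁻³ per level. These sizes make the realized
mutation-count matrix additive on the true topology with overwhelming
probability (≈ 20 expected mutations per internal edge, so the chance of
an unresolved edge is ~e⁻²⁰, and homoplastic collisions perturb distances
by far less than half the shortest edge), hence the reconstruction must
match the truth with triples distance exactly 0.

What the simulations do not capture: real WGA locus dropout is not
missing-at-random, stutter parameters vary per locus, sequencing and
flank errors exist, and real biallelic imbalance is not 50/50. Passing
the suite therefore demonstrates the correctness and internal consistency
of the algorithms under the stated models, not performance guarantees on
arbitrary real data.

## Numerical notes

- All randomness flows through `numpy.random.Generator`; pipeline stages
  derive independent child streams via `SeedSequence.spawn`, so every
  artifact is reproducible from one integer seed.
- Pearson correlations with zero variance on either side (single-bin
  windows) are defined as 1 for identical vectors, else 0.
- NJ Q-criterion ties are broken by the lexicographically smallest pair of
  cluster names (a cluster is named after its smallest member), making the
  topology invariant to input row order in the absence of exact ties.
- Hypergeometric p-values are discrete and therefore super-uniform under a
  permutation null; calibration is asserted as P(p ≤ t) ≤ t + Monte-Carlo
  slack rather than as distributional uniformity.
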