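# strlineage

Retrospective single-cell lineage reconstruction from targeted
short-tandem-repeat (STR) panels.

Somatic cells accumulate mutations at every division, and STR loci —
especially long AC di-repeats and A/G mono-repeats — are the most mutable
and abundant such markers in the human genome, with per-generation slippage
rates around 10⁻³ per locus. A duplex molecular-inversion-probe (MIP) panel
can capture ~10,000 such loci from single-cell whole-genome-amplified DNA,
and the repeat-length changes read out from sequencing let one reconstruct
the cell lineage tree of a tumor, a set of metastases, or healthy tissues.
The catch is that PCR *stutter* corrupts every repeat-length measurement,
so the whole analysis has to be stutter-aware end to end.

`strlineage` implements that computational pipeline:

- **panel design** (`strlineage.panel`) — hyper-mutability filters
  (AC/AG > 10 repeats, A/G > 6), TTAA/length amplicon checks, duplex-MIP
  precursor assembly in the fixed element order
  `Mly1_F · fw-arm · UMI · backbone · UMI · rc(rv-arm) · rc(Mly1_R)`
  (≤ 150 nt), and in-silico MlyI digestion to the ~105 nt active probe;
- **stutter model** (`strlineage.stutter`) — a per-cycle slippage Markov
  chain (default 17 effective cycles): exact DP prediction of the
  read-length distribution per allele, mixtures for heterozygotes, and
  Monte-Carlo sampling;
- **simulation** (`strlineage.simulate`) — ground-truth clonal-expansion
  trees (nine sampling levels of 12–15 divisions), stepwise-mutation-model
  genotype evolution (μ = 10⁻³/locus/generation), labeled populations, and
  full synthetic datasets;
- **read mapping** (`strlineage.readmap`) — an enumerated reference of all
  repeat-count variants per locus; reads are classified by flanking 15-mer
  anchors into per cell-locus repeat-length histograms;
- **genotyping** (`strlineage.genotype`) — maximum-correlation calling
  against the stutter model (call only if coverage ≥ 10 reads and Pearson
  correlation ≥ 0.95), population-wide biallelic splitting into
  mono-allelic pseudo-loci (separation must exceed 3 repeat units);
- **phylogeny** (`strlineage.phylo`) — mutation-count distances (fraction
  of shared pseudo-loci that differ), neighbor joining, PHYLIP export for
  external tree builders, rooting at the median genotype of an outgroup
  population;
- **support & enrichment** (`strlineage.support`) — bootstrap that leaves
  out a third of the loci per round, transfer bootstrap expectation
  TBE = 1 − mean δ/(p−1) with the TBE > 70% significance convention, and
  per-branch hypergeometric label enrichment with Benjamini–Hochberg
  adjustment;
- **tree comparison** (`strlineage.compare`) — normalized triples distance
  between rooted trees and the coverage-subsampling stability curve.

## Worked example

```python
from strlineage.benchmark import BenchmarkConfig, run_benchmark

config = BenchmarkConfig(levels=5, max_leaves=16, n_loci=1500, n_replicates=50)
result = run_benchmark(seed=0, config=config)
print(result.report())
```

Running `python examples/simulate_and_reconstruct.py` (the same
computation) prints:

```
cells genotyped:        16
call rate:              0.999
genotype accuracy:      1.0000
mutation rate estimate: 1.10e-03  (simulated 1e-3)
median TBE, true splits:96.1%
triples distance:       0.0286  (0 = exact)
```

Read this as: 99.9% of the 16 × 1,500 cell-locus histograms produced a
confident genotype; essentially all calls match the simulated truth; the
per-generation mutation rate estimated from the called genotypes along the
known tree recovers the simulated 10⁻³; the true sampling splits are
reproduced with median transfer-bootstrap support well above the 70%
significance bar; and the reconstructed rooted tree is near-identical to
the truth (2.9% of leaf triples differ).

The other scripts under `examples/` each demonstrate one capability
(panel design, the stutter model, bootstrap support + enrichment on
labeled populations, the coverage curve). The `strlineage` command exposes
the same stages as subcommands (`design-panel`, `simulate`, `map`,
`genotype`, `tree`, `support`, `enrich`, `compare`, `benchmark`).

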