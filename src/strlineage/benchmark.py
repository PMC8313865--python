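"""End-to-end simulated benchmark: a nine-level clonal-expansion tree with
known ground truth, pushed through stutter simulation, genotyping, tree
reconstruction, bootstrap support and mutation-rate estimation.

The default configuration emulates the validation experiment the pipeline
is designed around: 9 sampling levels of 12-15 divisions each, ~32 sampled
cells, 5,000 mono-allelic AC-repeat loci mutating at 1e-3 per locus per
sampling generation, amplification stutter equivalent to 17 cycles, and 30
reads per cell-locus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype import GenotypeCaller, assemble_matrix, call_histograms
from .phylo import (
    DistanceMatrix,
    LineageTree,
    build_nj_tree,
    mutation_count_distance,
    root_tree,
)
from .simulate import (
    Dataset,
    MutationModel,
    TrueTree,
    generate_dataset,
    make_panel,
    reference_genotype,
    simulate_benchmark_tree,
)
from .stutter import StutterModel, zero_stutter_model
from .support import (
    BranchSupport,
    bootstrap_replicates,
    compute_tbe,
    tbe_for_split,
)


@dataclass
class BenchmarkConfig:
    """Study conditions of the simulated benchmark."""

    levels: int = 9
    divisions_per_level: tuple[int, int] = (12, 15)
    branching: int = 2
    max_leaves: int = 32
    n_loci: int = 5000
    unit: str = "AC"
    repeat_range: tuple[int, int] = (11, 17)
    mutation_rate: float = 1e-3
    stutter_cycles: int = 17
    coverage: int = 30
    n_replicates: int = 100
    keep_fraction: float = 2.0 / 3.0
    min_shared: int = 50

    def stutter_model(self) -> StutterModel:
        if self.stutter_cycles == 0:
            return zero_stutter_model()
        return StutterModel(cycles=self.stutter_cycles)


# A small, deliberately over-powered configuration for the noise-free
# end-to-end oracle: no stutter, fewer cells, and enough mutations per
# sampling level (n_loci * rate = 20) that the realized mutation-count
# matrix is additive on the true topology with overwhelming probability.
ZERO_NOISE_CONFIG = BenchmarkConfig(
    levels=3,
    branching=2,
    max_leaves=8,
    n_loci=4000,
    mutation_rate=5e-3,
    stutter_cycles=0,
    coverage=30,
    n_replicates=10,
)


def estimate_mutation_rate(
    matrix: pd.DataFrame,
    founder: pd.Series,
    generations: dict[str, int],
) -> float:
    """Per-locus per-generation mutation rate from called genotypes.

    For each cell the fraction d of its called pseudo-loci that differ from
    the founder genotype is converted to a per-generation rate via
    1 - (1 - d)^(1/g) (g = sampling generations separating the cell from
    the founder), then averaged over cells.
    """
    rates = []
    f = founder.reindex(matrix.columns).to_numpy(dtype=float)
    for cell in matrix.index:
        x = matrix.loc[cell].to_numpy(dtype=float)
        both = np.isfinite(x) & np.isfinite(f)
        n = int(both.sum())
        if n == 0 or cell not in generations:
            continue
        d = float((x[both] != f[both]).sum()) / n
        g = generations[cell]
        if g <= 0:
            continue
        rates.append(1.0 - (1.0 - d) ** (1.0 / g))
    if not rates:
        raise ValueError("no cells with usable genotypes")
    return float(np.mean(rates))


@dataclass
class BenchmarkResult:
    config: BenchmarkConfig
    truth: Dataset
    matrix: pd.DataFrame
    distance: DistanceMatrix
    tree: LineageTree
    rooted_tree: LineageTree
    replicates: list[LineageTree]
    level_split_support: list[BranchSupport]
    tree_support: list[BranchSupport]
    mutation_rate_estimate: float
    call_rate: float
    genotype_accuracy: float

    @property
    def median_level_split_tbe_percent(self) -> float:
        return float(
            np.median([s.tbe_percent for s in self.level_split_support])
        )

    def triples_distance_to_truth(self) -> float:
        from .compare import triples_distance

        return triples_distance(
            self.rooted_tree, self.truth.tree.to_dendropy()
        )

    def report(self) -> dict:
        return {
            "n_cells": int(self.matrix.shape[0]),
            "n_pseudo_loci": int(self.matrix.shape[1]),
            "call_rate": round(self.call_rate, 4),
            "genotype_accuracy": round(self.genotype_accuracy, 5),
            "mutation_rate_estimate": self.mutation_rate_estimate,
            "median_level_split_tbe_percent": round(
                self.median_level_split_tbe_percent, 2
            ),
            "level_split_tbe_percent": [
                round(s.tbe_percent, 2) for s in self.level_split_support
            ],
            "n_bootstrap_replicates": len(self.replicates),
            "triples_distance_to_truth": self.triples_distance_to_truth(),
        }

    def write_report(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report(), fh, indent=2)
            fh.write("\n")


def _genotype_accuracy(matrix: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Fraction of called entries matching the true genotypes (mono-allelic
    columns shared between the two matrices)."""
    common = [c for c in matrix.columns if c in truth.columns]
    if not common:
        return float("nan")
    x = matrix[common].to_numpy(dtype=float)
    t = truth[common].reindex(matrix.index).to_numpy(dtype=float)
    called = np.isfinite(x)
    if called.sum() == 0:
        return float("nan")
    return float((x[called] == t[called]).mean())


def run_benchmark(
    seed: int = 0,
    config: BenchmarkConfig | None = None,
) -> BenchmarkResult:
    """Simulate, genotype, reconstruct, and score one benchmark run."""
    config = config or BenchmarkConfig()
    root_seq = np.random.SeedSequence(seed)
    s_tree, s_panel, s_data, s_boot = root_seq.spawn(4)

    tree = simulate_benchmark_tree(
        levels=config.levels,
        divisions_per_level=config.divisions_per_level,
        branching=config.branching,
        max_leaves=config.max_leaves,
        seed=np.random.default_rng(s_tree),
    )
    loci = make_panel(
        config.n_loci,
        unit=config.unit,
        repeat_range=config.repeat_range,
        seed=np.random.default_rng(s_panel),
    )
    stutter = config.stutter_model()
    dataset = generate_dataset(
        tree,
        loci,
        stutter,
        coverage=config.coverage,
        seed=np.random.default_rng(s_data),
        mutation_model=MutationModel(rate_per_generation=config.mutation_rate),
    )

    caller = GenotypeCaller(stutter)
    units = {l.locus_id: l.unit for l in loci}
    calls = call_histograms(dataset.histograms, caller, units)
    matrix, assembly = assemble_matrix(
        calls, cells=dataset.true_genotypes.index.tolist()
    )

    min_shared = min(config.min_shared, max(1, matrix.shape[1] // 4))
    dm = mutation_count_distance(matrix, min_shared=min_shared)
    nj_tree = build_nj_tree(dm)
    founder = reference_genotype(loci)
    rooted = root_tree(nj_tree, matrix, genotype=founder, dm=dm, min_shared=min_shared)

    replicates = bootstrap_replicates(
        matrix,
        keep_fraction=config.keep_fraction,
        n_replicates=config.n_replicates,
        seed=np.random.default_rng(s_boot),
        min_shared=min_shared,
    )

    n_leaves = matrix.shape[0]
    level_support = [
        tbe_for_split(
            side if len(side) <= n_leaves - len(side)
            else frozenset(matrix.index) - side,
            replicates,
            n_leaves,
        )
        for side in tree.level_splits((1, 2))
    ]
    tree_support = compute_tbe(nj_tree, replicates)

    mu_hat = estimate_mutation_rate(
        matrix, founder, tree.leaf_depths_generations()
    )
    accuracy = _genotype_accuracy(matrix, dataset.true_genotypes)

    return BenchmarkResult(
        config=config,
        truth=dataset,
        matrix=matrix,
        distance=dm,
        tree=nj_tree,
        rooted_tree=rooted,
        replicates=replicates,
        level_split_support=level_support,
        tree_support=tree_support,
        mutation_rate_estimate=mu_hat,
        call_rate=assembly.call_rate,
        genotype_accuracy=accuracy,
    )
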