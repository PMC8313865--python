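"""Ground-truth lineage simulation: clonal-expansion trees, stepwise STR
mutation, labeled populations, and full synthetic datasets.

The benchmark emulated here is an ex vivo clonal-expansion experiment: a
founding cell is cultured, single cells are re-sampled every 12-15
divisions and expanded again, over nine sampling levels.  Mutations follow
the stepwise mutation model: each locus independently gains or loses one
repeat unit with a small probability per sampling generation (default
1e-3, expressed per sampling level, with a per-division alternative behind
a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .histogram import RepeatHistogram
from .panel import StrLocus
from .stutter import StutterModel, sample_histogram


# ---------------------------------------------------------------------------
# Mutation model
# ---------------------------------------------------------------------------

@dataclass
class MutationModel:
    """Stepwise STR mutation model.

    ``rate_per_generation`` is the probability that a locus mutates over one
    sampling generation (default 1e-3).  When ``per_division`` is set, each
    cell division instead mutates a locus with ``rate_per_generation``
    divided by the mean number of divisions per sampling level, so the
    per-level expectation is unchanged.  Steps are +/-1 repeat unit with the
    given probabilities; repeat counts never drop below 1.
    """

    rate_per_generation: float = 1e-3
    step_probs: dict[int, float] = field(default_factory=lambda: {-1: 0.5, 1: 0.5})
    per_division: bool = False
    rate_scaling: "callable | None" = None  # (unit, repeat_length) -> multiplier

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate_per_generation <= 1.0:
            raise ValueError("rate_per_generation must lie in [0, 1]")
        total = sum(self.step_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("step probabilities must sum to 1")


# ---------------------------------------------------------------------------
# True trees
# ---------------------------------------------------------------------------

@dataclass
class SampleNode:
    """One sampled cell in the expansion experiment."""

    name: str
    level: int
    divisions_from_parent: int = 0
    children: list["SampleNode"] = field(default_factory=list)
    label: str | None = None

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class TrueTree:
    """Rooted ground-truth tree over sampled cells.

    Leaves are the genotyped cells; internal nodes are earlier sampling
    events.  Edges span exactly one sampling level and record the number of
    cell divisions drawn for that level.
    """

    root: SampleNode
    labels: dict[str, str] = field(default_factory=dict)

    def nodes(self) -> list[SampleNode]:
        return list(self.root.walk())

    def leaves(self) -> list[SampleNode]:
        return [n for n in self.root.walk() if not n.children]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def leaf_depths_divisions(self) -> dict[str, int]:
        depths = {}

        def rec(node: SampleNode, acc: int) -> None:
            acc += node.divisions_from_parent
            if not node.children:
                depths[node.name] = acc
            for c in node.children:
                rec(c, acc)

        rec(self.root, 0)
        return depths

    def leaf_depths_generations(self) -> dict[str, int]:
        depths = {}

        def rec(node: SampleNode, acc: int) -> None:
            if not node.children:
                depths[node.name] = acc
            for c in node.children:
                rec(c, acc + 1)

        rec(self.root, 0)
        return depths

    def level_splits(self, levels: tuple[int, ...] = (1, 2)) -> list[frozenset]:
        """Leaf bipartition sides induced by nodes at the given sampling
        levels (non-trivial splits only)."""
        all_leaves = frozenset(self.leaf_names())
        splits = []
        for node in self.root.walk():
            if node.level in levels:
                side = frozenset(
                    n.name for n in node.walk() if not n.children
                )
                if 2 <= len(side) <= len(all_leaves) - 2:
                    splits.append(side)
        return splits

    def to_dendropy(
        self,
        taxon_namespace: dendropy.TaxonNamespace | None = None,
        branch_length: str = "generations",
    ) -> dendropy.Tree:
        """Export as a rooted dendropy tree; unary chain nodes (levels with
        a single re-sampled cell) are collapsed into single edges."""
        tns = taxon_namespace or dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=tns)
        tree.is_rooted = True

        def edge_len(node: SampleNode) -> float:
            if branch_length == "divisions":
                return float(node.divisions_from_parent)
            return 1.0

        def build(node: SampleNode, parent: dendropy.Node, acc_len: float) -> None:
            length = acc_len + edge_len(node)
            if len(node.children) == 1:
                build(node.children[0], parent, length)
                return
            dnode = dendropy.Node()
            dnode.edge.length = length
            parent.add_child(dnode)
            if not node.children:
                dnode.taxon = tns.require_taxon(label=node.name)
            for c in node.children:
                build(c, dnode, 0.0)

        seed = tree.seed_node
        if len(self.root.children) == 1:
            # collapse the root chain as well
            node = self.root
            while len(node.children) == 1:
                node = node.children[0]
            for c in node.children:
                build(c, seed, 0.0)
            if not node.children:
                seed.taxon = tns.require_taxon(label=node.name)
        else:
            for c in self.root.children:
                build(c, seed, 0.0)
        return tree

    def newick(self) -> str:
        return self.to_dendropy().as_string(schema="newick").strip()


def simulate_benchmark_tree(
    levels: int = 9,
    divisions_per_level: tuple[int, int] = (12, 15),
    branching: int = 2,
    max_leaves: int = 32,
    seed: np.random.Generator | int | None = None,
) -> TrueTree:
    """Simulate the clonal-expansion sampling tree.

    Starting from the founding cell, every sampling level re-samples
    ``branching`` single cells per current lineage until ``max_leaves``
    lineages exist, after which one cell per lineage is carried forward.
    Each edge spans one sampling level and records a division count drawn
    uniformly from ``divisions_per_level`` (inclusive).
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if branching < 1:
        raise ValueError("branching must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = divisions_per_level
    root = SampleNode(name="root", level=0)
    frontier = [root]
    for level in range(1, levels + 1):
        next_frontier = []
        for node in frontier:
            n_children = branching if len(frontier) * branching <= max_leaves else 1
            for i in range(n_children):
                child = SampleNode(
                    name=f"{node.name}.{i}" if node.name != "root" else f"c{i}",
                    level=level,
                    divisions_from_parent=int(rng.integers(lo, hi + 1)),
                )
                node.children.append(child)
                next_frontier.append(child)
        frontier = next_frontier
    return TrueTree(root=root)


def simulate_labeled_populations(
    group_spec: dict[str, tuple[int, int]],
    levels: int | None = None,
    divisions_per_level: tuple[int, int] = (12, 15),
    seed: np.random.Generator | int | None = None,
) -> TrueTree:
    """Simulate labeled cell populations diverging at given ancestral depths.

    ``group_spec`` maps a population label to ``(n_cells, divergence_level)``:
    the group's ancestor branches off the backbone lineage at that sampling
    level and then expands (binary splits, one level per split) until it
    carries ``n_cells`` leaves.  Requires at least two groups.
    """
    if len(group_spec) < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(seed)
    lo, hi = divisions_per_level

    def divs() -> int:
        return int(rng.integers(lo, hi + 1))

    max_depth = max(d for _, d in group_spec.values())
    root = SampleNode(name="root", level=0)
    backbone = [root]
    for level in range(1, max_depth + 1):
        node = SampleNode(
            name=f"bb{level}", level=level, divisions_from_parent=divs()
        )
        backbone[-1].children.append(node)
        backbone.append(node)

    labels: dict[str, str] = {}
    for label in sorted(group_spec):
        n_cells, depth = group_spec[label]
        if n_cells < 1:
            raise ValueError(f"group {label}: n_cells must be >= 1")
        anchor = backbone[depth]
        ancestor = SampleNode(
            name=f"{label}_anc",
            level=depth + 1,
            divisions_from_parent=divs(),
        )
        anchor.children.append(ancestor)
        # balanced binary expansion to n_cells leaves
        frontier = [ancestor]
        while len(frontier) < n_cells:
            frontier.sort(key=lambda n: (n.level, n.name))
            node = frontier.pop(0)
            for i in range(2):
                child = SampleNode(
                    name=f"{node.name}.{i}",
                    level=node.level + 1,
                    divisions_from_parent=divs(),
                )
                node.children.append(child)
                frontier.append(child)
        for i, node in enumerate(sorted(frontier, key=lambda n: n.name)):
            leaf = SampleNode(
                name=f"{label}_{i}",
                level=node.level + 1,
                divisions_from_parent=divs(),
            )
            node.children.append(leaf)
            labels[leaf.name] = label
    return TrueTree(root=root, labels=labels)


# ---------------------------------------------------------------------------
# Genotype evolution
# ---------------------------------------------------------------------------

def make_panel(
    n_loci: int,
    unit: str = "AC",
    repeat_range: tuple[int, int] = (11, 17),
    flank_length: int = 20,
    seed: np.random.Generator | int | None = None,
) -> list[StrLocus]:
    """Synthesize a mono-allelic panel of STR loci with random flanks.

    Reference repeat counts are drawn uniformly from ``repeat_range``
    (inclusive); flanks are random sequences so that read-mapping anchors
    are (almost surely) locus-specific.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    loci = []
    width = len(str(max(n_loci - 1, 1)))
    for i in range(n_loci):
        count = int(rng.integers(repeat_range[0], repeat_range[1] + 1))
        start = int(rng.integers(1_000, 50_000_000))
        flank_l = "".join(rng.choice(bases, size=flank_length))
        flank_r = "".join(rng.choice(bases, size=flank_length))
        loci.append(
            StrLocus(
                locus_id=f"L{i:0{width}d}",
                chrom="chrX",
                start=start,
                end=start + len(unit) * count,
                unit=unit,
                ref_repeat_count=count,
                flank_left=flank_l,
                flank_right=flank_r,
            )
        )
    return loci


def _mean_divisions(divisions_per_level: tuple[int, int] = (12, 15)) -> float:
    return (divisions_per_level[0] + divisions_per_level[1]) / 2.0


def evolve_genotypes(
    tree: TrueTree,
    loci: list[StrLocus],
    model: MutationModel | None = None,
    seed: np.random.Generator | int | None = None,
    diploid: bool = False,
    initial_separation: int = 5,
) -> pd.DataFrame:
    """Evolve repeat counts down the tree; returns leaves x loci integers.

    Along each edge (one sampling level) every locus mutates independently
    with ``rate_per_generation`` (or per division when the model says so),
    stepping +/-1 unit and never dropping below one repeat.  In diploid mode
    each locus carries two allele series, columns ``<locus>/a`` starting at
    the reference and ``<locus>/b`` starting ``initial_separation`` units
    higher; the default is haploid (X/Y loci in male samples).
    """
    model = model or MutationModel()
    rng = np.random.default_rng(seed)
    units = [l.unit for l in loci]
    ref = np.array([l.ref_repeat_count for l in loci], dtype=np.int64)
    if diploid:
        columns = [f"{l.locus_id}/a" for l in loci] + [f"{l.locus_id}/b" for l in loci]
        root_genotype = np.concatenate([ref, ref + initial_separation])
        units = units + units
    else:
        columns = [l.locus_id for l in loci]
        root_genotype = ref
    n = root_genotype.size

    step_values = np.array(sorted(model.step_probs), dtype=np.int64)
    step_p = np.array([model.step_probs[int(v)] for v in step_values])

    if model.rate_scaling is None:
        base_rate = np.full(n, model.rate_per_generation)
    else:
        base_rate = np.array(
            [
                model.rate_per_generation * model.rate_scaling(u, int(r))
                for u, r in zip(units, root_genotype)
            ]
        )

    rows: dict[str, np.ndarray] = {}

    def mutate(genotype: np.ndarray, rounds: int) -> np.ndarray:
        g = genotype.copy()
        for _ in range(rounds):
            hit = rng.random(n) < rate_per_round
            if hit.any():
                steps = step_values[
                    rng.choice(step_values.size, size=int(hit.sum()), p=step_p)
                ]
                g[hit] = np.maximum(g[hit] + steps, 1)
        return g

    def rec(node: SampleNode, genotype: np.ndarray) -> None:
        if not node.children:
            rows[node.name] = genotype
        for child in node.children:
            if model.per_division:
                rounds = max(child.divisions_from_parent, 1)
            else:
                rounds = 1
            rec(child, mutate(genotype, rounds))

    rate_per_round = (
        base_rate / _mean_divisions() if model.per_division else base_rate
    )
    rec(tree.root, root_genotype)
    leaf_names = tree.leaf_names()
    return pd.DataFrame(
        [rows[name] for name in leaf_names], index=leaf_names, columns=columns
    )


def reference_genotype(
    loci: list[StrLocus], diploid: bool = False, initial_separation: int = 5
) -> pd.Series:
    """Founder genotype row matching :func:`evolve_genotypes` columns."""
    ref = {l.locus_id: l.ref_repeat_count for l in loci}
    if not diploid:
        return pd.Series(ref, dtype=float)
    out = {}
    for l in loci:
        out[f"{l.locus_id}/a"] = float(l.ref_repeat_count)
        out[f"{l.locus_id}/b"] = float(l.ref_repeat_count + initial_separation)
    return pd.Series(out, dtype=float)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """A simulated experiment: histograms plus the truth bundle."""

    tree: TrueTree
    loci: list[StrLocus]
    true_genotypes: pd.DataFrame
    histograms: list[RepeatHistogram]
    stutter: StutterModel
    coverage: int
    diploid: bool = False

    def histogram_index(self) -> dict[tuple[str, str], RepeatHistogram]:
        return {(h.cell_id, h.locus_id): h for h in self.histograms}

    def write(self, out_dir: str | Path) -> None:
        from .histogram import write_histograms_tsv
        from .panel import write_loci_tsv

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_histograms_tsv(self.histograms, out / "histograms.tsv")
        write_loci_tsv(self.loci, out / "panel.tsv")
        self.true_genotypes.to_csv(
            out / "true_genotypes.tsv", sep="\t", na_rep="NA", index_label="cell_id"
        )
        with open(out / "true_tree.nwk", "w") as fh:
            fh.write(self.tree.newick() + "\n")
        if self.tree.labels:
            with open(out / "labels.csv", "w") as fh:
                fh.write("cell_id,label\n")
                for cell, label in sorted(self.tree.labels.items()):
                    fh.write(f"{cell},{label}\n")


def read_labels_csv(path: str | Path) -> dict[str, str]:
    labels = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("cell_id"):
            cell, label = header.strip().split(",", 1)
            labels[cell] = label
        for line in fh:
            if not line.strip():
                continue
            cell, label = line.strip().split(",", 1)
            labels[cell] = label
    return labels


def generate_dataset(
    tree: TrueTree,
    loci: list[StrLocus],
    stutter: StutterModel,
    coverage: int = 30,
    seed: np.random.Generator | int | None = None,
    mutation_model: MutationModel | None = None,
    diploid: bool = False,
    initial_separation: int = 5,
    fraction_a: float = 0.5,
) -> Dataset:
    """Evolve genotypes and sample per cell-locus stutter histograms."""
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    rng = np.random.default_rng(seed)
    genotypes = evolve_genotypes(
        tree,
        loci,
        model=mutation_model,
        seed=rng,
        diploid=diploid,
        initial_separation=initial_separation,
    )
    histograms: list[RepeatHistogram] = []
    if coverage > 0:
        from .stutter import predict_histogram, predict_mixture

        # cache predicted distributions per (unit, genotype) for speed
        cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

        def dist_for(unit: str, alleles: tuple[int, ...]):
            key = (unit,) + alleles
            if key not in cache:
                if len(alleles) == 1:
                    d = predict_histogram(stutter, alleles[0], unit)
                else:
                    d = predict_mixture(
                        stutter, alleles[0], alleles[1], fraction_a, unit
                    )
                p = d.probabilities / d.probabilities.sum()
                cache[key] = (d.lengths, p)
            return cache[key]

        for cell in genotypes.index:
            row = genotypes.loc[cell]
            for locus in loci:
                if diploid:
                    alleles = tuple(
                        sorted(
                            (
                                int(row[f"{locus.locus_id}/a"]),
                                int(row[f"{locus.locus_id}/b"]),
                            )
                        )
                    )
                else:
                    alleles = (int(row[locus.locus_id]),)
                lengths, probs = dist_for(locus.unit, alleles)
                draws = rng.multinomial(coverage, probs)
                counts = {
                    int(l): int(c) for l, c in zip(lengths, draws) if c > 0
                }
                histograms.append(
                    RepeatHistogram(
                        cell_id=cell, locus_id=locus.locus_id, counts=counts
                    )
                )
    return Dataset(
        tree=tree,
        loci=loci,
        true_genotypes=genotypes,
        histograms=histograms,
        stutter=stutter,
        coverage=coverage,
        diploid=diploid,
    )
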