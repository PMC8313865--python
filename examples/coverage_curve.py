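"""How much sequencing coverage does a stable tree need?

Subsamples the per cell-locus read histograms of a simulated dataset to a
range of coverages, re-genotypes and re-reconstructs at each, and measures
the normalized triples distance to the tree built from full data.
"""

from strlineage.compare import coverage_curve
from strlineage.simulate import MutationModel, generate_dataset, make_panel, simulate_benchmark_tree
from strlineage.stutter import StutterModel

tree = simulate_benchmark_tree(levels=4, max_leaves=8, seed=0)
panel = make_panel(250, seed=1)
ds = generate_dataset(
    tree, panel, StutterModel(cycles=17), coverage=60, seed=2,
    mutation_model=MutationModel(rate_per_generation=2e-3),
)

table = coverage_curve(ds, coverages=[12, 20, 40, 60], n_runs_per_point=3, seed=3)
print(table.to_string(index=False))
# mean_distance is the triples distance to the full-coverage tree: it
# shrinks toward 0 as coverage rises (genotyping requires >= 10 reads, so
# coverages near that floor lose loci and destabilize the topology).
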