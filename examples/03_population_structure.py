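"""Population-structure views of a simulated cohort.

Identity-by-state distances feed a neighbor-joining tree; PCA of
standardized dosages summarizes the same differentiation; LD decay
curves show how fast r² falls with distance in each population.
"""

from sweepscan import SimulationConfig, simulate_cohort
from sweepscan import pop_structure
from sweepscan.variants_io import filter_sites_structure, ld_prune

config = SimulationConfig(chrom_lengths={"chr1": 5_000_000}, n_sites=5_000,
                          sweep_intervals=[], background_F=0.1, seed=2)
genotypes, _ = simulate_cohort(config)
filtered, _ = filter_sites_structure(genotypes)
pruned = ld_prune(filtered, window_snps=100, step_snps=10, r2_max=0.2)
print(f"sites: {genotypes.n_sites} -> {filtered.n_sites} after filters "
      f"-> {pruned.n_sites} after LD pruning")

dist = pop_structure.ibs_distance(pruned)
tree = pop_structure.neighbor_joining(dist)
domestic = {s for s, p in zip(pruned.sample_ids, pruned.populations)
            if p == "domestic"}
print(f"NJ tree splits domestic from wild: "
      f"{pop_structure.is_monophyletic(tree, domestic)}")

coords, var_exp = pop_structure.genotype_pca(pruned, n_components=2)
print(f"PC1 explains {var_exp[0]:.1%}, PC2 {var_exp[1]:.1%} of variance")
dom = coords[pruned.populations == "domestic", 0]
wld = coords[pruned.populations == "wild", 0]
print(f"PC1 centroid gap: {abs(dom.mean() - wld.mean()):.2f} "
      f"(within-population SD {max(dom.std(), wld.std()):.2f})")

curve = pop_structure.ld_decay(filtered, "wild", max_dist=100_000,
                               bin_width=20_000)
print("\nLD decay (wild population):")
for _, row in curve.iterrows():
    if row["n_pairs"]:
        print(f"  {row['bin_start']/1e3:5.0f}-{row['bin_end']/1e3:5.0f} kb: "
              f"mean r2 = {row['mean_r2']:.3f}  ({int(row['n_pairs'])} pairs)")
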