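"""Gene classes and set statistics: k-means, thresholds, overlap, Tukey.

Clusters genes by RNAPII occupancy (k=3), takes the high-occupancy class,
intersects it with the set of genes losing RNAPII in the remodeller-null
genotype, tests the overlap with the hypergeometric distribution, and
compares occupancy changes between classes with Tukey's HSD.
"""

from nucdis import (
    GeneratorConfig,
    generate_cohort,
    hypergeometric_overlap,
    kmeans_cluster,
    select_extreme_cluster,
    threshold_gene_set,
    tukey_pairwise,
)

cohort = generate_cohort(GeneratorConfig(n_genes=1500, seed=4), tracks=False)
table = cohort.gene_table.values

clusters = kmeans_cluster(table["pol_wt"], k=3, seed=0)
high = select_extreme_cluster(clusters, "highest")
print(f"k=3 occupancy classes, sizes: {clusters.cluster_sizes().tolist()}")
print(f"high-occupancy class: {len(high)} genes")

down = threshold_gene_set(table["dpol_fft3"], cutoff=-0.1, direction="le",
                          name="pol_down_in_fft3_null")
print(f"genes with RNAPII change <= -0.1 in the remodeller-null: {len(down)}")

overlap = hypergeometric_overlap(high, down)
print(f"overlap {overlap.n_overlap}/{min(overlap.n_a, overlap.n_b)}, "
      f"hypergeometric p = {overlap.p_value:.3g}")
print("a small p means RNAPII loss concentrates in highly transcribed genes.")

groups = {
    f"class{lab}": table.loc[clusters.labels == lab, "dpol_fft3"].to_numpy()
    for lab in sorted(clusters.labels.unique())
}
tukey = tukey_pairwise(groups)
print("Tukey HSD on RNAPII change between classes:")
for row in tukey.itertuples(index=False):
    print(f"  {row.group1} vs {row.group2}: mean diff {row.mean_diff:+.3f}, "
          f"adjusted p = {row.p_adj:.3g}")
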