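"""Proteome-composition similarity, UPGMA tree and gene classes by hand.

Works directly with per-locus sets of homology-group ids, bypassing
sequence parsing, to show the numeric core of the pipeline.
"""

from locusplot import classify_groups, cut_clusters, similarity_matrix, to_newick, upgma
from locusplot.proteome import analyze, cluster_membership

group_sets = {
    "phageA": {"cap", "ter", "pol", "fib", "hol"},
    "phageB": {"cap", "ter", "pol", "fib", "lys"},
    "phageC": {"cap", "ter", "pol"},  # deletion variant of A/B
    "phageD": {"int", "exc", "rep"},  # unrelated proteome
}

matrix = similarity_matrix(group_sets)
analyze(matrix, max_distance=0.75)

print("similarity matrix (fraction of shared homologous protein groups):")
for i, lid in enumerate(matrix.locus_ids):
    row = "  ".join(f"{matrix.S[i, j]:.2f}" for j in range(len(matrix.locus_ids)))
    print(f"  {lid}: {row}")
print(f"UPGMA dendrogram: {to_newick(matrix.dendrogram)}")
print(f"row order: {matrix.leaf_order}")
print(f"sequence clusters: {matrix.cluster_of}")

classes = classify_groups(cluster_membership(matrix.cluster_of), group_sets)
for cluster, table in classes.items():
    for gid, (f, cls) in sorted(table.items()):
        print(f"  {cluster} {gid}: presence {f:.2f} -> {cls}")

# phageC scores S(A,C) = (3/5 + 3/3)/2 = 0.80 against A despite its smaller
# proteome: the symmetric mean of directional shared fractions keeps a
# deletion variant close to its parent (Jaccard would give 0.60).
# phageD shares nothing, forms its own cluster, and every group there is
# conserved by the singleton-cluster rule.
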