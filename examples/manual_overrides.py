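"""Manual overrides: re-feeding a run's own annotation tables.

Every automatic decision (row order, clusters, group ids, classes, labels)
is emitted as a table; editing those tables and re-running with clustering
disabled gives full manual control.  Here the row order is flipped.
"""

from pathlib import Path

from locusplot import make_locus_set, run_comparative

truth = make_locus_set(n_loci=3, seed=19, outdir="example_input")
first = run_comparative(gb=[truth.files["genbank"]], outdir="run1")
print(f"automatic order: {first.order}")

# flip the order column of the emitted locus table
table = Path(first.outputs["locus_table"])
lines = table.read_text().splitlines()
header, rows = lines[0], lines[1:]
flipped = []
for row in rows:
    cols = row.split("\t")
    cols[1] = str(len(rows) + 1 - int(cols[1]))
    flipped.append("\t".join(cols))
edited = Path("run1/locus_table_flipped.tsv")
edited.write_text("\n".join([header] + flipped) + "\n")

second = run_comparative(
    gb=[truth.files["genbank"]],
    outdir="run2",
    feature_table=first.outputs["feature_table"],
    locus_table=edited,
    no_cluster=True,
)
print(f"overridden order: {second.order}")
# the table order wins over the dendrogram; everything else is unchanged
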