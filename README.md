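# locusplot

Comparative visualization of annotated genomic loci — whole phage and
plasmid genomes, or windows of larger prokaryotic genomes — as
publication-quality vector PDF figures, with the analysis steps a
comparative-genomics figure actually needs built in:

* **Homology grouping.** Every encoded protein is assigned to a homology
  group, by a built-in greedy clusterer (global-alignment identity and
  bidirectional coverage thresholds), a predefined group table, or an
  adapter around an external clustering tool.
* **Proteome-composition ordering.** For loci *i, j* with group sets
  *G<sub>i</sub>, G<sub>j</sub>*, the similarity
  *S<sub>ij</sub> = ½ (|G<sub>i</sub>∩G<sub>j</sub>|/|G<sub>i</sub>| +
  |G<sub>i</sub>∩G<sub>j</sub>|/|G<sub>j</sub>|)* measures the fraction of
  shared homologous proteins; rows are ordered by the leaf order of a UPGMA
  (average-linkage) tree on *D = 1 − S*, and flat sequence clusters come
  from a cophenetic-distance cut.
* **Gene classes.** Within each sequence cluster, a group present in a
  fraction *f* of member loci is **conserved** (*f* ≥ 0.75),
  **variable** (*f* ≤ 0.25) or **intermediate** — the per-cluster analogue
  of core / shell / cloud in pangenomics. Variable groups are highlighted
  with distinct colours; conserved genes are grey and connected across
  adjacent rows by homology lines.
* **Figure conventions.** Labels are placed greedily without overlaps
  (slide, promote to a second tier, or drop); hypothetical-protein labels
  are hidden; conserved-group labels appear only at their first occurrence;
  functional categories (PHROG-style) are drawn as coloured strips; a
  compact mode replaces per-row axes with a single 1-2-5 scale bar.
* **Genome browser mode.** A single locus stacked over GC-content and
  GC-skew profiles (centred at their mean, positive and negative deviations
  filled in different colours) and any number of coverage tracks from
  bedGraph or bigWig, with image-width-aware moving-average smoothing.

Inputs are GenBank flat files or "extended GFF" (GFF3 with the sequence
appended after `##FASTA`, as written by prokka/pharokka), plus optional
tab-separated tables for manual control of order, clusters, groups, classes
and labels. Every automatic decision is emitted back as a table, so a run
can be reproduced and hand-edited. A synthetic-data generator
(`locusplot.synthetic`) builds phage-like locus sets with known core/cargo
ground truth, so the whole pipeline is testable without downloads.

## Worked example

```python
from locusplot import make_locus_set, run_comparative

truth = make_locus_set(n_loci=4, n_core=10, n_cargo_pool=8,
                       cargo_per_locus=2, seed=11)
result = run_comparative(loci=truth.loci, outdir="example_output")
print(result.assignment.n_groups(), result.order)
```

Running `python examples/comparative_figure.py` prints:

```
loci: ['L001', 'L002', 'L003', 'L004']
protein homology groups: 18
row order (UPGMA leaf order): ['L001', 'L002', 'L003', 'L004']
group classes: {'conserved': 10, 'intermediate': 0, 'variable': 8}
outputs: ['dendrogram.nwk', 'feature_table.tsv', 'figure.pdf', 'group_classes.tsv', 'locus_table.tsv', 'similarity.tsv']
```

The 18 groups are the 10 core families (present in all four loci, hence
conserved) and 8 unique cargo families (present in one locus each, hence
variable). `figure.pdf` shows four rows of gene arrows on a shared bp
scale: grey conserved genes joined by homology ribbons, coloured cargo, and
labels placed without overlap.

The other scripts in `examples/` demonstrate the numeric core on hand-built
group sets (`proteome_similarity.py`), the browser mode with a simulated
coverage peak (`genome_browser.py`), and manual override tables
(`manual_overrides.py`).

The same pipelines are available from the shell:

```sh
locusplot comparative --gb genomes/ -o out --compact
locusplot browser --gff genome.gff --bedgraph cov.bedGraph --window 1:40000 -o out
```

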