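# Methods

This note documents the models, algorithms and numerical choices behind
locusplot, the parameters that matter, and what the synthetic-data tests do
and do not demonstrate.

## Input model and coordinates

A *locus* is one annotated nucleotide sequence displayed as one row.
Internally all coordinates are 0-based half-open; GenBank and GFF3 1-based
inclusive coordinates are converted at the parsing boundary, which keeps
wrapping and scaling arithmetic uniform. A feature or display region on a
circular sequence may span the origin; it is stored as a single object with
a wrap flag (never split in two), so circular sequences draw continuously
across the seam with no gap between end and start coordinates.

CDS translations are taken from the `/translation` qualifier when present
and otherwise computed under translation table 11, with the trailing stop
removed and the initiator codon rendered as methionine when it is a
table-11 start codon (TTG/CTG/ATT/ATC/ATA/ATG/GTG). Internal stops produce
a warning but keep the feature, since draft annotations contain them.
Labels are read from `product`, falling back to `Name` in GFF; a feature is
flagged *hypothetical* when its label matches any of the configurable
patterns (`hypothetical protein`, `unknown function`, `uncharacterized`,
case-insensitive substrings) or is empty.

## Homology grouping

The built-in clusterer is a deterministic greedy set-cover procedure sized
for desk-scale inputs (up to a few thousand proteins). Proteins are
processed by decreasing length (ties by id); each joins the first existing
representative whose global alignment reaches both thresholds, else founds
a new group. Scoring: match 1, mismatch 0, gap open −10, gap extend −1;
identity is exact matches divided by alignment columns *including gap
columns* (unambiguous and directly testable); coverage of a sequence is the
fraction of its residues in residue-vs-residue columns, and both sequences
must reach the coverage threshold. Defaults `min_identity = 0.35`,
`min_coverage = 0.7` mimic common remote-homologue clustering settings.
Two shortcuts change nothing about the result: byte-identical sequences
join the same group without alignment, and a pair whose length ratio makes
bidirectional coverage unreachable (`min_len < min_coverage × max_len`) is
skipped. Greedy clustering is order-dependent near the thresholds; that is
accepted and pinned down by fixed tie-breaking. Predefined group tables
bypass clustering entirely (uncovered proteins become singletons with a
warning), and an external-tool adapter runs any clusterer that consumes
FASTA and emits a representative/member TSV.

## Proteome composition, ordering, classes

The similarity between two loci is the symmetric mean of directional shared
fractions, S = ½(|G∩H|/|G| + |G∩H|/|H|). This was an open design choice:
plain Jaccard penalises nested proteomes, whereas the symmetric mean keeps
a deletion variant close to its parent genome, matching how related phages
should group visually; `similarity_formula = jaccard` is available. A
locus with an empty proteome has similarity 0 to everything (and never
perturbs entries among other loci). D = 1 − S.

UPGMA is implemented directly because the display contract needs exact
determinism: merge heights are half the average inter-cluster distance
(ultrametric, so the cophenetic distance of two leaves is twice the height
of their lowest common ancestor), exact ties merge the smallest active
index pair, and at every node the child containing the lexicographically
smallest leaf is drawn first. scipy's average-linkage implementation is
used only as an independent cross-check in the tests. Flat sequence
clusters are the maximal subtrees with cophenetic diameter at most
`cluster_cut_distance` (default 0.75 — not a published value; chosen to
mirror common pangenome soft-core conventions, and exposed in config).

Within each cluster, a group's presence fraction f counts member loci
carrying at least one copy (paralogues count once — also a documented
choice, not a published rule). Classes: conserved if f ≥ 0.75, variable if
f ≤ 0.25, else intermediate; both cutoffs configurable. A singleton
cluster carries no variability evidence, so all its groups are conserved —
this avoids rainbow-colouring a lone sequence.

## Signal and property tracks

bedGraph input is expanded per base over the requested span; uncovered
bases are 0; overlapping intervals resolve last-wins with a warning
(tolerating real-world exports that overlap at chunk borders). bigWig is
read natively via pyBigWig when importable, else through a
`bigWigToBedGraph`-style converter executable.

GC content is (G+C)/(non-N bases) and GC skew (G−C)/(G+C) in a centred
window shrunk at the sequence edges (centred windows avoid the phase shift
trailing windows cause in plotted profiles); windows of only N get 0 and a
mask flag, and G+C = 0 windows give skew 0. Smoothing is a boxcar moving
average whose window is derived from the figure: with target point count
P = ⌈plot_width × points_per_unit⌉ (default 2 points per canvas unit), the
window is w = max(1, ⌊span/P⌋), and the smoothed series is sampled at
window centres so that when w divides the span the samples are exact block
means and the track mean is preserved. Property tracks are then centred at
their mean; the raw mean/min/max are kept for the corner annotation, and
positive and negative deviations are filled in different colours.

## Layout

All rows share one bp-to-unit scale (the widest row spans the usable
width), so gene lengths are comparable across rows; regions of one locus
are laid left-to-right with a fixed gap, each mapped affinely. Gene arrows
point with the strand, degrade to triangles when shorter than the head
length, and get a flat cut edge where clipped by the display window.

Label rules follow the figure conventions: hypothetical labels hidden;
conserved-group labels shown only at the first occurrence in reading order
(top row, then left-to-right) since homology lines mark later occurrences;
variable/intermediate labels shown; a per-feature `show_label` override
beats everything. Placement is greedy and two-tiered: preferred slot
centred above the feature; on collision the box slides up to half the
feature's width (candidate shifts on a fixed grid, nearest first); then it
is promoted one label-height up with a leader line; if that also fails the
label is dropped and reported. Non-overlap among visible labels therefore
holds by construction and is verified exhaustively in tests.

Homology connectors are straight-edged quadrilaterals drawn beneath the
arrows, only between vertically adjacent rows (longer chains are conveyed
transitively); when a group has several copies in a row the pair with the
smallest x-midpoint distance is joined. The compact mode hides per-row
axes and category strips and adds a scale bar: the largest 1-2-5 × 10^k bp
length occupying at most 25 % of the canvas width (fraction configurable).
Browser-mode panels stack top-to-bottom: category strip and gene map, GC
content, GC skew, then signal tracks in input order.

## Rendering

Output is a single-page PDF 1.4 with uncompressed content streams, base-14
Helvetica fonts and caller-pinned metadata, written by a small canvas class
in the package. This makes rendering a pure function of layout and style —
identical inputs give byte-identical files (the test suite pins a golden
hash) — and keeps every label a real text object, editable downstream and
recoverable from the content stream for verification. An SVG mirror of the
same geometry is provided for convenience. Group colours use golden-angle
hue stepping from a seed: n highlighted groups occupy an even grid of n hue
slots (pairwise separation exactly 360/n degrees) visited in golden-angle
order, at fixed saturation/value. In the default `variable` highlight mode
variable (and intermediate) groups get distinct colours and conserved
groups share one grey; `conserved` mode inverts the emphasis.

## Synthetic data: what it shows and what it does not

The generator emulates the *structure* the pipeline reasons about: blocks
of loci with identical core proteins in conserved order, cargo families
placed in known subsets of loci, random intergenic spacers, a fraction of
hypothetical labels, and optional point mutations for clustering stress
tests. Signal fixtures are Gaussian bumps plus non-negative half-normal
noise with an analytic ground-truth profile. Expected classes and blocks
are computed from the construction, so recovery tests have exact answers.
The genomes are deliberately cartoonish — uniform codon usage, no operon
structure, no mosaic recombination, no annotation errors — so passing
tests demonstrate the correctness of the clustering/ordering/
classification/layout machinery, not annotation quality or clustering
sensitivity on real sequence divergence.

Test and acceptance problem sizes (200 random matrices at n ≤ 12, 100
UPGMA trials at n ≤ 6, 20 recovery seeds, 50 layout figures, and a
78-locus × 60-gene many-genome run) were chosen as the smallest sizes that
still exercise every code path and tie-break; the many-genome run mirrors
a realistic full-collection figure at desk scale.

## Known limitations

Multi-exon eukaryotic gene models beyond simple two-part joins are out of
scope, as are EMBL input, curved connector ribbons, interactive output,
per-row independent zoom, and HMM-based functional annotation (functional
categories are ingested from annotations or tables instead). The greedy
clusterer is not a substitute for profile-based methods on remote
homologues; the external-adapter hook exists for that. Per-base track
expansion assumes phage/plasmid-scale spans (up to a few hundred kb);
chromosome-scale tracks should be windowed first.
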