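"""Single-genome browser figure: gene map over GC and coverage tracks.

Generates one synthetic genome and a mock DNA-seq coverage track with a
single peak, then stacks gene map, GC content, GC skew and the coverage
profile into one browser-mode PDF.
"""

from locusplot import make_locus_set, make_signal, run_browser

truth = make_locus_set(n_loci=1, n_core=12, cargo_per_locus=3, seed=7)
locus = truth.loci[0]

make_signal(
    locus.length_bp,
    peaks=[(locus.length_bp // 2, 300, 40.0)],
    noise_sd=2.0,
    seed=1,
    locus_id=locus.locus_id,
    out_path="coverage.bedGraph",
)

layout, outputs = run_browser(
    locus=locus, bedgraph=["coverage.bedGraph"], outdir="example_output"
)

print(f"locus: {locus.locus_id}, {locus.length_bp} bp")
for panel in layout.track_panels:
    print(f"track panel: {panel.name:<12} ({panel.kind}); {panel.annotation}")
print(f"figure: {outputs['pdf']}")

# GC content and GC skew are centred at their average value (the annotation
# keeps the raw range and mean for the corner label); the coverage track
# peaks at the simulated peak centre.
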