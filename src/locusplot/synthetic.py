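"""Synthetic phage-like locus sets and signal tracks with known ground truth.

Every pipeline stage is testable without downloads: the generator builds
small circular genomes whose proteomes follow a known core/cargo structure
(core protein families present in every locus of a block, cargo families in
known subsets), writes them in the same formats the pipeline reads
(GenBank, extended GFF, bedGraph), and emits a truth table giving each
feature's family and the class it should receive for a given pair of
classification cutoffs.

Core proteins are byte-identical across loci by default so that homology
grouping is threshold-independent; a mutation-rate knob introduces point
substitutions for clustering stress tests.  These genomes are deliberately
cartoonish — uniform codon usage, random spacers, no operon structure —
which is irrelevant for the geometry, clustering and classification
contracts they exercise, but means they say nothing about annotation
quality on real genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import Feature, Locus

_AA = "ACDEFGHIKLMNPQRSTVWY"
# one fixed codon per amino acid (standard-code consistent, table 11 safe)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_LABEL_POOL = (
    "terminase large subunit", "portal protein", "major capsid protein",
    "head scaffolding protein", "tail fiber protein", "tape measure protein",
    "baseplate protein", "holin", "endolysin", "DNA polymerase",
    "helicase", "primase", "integrase", "excisionase", "anti-repressor",
    "single-stranded DNA binding protein", "recombinase", "exonuclease",
    "tail sheath protein", "neck protein",
)

_CATEGORY_POOL = (
    "head and packaging", "tail", "lysis",
    "DNA, RNA and nucleotide metabolism", "other",
)


@dataclass
class LocusSetTruth:
    """Generated loci plus the ground truth they encode."""

    loci: list[Locus]
    family_of: dict[str, str]  # feature_id -> family id
    expected_class: dict[str, str]  # family id -> conserved/intermediate/variable
    expected_cluster: dict[str, str]  # locus_id -> block label
    files: dict[str, Path] = field(default_factory=dict)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length - 1))
    return "M" + body


def _mutate(rng: np.random.Generator, protein: str, rate: float) -> str:
    if rate <= 0:
        return protein
    chars = list(protein)
    for i in range(1, len(chars)):  # keep the initiator M
        if rng.random() < rate:
            chars[i] = _AA[int(rng.integers(0, len(_AA)))]
    return "".join(chars)


def _cds_nt(protein: str) -> str:
    return "".join(_CODON[a] for a in protein) + "TAA"


def make_locus_set(
    n_loci: int = 4,
    n_core: int = 10,
    n_cargo_pool: int = 8,
    cargo_per_locus: int = 2,
    gene_len_range: tuple[int, int] = (60, 200),  # protein length in aa
    seed: int = 1,
    n_blocks: int = 1,
    mutation_rate: float = 0.0,
    hypothetical_fraction: float = 0.25,
    category_fraction: float = 0.5,
    outdir: Optional[str | Path] = None,
    conserved_cutoff: float = 0.75,
    variable_cutoff: float = 0.25,
) -> LocusSetTruth:
    """Generate circular phage-like loci with a known core/cargo structure.

    Each block of loci carries its own set of ``n_core`` core families
    (identical protein sequences, conserved gene order) plus
    ``cargo_per_locus`` genes drawn round-robin from a block-specific cargo
    pool, so each cargo family lands in a known subset of loci.  With
    ``n_blocks=2`` the blocks share no families at all and form two exact
    similarity blocks.  The expected class of each family follows from its
    presence fraction and the supplied cutoffs.

    When ``outdir`` is given, GenBank and extended-GFF files plus a truth
    TSV are written there (same content, byte-deterministic for a seed).
    """
    if n_loci < 1 or n_core < 0:
        raise ValueError("need n_loci >= 1 and n_core >= 0")
    if n_blocks < 1 or n_blocks > n_loci:
        raise ValueError("n_blocks must be in [1, n_loci]")
    if cargo_per_locus > 0 and n_cargo_pool < cargo_per_locus:
        raise ValueError(
            "n_cargo_pool must be >= cargo_per_locus so a locus never draws "
            "the same cargo family twice (presence counts loci, not copies)"
        )
    rng = np.random.default_rng(seed)
    lo_aa, hi_aa = gene_len_range
    if not (10 <= lo_aa <= hi_aa):
        raise ValueError("gene_len_range must satisfy 10 <= lo <= hi")

    block_of_locus = [i * n_blocks // n_loci for i in range(n_loci)]
    block_sizes = [block_of_locus.count(b) for b in range(n_blocks)]

    # family proteins, per block
    core_fams: dict[tuple[int, int], str] = {}
    cargo_fams: dict[tuple[int, int], str] = {}
    for b in range(n_blocks):
        for k in range(n_core):
            core_fams[(b, k)] = _random_protein(
                rng, int(rng.integers(lo_aa, hi_aa + 1))
            )
        for k in range(n_cargo_pool):
            cargo_fams[(b, k)] = _random_protein(
                rng, int(rng.integers(lo_aa, hi_aa + 1))
            )

    cargo_presence: dict[tuple[int, int], int] = {}
    loci: list[Locus] = []
    family_of: dict[str, str] = {}
    expected_cluster: dict[str, str] = {}
    fam_labels: dict[str, tuple[str, bool, Optional[str]]] = {}

    def fam_meta(fam_id: str) -> tuple[str, bool, Optional[str]]:
        if fam_id not in fam_labels:
            hyp = rng.random() < hypothetical_fraction
            label = (
                "hypothetical protein"
                if hyp
                else str(_LABEL_POOL[int(rng.integers(0, len(_LABEL_POOL)))])
            )
            cat = (
                str(_CATEGORY_POOL[int(rng.integers(0, len(_CATEGORY_POOL)))])
                if rng.random() < category_fraction
                else None
            )
            fam_labels[fam_id] = (label, hyp, cat)
        return fam_labels[fam_id]

    cargo_cursor = [0] * n_blocks
    for li in range(n_loci):
        b = block_of_locus[li]
        lid = f"L{li + 1:03d}"
        expected_cluster[lid] = f"B{b + 1}"
        genes: list[tuple[str, str]] = []  # (family_id, protein)
        for k in range(n_core):
            prot = _mutate(rng, core_fams[(b, k)], mutation_rate)
            genes.append((f"B{b + 1}_CORE{k + 1:03d}", prot))
        for _ in range(cargo_per_locus):
            k = cargo_cursor[b] % n_cargo_pool
            cargo_cursor[b] += 1
            cargo_presence[(b, k)] = cargo_presence.get((b, k), 0) + 1
            genes.append((f"B{b + 1}_CARGO{k + 1:03d}", cargo_fams[(b, k)]))
        # assemble the nucleotide sequence: spacer, gene, spacer, gene, ...
        seq_parts: list[str] = []
        features: list[Feature] = []
        pos = 0
        for gi, (fam, prot) in enumerate(genes):
            spacer = "".join(
                "ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(20, 120)))
            )
            seq_parts.append(spacer)
            pos += len(spacer)
            nt = _cds_nt(prot)
            strand = "+" if rng.random() < 0.8 else "-"
            if strand == "-":
                comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
                nt_seq = "".join(comp[c] for c in reversed(nt))
            else:
                nt_seq = nt
            fid = f"{lid}_g{gi + 1:03d}"
            label, hyp, cat = fam_meta(fam)
            features.append(
                Feature(
                    feature_id=fid,
                    type="CDS",
                    start=pos,
                    end=pos + len(nt),
                    strand=strand,
                    label=label,
                    protein_seq=prot,
                    category=cat,
                    hypothetical=hyp,
                )
            )
            family_of[fid] = fam
            seq_parts.append(nt_seq)
            pos += len(nt)
        tail = "".join(
            "ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(30, 150)))
        )
        seq_parts.append(tail)
        sequence = "".join(seq_parts)
        loci.append(
            Locus(
                locus_id=lid,
                length_bp=len(sequence),
                sequence=sequence,
                description=f"synthetic phage {lid}",
                circular=True,
                features=features,
            )
        )

    # expected class per family from its presence fraction within its block
    expected_class: dict[str, str] = {}
    for b in range(n_blocks):
        size = block_sizes[b]
        for k in range(n_core):
            fam = f"B{b + 1}_CORE{k + 1:03d}"
            expected_class[fam] = _class_of(1.0, size, conserved_cutoff, variable_cutoff)
        for k in range(n_cargo_pool):
            count = cargo_presence.get((b, k), 0)
            if count == 0:
                continue
            fam = f"B{b + 1}_CARGO{k + 1:03d}"
            expected_class[fam] = _class_of(
                count / size, size, conserved_cutoff, variable_cutoff
            )

    truth = LocusSetTruth(
        loci=loci,
        family_of=family_of,
        expected_class=expected_class,
        expected_cluster=expected_cluster,
    )
    if outdir is not None:
        from .annotation_io import write_extended_gff, write_genbank

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gb = outdir / "loci.gbk"
        gff = outdir / "loci.gff"
        write_genbank(loci, gb)
        write_extended_gff(loci, gff)
        tsv = outdir / "truth.tsv"
        lines = ["feature_id\tlocus_id\tfamily\texpected_class"]
        for locus in loci:
            for f in locus.features:
                fam = family_of[f.feature_id]
                lines.append(
                    f"{f.feature_id}\t{locus.locus_id}\t{fam}\t"
                    f"{expected_class.get(fam, '')}"
                )
        tsv.write_text("\n".join(lines) + "\n")
        truth.files = {"genbank": gb, "gff": gff, "truth": tsv}
    return truth


def _class_of(f: float, cluster_size: int, conserved_cutoff: float,
              variable_cutoff: float) -> str:
    if cluster_size == 1 or f >= conserved_cutoff:
        return "conserved"
    if f <= variable_cutoff:
        return "variable"
    return "intermediate"


# ---------------------------------------------------------------------------
# Signal fixture
# ---------------------------------------------------------------------------


def make_signal(
    locus_length: int,
    peaks: Sequence[tuple[int, float, float]] = (),
    noise_sd: float = 0.0,
    seed: int = 1,
    locus_id: str = "L001",
    out_path: Optional[str | Path] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-base Gaussian-bump coverage with optional non-negative noise.

    ``peaks`` holds (centre, width, height) triples (all inside the locus).
    Returns (noisy values, analytic profile); when ``out_path`` is set the
    noisy track is written as run-length-compressed bedGraph.
    """
    x = np.arange(locus_length, dtype=float)
    profile = np.zeros(locus_length)
    for centre, width, height in peaks:
        if not (0 <= centre < locus_length):
            raise ValueError(f"peak centre {centre} outside locus")
        profile += height * np.exp(-((x - centre) ** 2) / (2.0 * width**2))
    rng = np.random.default_rng(seed)
    noise = np.abs(rng.normal(0.0, noise_sd, size=locus_length)) if noise_sd > 0 else 0.0
    values = profile + noise
    if out_path is not None:
        from .model import Region
        from .tracks import SignalTrack, write_bedgraph

        track = SignalTrack(
            locus_id=locus_id, span=Region(0, locus_length),
            values=np.round(values, 4), kind="coverage",
        )
        write_bedgraph(track, out_path)
    return values, profile
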