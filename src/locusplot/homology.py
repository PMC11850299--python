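"""Protein homology grouping.

Every CDS protein is assigned to a homology group; one group later means one
colour and one connector identity in the figure.  Three routes share a single
contract:

* :func:`cluster_builtin` — a deterministic greedy set-cover clusterer based
  on global pairwise alignment, sized for desk-scale inputs (up to a few
  thousand proteins);
* :func:`from_table` — a user-supplied table of predefined groups;
* :func:`external_adapter` — delegation to an external clustering executable
  (e.g. an MMseqs2-style tool) through a FASTA-in / cluster-TSV-out contract.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import Align

from .annotation_io import Overrides


@dataclass
class GroupAssignment:
    """Mapping from CDS feature ids to homology-group ids."""

    groups: dict[str, str] = field(default_factory=dict)  # feature_id -> group_id
    representatives: dict[str, str] = field(default_factory=dict)
    method: str = "builtin_greedy"  # builtin_greedy | table | external

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for fid, gid in self.groups.items():
            out.setdefault(gid, []).append(fid)
        return out

    def n_groups(self) -> int:
        return len(set(self.groups.values()))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def alignment_identity_coverage(
    a: str, b: str, aligner: Optional[Align.PairwiseAligner] = None
) -> tuple[float, float, float]:
    """Global-alignment identity and per-sequence coverages for one pair.

    Identity is exact matches divided by alignment columns (gap columns
    included in the denominator).  Coverage of a sequence is the fraction of
    its residues sitting in aligned (residue-vs-residue) columns.
    """
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    columns = len(sa)
    matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    aligned = sum(1 for x, y in zip(sa, sb) if x != "-" and y != "-")
    identity = matches / columns if columns else 0.0
    cov_a = aligned / len(a) if a else 0.0
    cov_b = aligned / len(b) if b else 0.0
    return identity, cov_a, cov_b


def cluster_builtin(
    proteins: Sequence[tuple[str, str]],
    min_identity: float = 0.35,
    min_coverage: float = 0.7,
) -> GroupAssignment:
    """Greedy set-cover clustering of proteins into homology groups.

    Proteins are processed in order of decreasing length (ties broken by
    lexicographic id, mirroring the longest-sequence-as-representative
    convention of greedy sequence clusterers).  Each protein joins the first
    existing representative reached with global-alignment identity >=
    ``min_identity`` and bidirectional coverage >= ``min_coverage``;
    otherwise it founds a new group.  Deterministic for fixed input.
    """
    if not proteins:
        raise ValueError("no proteins to cluster")
    if not (0 < min_identity <= 1 and 0 < min_coverage <= 1):
        raise ValueError("min_identity and min_coverage must be in (0, 1]")
    for fid, seq in proteins:
        if not seq:
            raise ValueError(f"empty protein sequence for feature {fid}")
    order = sorted(proteins, key=lambda p: (-len(p[1]), p[0]))
    aligner = _make_aligner()
    groups: dict[str, str] = {}
    representatives: dict[str, str] = {}
    # exact-duplicate shortcut: identical sequences always cluster together
    seq_to_group: dict[str, str] = {}
    rep_seqs: list[tuple[str, str, str]] = []  # (group_id, rep_id, seq)
    next_idx = 1
    for fid, seq in order:
        gid = seq_to_group.get(seq)
        if gid is None:
            for cand_gid, _rep_id, rep_seq in rep_seqs:
                la, lb = len(seq), len(rep_seq)
                # bidirectional coverage bounds: aligned columns <= min(la, lb)
                if min(la, lb) < min_coverage * max(la, lb):
                    continue
                ident, cov_a, cov_b = alignment_identity_coverage(
                    seq, rep_seq, aligner
                )
                if ident >= min_identity and cov_a >= min_coverage and cov_b >= min_coverage:
                    gid = cand_gid
                    break
        if gid is None:
            gid = f"G{next_idx:05d}"
            next_idx += 1
            representatives[gid] = fid
            rep_seqs.append((gid, fid, seq))
            seq_to_group[seq] = gid
        groups[fid] = gid
    return GroupAssignment(groups=groups, representatives=representatives,
                           method="builtin_greedy")


def from_table(
    table: "Overrides | dict[str, str] | str | Path",
    all_cds_ids: Optional[Iterable[str]] = None,
) -> GroupAssignment:
    """Build a group assignment from a predefined protein-group table.

    ``table`` may be a path to a two-column TSV (feature_id, group_id), an
    :class:`~locusplot.annotation_io.Overrides` object, or a plain mapping.
    Features not covered by the table each found a singleton group (with a
    warning); a feature mapped to two groups is an error at parse time.
    """
    if isinstance(table, (str, Path)):
        from .annotation_io import load_tables

        mapping = load_tables(group_table=table).groups
    elif isinstance(table, Overrides):
        mapping = dict(table.groups)
    else:
        mapping = dict(table)
    groups = dict(mapping)
    representatives: dict[str, str] = {}
    for fid, gid in mapping.items():  # first member in file order represents
        representatives.setdefault(gid, fid)
    if all_cds_ids is not None:
        missing = [fid for fid in all_cds_ids if fid not in groups]
        if missing:
            warnings.warn(
                f"{len(missing)} CDS feature(s) not covered by the group "
                "table; assigned singleton groups: " + ", ".join(missing[:10]),
                stacklevel=2,
            )
        for fid in missing:
            gid = f"SINGLETON_{fid}"
            groups[fid] = gid
            representatives[gid] = fid
    return GroupAssignment(groups=groups, representatives=representatives,
                           method="table")


def external_adapter(
    proteins: Sequence[tuple[str, str]],
    command_template: str,
    workdir: Optional[str | Path] = None,
) -> GroupAssignment:
    """Run an external clustering executable and parse its cluster TSV.

    ``command_template`` must contain ``{fasta}`` and ``{out}`` placeholders;
    the adapter writes the proteins as FASTA, substitutes the paths, runs the
    command, and reads a two-column TSV (representative_id, member_id per
    line).  On any failure, temporary files are removed and a clear error is
    raised suggesting the built-in clusterer as a fallback.
    """
    if not proteins:
        raise ValueError("no proteins to cluster")
    executable = command_template.split()[0]
    if shutil.which(executable) is None and not Path(executable).exists():
        raise FileNotFoundError(
            f"external clusterer {executable!r} not found; use the built-in "
            "clusterer (cluster_builtin) instead"
        )
    tmpdir = tempfile.mkdtemp(prefix="locusplot_clust_", dir=workdir)
    try:
        fasta = Path(tmpdir) / "proteins.faa"
        out = Path(tmpdir) / "clusters.tsv"
        with open(fasta, "w") as fh:
            for fid, seq in proteins:
                fh.write(f">{fid}\n{seq}\n")
        cmd = command_template.format(fasta=fasta, out=out)
        proc = subprocess.run(
            cmd, shell=True, capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise RuntimeError(
                f"external clusterer failed (exit {proc.returncode}): "
                f"{proc.stderr.strip()[:500]}"
            )
        groups: dict[str, str] = {}
        representatives: dict[str, str] = {}
        rep_to_gid: dict[str, str] = {}
        known = {fid for fid, _ in proteins}
        for lineno, line in enumerate(out.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise RuntimeError(
                    f"unparseable cluster TSV line {lineno}: {line!r}"
                )
            rep, member = parts
            if rep not in known or member not in known:
                raise RuntimeError(
                    f"cluster TSV line {lineno} names unknown protein ids"
                )
            gid = rep_to_gid.setdefault(rep, f"G{len(rep_to_gid) + 1:05d}")
            representatives[gid] = rep
            groups[member] = gid
        missing = known - set(groups)
        if missing:
            raise RuntimeError(
                f"cluster TSV does not cover {len(missing)} input protein(s)"
            )
        return GroupAssignment(groups=groups, representatives=representatives,
                               method="external")
    finally:
        shutil.rmtree(tmpdir, ignore_errors=True)


def assign_groups_to_loci(loci, assignment: GroupAssignment) -> None:
    """Write group ids from an assignment back onto CDS features."""
    for locus in loci:
        for f in locus.cds_features:
            if f.feature_id in assignment.groups:
                f.group_id = assignment.groups[f.feature_id]
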