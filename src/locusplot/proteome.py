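"""Proteome-composition similarity, sequence ordering, and gene classes.

From per-locus sets of homology-group ids we compute a pairwise similarity
matrix S (the fraction of shared homologous protein groups between two loci)
and the distance matrix D = 1 - S.  Average-linkage (UPGMA) hierarchical
clustering of D determines the display order of sequences and flat sequence
clusters.  Within each cluster, every protein group is classified as
``conserved``, ``intermediate`` or ``variable`` by its presence fraction —
the per-cluster analogue of the core / shell / cloud partition of pangenome
analysis.

The similarity score between loci with group sets Gi, Gj defaults to the
symmetric mean of directional shared fractions,

    S_ij = (|Gi ∩ Gj| / |Gi| + |Gi ∩ Gj| / |Gj|) / 2,

so a short locus fully contained in a longer one still scores high (a phage
and its deletion variant group together); plain Jaccard is available as an
alternative.  UPGMA is implemented here rather than delegated because the
display contract needs exact, documented tie-breaking (smallest active index
pair) and ultrametric half-heights; scipy's implementation serves as an
independent cross-check in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np


# ---------------------------------------------------------------------------
# Dendrogram
# ---------------------------------------------------------------------------


@dataclass
class Node:
    """Binary dendrogram node; a leaf has a name, an internal node a height.

    Heights are ultrametric: the height of a merge is half the average
    distance between the two merged clusters, so the cophenetic distance
    between two leaves is twice the height of their lowest common ancestor.
    """

    name: Optional[str] = None
    height: float = 0.0
    left: Optional["Node"] = None
    right: Optional["Node"] = None

    @property
    def is_leaf(self) -> bool:
        return self.name is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return self.left.leaves() + self.right.leaves()

    def min_leaf(self) -> str:
        if self.is_leaf:
            return self.name
        return min(self.left.min_leaf(), self.right.min_leaf())


@dataclass
class ProteomeMatrix:
    """Similarity/distance matrices plus the derived ordering artefacts."""

    locus_ids: list[str]
    S: np.ndarray
    D: np.ndarray
    dendrogram: Optional[Node] = None
    leaf_order: Optional[list[str]] = None
    cluster_of: dict[str, str] = field(default_factory=dict)


def similarity_matrix(
    group_sets: dict[str, set[str]],
    formula: str = "mean_directional",
) -> ProteomeMatrix:
    """Pairwise proteome-composition similarity over loci.

    ``group_sets`` maps locus_id -> set of homology-group ids.  S is
    symmetric with unit diagonal; an empty set yields similarity 0 to every
    other locus.  ``formula`` is ``mean_directional`` (default) or
    ``jaccard``.
    """
    if not group_sets:
        raise ValueError("need at least one locus")
    if formula not in ("mean_directional", "jaccard"):
        raise ValueError(f"unknown similarity formula {formula!r}")
    ids = list(group_sets)
    n = len(ids)
    S = np.eye(n)
    for i in range(n):
        Gi = group_sets[ids[i]]
        for j in range(i + 1, n):
            Gj = group_sets[ids[j]]
            if not Gi or not Gj:
                s = 0.0
            else:
                inter = len(Gi & Gj)
                if formula == "mean_directional":
                    s = 0.5 * (inter / len(Gi) + inter / len(Gj))
                else:
                    s = inter / len(Gi | Gj)
            S[i, j] = S[j, i] = s
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    return ProteomeMatrix(locus_ids=ids, S=S, D=D)


def upgma(D: np.ndarray, labels: Sequence[str]) -> Node:
    """Unweighted average-linkage clustering with deterministic ties.

    Merge heights are half the average inter-cluster distance (ultrametric).
    At each step the pair with the smallest distance is merged; exact ties
    are broken by the smallest (i, j) pair of active cluster indices, where
    indices count leaves first (input order) and then merge creation order.
    A single label yields a single-leaf tree.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if n == 0:
        raise ValueError("need at least one label")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distance matrix must be non-negative")
    nodes: dict[int, Node] = {i: Node(name=labels[i]) for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_idx = n
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                d = dist[(i, j)]
                key = (d, i, j)
                if best is None or key < best:
                    best = key
        d, i, j = best
        merged = Node(height=d / 2.0, left=nodes[i], right=nodes[j])
        nodes[next_idx] = merged
        sizes[next_idx] = sizes[i] + sizes[j]
        active = [k for k in active if k not in (i, j)]
        for k in active:
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            # unweighted average: weight by cluster sizes
            dist[(k, next_idx)] = (sizes[i] * dik + sizes[j] * djk) / (
                sizes[i] + sizes[j]
            )
        active.append(next_idx)
        next_idx += 1
    return nodes[active[0]]


def leaf_order(tree: Node, override: Optional[Sequence[str]] = None) -> list[str]:
    """Left-to-right leaf traversal with deterministic orientation.

    At each internal node the child containing the lexicographically
    smallest leaf goes first.  An explicit ``override`` order (from the
    locus table) wins over the dendrogram.
    """
    if override is not None:
        return list(override)

    def walk(node: Node) -> list[str]:
        if node.is_leaf:
            return [node.name]
        first, second = node.left, node.right
        if second.min_leaf() < first.min_leaf():
            first, second = second, first
        return walk(first) + walk(second)

    return walk(tree)


def cophenetic_matrix(tree: Node, labels: Sequence[str]) -> np.ndarray:
    """Cophenetic distances: 2 x height of the lowest common ancestor."""
    idx = {name: k for k, name in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    def walk(node: Node) -> list[str]:
        if node.is_leaf:
            return [node.name]
        left = walk(node.left)
        right = walk(node.right)
        for a in left:
            for b in right:
                C[idx[a], idx[b]] = C[idx[b], idx[a]] = 2.0 * node.height
        return left + right

    walk(tree)
    return C


def cut_clusters(tree: Node, max_distance: float = 0.75) -> dict[str, str]:
    """Flat sequence clusters by a cophenetic-distance threshold.

    Clusters are the maximal subtrees whose merge heights are at most
    ``max_distance / 2`` (equivalently, whose members are all within
    cophenetic distance ``max_distance``).  Labels C1, C2, ... are assigned
    in leaf order of first appearance.
    """
    if not (0 <= max_distance <= 1):
        raise ValueError("max_distance must be in [0, 1]")
    clusters: list[list[str]] = []

    def walk(node: Node) -> None:
        if node.is_leaf or node.height <= max_distance / 2.0 + 1e-12:
            clusters.append(ordered_leaves(node))
        else:
            first, second = node.left, node.right
            if second.min_leaf() < first.min_leaf():
                first, second = second, first
            walk(first)
            walk(second)

    def ordered_leaves(node: Node) -> list[str]:
        if node.is_leaf:
            return [node.name]
        first, second = node.left, node.right
        if second.min_leaf() < first.min_leaf():
            first, second = second, first
        return ordered_leaves(first) + ordered_leaves(second)

    walk(tree)
    out: dict[str, str] = {}
    for k, members in enumerate(clusters, start=1):
        for name in members:
            out[name] = f"C{k}"
    return out


def analyze(
    matrix: ProteomeMatrix,
    max_distance: float = 0.75,
    order_override: Optional[Sequence[str]] = None,
    cluster_override: Optional[dict[str, str]] = None,
) -> ProteomeMatrix:
    """Fill dendrogram, leaf order and clusters on a similarity matrix."""
    matrix.dendrogram = upgma(matrix.D, matrix.locus_ids)
    matrix.leaf_order = leaf_order(matrix.dendrogram, override=order_override)
    if cluster_override:
        matrix.cluster_of = dict(cluster_override)
    else:
        matrix.cluster_of = cut_clusters(matrix.dendrogram, max_distance)
    return matrix


# ---------------------------------------------------------------------------
# Protein-group classes (per-cluster core / shell / cloud analogue)
# ---------------------------------------------------------------------------


def classify_groups(
    cluster_members: dict[str, list[str]],
    group_sets: dict[str, set[str]],
    conserved_cutoff: float = 0.75,
    variable_cutoff: float = 0.25,
) -> dict[str, dict[str, tuple[float, str]]]:
    """Per-cluster presence fraction and class for every protein group.

    A group's presence fraction f is the number of member loci carrying at
    least one feature of the group (paralogues count once) divided by the
    cluster size.  Classes: conserved if f >= ``conserved_cutoff``; variable
    if f <= ``variable_cutoff``; else intermediate.  A cluster of size 1
    offers no variability evidence, so all its groups are conserved.
    """
    if not (0 <= variable_cutoff < conserved_cutoff <= 1):
        raise ValueError("need 0 <= variable_cutoff < conserved_cutoff <= 1")
    out: dict[str, dict[str, tuple[float, str]]] = {}
    for cluster, members in cluster_members.items():
        size = len(members)
        table: dict[str, tuple[float, str]] = {}
        all_groups: set[str] = set()
        for lid in members:
            all_groups |= group_sets.get(lid, set())
        for gid in sorted(all_groups):
            count = sum(1 for lid in members if gid in group_sets.get(lid, set()))
            f = count / size
            if size == 1:
                cls = "conserved"
            elif f >= conserved_cutoff:
                cls = "conserved"
            elif f <= variable_cutoff:
                cls = "variable"
            else:
                cls = "intermediate"
            table[gid] = (f, cls)
        out[cluster] = table
    return out


def cluster_membership(cluster_of: dict[str, str]) -> dict[str, list[str]]:
    """Invert a locus -> cluster mapping (membership in insertion order)."""
    out: dict[str, list[str]] = {}
    for lid, cl in cluster_of.items():
        out.setdefault(cl, []).append(lid)
    return out


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def to_newick(tree: Node) -> str:
    """Newick string with branch lengths derived from merge heights."""

    def walk(node: Node, parent_height: float) -> str:
        if node.is_leaf:
            return f"{node.name}:{_fmt(parent_height)}"
        first, second = node.left, node.right
        if second.min_leaf() < first.min_leaf():
            first, second = second, first
        inner = ",".join(walk(c, node.height) for c in (first, second))
        if parent_height is None:
            return f"({inner})"
        return f"({inner}):{_fmt(parent_height - node.height)}"

    if tree.is_leaf:
        return f"{tree.name};"
    first, second = tree.left, tree.right
    if second.min_leaf() < first.min_leaf():
        first, second = second, first
    inner = ",".join(walk(c, tree.height) for c in (first, second))
    return f"({inner});"


def _fmt(x: float) -> str:
    s = f"{x:.10f}".rstrip("0").rstrip(".")
    return s if s else "0"


def write_similarity_tsv(matrix: ProteomeMatrix, path: str | Path) -> None:
    """Write S as a TSV with locus ids as header row and first column."""
    lines = ["\t" + "\t".join(matrix.locus_ids)]
    for i, lid in enumerate(matrix.locus_ids):
        vals = "\t".join(_fmt(matrix.S[i, j]) for j in range(len(matrix.locus_ids)))
        lines.append(f"{lid}\t{vals}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_newick(matrix: ProteomeMatrix, path: str | Path) -> None:
    if matrix.dendrogram is None:
        raise ValueError("dendrogram not computed; call analyze() first")
    Path(path).write_text(to_newick(matrix.dendrogram) + "\n")


def write_group_class_tsv(
    classes: dict[str, dict[str, tuple[float, str]]], path: str | Path
) -> None:
    lines = ["cluster\tgroup_id\tpresence_fraction\tclass"]
    for cluster in classes:
        for gid, (f, cls) in classes[cluster].items():
            lines.append(f"{cluster}\t{gid}\t{_fmt(f)}\t{cls}")
    Path(path).write_text("\n".join(lines) + "\n")


def apply_classes_to_loci(loci, classes, cluster_of) -> None:
    """Write per-cluster group classes back onto CDS features.

    Features with a table-overridden class keep it.
    """
    for locus in loci:
        cl = cluster_of.get(locus.locus_id)
        table = classes.get(cl, {})
        for f in locus.cds_features:
            if f.group_class is None and f.group_id in table:
                f.group_class = table[f.group_id][1]
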