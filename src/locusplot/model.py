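"""Core data model: loci, features and display regions.

Coordinates are 0-based half-open internally; GenBank/GFF 1-based inclusive
coordinates are converted at the parsing boundary.  A feature or region on a
circular sequence may wrap the origin, in which case it is kept as a single
object with a wrap flag rather than being split in two, so that circular
sequences display without a gap between end and start coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

FEATURE_TYPES = ("CDS", "tRNA", "other")
GROUP_CLASSES = ("conserved", "intermediate", "variable")

#: label patterns (case-insensitive substrings) marking proteins of unknown
#: function whose labels are hidden by default
DEFAULT_HYPOTHETICAL_PATTERNS = (
    "hypothetical protein",
    "unknown function",
    "uncharacterized",
)


@dataclass
class Region:
    """A display window on a locus, 0-based half-open.

    When ``wraps_origin`` is true the displayed span is
    ``[start, length_bp) ++ [0, end)`` on a circular sequence.
    """

    start: int
    end: int
    wraps_origin: bool = False

    def span(self, length_bp: int) -> int:
        """Number of displayed bases."""
        if self.wraps_origin:
            return (length_bp - self.start) + self.end
        return self.end - self.start


@dataclass
class Feature:
    """One annotated element (CDS, tRNA or other) on a locus."""

    feature_id: str
    type: str  # one of FEATURE_TYPES
    start: int  # 0-based inclusive
    end: int  # exclusive; if wraps_origin, end < start and span wraps
    strand: str  # '+' or '-'
    label: str = ""
    protein_seq: str = ""  # CDS only
    group_id: Optional[str] = None
    group_class: Optional[str] = None  # conserved | intermediate | variable
    category: Optional[str] = None  # functional category, e.g. PHROG class
    hypothetical: bool = False
    wraps_origin: bool = False
    show_label: Optional[bool] = None  # tri-state manual override

    def span(self, length_bp: int) -> int:
        if self.wraps_origin:
            return (length_bp - self.start) + self.end
        return self.end - self.start

    def is_hypothetical_label(
        self, patterns: tuple[str, ...] = DEFAULT_HYPOTHETICAL_PATTERNS
    ) -> bool:
        low = self.label.lower()
        return any(p in low for p in patterns) or not self.label


@dataclass
class Locus:
    """One input sequence displayed as a single row."""

    locus_id: str
    length_bp: int
    sequence: str = ""
    description: str = ""
    circular: bool = False
    features: list[Feature] = field(default_factory=list)
    regions: list[Region] = field(default_factory=list)
    row_order_hint: Optional[int] = None
    cluster_hint: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"locus {self.locus_id}: length_bp must be >= 1")
        if self.sequence and len(self.sequence) != self.length_bp:
            raise ValueError(
                f"locus {self.locus_id}: sequence length "
                f"{len(self.sequence)} != length_bp {self.length_bp}"
            )
        if not self.regions:
            self.regions = [Region(0, self.length_bp)]

    @property
    def cds_features(self) -> list[Feature]:
        return [f for f in self.features if f.type == "CDS"]

    def displayed_span(self) -> int:
        """Total number of displayed bases across all regions."""
        return sum(r.span(self.length_bp) for r in self.regions)

    def group_set(self) -> set[str]:
        """Set of homology-group ids present on this locus (CDS only)."""
        return {f.group_id for f in self.cds_features if f.group_id is not None}


def mark_hypothetical(
    loci: list[Locus],
    patterns: tuple[str, ...] = DEFAULT_HYPOTHETICAL_PATTERNS,
) -> None:
    """Set the ``hypothetical`` flag on every feature by label matching."""
    for locus in loci:
        for feat in locus.features:
            feat.hypothetical = feat.is_hypothetical_label(patterns)
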