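"""Genomic signal tracks and sequence-property profiles.

The genome-browser mode draws per-base numeric signals under the gene map:
sequencing coverage read from bedGraph (or bigWig through an adapter), plus
sequence-property tracks computed from the nucleotide sequence itself — GC
content and GC skew ((G - C) / (G + C)) in a centred sliding window.  Tracks
are smoothed with a boxcar moving average whose window is chosen from the
image width and the size of the visualized span, and property tracks are
centred at their average value so deviations above and below the mean can be
filled with different colours.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .model import Region


@dataclass
class SignalTrack:
    """A numeric signal over a span of one locus.

    ``values`` holds one number per ``step`` bases starting at
    ``span.start``.  When ``centred`` the stored values are raw minus
    ``mean_value`` and the raw mean / min / max are kept for the corner
    annotation of the rendered track.
    """

    locus_id: str
    span: Region
    values: np.ndarray
    kind: str = "custom"  # coverage | gc_content | gc_skew | custom
    step: int = 1
    mean_value: float = 0.0
    value_range: tuple[float, float] = (0.0, 0.0)
    centred: bool = False
    smoothing_window: int = 1
    mask: Optional[np.ndarray] = None  # True where the value is undefined
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.centred:
            self.mean_value = float(self.values.mean()) if self.values.size else 0.0
            self.value_range = (
                (float(self.values.min()), float(self.values.max()))
                if self.values.size
                else (0.0, 0.0)
            )


class TrackError(ValueError):
    """Raised for malformed signal input."""


# ---------------------------------------------------------------------------
# bedGraph / bigWig
# ---------------------------------------------------------------------------


def parse_bedgraph(
    path: str | Path, locus_id: str, span: Region, name: str = ""
) -> SignalTrack:
    """Read a 4-column bedGraph (0-based half-open) into a per-base track.

    Bases of the span not covered by any interval get value 0; overlapping
    intervals resolve last-wins with a warning; rows for other chromosomes
    are skipped with a warning.
    """
    path = Path(path)
    n = span.end - span.start
    values = np.zeros(n)
    covered = np.zeros(n, dtype=bool)
    overlap_warned = False
    skipped_chroms: set[str] = set()
    any_rows = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "track", "browser")):
                continue
            parts = s.split()
            if len(parts) < 4:
                raise TrackError(f"{path}:{lineno}: expected 4 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
                value = float(parts[3])
            except ValueError as exc:
                raise TrackError(f"{path}:{lineno}: malformed interval") from exc
            if chrom != locus_id:
                skipped_chroms.add(chrom)
                continue
            any_rows = True
            lo = max(start, span.start) - span.start
            hi = min(end, span.end) - span.start
            if hi <= lo:
                continue
            if not overlap_warned and covered[lo:hi].any():
                warnings.warn(
                    f"{path}: overlapping bedGraph intervals; last value wins",
                    stacklevel=2,
                )
                overlap_warned = True
            values[lo:hi] = value
            covered[lo:hi] = True
    if skipped_chroms:
        warnings.warn(
            f"{path}: skipped rows for chromosome(s) not matching "
            f"{locus_id!r}: {', '.join(sorted(skipped_chroms))}",
            stacklevel=2,
        )
    if not any_rows:
        warnings.warn(f"{path}: no intervals for {locus_id}; all-zero track",
                      stacklevel=2)
    return SignalTrack(
        locus_id=locus_id, span=span, values=values, kind="coverage",
        name=name or path.stem,
    )


def bigwig_adapter(
    path: str | Path,
    locus_id: str,
    span: Region,
    converter: str = "bigWigToBedGraph",
    name: str = "",
) -> SignalTrack:
    """Read a bigWig track, natively when pyBigWig is importable, else by
    converting to bedGraph with an external executable.

    The result follows the :func:`parse_bedgraph` contract exactly.
    """
    path = Path(path)
    try:
        import pyBigWig  # noqa: PLC0415
    except ImportError:
        pyBigWig = None
    if pyBigWig is not None:
        bw = pyBigWig.open(str(path))
        try:
            if locus_id not in bw.chroms():
                warnings.warn(
                    f"{path}: no chromosome {locus_id!r}; all-zero track",
                    stacklevel=2,
                )
                values = np.zeros(span.end - span.start)
            else:
                chrom_len = bw.chroms()[locus_id]
                hi = min(span.end, chrom_len)
                vals = bw.values(locus_id, span.start, hi)
                values = np.nan_to_num(np.asarray(vals, dtype=float))
                if hi < span.end:
                    values = np.concatenate([values, np.zeros(span.end - hi)])
        finally:
            bw.close()
        return SignalTrack(
            locus_id=locus_id, span=span, values=values, kind="coverage",
            name=name or path.stem,
        )
    if shutil.which(converter) is None:
        raise TrackError(
            f"cannot read bigWig {path}: pyBigWig is not installed and no "
            f"{converter!r} executable is on PATH; convert the file to "
            "bedGraph and pass that instead"
        )
    with tempfile.NamedTemporaryFile(suffix=".bedGraph", delete=False) as tmp:
        tmp_path = Path(tmp.name)
    try:
        proc = subprocess.run(
            [converter, str(path), str(tmp_path)], capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise TrackError(
                f"{converter} failed on {path}: {proc.stderr.strip()[:500]}"
            )
        return parse_bedgraph(tmp_path, locus_id, span, name=name or path.stem)
    finally:
        tmp_path.unlink(missing_ok=True)


# ---------------------------------------------------------------------------
# Sequence-property tracks
# ---------------------------------------------------------------------------


def _window_bounds(i: int, n: int, w: int) -> tuple[int, int]:
    """Centred window of size w at position i, shrunk at the edges."""
    lo = max(0, i - w // 2)
    hi = min(n, i - w // 2 + w)
    return lo, hi


def gc_content(
    sequence: str, window: int = 1, locus_id: str = "", span: Optional[Region] = None
) -> SignalTrack:
    """Per-base GC fraction in a centred sliding window.

    The denominator counts only non-N bases in the window; a window of only
    N bases gets value 0 and is flagged in the mask.
    """
    seq = sequence.upper()
    n = len(seq)
    if not (1 <= window <= n):
        raise ValueError("window must be in [1, len(sequence)]")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(float)
    is_known = np.isin(arr, [ord(b) for b in "ACGT"]).astype(float)
    cs_gc = np.concatenate([[0.0], np.cumsum(is_gc)])
    cs_known = np.concatenate([[0.0], np.cumsum(is_known)])
    values = np.zeros(n)
    mask = np.zeros(n, dtype=bool)
    for i in range(n):
        lo, hi = _window_bounds(i, n, window)
        known = cs_known[hi] - cs_known[lo]
        if known == 0:
            mask[i] = True
        else:
            values[i] = (cs_gc[hi] - cs_gc[lo]) / known
    return SignalTrack(
        locus_id=locus_id, span=span or Region(0, n), values=values,
        kind="gc_content", smoothing_window=window, mask=mask, name="GC content",
    )


def gc_skew(
    sequence: str, window: int = 1, locus_id: str = "", span: Optional[Region] = None
) -> SignalTrack:
    """Per-base GC skew (G - C) / (G + C) in a centred sliding window.

    Windows with G + C = 0 get value 0.
    """
    seq = sequence.upper()
    n = len(seq)
    if not (1 <= window <= n):
        raise ValueError("window must be in [1, len(sequence)]")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    g = (arr == ord("G")).astype(float)
    c = (arr == ord("C")).astype(float)
    cs_g = np.concatenate([[0.0], np.cumsum(g)])
    cs_c = np.concatenate([[0.0], np.cumsum(c)])
    values = np.zeros(n)
    for i in range(n):
        lo, hi = _window_bounds(i, n, window)
        ng = cs_g[hi] - cs_g[lo]
        nc = cs_c[hi] - cs_c[lo]
        if ng + nc > 0:
            values[i] = (ng - nc) / (ng + nc)
    return SignalTrack(
        locus_id=locus_id, span=span or Region(0, n), values=values,
        kind="gc_skew", smoothing_window=window, name="GC skew",
    )


# ---------------------------------------------------------------------------
# Smoothing and centring
# ---------------------------------------------------------------------------


def moving_average(values: np.ndarray, w: int) -> np.ndarray:
    """Centred boxcar moving average with edge-shrunk windows."""
    values = np.asarray(values, dtype=float)
    if w <= 1:
        return values.copy()
    n = len(values)
    cs = np.concatenate([[0.0], np.cumsum(values)])
    out = np.empty(n)
    for i in range(n):
        lo, hi = _window_bounds(i, n, w)
        out[i] = (cs[hi] - cs[lo]) / (hi - lo)
    return out


def smooth_adaptive(
    track: SignalTrack, plot_width_units: float, points_per_unit: float = 2.0
) -> SignalTrack:
    """Image-width-aware moving-average smoothing.

    The target point count is P = ceil(plot_width_units * points_per_unit);
    the boxcar window is w = max(1, floor(span_bp / P)).  The per-base track
    is smoothed and then subsampled every w bases (at window centres, so
    when w divides the span the samples are exact block means and the track
    mean is preserved).  w = 1 leaves the track unchanged.
    """
    if plot_width_units <= 0:
        raise ValueError("plot_width_units must be positive")
    n = len(track.values)
    P = int(np.ceil(plot_width_units * points_per_unit))
    w = max(1, n // P)
    if w <= 1:
        return replace(track, values=track.values.copy(), smoothing_window=1)
    smoothed = moving_average(track.values, w)
    idx = np.arange(w // 2, n, w)
    out = SignalTrack(
        locus_id=track.locus_id,
        span=track.span,
        values=smoothed[idx],
        kind=track.kind,
        step=track.step * w,
        centred=track.centred,
        smoothing_window=w,
        name=track.name,
    )
    if track.centred:
        out.mean_value = track.mean_value
        out.value_range = track.value_range
    return out


def centre_track(track: SignalTrack) -> SignalTrack:
    """Subtract the mean; keep raw mean/min/max for the corner annotation.

    Idempotent: centring an already-centred track returns it unchanged.
    """
    if track.values.size == 0:
        raise ValueError("cannot centre an empty track")
    if track.centred:
        return track
    mean = float(track.values.mean())
    out = replace(track, values=track.values - mean, centred=True)
    out.mean_value = mean
    out.value_range = (float(track.values.min()), float(track.values.max()))
    return out


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Export a track as run-length-compressed bedGraph for inspection."""
    lines = []
    vals = track.values
    i = 0
    while i < len(vals):
        j = i
        while j + 1 < len(vals) and vals[j + 1] == vals[i]:
            j += 1
        start = track.span.start + i * track.step
        end = track.span.start + (j + 1) * track.step
        lines.append(f"{track.locus_id}\t{start}\t{end}\t{vals[i]:g}")
        i = j + 1
    Path(path).write_text("\n".join(lines) + "\n")
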