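"""Minimal deterministic vector-PDF canvas.

A small PDF 1.4 writer producing a single page of uncompressed vector
primitives (paths and text) using the standard base-14 Helvetica fonts.
Keeping streams uncompressed and all metadata caller-controlled makes the
output a pure function of the drawing calls: the same figure renders to a
byte-identical file on every run, and the text content can be recovered from
the content stream for verification.

Coordinates are PDF points with the origin at the bottom-left.  Colours are
(r, g, b) floats in [0, 1].
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

# Standard AFM advance widths (1/1000 em) for ASCII 32..126
_HELVETICA_WIDTHS = [
    278, 278, 355, 556, 556, 889, 667, 222, 333, 333, 389, 584, 278, 333,
    278, 278, 556, 556, 556, 556, 556, 556, 556, 556, 556, 556, 278, 278,
    584, 584, 584, 556, 1015, 667, 667, 722, 722, 667, 611, 778, 722, 278,
    500, 667, 556, 833, 722, 778, 667, 778, 722, 667, 611, 722, 667, 944,
    667, 667, 611, 278, 278, 278, 469, 556, 222, 556, 556, 500, 556, 556,
    278, 556, 556, 222, 222, 500, 222, 833, 556, 556, 556, 556, 333, 500,
    278, 556, 500, 722, 500, 500, 500, 334, 260, 334, 584,
]
_HELVETICA_BOLD_WIDTHS = [
    278, 333, 474, 556, 556, 889, 722, 278, 333, 333, 389, 584, 278, 333,
    278, 278, 556, 556, 556, 556, 556, 556, 556, 556, 556, 556, 333, 333,
    584, 584, 584, 611, 975, 722, 722, 722, 722, 667, 611, 778, 722, 278,
    556, 722, 611, 833, 722, 778, 667, 778, 722, 667, 611, 722, 667, 944,
    667, 667, 611, 333, 278, 333, 584, 556, 278, 556, 611, 556, 611, 556,
    333, 611, 611, 278, 278, 556, 278, 889, 611, 611, 611, 611, 389, 556,
    333, 611, 556, 778, 556, 556, 500, 389, 280, 389, 584,
]

FONTS = {
    "Helvetica": ("F1", _HELVETICA_WIDTHS),
    "Helvetica-Bold": ("F2", _HELVETICA_BOLD_WIDTHS),
}


def text_width(text: str, font_size: float, font: str = "Helvetica") -> float:
    """Width of ``text`` in points at ``font_size``."""
    widths = FONTS.get(font, FONTS["Helvetica"])[1]
    total = 0
    for ch in text:
        code = ord(ch)
        if 32 <= code <= 126:
            total += widths[code - 32]
        else:
            total += 556  # fallback: average glyph width
    return total * font_size / 1000.0


def _num(x: float) -> str:
    """Deterministic fixed-precision number formatting."""
    s = f"{x:.4f}".rstrip("0").rstrip(".")
    return s if s and s != "-0" else "0"


def _escape(text: str) -> str:
    return (
        text.replace("\\", r"\\").replace("(", r"\(").replace(")", r"\)")
    )


class PDFCanvas:
    """Single-page vector canvas with deterministic byte output."""

    def __init__(self, width: float, height: float,
                 creation_date: str = "D:20250101000000Z") -> None:
        self.width = width
        self.height = height
        self.creation_date = creation_date
        self._ops: list[str] = []
        self._fonts_used: set[str] = set()

    # -- path primitives ---------------------------------------------------

    def polygon(
        self,
        points: Sequence[tuple[float, float]],
        fill: Optional[tuple[float, float, float]] = None,
        stroke: Optional[tuple[float, float, float]] = None,
        line_width: float = 0.5,
    ) -> None:
        if len(points) < 3:
            return
        ops = []
        if fill is not None:
            ops.append(" ".join(_num(c) for c in fill) + " rg")
        if stroke is not None:
            ops.append(" ".join(_num(c) for c in stroke) + " RG")
            ops.append(f"{_num(line_width)} w")
        x0, y0 = points[0]
        ops.append(f"{_num(x0)} {_num(y0)} m")
        for x, y in points[1:]:
            ops.append(f"{_num(x)} {_num(y)} l")
        ops.append("h")
        if fill is not None and stroke is not None:
            ops.append("B")
        elif fill is not None:
            ops.append("f")
        else:
            ops.append("S")
        self._ops.append("\n".join(ops))

    def line(
        self,
        x0: float, y0: float, x1: float, y1: float,
        color: tuple[float, float, float] = (0, 0, 0),
        width: float = 0.5,
        dash: Optional[Sequence[float]] = None,
    ) -> None:
        ops = [" ".join(_num(c) for c in color) + " RG", f"{_num(width)} w"]
        if dash:
            ops.append("[" + " ".join(_num(d) for d in dash) + "] 0 d")
        ops.append(f"{_num(x0)} {_num(y0)} m {_num(x1)} {_num(y1)} l S")
        if dash:
            ops.append("[] 0 d")
        self._ops.append("\n".join(ops))

    def polyline(
        self,
        points: Sequence[tuple[float, float]],
        color: tuple[float, float, float] = (0, 0, 0),
        width: float = 0.5,
    ) -> None:
        if len(points) < 2:
            return
        ops = [" ".join(_num(c) for c in color) + " RG", f"{_num(width)} w"]
        x0, y0 = points[0]
        ops.append(f"{_num(x0)} {_num(y0)} m")
        for x, y in points[1:]:
            ops.append(f"{_num(x)} {_num(y)} l")
        ops.append("S")
        self._ops.append("\n".join(ops))

    def rect(
        self,
        x: float, y: float, w: float, h: float,
        fill: Optional[tuple[float, float, float]] = None,
        stroke: Optional[tuple[float, float, float]] = None,
        line_width: float = 0.5,
    ) -> None:
        self.polygon(
            [(x, y), (x + w, y), (x + w, y + h), (x, y + h)],
            fill=fill, stroke=stroke, line_width=line_width,
        )

    # -- text --------------------------------------------------------------

    def text(
        self,
        x: float, y: float, content: str,
        font_size: float = 8.0,
        font: str = "Helvetica",
        color: tuple[float, float, float] = (0, 0, 0),
    ) -> None:
        if not content:
            return
        font_key = FONTS.get(font, FONTS["Helvetica"])[0]
        self._fonts_used.add(font if font in FONTS else "Helvetica")
        self._ops.append(
            "BT\n"
            + " ".join(_num(c) for c in color) + " rg\n"
            + f"/{font_key} {_num(font_size)} Tf\n"
            + f"{_num(x)} {_num(y)} Td\n"
            + f"({_escape(content)}) Tj\n"
            + "ET"
        )

    # -- serialisation -----------------------------------------------------

    def tobytes(self) -> bytes:
        content = ("\n".join(self._ops) + "\n").encode("latin-1", "replace")
        objects: list[bytes] = []
        font_objs = {}
        # object numbering: 1 catalog, 2 pages, 3 page, 4 content, 5 info,
        # then one object per used font
        next_num = 6
        for name in sorted(self._fonts_used or {"Helvetica"}):
            font_objs[name] = next_num
            next_num += 1
        font_res = " ".join(
            f"/{FONTS[name][0]} {num} 0 R" for name, num in font_objs.items()
        )
        objects.append(b"1 0 obj\n<< /Type /Catalog /Pages 2 0 R >>\nendobj\n")
        objects.append(b"2 0 obj\n<< /Type /Pages /Kids [3 0 R] /Count 1 >>\nendobj\n")
        objects.append(
            (
                "3 0 obj\n<< /Type /Page /Parent 2 0 R "
                f"/MediaBox [0 0 {_num(self.width)} {_num(self.height)}] "
                f"/Resources << /Font << {font_res} >> >> "
                "/Contents 4 0 R >>\nendobj\n"
            ).encode()
        )
        objects.append(
            b"4 0 obj\n<< /Length %d >>\nstream\n" % len(content)
            + content
            + b"endstream\nendobj\n"
        )
        objects.append(
            (
                "5 0 obj\n<< /Producer (locusplot) "
                f"/CreationDate ({self.creation_date}) >>\nendobj\n"
            ).encode()
        )
        for name, num in font_objs.items():
            objects.append(
                (
                    f"{num} 0 obj\n<< /Type /Font /Subtype /Type1 "
                    f"/BaseFont /{name} /Encoding /WinAnsiEncoding >>\nendobj\n"
                ).encode()
            )
        out = bytearray(b"%PDF-1.4\n%\xe2\xe3\xcf\xd3\n")
        offsets = [0]
        for obj in objects:
            offsets.append(len(out))
            out += obj
        xref_pos = len(out)
        n_obj = len(objects) + 1
        out += b"xref\n0 %d\n" % n_obj
        out += b"0000000000 65535 f \n"
        for off in offsets[1:]:
            out += b"%010d 00000 n \n" % off
        out += (
            f"trailer\n<< /Size {n_obj} /Root 1 0 R /Info 5 0 R >>\n"
            f"startxref\n{xref_pos}\n%%EOF\n"
        ).encode()
        return bytes(out)

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(self.tobytes())


def extract_text(pdf_bytes: bytes) -> list[str]:
    """Recover text strings shown by ``Tj`` operators, in drawing order.

    Works on this module's uncompressed output (and any PDF with literal
    strings in plain content streams); used for verification, not as a
    general PDF parser.
    """
    out: list[str] = []
    i = 0
    data = pdf_bytes.decode("latin-1")
    while True:
        j = data.find(" Tj", i)
        if j < 0:
            break
        # scan backwards for the unescaped opening parenthesis
        k = j - 1
        if k < 0 or data[k] != ")":
            i = j + 3
            continue
        depth = 0
        m = k
        while m >= 0:
            ch = data[m]
            if ch == ")" and (m == 0 or data[m - 1] != "\\"):
                depth += 1
            elif ch == "(" and (m == 0 or data[m - 1] != "\\"):
                depth -= 1
                if depth == 0:
                    break
            m -= 1
        raw = data[m + 1 : k]
        out.append(
            raw.replace(r"\(", "(").replace(r"\)", ")").replace("\\\\", "\\")
        )
        i = j + 3
    return out
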