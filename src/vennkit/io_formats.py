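"""Input dialects, CSV/SVG writers and the color-interpolation rule.

Three text input dialects are supported, mirroring how set data circulates
in omics work:

* a TAB-separated two-column long format — element ID, set label — with an
  optional header line;
* per-set element lists (one block of newline/comma-separated IDs per set);
* an intersection-count table whose first column is an ``"&"``-joined
  signature and whose second column is a non-negative count.

Element and set names are case-sensitive and whitespace-trimmed at both
ends; header handling is always an explicit flag, never guessed.
"""

from __future__ import annotations

import csv
import io
import math
import xml.etree.ElementTree as ET
from typing import Mapping

from .errors import FormatError
from .scene import (
    RGB,
    CirclePrim,
    EllipsePrim,
    LinePrim,
    PolygonPrim,
    RectPrim,
    SceneGraph,
    TextPrim,
)
from .setcore import (
    IntersectionCountTable,
    RegionPartition,
    SetCollection,
    canonical_signature,
    parse_signature,
)

__all__ = [
    "read_two_column",
    "write_two_column",
    "read_element_lists",
    "read_intersection_counts",
    "write_region_csv",
    "render_svg",
    "interpolate_colors",
    "DEFAULT_PALETTE",
    "hex_to_rgb",
    "rgb_to_hex",
]

#: Default per-set fill palette (yellow, pink, green, purple, blue — the
#: palette order used throughout the worked examples).
DEFAULT_PALETTE: list[RGB] = [
    (240, 200, 0),
    (230, 120, 170),
    (60, 160, 90),
    (130, 90, 180),
    (60, 120, 200),
]


def hex_to_rgb(text: str) -> RGB:
    s = text.strip().lstrip("#")
    if len(s) != 6:
        raise FormatError(f"not a #RRGGBB color: {text!r}")
    try:
        return (int(s[0:2], 16), int(s[2:4], 16), int(s[4:6], 16))
    except ValueError as exc:
        raise FormatError(f"not a #RRGGBB color: {text!r}") from exc


def rgb_to_hex(color: RGB) -> str:
    return "#{:02x}{:02x}{:02x}".format(*color)


def _data_lines(text: str, has_header: bool):
    """Yield (1-based line number, raw line) of non-blank data lines."""
    lines = text.splitlines()
    start = 0
    if has_header:
        # skip the first non-blank line
        for i, line in enumerate(lines):
            if line.strip():
                start = i + 1
                break
        else:
            start = len(lines)
    for i in range(start, len(lines)):
        if lines[i].strip():
            yield i + 1, lines[i]


def _two_tokens(line: str, lineno: int) -> tuple[str, str]:
    parts = line.split("\t")
    if len(parts) != 2:
        raise FormatError(
            f"expected 2 TAB-separated columns, found {len(parts)}", line=lineno
        )
    a, b = parts[0].strip(), parts[1].strip()
    if not a or not b:
        raise FormatError("empty token", line=lineno)
    return a, b


def read_two_column(text: str, has_header: bool = False) -> SetCollection:
    """Parse the two-column long format (element TAB set-label).

    Set order follows first appearance in column 2; duplicate (element, set)
    pairs collapse to a single membership.
    """
    order: list[str] = []
    membership: dict[str, set[str]] = {}
    for lineno, line in _data_lines(text, has_header):
        elem, set_name = _two_tokens(line, lineno)
        if set_name not in order:
            order.append(set_name)
        membership.setdefault(elem, set()).add(set_name)
    return SetCollection(
        tuple(order), {e: frozenset(s) for e, s in membership.items()}
    )


def write_two_column(collection: SetCollection, header: bool = True) -> str:
    """Serialize a collection back to the two-column format (round-trips)."""
    out = ["id\tset"] if header else []
    for set_name in collection.set_names:
        for elem in sorted(collection.elements_of(set_name)):
            out.append(f"{elem}\t{set_name}")
    return "\n".join(out) + "\n"


def read_element_lists(blocks: Mapping[str, str]) -> SetCollection:
    """Parse one pasted element list per set.

    Each block splits on newlines and commas; blank tokens are dropped and
    within-set duplicates collapsed.  Set order follows block order.
    """
    sets: dict[str, list[str]] = {}
    for name, block in blocks.items():
        name = name.strip()
        if not name:
            raise FormatError("empty set name")
        tokens = [
            tok.strip()
            for line in block.splitlines()
            for tok in line.split(",")
        ]
        seen: list[str] = []
        for tok in tokens:
            if tok and tok not in seen:
                seen.append(tok)
        sets[name] = seen
    return SetCollection.from_sets(sets)


def read_intersection_counts(
    text: str, has_header: bool = False, semantics: str = "exclusive"
) -> IntersectionCountTable:
    """Parse the ``"&"``-signature count table.

    The set universe is the union of names appearing in any signature, in
    first-appearance order; signatures are canonicalized against it, so row
    order never changes the result.  ``semantics`` says whether the counts
    are disjoint-region counts (``"exclusive"``, the default) or full
    intersection sizes (``"inclusive"``).
    """
    raw: list[tuple[int, frozenset[str], int]] = []
    order: list[str] = []
    for lineno, line in _data_lines(text, has_header):
        sig_text, count_text = _two_tokens(line, lineno)
        try:
            subset = parse_signature(sig_text)
        except Exception as exc:
            raise FormatError(str(exc), line=lineno) from exc
        try:
            count = int(count_text)
        except ValueError as exc:
            raise FormatError(
                f"count is not an integer: {count_text!r}", line=lineno
            ) from exc
        if count < 0:
            raise FormatError(f"negative count: {count}", line=lineno)
        # preserve within-signature name order for universe ordering
        for tok in sig_text.split("&"):
            tok = tok.strip()
            if tok and tok not in order:
                order.append(tok)
        raw.append((lineno, subset, count))
    rows: dict[str, int] = {}
    for lineno, subset, count in raw:
        sig = canonical_signature(subset, order)
        if sig in rows:
            raise FormatError(f"duplicate signature {sig!r}", line=lineno)
        rows[sig] = count
    return IntersectionCountTable(tuple(order), rows, semantics)


def _signature_sort_key(partition: RegionPartition):
    pos = {name: i for i, name in enumerate(partition.set_names)}

    def key(sig: str):
        names = sig.split("&")
        return (len(names), tuple(pos[n] for n in names))

    return key


def write_region_csv(partition: RegionPartition) -> str:
    """One CSV column per non-empty region: header = signature, rows = IDs.

    Columns are ordered by signature degree then set order; elements sort
    lexicographically.  RFC 4180 dialect (comma separator, CRLF).
    """
    sigs = sorted(partition.regions, key=_signature_sort_key(partition))
    columns = [list(partition.elements(sig)) for sig in sigs]
    depth = max((len(c) for c in columns), default=0)
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(sigs)
    for i in range(depth):
        writer.writerow([col[i] if i < len(col) else "" for col in columns])
    return buf.getvalue()


def interpolate_colors(colors: list[RGB], n_sets: int) -> list[RGB]:
    """Stretch or truncate a color list to exactly ``n_sets`` entries.

    With enough colors the first ``n_sets`` are kept.  With fewer, colors
    are placed at evenly spaced positions along the input sequence and the
    gaps filled by linear RGB interpolation, rounding half up per channel;
    endpoints are preserved.  A single input color is simply repeated.
    """
    if not colors:
        raise FormatError("color list must be non-empty")
    if n_sets < 1:
        raise FormatError("n_sets must be >= 1")
    if len(colors) >= n_sets:
        return list(colors[:n_sets])
    if len(colors) == 1:
        return [colors[0]] * n_sets
    out: list[RGB] = []
    span = len(colors) - 1
    for j in range(n_sets):
        t = j * span / (n_sets - 1)
        i = min(int(t), span - 1)
        frac = t - i
        c0, c1 = colors[i], colors[i + 1]
        out.append(
            tuple(
                int(math.floor(c0[k] + (c1[k] - c0[k]) * frac + 0.5))
                for k in range(3)
            )
        )
    return out


# ---------------------------------------------------------------------------
# SVG writer


def _style_attrs(style) -> dict[str, str]:
    attrs = {}
    attrs["fill"] = rgb_to_hex(style.fill) if style.fill is not None else "none"
    if style.fill is not None and style.fill_opacity != 1.0:
        attrs["fill-opacity"] = f"{style.fill_opacity:g}"
    attrs["stroke"] = rgb_to_hex(style.stroke) if style.stroke is not None else "none"
    if style.stroke is not None:
        attrs["stroke-width"] = f"{style.stroke_width:g}"
    return attrs


def render_svg(scene: SceneGraph, size: int = 600) -> str:
    """Serialize a scene to an SVG 1.1 document.

    The scene bounding box is mapped (uniform scale, y flipped so the SVG
    y-axis points down) onto a ``size``×``size`` viewBox.  One SVG element is
    emitted per primitive, in scene order; text labels carry their strings
    verbatim.  An empty scene yields a minimal valid document.
    """
    x0, y0, x1, y1 = scene.bbox()
    w, h = max(x1 - x0, 1e-9), max(y1 - y0, 1e-9)
    s = size / max(w, h)
    pad = 0.02 * size

    def tx(x: float) -> float:
        return pad + (x - x0) * s

    def ty(y: float) -> float:
        return pad + (y1 - y) * s  # flip

    width = 2 * pad + w * s
    height = 2 * pad + h * s
    root = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "viewBox": f"0 0 {width:.2f} {height:.2f}",
            "width": f"{width:.0f}",
            "height": f"{height:.0f}",
        },
    )
    if scene.metadata:
        meta = ET.SubElement(root, "metadata")
        meta.text = " ".join(f"{k}={v}" for k, v in sorted(scene.metadata.items()))
    for prim in scene:
        if isinstance(prim, CirclePrim):
            el = ET.SubElement(root, "circle", _style_attrs(prim.style))
            el.set("cx", f"{tx(prim.cx):.3f}")
            el.set("cy", f"{ty(prim.cy):.3f}")
            el.set("r", f"{prim.r * s:.3f}")
        elif isinstance(prim, EllipsePrim):
            el = ET.SubElement(root, "ellipse", _style_attrs(prim.style))
            el.set("cx", "0")
            el.set("cy", "0")
            el.set("rx", f"{prim.rx * s:.3f}")
            el.set("ry", f"{prim.ry * s:.3f}")
            # plot-frame CCW rotation becomes CW in the flipped SVG frame
            el.set(
                "transform",
                f"translate({tx(prim.cx):.3f} {ty(prim.cy):.3f}) "
                f"rotate({-prim.rotation:.3f})",
            )
        elif isinstance(prim, PolygonPrim):
            el = ET.SubElement(root, "polygon", _style_attrs(prim.style))
            el.set(
                "points",
                " ".join(f"{tx(px):.3f},{ty(py):.3f}" for px, py in prim.points),
            )
        elif isinstance(prim, LinePrim):
            el = ET.SubElement(root, "line", _style_attrs(prim.style))
            el.set("x1", f"{tx(prim.x1):.3f}")
            el.set("y1", f"{ty(prim.y1):.3f}")
            el.set("x2", f"{tx(prim.x2):.3f}")
            el.set("y2", f"{ty(prim.y2):.3f}")
        elif isinstance(prim, RectPrim):
            el = ET.SubElement(root, "rect", _style_attrs(prim.style))
            el.set("x", f"{tx(prim.x):.3f}")
            el.set("y", f"{ty(prim.y + prim.height):.3f}")
            el.set("width", f"{prim.width * s:.3f}")
            el.set("height", f"{prim.height * s:.3f}")
        elif isinstance(prim, TextPrim):
            el = ET.SubElement(
                root,
                "text",
                {
                    "font-size": f"{prim.size * s:.3f}",
                    "font-family": "sans-serif",
                    "text-anchor": prim.anchor,
                    "fill": rgb_to_hex(prim.color),
                    "dominant-baseline": "middle",
                },
            )
            if prim.rotation:
                el.set(
                    "transform",
                    f"translate({tx(prim.x):.3f} {ty(prim.y):.3f}) "
                    f"rotate({-prim.rotation:.3f})",
                )
            else:
                el.set("x", f"{tx(prim.x):.3f}")
                el.set("y", f"{ty(prim.y):.3f}")
            el.text = prim.text
        else:  # pragma: no cover - defensive
            raise TypeError(f"unknown primitive {type(prim).__name__}")
    return ET.tostring(root, encoding="unicode", xml_declaration=True)
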