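"""Renderer-agnostic scene graph.

Every diagram builder emits a :class:`SceneGraph`: an ordered list of drawing
primitives in abstract plot units with a y-up mathematical coordinate frame.
The SVG writer in :mod:`vennkit.io_formats` maps it to a viewBox (flipping y).
Primitives carry only geometry and style; no diagram logic lives here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

RGB = tuple[int, int, int]


def _rot(x: float, y: float, cx: float, cy: float, deg: float) -> tuple[float, float]:
    t = math.radians(deg)
    dx, dy = x - cx, y - cy
    return cx + dx * math.cos(t) - dy * math.sin(t), cy + dx * math.sin(t) + dy * math.cos(t)


@dataclass
class Style:
    fill: RGB | None = None
    fill_opacity: float = 1.0
    stroke: RGB | None = (0, 0, 0)
    stroke_width: float = 0.01


@dataclass
class CirclePrim:
    cx: float
    cy: float
    r: float
    style: Style = field(default_factory=Style)

    def bbox(self):
        return (self.cx - self.r, self.cy - self.r, self.cx + self.r, self.cy + self.r)


@dataclass
class EllipsePrim:
    cx: float
    cy: float
    rx: float
    ry: float
    rotation: float = 0.0  # degrees, counter-clockwise in plot frame
    style: Style = field(default_factory=Style)

    def bbox(self):
        t = math.radians(self.rotation)
        hx = math.hypot(self.rx * math.cos(t), self.ry * math.sin(t))
        hy = math.hypot(self.rx * math.sin(t), self.ry * math.cos(t))
        return (self.cx - hx, self.cy - hy, self.cx + hx, self.cy + hy)


@dataclass
class PolygonPrim:
    points: Sequence[tuple[float, float]]
    style: Style = field(default_factory=Style)

    def bbox(self):
        xs = [p[0] for p in self.points]
        ys = [p[1] for p in self.points]
        return (min(xs), min(ys), max(xs), max(ys))


@dataclass
class LinePrim:
    x1: float
    y1: float
    x2: float
    y2: float
    style: Style = field(default_factory=Style)

    def bbox(self):
        return (
            min(self.x1, self.x2),
            min(self.y1, self.y2),
            max(self.x1, self.x2),
            max(self.y1, self.y2),
        )


@dataclass
class RectPrim:
    x: float
    y: float
    width: float
    height: float
    style: Style = field(default_factory=Style)

    def bbox(self):
        return (self.x, self.y, self.x + self.width, self.y + self.height)


@dataclass
class TextPrim:
    x: float
    y: float
    text: str
    size: float = 0.1
    anchor: str = "middle"  # start | middle | end
    rotation: float = 0.0  # degrees, counter-clockwise about (x, y)
    color: RGB = (0, 0, 0)

    def _corners(self):
        # crude glyph metrics: advance ~0.6 em, ascent+descent ~1 em
        w = 0.6 * self.size * max(len(self.text), 1)
        h = self.size
        if self.anchor == "start":
            x0 = self.x
        elif self.anchor == "end":
            x0 = self.x - w
        else:
            x0 = self.x - w / 2
        y0 = self.y - h / 2
        pts = [(x0, y0), (x0 + w, y0), (x0 + w, y0 + h), (x0, y0 + h)]
        return [_rot(px, py, self.x, self.y, self.rotation) for px, py in pts]

    def bbox(self):
        pts = self._corners()
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        return (min(xs), min(ys), max(xs), max(ys))


Primitive = CirclePrim | EllipsePrim | PolygonPrim | LinePrim | RectPrim | TextPrim


@dataclass
class SceneGraph:
    """Ordered drawing primitives plus free-form metadata for provenance."""

    primitives: list[Primitive] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def add(self, *prims: Primitive) -> "SceneGraph":
        self.primitives.extend(prims)
        return self

    def __iter__(self) -> Iterator[Primitive]:
        return iter(self.primitives)

    def __len__(self) -> int:
        return len(self.primitives)

    def texts(self) -> list[TextPrim]:
        return [p for p in self.primitives if isinstance(p, TextPrim)]

    def bbox(self) -> tuple[float, float, float, float]:
        """Union bounding box (x0, y0, x1, y1); unit square if empty."""
        if not self.primitives:
            return (0.0, 0.0, 1.0, 1.0)
        boxes = [p.bbox() for p in self.primitives]
        return (
            min(b[0] for b in boxes),
            min(b[1] for b in boxes),
            max(b[2] for b in boxes),
            max(b[3] for b in boxes),
        )
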