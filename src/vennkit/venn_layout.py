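"""Fixed-template classic and Edwards Venn diagrams for 2–6 sets.

A template is a list of shapes with point-membership tests over a canvas.
Region geometry (which cells exist, where labels go) is derived purely by
grid sampling the membership tests — no analytic arrangement computation —
so any shape family that realizes all 2^n − 1 interior cells can slot in.

Classic mode uses circles for 2–3 sets and the well-known congruent-ellipse
arrangements for 4–5.  For six sets no arrangement of convex shapes can
realize all 63 regions (two convex boundaries cross at most a bounded number
of times — for triangle pairs at most 6 — while the sixth curve must enter
all 32 faces of the five-set diagram), so classic n=6 switches to a
circle-based weave: two large circles whose arcs act as near-straight plane
splits, a central circle, and three serpentine curves of doubling frequency.
Edwards mode is the standard construction — two half-planes, a circle, and
serpentine curves — for every n.

All template constants are frozen after grid verification that every cell
exists and is comfortably larger than one grid pixel at 500×500.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import CapacityError, ResolutionError, VennKitError
from .scene import (
    RGB,
    CirclePrim,
    EllipsePrim,
    PolygonPrim,
    SceneGraph,
    Style,
    TextPrim,
)
from .setcore import RegionPartition, SIGNATURE_SEP

__all__ = [
    "ShapeSpec",
    "VennTemplate",
    "classic_template",
    "edwards_template",
    "region_label_positions",
    "venn_scene",
]

DEFAULT_RESOLUTION = 500


@dataclass(frozen=True)
class ShapeSpec:
    """One set's shape: a vectorized membership test plus draw geometry.

    ``kind`` is one of circle | ellipse | halfplane | parametric-curve.
    ``contains`` maps coordinate arrays to a boolean mask; ``params`` holds
    whatever the renderer needs for that kind.
    """

    kind: str
    params: dict
    contains: Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class VennTemplate:
    n_sets: int
    shapes: tuple[ShapeSpec, ...]
    canvas: tuple[float, float, float, float]  # x0, y0, x1, y1

    def signature_grid(self, resolution: int = DEFAULT_RESOLUTION):
        """Bitmask membership codes on a resolution² grid over the canvas."""
        x0, y0, x1, y1 = self.canvas
        gx = np.linspace(x0, x1, resolution)
        gy = np.linspace(y0, y1, resolution)
        X, Y = np.meshgrid(gx, gy)
        code = np.zeros(X.shape, dtype=np.int64)
        for i, shape in enumerate(self.shapes):
            code |= shape.contains(X, Y).astype(np.int64) << i
        return X, Y, code

    def interior_cells(self, resolution: int = DEFAULT_RESOLUTION) -> set[int]:
        """Distinct non-empty membership codes found by sampling."""
        _, _, code = self.signature_grid(resolution)
        u = np.unique(code)
        return {int(c) for c in u if c > 0}

    def point_code(self, x: float, y: float) -> int:
        xa, ya = np.asarray([x]), np.asarray([y])
        code = 0
        for i, shape in enumerate(self.shapes):
            if bool(shape.contains(xa, ya)[0]):
                code |= 1 << i
        return code


def _circle(cx: float, cy: float, r: float) -> ShapeSpec:
    return ShapeSpec(
        "circle",
        {"cx": cx, "cy": cy, "r": r},
        lambda X, Y, cx=cx, cy=cy, r=r: (X - cx) ** 2 + (Y - cy) ** 2 <= r * r,
    )


def _ellipse(cx: float, cy: float, a: float, b: float, deg: float) -> ShapeSpec:
    t = math.radians(deg)

    def contains(X, Y, cx=cx, cy=cy, a=a, b=b, t=t):
        dx, dy = X - cx, Y - cy
        u = dx * math.cos(t) + dy * math.sin(t)
        v = -dx * math.sin(t) + dy * math.cos(t)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    return ShapeSpec(
        "ellipse", {"cx": cx, "cy": cy, "a": a, "b": b, "rotation": deg}, contains
    )


def _halfplane(axis: str, sign: int) -> ShapeSpec:
    if axis == "x":
        contains = lambda X, Y, s=sign: s * X > 0  # noqa: E731
    else:
        contains = lambda X, Y, s=sign: s * Y > 0  # noqa: E731
    return ShapeSpec("halfplane", {"axis": axis, "sign": sign}, contains)


def _serpentine(freq: int, amp: float, base_r: float = 1.0) -> ShapeSpec:
    def contains(X, Y, f=freq, a=amp, r0=base_r):
        R = np.hypot(X, Y)
        TH = np.arctan2(Y, X)
        return R <= r0 + a * np.cos(f * TH)

    return ShapeSpec(
        "parametric-curve", {"freq": freq, "amp": amp, "base_r": base_r}, contains
    )


# frozen constants: congruent-ellipse arrangements for classic 4 and 5 sets
# (centers/semi-axes in canvas units, rotation in degrees)
_ELLIPSES_4 = [
    (0.350, 0.400, 0.36, 0.225, 140.0),
    (0.450, 0.500, 0.36, 0.225, 140.0),
    (0.544, 0.500, 0.36, 0.225, 40.0),
    (0.644, 0.400, 0.36, 0.225, 40.0),
]
_ELLIPSES_5 = [
    (0.428, 0.449, 0.435, 0.250, 155.0),
    (0.469, 0.543, 0.435, 0.250, 82.0),
    (0.558, 0.523, 0.435, 0.250, 10.0),
    (0.578, 0.432, 0.435, 0.250, 118.0),
    (0.489, 0.383, 0.435, 0.250, 46.0),
]
_SERPENTINE_AMPS = {2: 0.40, 4: 0.20, 8: 0.10}
_BIG_R = 40.0  # classic-6 weave: radius of the two near-straight circles


def classic_template(n: int) -> VennTemplate:
    """Classic-mode template: circles (2–3), ellipses (4–5), weave (6)."""
    if not 2 <= n <= 6:
        raise CapacityError(f"classic Venn templates cover 2-6 sets, got {n}")
    if n == 2:
        shapes = (_circle(-0.5, 0.0, 1.0), _circle(0.5, 0.0, 1.0))
        return VennTemplate(2, shapes, (-1.7, -1.2, 1.7, 1.2))
    if n == 3:
        h = 1 / math.sqrt(3)
        shapes = (
            _circle(0.0, h, 1.0),
            _circle(-0.5, -h / 2, 1.0),
            _circle(0.5, -h / 2, 1.0),
        )
        return VennTemplate(3, shapes, (-1.7, -1.7, 1.7, 1.8))
    if n == 4:
        shapes = tuple(_ellipse(*p) for p in _ELLIPSES_4)
        return VennTemplate(4, shapes, (-0.1, 0.0, 1.1, 0.95))
    if n == 5:
        shapes = tuple(_ellipse(*p) for p in _ELLIPSES_5)
        return VennTemplate(5, shapes, (-0.05, -0.05, 1.05, 1.05))
    shapes = (
        _circle(0.0, _BIG_R, _BIG_R),
        _circle(_BIG_R, 0.0, _BIG_R),
        _circle(0.0, 0.0, 1.0),
        _serpentine(2, _SERPENTINE_AMPS[2]),
        _serpentine(4, _SERPENTINE_AMPS[4]),
        _serpentine(8, _SERPENTINE_AMPS[8]),
    )
    return VennTemplate(6, shapes, (-2.2, -2.2, 2.2, 2.2))


def edwards_template(n: int) -> VennTemplate:
    """Edwards construction: half-planes, circle, serpentines of doubling
    frequency."""
    if not 2 <= n <= 6:
        raise CapacityError(f"Edwards templates cover 2-6 sets, got {n}")
    shapes: list[ShapeSpec] = [_halfplane("y", 1), _halfplane("x", 1)]
    if n >= 3:
        shapes.append(_circle(0.0, 0.0, 1.0))
    for k in range(4, n + 1):
        freq = 2 ** (k - 3)
        shapes.append(_serpentine(freq, _SERPENTINE_AMPS[freq]))
    return VennTemplate(n, tuple(shapes), (-2.2, -2.2, 2.2, 2.2))


def _code_to_signature(code: int, set_names: Sequence[str]) -> str:
    return SIGNATURE_SEP.join(
        set_names[i] for i in range(len(set_names)) if code >> i & 1
    )


def region_label_positions(
    template: VennTemplate, resolution: int = DEFAULT_RESOLUTION
) -> dict[int, tuple[float, float]]:
    """A label anchor inside every interior cell, keyed by membership code.

    The anchor is the cell's sampled centroid; if that falls outside the
    (possibly non-convex) cell it snaps to the cell's deepest sampled point,
    i.e. the grid point farthest from any non-member pixel.
    """
    from scipy import ndimage

    X, Y, code = template.signature_grid(resolution)
    positions: dict[int, tuple[float, float]] = {}
    found = {int(c) for c in np.unique(code) if c > 0}
    for c in range(1, 2**template.n_sets):
        if c not in found:
            raise ResolutionError(
                f"cell {c:#x} not sampled at resolution {resolution}; "
                "increase the grid resolution"
            )
    for c in sorted(found):
        mask = code == c
        cx = float(X[mask].mean())
        cy = float(Y[mask].mean())
        if template.point_code(cx, cy) != c:
            depth = ndimage.distance_transform_edt(mask)
            iy, ix = np.unravel_index(int(np.argmax(depth)), depth.shape)
            cx, cy = float(X[iy, ix]), float(Y[iy, ix])
        positions[c] = (cx, cy)
    return positions


def _shape_primitives(template: VennTemplate, colors: Sequence[RGB]):
    """Draw each template shape as a filled translucent primitive."""
    x0, y0, x1, y1 = template.canvas
    prims = []
    for shape, color in zip(template.shapes, colors):
        style = Style(fill=color, fill_opacity=0.35, stroke=(40, 40, 40),
                      stroke_width=0.004 * (x1 - x0))
        p = shape.params
        if shape.kind == "circle":
            # huge weave circles render as canvas-clipped polygons
            if p["r"] > 2 * (x1 - x0):
                prims.append(_clip_halfdisk(shape, template.canvas, style))
            else:
                prims.append(CirclePrim(p["cx"], p["cy"], p["r"], style))
        elif shape.kind == "ellipse":
            prims.append(
                EllipsePrim(p["cx"], p["cy"], p["a"], p["b"], p["rotation"], style)
            )
        elif shape.kind == "halfplane":
            if p["axis"] == "x":
                pts = [(0, y0), (x1, y0), (x1, y1), (0, y1)] if p["sign"] > 0 else [
                    (x0, y0), (0, y0), (0, y1), (x0, y1)]
            else:
                pts = [(x0, 0), (x1, 0), (x1, y1), (x0, y1)] if p["sign"] > 0 else [
                    (x0, y0), (x1, y0), (x1, 0), (x0, 0)]
            prims.append(PolygonPrim(pts, style))
        else:  # serpentine
            th = np.linspace(0, 2 * math.pi, 720, endpoint=False)
            r = p["base_r"] + p["amp"] * np.cos(p["freq"] * th)
            pts = list(zip(r * np.cos(th), r * np.sin(th)))
            prims.append(PolygonPrim(pts, style))
    return prims


def _clip_halfdisk(shape: ShapeSpec, canvas, style) -> PolygonPrim:
    """Intersect a huge disk with the canvas rectangle, as a polygon."""
    x0, y0, x1, y1 = canvas
    p = shape.params
    rect = [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]
    # Sutherland–Hodgman against the circle is overkill at this curvature;
    # sample the boundary chord across the canvas instead.
    ts = np.linspace(0, 2 * math.pi, 4096)
    bx = p["cx"] + p["r"] * np.cos(ts)
    by = p["cy"] + p["r"] * np.sin(ts)
    inside_canvas = (bx >= x0) & (bx <= x1) & (by >= y0) & (by <= y1)
    chord = [(float(x), float(y)) for x, y in zip(bx[inside_canvas], by[inside_canvas])]
    corners = [
        (cx, cy)
        for cx, cy in rect
        if (cx - p["cx"]) ** 2 + (cy - p["cy"]) ** 2 <= p["r"] ** 2
    ]
    if not chord:
        return PolygonPrim(rect if len(corners) == 4 else corners or rect, style)
    # order: chord endpoints plus interior corners, sorted by angle about
    # the chord midpoint projected toward the disk center
    mx = sum(pt[0] for pt in chord) / len(chord)
    my = sum(pt[1] for pt in chord) / len(chord)
    pts = chord + corners
    pts.sort(key=lambda q: math.atan2(q[1] - my, q[0] - mx))
    return PolygonPrim(pts, style)


def venn_scene(
    partition: RegionPartition,
    mode: str = "classic",
    colors: Sequence[RGB] | None = None,
    resolution: int = DEFAULT_RESOLUTION,
) -> SceneGraph:
    """Draw a partition on a fixed Venn template.

    Every region gets its exclusive count label (0 shown for empty regions);
    labels are never recomputed from set logic here — they are exactly the
    partition's counts.  Set-name labels sit outside the shapes.
    """
    n = partition.n_sets
    if n > 6:
        raise CapacityError(
            f"Venn templates cover 2-6 sets, got {n}; "
            "use an UpSet plot or a flower plot instead"
        )
    if mode == "classic":
        template = classic_template(n)
    elif mode == "edwards":
        template = edwards_template(n)
    else:
        raise VennKitError(f"unknown mode {mode!r} (classic | edwards)")
    from .io_formats import DEFAULT_PALETTE, interpolate_colors

    colors = interpolate_colors(list(colors) if colors else DEFAULT_PALETTE, n)
    x0, y0, x1, y1 = template.canvas
    span = max(x1 - x0, y1 - y0)
    scene = SceneGraph(metadata={"diagram": f"venn-{mode}", "n_sets": n})
    scene.add(*_shape_primitives(template, colors))
    positions = region_label_positions(template, resolution)
    counts = partition.counts()
    label_size = 0.03 * span
    for code, (cx, cy) in positions.items():
        sig = _code_to_signature(code, partition.set_names)
        scene.add(TextPrim(cx, cy, str(counts.get(sig, 0)), size=label_size))
    # set-name labels: push the singleton-region anchor outward past the canvas
    ccx, ccy = (x0 + x1) / 2, (y0 + y1) / 2
    for i, name in enumerate(partition.set_names):
        ax, ay = positions[1 << i]
        dx, dy = ax - ccx, ay - ccy
        norm = math.hypot(dx, dy) or 1.0
        margin = 0.52 * span
        lx = ccx + dx / norm * margin * 1.02
        ly = ccy + dy / norm * margin * 1.02
        scene.add(
            TextPrim(lx, ly, name, size=label_size, color=colors[i])
        )
    return scene
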