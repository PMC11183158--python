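"""Flower plots: a shared core with one petal per set, for many-set data.

The central circle carries the count of elements present in *every* set.
Petals carry either each set's strictly unique count (``unique`` mode) or
its size after subtracting the core (``residual`` mode; petal + core equals
the set size).  Petal k sits at angle 2πk/n on a fixed orbit; petal size and
label size shrink like 1/√n so plots stay legible up to ~70 sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import CapacityError, VennKitError
from .scene import (
    RGB,
    CirclePrim,
    EllipsePrim,
    SceneGraph,
    Style,
    TextPrim,
)
from .setcore import SetCollection, flower_decomposition

__all__ = ["FlowerSpec", "flower_values", "flower_scene"]

MIN_SETS = 3


@dataclass(frozen=True)
class FlowerSpec:
    core_value: int
    petals: tuple[tuple[str, int], ...]
    mode: str  # unique | residual

    def __post_init__(self):
        if self.mode not in ("unique", "residual"):
            raise VennKitError(f"unknown petal mode {self.mode!r}")
        if any(v < 0 for _, v in self.petals):
            raise VennKitError("petal values must be non-negative")


def flower_values(collection: SetCollection, mode: str = "unique") -> FlowerSpec:
    """Core plus per-set petal values in the requested mode."""
    if collection.n_sets < MIN_SETS:
        raise CapacityError(
            f"flower plots need at least {MIN_SETS} sets, got {collection.n_sets}"
        )
    dec = flower_decomposition(collection)
    values = dec.unique if mode == "unique" else dec.residual
    if mode not in ("unique", "residual"):
        raise VennKitError(f"unknown petal mode {mode!r}")
    petals = tuple((name, values[name]) for name in collection.set_names)
    return FlowerSpec(dec.core, petals, mode)


def petal_angle(k: int, n: int) -> float:
    """Angle of petal k (radians, counter-clockwise from +x)."""
    return 2.0 * math.pi * k / n


def flower_scene(spec: FlowerSpec, colors: Sequence[RGB] | None = None) -> SceneGraph:
    """Central labelled circle plus n congruent ellipse petals on an orbit.

    Petal k is rotated to its axis at 2πk/n; value labels sit at the petal
    tip and set names beyond it, rotated along the axis and flipped upright
    for angles in (90°, 270°).
    """
    from .io_formats import DEFAULT_PALETTE, interpolate_colors

    n = len(spec.petals)
    if n == 0:
        raise VennKitError("flower needs at least one petal")
    colors = interpolate_colors(list(colors) if colors else DEFAULT_PALETTE, n)
    rs = 1.0 / math.sqrt(n)  # legibility scale
    orbit = 1.0
    core_r = 0.55
    petal_a = 1.35 * rs  # semi-major, along axis
    petal_b = 0.85 * rs  # semi-minor
    label_size = 0.30 * rs
    scene = SceneGraph(metadata={"diagram": "flower", "mode": spec.mode, "n_sets": n})
    for k, ((name, value), color) in enumerate(zip(spec.petals, colors)):
        ang = petal_angle(k, n)
        deg = math.degrees(ang)
        cx = (orbit + petal_a * 0.4) * math.cos(ang)
        cy = (orbit + petal_a * 0.4) * math.sin(ang)
        scene.add(
            EllipsePrim(cx, cy, petal_a, petal_b, deg,
                        Style(fill=color, fill_opacity=0.55, stroke=(60, 60, 60),
                              stroke_width=0.01)),
        )
        upright = 90.0 < (deg % 360.0) < 270.0
        text_rot = deg + 180.0 if upright else deg
        vr = orbit + petal_a * 0.4 + petal_a + 0.8 * label_size
        nr = vr + 1.6 * label_size + 0.32 * label_size * len(name)
        scene.add(
            TextPrim(vr * math.cos(ang), vr * math.sin(ang), str(value),
                     size=label_size, rotation=text_rot),
            TextPrim(nr * math.cos(ang), nr * math.sin(ang), name,
                     size=label_size, rotation=text_rot, color=colors[k]),
        )
    scene.add(
        CirclePrim(0.0, 0.0, core_r,
                   Style(fill=(250, 245, 200), fill_opacity=0.95,
                         stroke=(60, 60, 60), stroke_width=0.012)),
        TextPrim(0.0, 0.0, str(spec.core_value), size=0.28),
    )
    return scene
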