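"""Area-proportional Euler layout for two and three sets.

Circle areas are proportional to inclusive set sizes and overlap areas to
shared-element counts.  Two-set layouts are exact: the center distance that
realizes the target lens area is solved by bisection of the closed-form
circle–circle intersection area, which is monotone non-increasing in the
distance.  Three sets generally admit no exact disk arrangement, so centers
are placed by minimizing a quadratic stress between achieved and target
region areas with a deterministic Nelder–Mead search started from the
pairwise-exact triangle; achieved areas come from a seeded quasi-random
(Halton) sampling oracle.  Empty overlaps are drawn disjoint and full
containment nested, mirroring Euler-diagram practice; an impossible area
specification is rendered at minimum stress with a warning rather than an
error.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .errors import CapacityError, VennKitError
from .scene import RGB, CirclePrim, SceneGraph, Style, TextPrim
from .setcore import (
    RegionPartition,
    canonical_signature,
    inclusive_size,
)

__all__ = [
    "CircleSpec",
    "EulerLayout",
    "lens_area",
    "solve_distance",
    "region_areas",
    "layout_euler",
    "euler_scene",
]

#: Halton points used by the area oracle (quasi-random, so the integration
#: error decays ~ (log N)^2 / N rather than N^-1/2).
DEFAULT_SAMPLES = 200_000


@dataclass(frozen=True)
class CircleSpec:
    center: tuple[float, float]
    radius: float

    def __post_init__(self):
        if not (self.radius > 0 and math.isfinite(self.radius)):
            raise VennKitError("radius must be positive and finite")
        if not all(math.isfinite(c) for c in self.center):
            raise VennKitError("center must be finite")


@dataclass(frozen=True)
class EulerLayout:
    set_names: tuple[str, ...]
    circles: tuple[CircleSpec, ...]
    target_areas: Mapping[str, float]
    achieved_region_areas: Mapping[str, float]
    stress: float
    stress_history: tuple[float, ...] = ()
    seed: int = 0


def lens_area(r1: float, r2: float, d: float) -> float:
    """Intersection area of two circles with radii r1, r2 at distance d.

    Zero when disjoint (d ≥ r1+r2); the smaller circle's area when contained
    (d ≤ |r1−r2|); otherwise the sum of the two circular segments.
    """
    if r1 <= 0 or r2 <= 0:
        raise VennKitError("radii must be positive")
    if d < 0:
        raise VennKitError("distance must be non-negative")
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return math.pi * min(r1, r2) ** 2
    # central angles of the two segments
    a1 = 2.0 * math.acos((d * d + r1 * r1 - r2 * r2) / (2.0 * d * r1))
    a2 = 2.0 * math.acos((d * d + r2 * r2 - r1 * r1) / (2.0 * d * r2))
    return 0.5 * r1 * r1 * (a1 - math.sin(a1)) + 0.5 * r2 * r2 * (a2 - math.sin(a2))


def solve_distance(r1: float, r2: float, target: float, tol: float = 1e-10) -> float:
    """Invert :func:`lens_area`: the center distance realizing ``target``.

    Bisection on [|r1−r2|, r1+r2]; ``lens_area`` is monotone non-increasing
    in d there.  ``target`` must lie in [0, π·min(r1,r2)²].
    """
    max_area = math.pi * min(r1, r2) ** 2
    if not (0 <= target <= max_area * (1 + 1e-12)):
        raise VennKitError(
            f"target lens area {target} outside [0, {max_area}]"
        )
    lo, hi = abs(r1 - r2), r1 + r2
    if target <= 0:
        return hi
    if target >= max_area:
        return lo
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if lens_area(r1, r2, mid) > target:
            lo = mid
        else:
            hi = mid
        if abs(lens_area(r1, r2, 0.5 * (lo + hi)) - target) <= tol:
            break
    return 0.5 * (lo + hi)


def region_areas(
    circles: Sequence[CircleSpec],
    n_samples: int = DEFAULT_SAMPLES,
    seed: int = 0,
) -> dict[str, float]:
    """Numeric exclusive-region areas for 1–3 circles by Halton sampling.

    Signatures use positional names "1", "2", "3" unless mapped by a caller.
    Deterministic for a fixed seed.
    """
    if not 1 <= len(circles) <= 3:
        raise VennKitError("region_areas supports 1-3 circles")
    x0 = min(c.center[0] - c.radius for c in circles)
    x1 = max(c.center[0] + c.radius for c in circles)
    y0 = min(c.center[1] - c.radius for c in circles)
    y1 = max(c.center[1] + c.radius for c in circles)
    box_area = (x1 - x0) * (y1 - y0)
    sampler = qmc.Halton(d=2, scramble=True, seed=seed)
    pts = sampler.random(n_samples)
    xs = x0 + pts[:, 0] * (x1 - x0)
    ys = y0 + pts[:, 1] * (y1 - y0)
    code = np.zeros(n_samples, dtype=np.int64)
    for i, c in enumerate(circles):
        inside = (xs - c.center[0]) ** 2 + (ys - c.center[1]) ** 2 <= c.radius**2
        code |= inside.astype(np.int64) << i
    counts = np.bincount(code, minlength=2 ** len(circles))
    names = [str(i + 1) for i in range(len(circles))]
    out: dict[str, float] = {}
    for mask in range(1, 2 ** len(circles)):
        sig = "&".join(names[i] for i in range(len(circles)) if mask >> i & 1)
        out[sig] = counts[mask] / n_samples * box_area
    return out


def _rename_regions(areas: Mapping[str, float], set_names: Sequence[str]):
    out = {}
    for sig, a in areas.items():
        idx = [int(tok) - 1 for tok in sig.split("&")]
        out["&".join(set_names[i] for i in idx)] = a
    return out


def _targets(partition: RegionPartition, area_per_element: float) -> dict[str, float]:
    return {sig: cnt * area_per_element for sig, cnt in partition.counts().items()}


def _stress(achieved: Mapping[str, float], targets: Mapping[str, float]) -> float:
    sigs = set(achieved) | set(targets)
    return sum((achieved.get(s, 0.0) - targets.get(s, 0.0)) ** 2 for s in sigs)


def layout_euler(
    partition: RegionPartition,
    n_samples: int = DEFAULT_SAMPLES,
    opt_samples: int = 20_000,
    seed: int = 0,
) -> EulerLayout:
    """Place area-proportional circles for a 2- or 3-set partition.

    Radii are scaled so the largest circle has radius 1 and each set's disk
    area is proportional to its inclusive size.  ``opt_samples`` controls the
    (cheaper) oracle used inside the 3-set optimizer; final achieved areas
    and stress always use ``n_samples``.
    """
    names = partition.set_names
    n = len(names)
    if n not in (2, 3):
        raise CapacityError(
            f"Euler layout supports 2 or 3 sets, got {n}; "
            "use a Venn template or an UpSet plot instead"
        )
    sizes = {nm: inclusive_size(partition, {nm}) for nm in names}
    if any(s <= 0 for s in sizes.values()):
        raise VennKitError("every set must have a positive inclusive size")
    max_size = max(sizes.values())
    # area per element such that the largest circle has radius exactly 1
    a0 = math.pi / max_size
    radii = {nm: math.sqrt(sizes[nm] * a0 / math.pi) for nm in names}
    targets = _targets(partition, a0)

    def pair_distance(na: str, nb: str) -> float:
        overlap = inclusive_size(partition, {na, nb}) * a0
        cap = math.pi * min(radii[na], radii[nb]) ** 2
        if overlap > cap:
            warnings.warn(
                f"overlap of {na} and {nb} exceeds the smaller circle; clamping",
                stacklevel=2,
            )
            overlap = cap
        d = solve_distance(radii[na], radii[nb], overlap, tol=1e-12)
        if overlap <= 0:
            d += 0.1 * min(radii[na], radii[nb])  # draw clearly disjoint
        elif overlap >= cap:
            d = max(0.0, d - 0.05 * min(radii[na], radii[nb]))  # nest strictly
        return d

    if n == 2:
        d = pair_distance(names[0], names[1])
        circles = (
            CircleSpec((0.0, 0.0), radii[names[0]]),
            CircleSpec((d, 0.0), radii[names[1]]),
        )
        r1, r2 = radii[names[0]], radii[names[1]]
        lens = lens_area(r1, r2, d)
        achieved = {
            names[0]: math.pi * r1 * r1 - lens,
            names[1]: math.pi * r2 * r2 - lens,
            canonical_signature(set(names), names): lens,
        }
        stress = _stress(achieved, targets)
        return EulerLayout(names, circles, targets, achieved, stress, (stress,), seed)

    # --- three sets: pairwise-exact triangle init, then stress descent
    d12 = pair_distance(names[0], names[1])
    d13 = pair_distance(names[0], names[2])
    d23 = pair_distance(names[1], names[2])
    c1 = (0.0, 0.0)
    c2 = (d12, 0.0)
    if d12 > 1e-12:
        cos_t = (d12**2 + d13**2 - d23**2) / (2 * d12 * d13)
        cos_t = min(1.0, max(-1.0, cos_t))
    else:
        cos_t = 1.0
    sin_t = math.sqrt(max(0.0, 1 - cos_t**2))
    c3 = (d13 * cos_t, d13 * sin_t)

    rs = [radii[nm] for nm in names]

    def circles_from(params) -> tuple[CircleSpec, ...]:
        x2, x3, y3 = params
        return (
            CircleSpec((0.0, 0.0), rs[0]),
            CircleSpec((float(x2), 0.0), rs[1]),
            CircleSpec((float(x3), float(y3)), rs[2]),
        )

    def objective(params) -> float:
        ach = _rename_regions(
            region_areas(circles_from(params), opt_samples, seed), names
        )
        return _stress(ach, targets)

    x0 = np.array([c2[0], c3[0], c3[1]])
    history: list[float] = [objective(x0)]

    def callback(xk):
        history.append(min(history[-1], objective(xk)))

    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        callback=callback,
        options={"maxiter": 300, "xatol": 1e-4, "fatol": 1e-8},
    )
    best = res.x if res.fun <= history[0] else x0
    circles = circles_from(best)
    achieved = _rename_regions(region_areas(circles, n_samples, seed), names)
    stress = _stress(achieved, targets)
    total = sum(targets.values())
    if total > 0 and stress > 0.01 * total**2:
        warnings.warn(
            "no circle arrangement realizes these region areas well; "
            "drawn at minimum stress",
            stacklevel=2,
        )
    return EulerLayout(
        names, circles, targets, achieved, stress, tuple(history), seed
    )


def _region_centroids(
    circles: Sequence[CircleSpec],
    set_names: Sequence[str],
    n_samples: int = 50_000,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    x0 = min(c.center[0] - c.radius for c in circles)
    x1 = max(c.center[0] + c.radius for c in circles)
    y0 = min(c.center[1] - c.radius for c in circles)
    y1 = max(c.center[1] + c.radius for c in circles)
    sampler = qmc.Halton(d=2, scramble=True, seed=seed)
    pts = sampler.random(n_samples)
    xs = x0 + pts[:, 0] * (x1 - x0)
    ys = y0 + pts[:, 1] * (y1 - y0)
    code = np.zeros(n_samples, dtype=np.int64)
    for i, c in enumerate(circles):
        inside = (xs - c.center[0]) ** 2 + (ys - c.center[1]) ** 2 <= c.radius**2
        code |= inside.astype(np.int64) << i
    out: dict[str, tuple[float, float]] = {}
    for mask in range(1, 2 ** len(circles)):
        sel = code == mask
        if not sel.any():
            continue
        sig = "&".join(set_names[i] for i in range(len(circles)) if mask >> i & 1)
        cx, cy = float(xs[sel].mean()), float(ys[sel].mean())
        # a lens/crescent can be non-convex; snap to the member point
        # closest to the centroid if the centroid itself fell outside
        pt_code = 0
        for i, c in enumerate(circles):
            if (cx - c.center[0]) ** 2 + (cy - c.center[1]) ** 2 <= c.radius**2:
                pt_code |= 1 << i
        if pt_code != mask:
            d2 = (xs[sel] - cx) ** 2 + (ys[sel] - cy) ** 2
            k = int(np.argmin(d2))
            cx, cy = float(xs[sel][k]), float(ys[sel][k])
        out[sig] = (cx, cy)
    return out


def euler_scene(
    layout: EulerLayout,
    partition: RegionPartition,
    colors: Sequence[RGB],
    label_size: float | None = None,
) -> SceneGraph:
    """Draw an Euler layout: filled circles plus a count label per region."""
    if tuple(partition.set_names) != tuple(layout.set_names):
        raise VennKitError("layout and partition must share the same sets")
    scene = SceneGraph(metadata={"diagram": "euler", "seed": layout.seed})
    rmax = max(c.radius for c in layout.circles)
    size = label_size if label_size is not None else 0.12 * rmax
    for circle, color in zip(layout.circles, colors):
        scene.add(
            CirclePrim(
                circle.center[0],
                circle.center[1],
                circle.radius,
                Style(fill=color, fill_opacity=0.5, stroke=(40, 40, 40),
                      stroke_width=0.01 * rmax),
            )
        )
    centroids = _region_centroids(layout.circles, layout.set_names, seed=layout.seed)
    for sig, cnt in partition.counts().items():
        if cnt <= 0 or sig not in centroids:
            continue
        x, y = centroids[sig]
        scene.add(TextPrim(x, y, str(cnt), size=size))
    for circle, name in zip(layout.circles, layout.set_names):
        scene.add(
            TextPrim(
                circle.center[0],
                circle.center[1] + circle.radius + 1.2 * size,
                name,
                size=size,
            )
        )
    return scene
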