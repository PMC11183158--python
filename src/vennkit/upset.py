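"""UpSet intersection matrices and their three-panel scene for 3–40 sets.

The matrix columns are the exclusive intersection regions; set totals are
inclusive sizes.  Default column order is count descending, ties broken by
signature degree ascending then canonical signature — the common UpSet
convention — with a degree-first alternative.  Keeping empty intersections
enumerates all 2^n − 1 signatures and is therefore capped at 12 sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .errors import CapacityError, VennKitError
from .scene import (
    CirclePrim,
    LinePrim,
    RectPrim,
    SceneGraph,
    Style,
    TextPrim,
)
from .setcore import (
    RegionPartition,
    SIGNATURE_SEP,
    inclusive_size,
    parse_signature,
)

__all__ = ["UpSetMatrix", "build_matrix", "upset_scene"]

MIN_SETS, MAX_SETS, MAX_ENUMERATED = 3, 40, 12


@dataclass(frozen=True)
class UpSetMatrix:
    set_names: tuple[str, ...]
    set_totals: dict[str, int]
    columns: tuple[tuple[str, int], ...]
    keep_empty: bool = False


def _sort_key(set_names, sort: str):
    pos = {name: i for i, name in enumerate(set_names)}

    def degree(sig: str) -> int:
        return sig.count(SIGNATURE_SEP) + 1

    if sort == "count":
        return lambda col: (-col[1], degree(col[0]), col[0])
    if sort == "degree":
        return lambda col: (
            degree(col[0]),
            tuple(pos[n] for n in col[0].split(SIGNATURE_SEP)),
        )
    raise VennKitError(f"unknown sort {sort!r} (count | degree)")


def build_matrix(
    partition: RegionPartition, keep_empty: bool = False, sort: str = "count"
) -> UpSetMatrix:
    """Assemble the UpSet column list from an exclusive-region partition."""
    n = partition.n_sets
    if not MIN_SETS <= n <= MAX_SETS:
        raise CapacityError(f"UpSet plots cover {MIN_SETS}-{MAX_SETS} sets, got {n}")
    if keep_empty and n > MAX_ENUMERATED:
        raise CapacityError(
            f"keep_empty enumerates 2^n-1 signatures; capped at {MAX_ENUMERATED} sets"
        )
    counts = partition.counts()
    if keep_empty:
        for k in range(1, n + 1):
            for combo in itertools.combinations(partition.set_names, k):
                counts.setdefault(SIGNATURE_SEP.join(combo), 0)
    else:
        counts = {sig: c for sig, c in counts.items() if c > 0}
    columns = tuple(sorted(counts.items(), key=_sort_key(partition.set_names, sort)))
    totals = {
        name: inclusive_size(partition, {name}) for name in partition.set_names
    }
    return UpSetMatrix(partition.set_names, totals, columns, keep_empty)


def upset_scene(matrix: UpSetMatrix) -> SceneGraph:
    """Three aligned panels: set-total bars, intersection bars, dot matrix.

    One filled dot per member set per column; consecutive member dots are
    joined by a vertical segment.  Bar lengths are linear in counts and each
    vertical bar carries its count printed above it.
    """
    n = len(matrix.set_names)
    ncol = len(matrix.columns)
    cell = 1.0  # dot-matrix cell pitch in plot units
    bar_h = 6.0  # height of the vertical-bar panel
    hbar_w = 5.0  # width of the horizontal-bar panel
    gap = 0.8
    max_count = max((c for _, c in matrix.columns), default=1) or 1
    max_total = max(matrix.set_totals.values(), default=1) or 1

    scene = SceneGraph(metadata={"diagram": "upset", "n_sets": n, "columns": ncol})
    grey = Style(fill=(150, 150, 150), stroke=None)
    dark = Style(fill=(60, 60, 60), stroke=None)
    open_dot = Style(fill=(225, 225, 225), stroke=None)

    # row y for each set (matrix rows run top to bottom in input order)
    row_y = {name: -(i + 1) * cell for i, name in enumerate(matrix.set_names)}
    col_x = {j: (j + 0.5) * cell for j in range(ncol)}

    # horizontal bars (set totals), to the left of the matrix
    for name in matrix.set_names:
        w = hbar_w * matrix.set_totals[name] / max_total
        y = row_y[name]
        scene.add(
            RectPrim(-gap - w, y - 0.35 * cell, w, 0.7 * cell, grey),
            TextPrim(-gap - w - 0.2, y, f"{matrix.set_totals[name]}",
                     size=0.38 * cell, anchor="end"),
            TextPrim(-gap - hbar_w - 2.5, y, name, size=0.38 * cell, anchor="end"),
        )
    # vertical bars (intersection counts), above the matrix
    for j, (sig, cnt) in enumerate(matrix.columns):
        h = bar_h * cnt / max_count
        scene.add(
            RectPrim(col_x[j] - 0.35 * cell, gap, 0.7 * cell, max(h, 1e-6), dark),
            TextPrim(col_x[j], gap + h + 0.45 * cell, str(cnt), size=0.38 * cell),
        )
    # dot matrix
    for j, (sig, _cnt) in enumerate(matrix.columns):
        members = parse_signature(sig)
        ys = sorted((row_y[name] for name in members), reverse=True)
        for name in matrix.set_names:
            style = dark if name in members else open_dot
            scene.add(CirclePrim(col_x[j], row_y[name], 0.28 * cell, style))
        for y1, y2 in zip(ys, ys[1:]):
            scene.add(
                LinePrim(col_x[j], y1, col_x[j], y2,
                         Style(stroke=(60, 60, 60), stroke_width=0.12 * cell))
            )
    return scene
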