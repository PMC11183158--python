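"""Exact set calculus: canonical signatures, exclusive-region partitions and
intersection-count tables.

The whole toolkit runs on one in-memory model: a :class:`SetCollection` maps
each element to the (non-empty) subset of named sets it belongs to.  Every
diagram is a view of the *exclusive-region partition* derived from it — each
element lands in exactly one region, the one labelled by its full membership
signature.  Inclusive intersection sizes (|A∩B| in the usual sense) are sums
of exclusive counts over superset signatures, and count-only inputs are
accepted in either semantics, with inclusive tables converted to exclusive
region counts by Möbius inversion over the subset lattice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import CapacityError, SemanticsError, VennKitError

SIGNATURE_SEP = "&"

__all__ = [
    "SetCollection",
    "RegionPartition",
    "IntersectionCountTable",
    "VennCalcResult",
    "FlowerDecomposition",
    "canonical_signature",
    "parse_signature",
    "exclusive_regions",
    "venn_calculator",
    "inclusive_size",
    "partition_from_counts",
    "flower_decomposition",
    "generate_collection",
    "reorder_collection",
]


def canonical_signature(subset: Iterable[str], order: Iterable[str]) -> str:
    """Return the canonical ``"&"``-joined signature for *subset*.

    Names are sorted by their position in *order* and joined with ``"&"``
    (no surrounding spaces).  Raises :class:`VennKitError` for an empty
    subset or a name not present in *order*.
    """
    order = list(order)
    pos = {name: i for i, name in enumerate(order)}
    names = set(subset)
    if not names:
        raise VennKitError("signature subset must be non-empty")
    for name in names:
        if name not in pos:
            raise VennKitError(f"unknown set name in signature: {name!r}")
    return SIGNATURE_SEP.join(sorted(names, key=pos.__getitem__))


def parse_signature(signature: str) -> frozenset[str]:
    """Split an ``"&"``-joined signature into its set names.

    Tolerates whitespace around each name (the canonical form has none).
    """
    names = [tok.strip() for tok in signature.split(SIGNATURE_SEP)]
    names = [n for n in names if n]
    if not names:
        raise VennKitError(f"empty signature: {signature!r}")
    return frozenset(names)


@dataclass(frozen=True)
class SetCollection:
    """Ordered named sets with an element → membership map.

    ``set_names`` preserves first-appearance order; ``membership`` maps each
    element ID to the non-empty frozenset of set names it belongs to.
    """

    set_names: tuple[str, ...]
    membership: Mapping[str, frozenset[str]]

    def __post_init__(self):
        if len(set(self.set_names)) != len(self.set_names):
            raise VennKitError("set names must be unique")
        universe = set(self.set_names)
        for elem, sets in self.membership.items():
            if not sets:
                raise VennKitError(f"element {elem!r} belongs to no set")
            if not sets <= universe:
                raise VennKitError(
                    f"element {elem!r} references unknown sets {sorted(sets - universe)}"
                )

    @classmethod
    def from_sets(
        cls, sets: Mapping[str, Iterable[str]], order: Iterable[str] | None = None
    ) -> "SetCollection":
        """Build a collection from a name → elements mapping."""
        names = tuple(order) if order is not None else tuple(sets)
        membership: dict[str, set[str]] = {}
        for name in names:
            for elem in sets.get(name, ()):
                membership.setdefault(elem, set()).add(name)
        return cls(names, {e: frozenset(s) for e, s in membership.items()})

    @property
    def n_sets(self) -> int:
        return len(self.set_names)

    @property
    def n_elements(self) -> int:
        return len(self.membership)

    def elements_of(self, name: str) -> set[str]:
        """All elements of one named set (inclusive)."""
        if name not in self.set_names:
            raise VennKitError(f"unknown set name: {name!r}")
        return {e for e, s in self.membership.items() if name in s}

    def set_sizes(self) -> dict[str, int]:
        sizes = dict.fromkeys(self.set_names, 0)
        for sets in self.membership.values():
            for name in sets:
                sizes[name] += 1
        return sizes


@dataclass(frozen=True)
class RegionPartition:
    """The exclusive (pairwise disjoint) regions of a collection.

    ``regions`` maps canonical signatures to ``(elements, count)``; empty
    regions are omitted.  ``counts_only`` marks partitions built from count
    tables, whose element tuples are empty.
    """

    set_names: tuple[str, ...]
    regions: Mapping[str, tuple[tuple[str, ...], int]]
    counts_only: bool = False

    @property
    def n_sets(self) -> int:
        return len(self.set_names)

    def count(self, signature: str) -> int:
        return self.regions.get(signature, ((), 0))[1]

    def counts(self) -> dict[str, int]:
        return {sig: cnt for sig, (_, cnt) in self.regions.items()}

    def elements(self, signature: str) -> tuple[str, ...]:
        return self.regions.get(signature, ((), 0))[0]

    def total(self) -> int:
        return sum(cnt for _, cnt in self.regions.values())


@dataclass(frozen=True)
class IntersectionCountTable:
    """Canonical signature → count rows, in one of two semantics.

    ``exclusive`` rows count the disjoint Venn regions; ``inclusive`` rows
    count full intersections |∩S| (so count(S) ≥ count(T) for S ⊆ T).
    """

    set_names: tuple[str, ...]
    rows: Mapping[str, int]
    semantics: str = "exclusive"

    def __post_init__(self):
        if self.semantics not in ("exclusive", "inclusive"):
            raise VennKitError(f"unknown semantics: {self.semantics!r}")
        for sig, cnt in self.rows.items():
            if cnt < 0:
                raise VennKitError(f"negative count for {sig!r}")


@dataclass(frozen=True)
class VennCalcResult:
    """Full intersection report: every signature in both semantics."""

    exclusive: IntersectionCountTable
    inclusive: IntersectionCountTable
    exclusive_elements: Mapping[str, tuple[str, ...]]
    inclusive_elements: Mapping[str, tuple[str, ...]]


def exclusive_regions(collection: SetCollection) -> RegionPartition:
    """Assign every element to the region of its full membership signature."""
    buckets: dict[str, list[str]] = {}
    for elem, sets in collection.membership.items():
        sig = canonical_signature(sets, collection.set_names)
        buckets.setdefault(sig, []).append(elem)
    regions = {
        sig: (tuple(sorted(elems)), len(elems)) for sig, elems in buckets.items()
    }
    return RegionPartition(collection.set_names, regions)


def _all_signatures(set_names: tuple[str, ...]):
    """Every non-empty subset as (canonical signature, frozenset), by degree."""
    for k in range(1, len(set_names) + 1):
        for combo in itertools.combinations(set_names, k):
            yield SIGNATURE_SEP.join(combo), frozenset(combo)


def venn_calculator(
    collection: SetCollection, max_enumerate: int = 12
) -> VennCalcResult:
    """Report counts and element lists of all 2^n − 1 intersections.

    Zero-count signatures are enumerated in full up to ``max_enumerate`` sets;
    beyond that only signatures reachable from the data are materialized (the
    number of non-empty signatures is bounded by the element count).
    """
    if collection.n_sets < 1:
        raise VennKitError("need at least one set")
    part = exclusive_regions(collection)
    enumerate_all = collection.n_sets <= max_enumerate
    if enumerate_all:
        sigs = list(_all_signatures(collection.set_names))
    else:
        seen = {parse_signature(s) for s in part.regions}
        closure: set[frozenset[str]] = set()
        for s in seen:
            for k in range(1, len(s) + 1):
                closure.update(map(frozenset, itertools.combinations(sorted(s), k)))
        sigs = sorted(
            ((canonical_signature(s, collection.set_names), s) for s in closure),
            key=lambda p: (len(p[1]), p[0]),
        )
    excl_counts, incl_counts = {}, {}
    excl_elems, incl_elems = {}, {}
    region_subsets = [(parse_signature(s), s) for s in part.regions]
    for sig, subset in sigs:
        excl_counts[sig] = part.count(sig)
        excl_elems[sig] = part.elements(sig)
        members: list[str] = []
        for rsub, rsig in region_subsets:
            if subset <= rsub:
                members.extend(part.regions[rsig][0])
        incl_elems[sig] = tuple(sorted(members))
        incl_counts[sig] = len(members)
    return VennCalcResult(
        exclusive=IntersectionCountTable(collection.set_names, excl_counts, "exclusive"),
        inclusive=IntersectionCountTable(collection.set_names, incl_counts, "inclusive"),
        exclusive_elements=excl_elems,
        inclusive_elements=incl_elems,
    )


def inclusive_size(partition: RegionPartition, subset: Iterable[str]) -> int:
    """|∩subset|: sum of exclusive counts over all superset signatures."""
    subset = frozenset(subset)
    if not subset:
        raise VennKitError("subset must be non-empty")
    unknown = subset - set(partition.set_names)
    if unknown:
        raise VennKitError(f"unknown set names: {sorted(unknown)}")
    return sum(
        cnt
        for sig, (_, cnt) in partition.regions.items()
        if subset <= parse_signature(sig)
    )


def partition_from_counts(table: IntersectionCountTable) -> RegionPartition:
    """Build a counts-only partition from a count table.

    Exclusive tables are copied verbatim.  Inclusive tables are inverted by
    inclusion–exclusion over supersets (Möbius inversion on the subset
    lattice); a negative recovered region count means the table is
    inconsistent and raises :class:`SemanticsError` naming the signature.
    Signatures absent from an inclusive table are treated as count 0.
    """
    names = table.set_names
    if table.semantics == "exclusive":
        regions = {sig: ((), cnt) for sig, cnt in table.rows.items()}
        return RegionPartition(names, regions, counts_only=True)

    incl = {parse_signature(sig): cnt for sig, cnt in table.rows.items()}
    regions = {}
    for sig, subset in _all_signatures(names):
        excl = 0
        rest = [n for n in names if n not in subset]
        for k in range(len(rest) + 1):
            for extra in itertools.combinations(rest, k):
                term = incl.get(subset | frozenset(extra), 0)
                excl += term if k % 2 == 0 else -term
        if excl < 0:
            raise SemanticsError(
                f"inclusive counts are inconsistent: region {sig!r} "
                f"would need {excl} elements",
                signature=sig,
            )
        if excl:
            regions[sig] = ((), excl)
    return RegionPartition(names, regions, counts_only=True)


def reorder_collection(
    collection: SetCollection, order: Iterable[str]
) -> SetCollection:
    """Return the same collection with its sets in a user-chosen order.

    *order* must be a permutation of the collection's set names.
    """
    names = tuple(order)
    if sorted(names) != sorted(collection.set_names):
        raise VennKitError(
            f"order {list(names)} is not a permutation of "
            f"{list(collection.set_names)}"
        )
    return SetCollection(names, collection.membership)


@dataclass(frozen=True)
class FlowerDecomposition:
    """Core / unique / residual counts behind a flower plot."""

    core: int
    unique: Mapping[str, int]
    residual: Mapping[str, int]


def flower_decomposition(collection: SetCollection) -> FlowerDecomposition:
    """Core (in all sets), per-set unique, and per-set residual counts.

    residual(i) = |set_i| − core, so residual + core is conserved per set.
    """
    part = exclusive_regions(collection)
    core = inclusive_size(part, collection.set_names)
    sizes = collection.set_sizes()
    unique = {
        name: part.count(canonical_signature({name}, collection.set_names))
        for name in collection.set_names
    }
    residual = {name: sizes[name] - core for name in collection.set_names}
    return FlowerDecomposition(core, unique, residual)


def generate_collection(
    n_sets: int,
    n_elements: int = 200,
    core_fraction: float = 0.25,
    unique_fraction: float = 0.35,
    seed: int = 0,
) -> SetCollection:
    """Synthesize a collection with the membership structure of typical
    multi-condition omics comparisons: a shared core present in every set,
    a slice of set-specific singletons, and the rest scattered over random
    non-empty subsets.

    Deterministic for a fixed seed.  Fractions must lie in [0, 1] and sum to
    at most 1; ``n_sets`` must be ≥ 1.
    """
    if n_sets < 1:
        raise VennKitError("n_sets must be >= 1")
    if not (0 <= core_fraction <= 1 and 0 <= unique_fraction <= 1):
        raise VennKitError("fractions must lie in [0, 1]")
    if core_fraction + unique_fraction > 1 + 1e-12:
        raise VennKitError("core_fraction + unique_fraction must be <= 1")
    rng = np.random.default_rng(seed)
    names = tuple(f"S{i + 1}" for i in range(n_sets))
    width = len(str(max(n_elements, 1)))
    membership: dict[str, frozenset[str]] = {}
    u = rng.random(n_elements)
    for i in range(n_elements):
        elem = f"e{i:0{width}d}"
        if u[i] < core_fraction:
            subset = frozenset(names)
        elif u[i] < core_fraction + unique_fraction:
            subset = frozenset({names[rng.integers(n_sets)]})
        else:
            mask = int(rng.integers(1, 2**n_sets))
            subset = frozenset(n for b, n in enumerate(names) if mask >> b & 1)
        membership[elem] = subset
    return SetCollection(names, membership)
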