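"""Overlap-significance statistics for pairwise set intersections.

The default (and only) statistic is the one-sided hypergeometric enrichment
test — Fisher's exact upper tail: with a universe of ``universe`` elements,
a set of size ``size_a`` and an independent draw of ``size_b`` elements, the
p-value is P(X ≥ overlap) for X ~ Hypergeometric(universe, size_a, size_b).
The survival function is evaluated in log space internally by scipy, so
large gene-scale counts are safe.  The universe size must be given
explicitly: inferring it from the union silently inflates significance.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

from .errors import VennKitError

__all__ = ["OverlapTest", "overlap_significance"]

METHOD = "hypergeometric-upper-tail"


@dataclass(frozen=True)
class OverlapTest:
    size_a: int
    size_b: int
    overlap: int
    universe: int
    p_value: float
    expected_overlap: float
    method: str = METHOD


def overlap_significance(
    size_a: int, size_b: int, overlap: int, universe: int
) -> OverlapTest:
    """Upper-tail hypergeometric probability of seeing ≥ ``overlap`` shared
    elements, plus the null expectation size_a·size_b/universe."""
    if min(size_a, size_b, overlap, universe) < 0:
        raise VennKitError("counts must be non-negative")
    if max(size_a, size_b) > universe:
        raise VennKitError("set sizes cannot exceed the universe")
    if overlap > min(size_a, size_b):
        raise VennKitError("overlap cannot exceed the smaller set")
    if overlap < max(0, size_a + size_b - universe):
        raise VennKitError("overlap below the minimum forced by the universe")
    if universe == 0:
        return OverlapTest(size_a, size_b, overlap, universe, 1.0, 0.0)
    # sf(k) = P(X > k), so P(X >= overlap) = sf(overlap - 1)
    p = float(hypergeom.sf(overlap - 1, universe, size_a, size_b))
    p = min(1.0, max(0.0, p))
    expected = size_a * size_b / universe
    return OverlapTest(size_a, size_b, overlap, universe, p, expected)
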