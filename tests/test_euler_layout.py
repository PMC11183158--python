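"""Euler geometry: lens areas, distance inversion, stress layout."""

import math

import numpy as np
import pytest

import vennkit as vk
from vennkit.errors import CapacityError, VennKitError
from vennkit.euler_layout import CircleSpec


class TestLensArea:
    def test_disjoint_and_coincident(self):
        assert vk.lens_area(1, 1, 2) == 0.0
        assert vk.lens_area(1, 1, 0) == pytest.approx(math.pi, abs=1e-12)

    def test_closed_form_unit_circles_at_distance_one(self):
        expected = 2 * math.pi / 3 - math.sqrt(3) / 2
        assert vk.lens_area(1, 1, 1) == pytest.approx(expected, abs=1e-9)

    def test_containment(self):
        assert vk.lens_area(2, 0.5, 1.0) == pytest.approx(math.pi * 0.25, abs=1e-12)

    def test_monotone_non_increasing_in_distance(self):
        ds = np.linspace(0, 3.5, 200)
        areas = [vk.lens_area(1.3, 0.9, d) for d in ds]
        assert all(a >= b - 1e-12 for a, b in zip(areas, areas[1:]))

    def test_monte_carlo_cross_check(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform([-1, -1], [2, 1], size=(400_000, 2))
        inside = ((pts**2).sum(1) <= 1) & (((pts - [1, 0]) ** 2).sum(1) <= 1)
        mc = inside.mean() * 6.0
        assert vk.lens_area(1, 1, 1) == pytest.approx(mc, rel=0.02)


class TestSolveDistance:
    def test_extremes(self):
        assert vk.solve_distance(1, 1, 0) == 2.0
        assert vk.solve_distance(2, 1, math.pi) == pytest.approx(1.0, abs=1e-9)

    def test_inverts_lens_area(self):
        target = 2 * math.pi / 3 - math.sqrt(3) / 2
        d = vk.solve_distance(1, 1, target, tol=1e-9)
        assert d == pytest.approx(1.0, abs=1e-6)

    def test_out_of_range_target(self):
        with pytest.raises(VennKitError):
            vk.solve_distance(1, 1, 10.0)


class TestRegionAreas:
    def test_single_circle(self):
        areas = vk.region_areas([CircleSpec((0, 0), 1.0)], seed=0)
        assert areas["1"] == pytest.approx(math.pi, rel=0.005)

    def test_disjoint_overlap_is_zero(self):
        areas = vk.region_areas(
            [CircleSpec((0, 0), 1.0), CircleSpec((3, 0), 1.0)], seed=0
        )
        assert areas["1&2"] == 0.0

    def test_matches_lens_area_within_half_percent(self):
        areas = vk.region_areas(
            [CircleSpec((0, 0), 1.0), CircleSpec((1, 0), 1.0)], seed=0
        )
        lens = vk.lens_area(1, 1, 1)
        assert areas["1&2"] == pytest.approx(lens, rel=0.005)
        assert areas["1"] == pytest.approx(math.pi - lens, rel=0.005)


def counts_partition(text: str, semantics="exclusive"):
    return vk.partition_from_counts(
        vk.read_intersection_counts(text, semantics=semantics)
    )


class TestLayoutEuler:
    def test_two_disjoint_sets(self):
        part = counts_partition("A\t10\nB\t10")
        lay = vk.layout_euler(part)
        (c1, c2) = lay.circles
        d = math.dist(c1.center, c2.center)
        assert d > c1.radius + c2.radius
        assert lay.stress < 1e-9

    def test_two_set_overlap_exact_within_tenth_percent(self):
        part = counts_partition("A\t70\nB\t50\nA&B\t30")
        lay = vk.layout_euler(part)
        sig = "A&B"
        assert lay.achieved_region_areas[sig] == pytest.approx(
            lay.target_areas[sig], rel=1e-3
        )
        assert lay.stress < 1e-6 * sum(lay.target_areas.values())

    def test_containment_nests_circles(self):
        # B ⊂ A: inclusive |A∩B| = |B|
        part = counts_partition("A\t80\nA&B\t20")
        lay = vk.layout_euler(part)
        ca, cb = lay.circles
        assert math.dist(ca.center, cb.center) + cb.radius <= ca.radius + 1e-9

    def test_largest_set_gets_radius_one(self):
        part = counts_partition("A\t70\nB\t50\nA&B\t30")
        assert max(c.radius for c in vk.layout_euler(part).circles) == 1.0

    def test_three_sets_deterministic_and_monotone(self):
        text = "A\t60\nB\t40\nC\t30\nA&B\t15\nA&C\t10\nB&C\t8\nA&B&C\t5"
        part = counts_partition(text)
        lay1 = vk.layout_euler(part, opt_samples=8000, seed=0)
        lay2 = vk.layout_euler(part, opt_samples=8000, seed=0)
        assert lay1.circles == lay2.circles
        hist = lay1.stress_history
        assert all(a >= b - 1e-12 for a, b in zip(hist, hist[1:]))

    def test_three_way_overlap_smallest_area(self):
        # dominant unique region and a tiny triple overlap, as in DE-gene
        # comparisons across three cell lines
        text = ("A\t666\nB\t120\nC\t90\nA&B\t40\nA&C\t30\nB&C\t20\nA&B&C\t15")
        part = counts_partition(text)
        lay = vk.layout_euler(part, opt_samples=8000, seed=0)
        areas = {s: a for s, a in lay.achieved_region_areas.items() if a > 0}
        assert min(areas, key=areas.get) == "A&B&C"

    def test_more_than_three_sets_rejected(self):
        part = counts_partition("A\t1\nB\t1\nC\t1\nD\t1")
        with pytest.raises(CapacityError):
            vk.layout_euler(part)


class TestEulerScene:
    def test_label_multiset_matches_counts(self):
        part = counts_partition("A\t40\nB\t25\nA&B\t10")
        lay = vk.layout_euler(part)
        scene = vk.euler_scene(lay, part, vk.DEFAULT_PALETTE[:2])
        labels = {t.text for t in scene.texts()} - set(part.set_names)
        assert labels == {"40", "25", "10"}

    def test_count_labels_lie_inside_their_region(self):
        part = counts_partition("A\t40\nB\t25\nA&B\t10")
        lay = vk.layout_euler(part)
        scene = vk.euler_scene(lay, part, vk.DEFAULT_PALETTE[:2])
        circles = dict(zip(part.set_names, lay.circles))
        by_text = {t.text: (t.x, t.y) for t in scene.texts()}
        for sig, cnt in part.counts().items():
            x, y = by_text[str(cnt)]
            members = vk.parse_signature(sig)
            for name, c in circles.items():
                inside = math.dist((x, y), c.center) <= c.radius
                assert inside == (name in members)
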