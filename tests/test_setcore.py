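"""Region calculus: signatures, partitions, inversion, generator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import vennkit as vk
from vennkit.errors import SemanticsError, VennKitError

from conftest import brute_force_regions


class TestCanonicalSignature:
    def test_sorts_by_set_order(self):
        assert vk.canonical_signature({"B", "A"}, ["A", "B", "C"]) == "A&B"
        assert vk.canonical_signature({"C", "A"}, ["C", "B", "A"]) == "C&A"

    def test_idempotent_on_parsed_output(self):
        order = ["FS1", "FS2", "FS3", "FS4", "FS5"]
        sig = vk.canonical_signature(set(order), order)
        assert sig == "FS1&FS2&FS3&FS4&FS5"
        assert vk.canonical_signature(vk.parse_signature(sig), order) == sig

    def test_rejects_unknown_and_empty(self):
        with pytest.raises(VennKitError):
            vk.canonical_signature({"Z"}, ["A"])
        with pytest.raises(VennKitError):
            vk.canonical_signature(set(), ["A"])


class TestExclusiveRegions:
    def test_toy_assignment(self, toy_pair):
        part = vk.exclusive_regions(toy_pair)
        assert part.counts() == {"A": 1, "A&B": 1}
        assert part.elements("A") == ("x",)
        assert part.elements("A&B") == ("y",)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_collections(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 7))
        coll = vk.generate_collection(n, int(rng.integers(5, 200)), seed=seed)
        sets = {name: coll.elements_of(name) for name in coll.set_names}
        assert vk.exclusive_regions(coll).counts() == brute_force_regions(sets)

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation(self, seed):
        coll = vk.generate_collection(5, 120, seed=seed)
        part = vk.exclusive_regions(coll)
        assert part.total() == coll.n_elements


class TestVennCalculator:
    def test_reports_all_signatures(self, toy_triple):
        res = vk.venn_calculator(toy_triple)
        assert len(res.exclusive.rows) == 7
        assert len(res.inclusive.rows) == 7

    def test_shared_singleton(self):
        coll = vk.SetCollection.from_sets({"A": ["x"], "B": ["x"]})
        res = vk.venn_calculator(coll)
        assert res.inclusive.rows["A&B"] == 1
        assert res.exclusive.rows["A"] == 0 and res.exclusive.rows["B"] == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_inclusive_is_sum_of_exclusive_supersets(self, seed):
        coll = vk.generate_collection(4, 80, seed=seed)
        res = vk.venn_calculator(coll)
        for sig, incl in res.inclusive.rows.items():
            subset = vk.parse_signature(sig)
            total = sum(
                cnt
                for other, cnt in res.exclusive.rows.items()
                if subset <= vk.parse_signature(other)
            )
            assert incl == total

    def test_beyond_enumeration_cap_keeps_nonempty(self):
        coll = vk.generate_collection(14, 60, seed=0)
        res = vk.venn_calculator(coll, max_enumerate=12)
        part = vk.exclusive_regions(coll)
        assert set(part.regions) <= set(res.exclusive.rows)
        assert sum(res.exclusive.rows.values()) == coll.n_elements


class TestInclusiveSize:
    def test_single_set_is_total_size(self, toy_triple):
        part = vk.exclusive_regions(toy_triple)
        assert vk.inclusive_size(part, {"A"}) == 3
        assert vk.inclusive_size(part, {"A", "B", "C"}) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_direct_intersection(self, seed):
        coll = vk.generate_collection(5, 100, seed=seed)
        part = vk.exclusive_regions(coll)
        sets = {name: coll.elements_of(name) for name in coll.set_names}
        rng = np.random.default_rng(seed)
        for _ in range(10):
            k = int(rng.integers(1, 6))
            subset = list(rng.choice(coll.set_names, size=k, replace=False))
            direct = len(set.intersection(*(sets[n] for n in subset)))
            assert vk.inclusive_size(part, subset) == direct

    def test_unknown_name_raises(self, toy_pair):
        with pytest.raises(VennKitError):
            vk.inclusive_size(vk.exclusive_regions(toy_pair), {"Z"})


class TestPartitionFromCounts:
    def test_exclusive_passthrough(self):
        t = vk.IntersectionCountTable(("A", "B"), {"A": 2, "A&B": 1}, "exclusive")
        part = vk.partition_from_counts(t)
        assert part.counts() == {"A": 2, "A&B": 1}
        assert part.counts_only

    def test_inclusive_inversion_by_hand(self):
        t = vk.IntersectionCountTable(
            ("A", "B"), {"A": 3, "B": 2, "A&B": 1}, "inclusive"
        )
        assert vk.partition_from_counts(t).counts() == {"A": 2, "B": 1, "A&B": 1}

    def test_inconsistent_inclusive_raises_naming_signature(self):
        t = vk.IntersectionCountTable(("A", "B"), {"A": 1, "A&B": 2}, "inclusive")
        with pytest.raises(SemanticsError) as err:
            vk.partition_from_counts(t)
        assert err.value.signature == "A"

    @given(st.integers(0, 1000))
    def test_mobius_roundtrip_on_consistent_tables(self, seed):
        """summation -> inversion is the identity on random exclusive counts."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 6))
        coll = vk.generate_collection(n, int(rng.integers(1, 60)), seed=seed)
        res = vk.venn_calculator(coll)
        inverted = vk.partition_from_counts(res.inclusive)
        expected = {s: c for s, c in res.exclusive.rows.items() if c > 0}
        assert inverted.counts() == expected


class TestFlowerDecomposition:
    def test_identical_sets(self):
        coll = vk.SetCollection.from_sets(
            {"A": ["x", "y"], "B": ["x", "y"], "C": ["x", "y"]}
        )
        dec = vk.flower_decomposition(coll)
        assert dec.core == 2
        assert set(dec.unique.values()) == {0}
        assert set(dec.residual.values()) == {0}

    @pytest.mark.parametrize("seed", range(8))
    def test_residual_conservation(self, seed):
        coll = vk.generate_collection(6, 90, seed=seed)
        dec = vk.flower_decomposition(coll)
        sizes = coll.set_sizes()
        for name in coll.set_names:
            assert dec.residual[name] + dec.core == sizes[name]
            assert 0 <= dec.unique[name] <= dec.residual[name] + dec.core


class TestGenerateCollection:
    def test_deterministic_for_fixed_seed(self):
        a = vk.generate_collection(4, 100, seed=7)
        b = vk.generate_collection(4, 100, seed=7)
        assert a == b

    def test_core_fraction_one_puts_everything_everywhere(self):
        coll = vk.generate_collection(3, 50, core_fraction=1.0, unique_fraction=0.0)
        assert all(len(s) == 3 for s in coll.membership.values())

    def test_realized_core_fraction_within_sampling_error(self):
        n = 10_000
        coll = vk.generate_collection(4, n, core_fraction=0.3,
                                      unique_fraction=0.2, seed=11)
        core = sum(1 for s in coll.membership.values() if len(s) == 4)
        # non-core elements land in all four sets with prob (1/15); allow 4 sigma
        p_all4 = 0.3 + 0.5 / 15
        sigma = (n * p_all4 * (1 - p_all4)) ** 0.5
        assert abs(core - n * p_all4) < 4 * sigma

    def test_invalid_parameters(self):
        with pytest.raises(VennKitError):
            vk.generate_collection(0, 10)
        with pytest.raises(VennKitError):
            vk.generate_collection(2, 10, core_fraction=0.7, unique_fraction=0.7)


class TestReorder:
    def test_permutation_preserves_membership(self, toy_triple):
        re = vk.reorder_collection(toy_triple, ("C", "A", "B"))
        assert re.set_names == ("C", "A", "B")
        assert re.membership == toy_triple.membership

    def test_non_permutation_rejected(self, toy_triple):
        with pytest.raises(VennKitError):
            vk.reorder_collection(toy_triple, ("A", "B"))
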