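from collections import Counter
from itertools import permutations

import pytest

from platedesign import (
    UnbalancedCategoriesError,
    ValidationError,
    block_randomize,
    block_randomize_unbalanced,
    complete_randomize,
    enumerate_block_permutations,
    intersperse_step,
    longest_run,
    merge_interspersed,
    n_block_permutations,
    n_blocks,
    partition_nested_groups,
)
from platedesign.blockrand import NestedGroup


def brute_force_blocks(dim, block):
    """Independent oracle: filter raw label permutations for equal counts."""
    labels = [chr(ord("A") + i) for i in range(dim)]
    pool = labels * (block // dim)
    return sorted(set(permutations(pool)))


class TestEnumeration:
    def test_dim2_block4_prints_the_six_blocks(self):
        perms = enumerate_block_permutations(2, 4)
        assert {"".join(p) for p in perms} == {
            "AABB", "ABAB", "ABBA", "BAAB", "BABA", "BBAA",
        }

    def test_dim2_block2(self):
        assert enumerate_block_permutations(2, 2) == [("A", "B"), ("B", "A")]

    def test_dim3_block3_has_six(self):
        assert len(enumerate_block_permutations(3, 3)) == 6

    @pytest.mark.parametrize("dim", [1, 2, 3])
    def test_closed_form_matches_brute_force(self, dim):
        for block in range(dim, 7, dim):
            expected = brute_force_blocks(dim, block)
            got = enumerate_block_permutations(dim, block)
            assert got == expected
            assert n_block_permutations(dim, block) == len(expected)

    def test_lexicographic_order(self):
        perms = enumerate_block_permutations(2, 4)
        assert perms == sorted(perms)

    def test_block_size_not_multiple_rejected(self):
        with pytest.raises(ValidationError, match="multiple of dim size"):
            enumerate_block_permutations(2, 3)


class TestNBlocks:
    def test_worked_example_100_samples_block_4(self):
        assert n_blocks(100, 4) == 25

    @pytest.mark.parametrize("n,bs,expected", [(4, 4, 1), (101, 4, 26), (1, 2, 1)])
    def test_ceiling(self, n, bs, expected):
        assert n_blocks(n, bs) == expected


class TestBlockRandomize:
    def test_every_block_balanced_over_seeds(self):
        samples = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
        for seed in range(50):
            seq = block_randomize(samples, 2, seed)
            cats = [s[0] for s in seq.order]
            assert Counter(cats[:2]) == Counter("ab")
            assert Counter(cats[2:]) == Counter("ab")

    def test_single_pair_gives_both_orders(self):
        outcomes = {
            tuple(block_randomize({"A": ["a1"], "B": ["b1"]}, 2, s).order)
            for s in range(30)
        }
        assert outcomes == {("a1", "b1"), ("b1", "a1")}

    def test_100_samples_block4_gives_25_blocks(self):
        samples = {"A": [f"a{i}" for i in range(50)], "B": [f"b{i}" for i in range(50)]}
        seq = block_randomize(samples, 4, seed=1)
        assert len(seq.block_boundaries) == 25
        assert all(length == 4 for length in seq.block_boundaries)

    def test_conservation(self):
        samples = {"A": [f"a{i}" for i in range(9)], "B": [f"b{i}" for i in range(9)]}
        seq = block_randomize(samples, 6, seed=3)
        assert sorted(seq.order) == sorted(samples["A"] + samples["B"])

    def test_auto_block_size_no_three_runs(self):
        """Block size = dim size: no >=3 same-category run, any seed."""
        samples = {"A": [f"a{i}" for i in range(30)], "B": [f"b{i}" for i in range(30)]}
        for seed in range(100):
            seq = block_randomize(samples, "auto", seed)
            assert longest_run([s[0] for s in seq.order]) <= 2

    def test_trailing_partial_block_conserves(self):
        samples = {"A": [f"a{i}" for i in range(3)], "B": [f"b{i}" for i in range(3)]}
        seq = block_randomize(samples, 4, seed=2)  # 6 samples -> blocks 4 + 2
        assert seq.block_boundaries == [4, 2]
        assert sorted(seq.order) == sorted(samples["A"] + samples["B"])

    def test_unequal_counts_directed_to_unbalanced(self):
        with pytest.raises(UnbalancedCategoriesError, match="unbalanced"):
            block_randomize({"A": ["a1"], "B": ["b1", "b2"]}, "auto", 0)

    def test_determinism(self):
        samples = {"A": [f"a{i}" for i in range(10)], "B": [f"b{i}" for i in range(10)]}
        assert block_randomize(samples, 2, 7).order == block_randomize(samples, 2, 7).order


class TestNestedGroups:
    def test_successive_minimum_subtraction(self):
        groups = partition_nested_groups({"A": 2, "B": 5, "C": 9})
        assert groups == [
            NestedGroup(("A", "B", "C"), 2),
            NestedGroup(("B", "C"), 3),
            NestedGroup(("C",), 4),
        ]

    def test_balanced_input_collapses_to_one_group(self):
        assert partition_nested_groups({"A": 3, "B": 3}) == [
            NestedGroup(("A", "B"), 3)
        ]

    def test_single_category(self):
        assert partition_nested_groups({"A": 7}) == [NestedGroup(("A",), 7)]

    def test_group_sizes_conserve_counts(self):
        counts = {"w": 4, "x": 11, "y": 11, "z": 30}
        groups = partition_nested_groups(counts)
        total = Counter()
        for g in groups:
            for cat in g.categories:
                total[cat] += g.per_category_count
        assert total == Counter(counts)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            partition_nested_groups({})


class TestIntersperse:
    @pytest.mark.parametrize("base,ins,expected", [(12, 6, 2), (10, 3, 3), (5, 5, 1)])
    def test_step(self, base, ins, expected):
        assert intersperse_step(base, ins) == expected

    def test_zero_length_rejected(self):
        with pytest.raises(ValidationError):
            intersperse_step(5, 0)

    def test_merge_worked_example(self):
        out = merge_interspersed([["b1"], ["b2"], ["b3"], ["b4"]], [["i1"], ["i2"]], 2)
        assert out == [["b1"], ["b2"], ["i1"], ["b3"], ["b4"], ["i2"]]

    def test_merge_empty_insert_is_identity(self):
        base = [["b1"], ["b2"]]
        assert merge_interspersed(base, [], 1) == base

    def test_merge_single_blocks(self):
        assert merge_interspersed([["b1"]], [["i1"]], 1) == [["b1"], ["i1"]]

    def test_merge_leftovers_cycle_from_start(self):
        out = merge_interspersed(
            [["b1"], ["b2"]], [["i1"], ["i2"], ["i3"]], 1
        )
        flat = [blk[0] for blk in out]
        assert sorted(flat) == ["b1", "b2", "i1", "i2", "i3"]
        # leftover i3 lands in the first slot again, not appended at the end
        assert flat[-1] != "i3"

    def test_merge_conserves_multiset(self):
        base = [[f"b{i}", f"c{i}"] for i in range(5)]
        ins = [[f"i{i}"] for i in range(3)]
        out = merge_interspersed(base, ins, 2)
        assert sorted(x for blk in out for x in blk) == sorted(
            x for blk in base + ins for x in blk
        )


class TestUnbalanced:
    def test_conservation_2_5_9(self):
        samples = {
            "A": [f"a{i}" for i in range(2)],
            "B": [f"b{i}" for i in range(5)],
            "C": [f"c{i}" for i in range(9)],
        }
        seq = block_randomize_unbalanced(samples, seed=4)
        assert len(seq) == 16
        assert sorted(seq.order) == sorted(sum(samples.values(), []))

    def test_balanced_input_reduces_to_block_structure(self):
        """On balanced input there is a single nested group and no merge:
        every block is a full permutation of the categories."""
        samples = {"A": [f"a{i}" for i in range(3)], "B": [f"b{i}" for i in range(3)]}
        for seed in range(30):
            seq = block_randomize_unbalanced(samples, seed)
            assert seq.block_boundaries == [2, 2, 2]
            for blk in seq.blocks():
                assert Counter(s[0] for s in blk) == Counter("ab")

    def test_conservation_property_over_shapes(self):
        shapes = [
            {"A": 1, "B": 1},
            {"A": 1, "B": 100},
            {"A": 7, "B": 7, "C": 2},
            {"A": 169, "B": 351, "C": 481, "D": 299},
        ]
        for seed, counts in enumerate(shapes):
            samples = {
                cat: [f"{cat}{i}" for i in range(n)] for cat, n in counts.items()
            }
            seq = block_randomize_unbalanced(samples, seed)
            assert sorted(seq.order) == sorted(sum(samples.values(), []))

    def test_case_study_age_windows_are_balanced(self, case_cohort):
        """Every 100-sample window holds each age class within +-15 of its
        expected share, across seeds."""
        label_of = dict(zip(case_cohort.sample_ids(), case_cohort.labels("age")))
        by_cat = {}
        for sid, lab in label_of.items():
            by_cat.setdefault(lab, []).append(sid)
        counts = {c: len(v) for c, v in by_cat.items()}
        for seed in range(5):
            seq = block_randomize_unbalanced(by_cat, seed)
            labels = [label_of[s] for s in seq.order]
            for cat, c in counts.items():
                expected = 100 * c / 1300
                for start in range(0, 1201, 40):
                    win = labels[start : start + 100]
                    assert abs(sum(lab == cat for lab in win) - expected) <= 15

    def test_determinism(self):
        samples = {"A": [f"a{i}" for i in range(4)], "B": [f"b{i}" for i in range(9)]}
        assert (
            block_randomize_unbalanced(samples, 11).order
            == block_randomize_unbalanced(samples, 11).order
        )


class TestCompleteRandomize:
    def test_single_sample(self):
        assert complete_randomize(["s1"], 0).order == ["s1"]

    def test_permutation_and_determinism(self):
        ids = [f"s{i}" for i in range(40)]
        seq = complete_randomize(ids, 9)
        assert sorted(seq.order) == sorted(ids)
        assert seq.order == complete_randomize(ids, 9).order
        assert seq.order != ids  # astronomically unlikely to be identity
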