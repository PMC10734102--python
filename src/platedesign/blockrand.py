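"""Intra-batch randomization: block, optimized (nested-group) and complete.

Block randomization fills the run order with fixed-size blocks, each
containing every category in equal proportion, which rules out long
same-category runs that would confound biology with instrument drift.  It
requires equal category counts.  For the unbalanced case — the common
situation in practice — an optimized variant first partitions the
categories into *nested groups* with internally equal counts, block
randomizes each group, and then intersperses the groups' blocks so the
scarce categories stay spread across the whole run.

The number of samples per block (the *block size*) must be a multiple of
the number of categories (the *dim size*); the default block size equals
the dim size, which yields the most balanced sequence.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sympy.utilities.iterables import multiset_permutations

from .errors import UnbalancedCategoriesError, ValidationError

__all__ = [
    "BlockFactor",
    "NestedGroup",
    "RandomizedSequence",
    "enumerate_block_permutations",
    "n_block_permutations",
    "n_blocks",
    "block_randomize",
    "partition_nested_groups",
    "intersperse_step",
    "merge_interspersed",
    "block_randomize_unbalanced",
    "complete_randomize",
]

#: Refuse to enumerate more block permutations than this; callers should use
#: a smaller block size instead (larger sizes approach complete randomness
#: anyway).
MAX_ENUMERATED_PERMUTATIONS = 500_000


@dataclass(frozen=True)
class BlockFactor:
    """The two knobs of block randomization: dim size and block size."""

    dim_size: int
    block_size: int

    def __post_init__(self) -> None:
        if self.dim_size < 1:
            raise ValidationError(f"dim_size must be >= 1, got {self.dim_size}")
        if self.block_size < self.dim_size or self.block_size % self.dim_size != 0:
            raise ValidationError(
                f"block size must be a multiple of dim size "
                f"(dim size {self.dim_size}: block size {self.dim_size}, "
                f"{2 * self.dim_size}, {3 * self.dim_size}, ...); "
                f"got block size {self.block_size}"
            )

    @property
    def per_category(self) -> int:
        return self.block_size // self.dim_size


@dataclass(frozen=True)
class NestedGroup:
    """A set of categories contributing the same per-category count."""

    categories: tuple[str, ...]
    per_category_count: int

    @property
    def n_samples(self) -> int:
        return len(self.categories) * self.per_category_count

    @property
    def dim_size(self) -> int:
        return len(self.categories)


@dataclass
class RandomizedSequence:
    """An ordered run list plus optional block-length diagnostics."""

    order: list[str]
    block_boundaries: list[int] | None = None

    def __len__(self) -> int:
        return len(self.order)

    def blocks(self) -> list[list[str]]:
        """Split the order back into its blocks (whole order if unknown)."""
        if not self.block_boundaries:
            return [list(self.order)]
        out, pos = [], 0
        for length in self.block_boundaries:
            out.append(self.order[pos : pos + length])
            pos += length
        return out


def _default_labels(dim_size: int) -> list[str]:
    if dim_size <= 26:
        return list(string.ascii_uppercase[:dim_size])
    return [f"C{i + 1}" for i in range(dim_size)]


def n_block_permutations(dim_size: int, block_size: int) -> int:
    """Closed-form count: block_size! / ((block_size/dim_size)!)^dim_size."""
    factor = BlockFactor(dim_size, block_size)
    return math.factorial(block_size) // math.factorial(factor.per_category) ** dim_size


def enumerate_block_permutations(
    dim_size: int, block_size: int, labels: Sequence[str] | None = None
) -> list[tuple[str, ...]]:
    """All distinct blocks, in lexicographic order of the labels.

    Each block is a sequence of length ``block_size`` containing each of the
    ``dim_size`` category labels exactly ``block_size / dim_size`` times —
    e.g. dim 2, block 4 gives the six blocks AABB, ABAB, ABBA, BAAB, BABA,
    BBAA.
    """
    factor = BlockFactor(dim_size, block_size)
    if labels is None:
        labels = _default_labels(dim_size)
    if len(labels) != dim_size:
        raise ValidationError(
            f"expected {dim_size} labels, got {len(labels)}"
        )
    total = n_block_permutations(dim_size, block_size)
    if total > MAX_ENUMERATED_PERMUTATIONS:
        raise ValidationError(
            f"{total} block permutations exceed the enumeration limit "
            f"({MAX_ENUMERATED_PERMUTATIONS}); choose a smaller block size"
        )
    pool = sorted(labels) * factor.per_category
    return [tuple(p) for p in multiset_permutations(sorted(pool))]


def n_blocks(n_samples: int, block_size: int) -> int:
    """Number of blocks needed: ceil(n_samples / block_size)."""
    if block_size < 1:
        raise ValidationError(f"block_size must be >= 1, got {block_size}")
    if n_samples < 1:
        raise ValidationError(f"n_samples must be >= 1, got {n_samples}")
    return math.ceil(n_samples / block_size)


def _blocks_from_patterns(
    samples_by_category: Mapping[str, Sequence[str]],
    block_size: int,
    rng: np.random.Generator,
) -> list[list[str]]:
    """Draw block patterns uniformly and substitute random samples.

    Assumes equal category counts.  A trailing partial block (when the
    total is not a multiple of the block size) is a uniform shuffle of the
    leftover category multiset, which preserves the no-long-run property at
    the boundary.
    """
    categories = list(samples_by_category)
    factor = BlockFactor(len(categories), block_size)
    perms = enumerate_block_permutations(
        factor.dim_size, factor.block_size, labels=categories
    )
    pools = {
        cat: [ids[i] for i in rng.permutation(len(ids))][::-1]
        for cat, ids in samples_by_category.items()
    }
    n = sum(len(v) for v in samples_by_category.values())
    blocks: list[list[str]] = []
    for _ in range(n // factor.block_size):
        pattern = perms[int(rng.integers(len(perms)))]
        blocks.append([pools[cat].pop() for cat in pattern])
    leftover = [cat for cat in categories for _ in range(len(pools[cat]))]
    if leftover:
        tail_pattern = [leftover[i] for i in rng.permutation(len(leftover))]
        blocks.append([pools[cat].pop() for cat in tail_pattern])
    assert all(not v for v in pools.values())
    return blocks


def block_randomize(
    samples_by_category: Mapping[str, Sequence[str]],
    block_size: int | str = "auto",
    seed: int = 0,
) -> RandomizedSequence:
    """Classic block randomization for equal category counts.

    Per block, a pattern is drawn uniformly (with replacement) from the
    enumerated block permutations and filled with randomly chosen samples
    of each category, so every consecutive block contains each category
    exactly ``block_size / dim_size`` times.  ``block_size="auto"`` uses the
    dim size, the most balanced choice.
    """
    counts = {cat: len(ids) for cat, ids in samples_by_category.items()}
    if not counts:
        raise ValidationError("samples_by_category is empty")
    if len(set(counts.values())) != 1:
        raise UnbalancedCategoriesError(
            f"category counts are unequal ({counts}); use "
            f"block_randomize_unbalanced for non-uniform distributions"
        )
    dim = len(counts)
    bs = dim if block_size == "auto" else int(block_size)
    rng = np.random.default_rng(seed)
    blocks = _blocks_from_patterns(samples_by_category, bs, rng)
    return RandomizedSequence(
        order=[sid for b in blocks for sid in b],
        block_boundaries=[len(b) for b in blocks],
    )


def partition_nested_groups(
    category_counts: Mapping[str, int]
) -> list[NestedGroup]:
    """Partition unequal category counts into internally uniform groups.

    Categories are sorted by ascending count; group *i* contains every
    category whose count reaches the *i*-th distinct level, each
    contributing the difference between successive levels.  The first group
    spans all categories (most dimensions), the last a single category:
    e.g. ``{A:2, B:5, C:9}`` → ``[{A,B,C}×2, {B,C}×3, {C}×4]``.
    """
    if not category_counts:
        raise ValidationError("category_counts is empty")
    if any(c < 1 for c in category_counts.values()):
        raise ValidationError("all category counts must be >= 1")
    items = sorted(category_counts.items(), key=lambda kv: kv[1])
    groups: list[NestedGroup] = []
    prev = 0
    for i, (_, count) in enumerate(items):
        delta = count - prev
        if delta > 0:
            groups.append(
                NestedGroup(
                    categories=tuple(cat for cat, _ in items[i:]),
                    per_category_count=delta,
                )
            )
        prev = count
    return groups


def intersperse_step(len_base: int, len_insert: int) -> int:
    """Insertion stride between adjacent groups: max(1, ⌊base / insert⌋)."""
    if len_insert < 1 or len_base < len_insert:
        raise ValidationError(
            f"need len_base >= len_insert >= 1, got ({len_base}, {len_insert})"
        )
    return max(1, len_base // len_insert)


def merge_interspersed(
    base_blocks: list[list[str]],
    insert_blocks: list[list[str]],
    step: int,
) -> list[list[str]]:
    """Intersperse insert blocks into the base every ``step`` base blocks.

    After every ``step`` base blocks the next insert block is appended.
    Insert blocks left over when the base runs out are assigned by cycling
    over the insertion slots again from the sequence start, which avoids
    piling leftovers at the end.  Within-block order is preserved and the
    output multiset is exactly the union of the inputs.
    """
    if step < 1:
        raise ValidationError(f"step must be >= 1, got {step}")
    if not base_blocks:
        return [list(b) for b in insert_blocks]
    chunks = [base_blocks[i : i + step] for i in range(0, len(base_blocks), step)]
    slots: list[list[list[str]]] = [[] for _ in chunks]
    for j, blk in enumerate(insert_blocks):
        slots[j % len(slots)].append(blk)
    out: list[list[str]] = []
    for chunk, slot in zip(chunks, slots):
        out.extend(list(b) for b in chunk)
        out.extend(list(b) for b in slot)
    return out


def block_randomize_unbalanced(
    samples_by_category: Mapping[str, Sequence[str]],
    seed: int = 0,
) -> RandomizedSequence:
    """Optimized block randomization for unequal category counts.

    The categories are partitioned into nested groups with internally equal
    counts (:func:`partition_nested_groups`).  Each multi-category group is
    block randomized with block size equal to its dim size; the final
    single-category group is completely randomized (blocking is meaningless
    within one category) and contributes single-sample blocks so it can be
    spread out.  Groups are then folded together from most-dimensional to
    least: at each fold the side with more blocks forms the backbone and
    the other side's blocks are interspersed at the stride given by
    :func:`intersperse_step` on the block counts.
    """
    if not samples_by_category:
        raise ValidationError("samples_by_category is empty")
    rng = np.random.default_rng(seed)
    counts = {cat: len(ids) for cat, ids in samples_by_category.items()}
    if any(c < 1 for c in counts.values()):
        raise ValidationError("every category needs at least one sample")
    pools = {
        cat: [ids[i] for i in rng.permutation(len(ids))]
        for cat, ids in samples_by_category.items()
    }
    offsets = dict.fromkeys(pools, 0)
    current: list[list[str]] | None = None
    for group in partition_nested_groups(counts):
        sub: dict[str, list[str]] = {}
        for cat in group.categories:
            start = offsets[cat]
            sub[cat] = pools[cat][start : start + group.per_category_count]
            offsets[cat] = start + group.per_category_count
        if group.dim_size > 1:
            gblocks = _blocks_from_patterns(sub, group.dim_size, rng)
        else:
            only = next(iter(sub.values()))
            shuffled = [only[i] for i in rng.permutation(len(only))]
            gblocks = [[sid] for sid in shuffled]
        if current is None:
            current = gblocks
            continue
        if len(current) >= len(gblocks):
            base, insert = current, gblocks
        else:
            base, insert = gblocks, current
        step = intersperse_step(len(base), len(insert))
        current = merge_interspersed(base, insert, step)
    assert current is not None
    return RandomizedSequence(
        order=[sid for b in current for sid in b],
        block_boundaries=[len(b) for b in current],
    )


def complete_randomize(sample_ids: Sequence[str], seed: int = 0) -> RandomizedSequence:
    """Seeded uniform shuffle — no balance guarantees at all."""
    rng = np.random.default_rng(seed)
    ids = list(sample_ids)
    return RandomizedSequence(
        order=[ids[i] for i in rng.permutation(len(ids))],
        block_boundaries=None,
    )
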