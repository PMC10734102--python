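"""Inter-batch balancing: distribute samples evenly across batches/plates.

Samples sharing the same joint covariate category ("stratum") are spread
across batches so no batch accumulates an excess of any stratum — the
standard defence against confounding biological factors with batch effects.
Each stratum contributes its floor share to every batch; the per-stratum
remainders ("tail samples") are pooled, re-shuffled and dealt round-robin
starting from a random batch so no batch is systematically larger.

Batch indices are 0-based internally and rendered 1-based ("Plate 1") in
all user-facing output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .errors import CapacityError, ValidationError
from .samples_io import Cohort

__all__ = [
    "BatchAssignment",
    "n_batches_for_capacity",
    "allocate_balanced",
    "distribute_tail",
    "allocate_complete_random",
]


@dataclass
class BatchAssignment:
    """A partition of a cohort's samples into batches.

    ``assignment`` maps 0-based batch index to the ordered sample IDs of
    that batch; ``strat_covariates`` records which covariates were used for
    stratification (empty for complete randomization).
    """

    n_batches: int
    assignment: dict[int, list[str]]
    strat_covariates: list[str] = field(default_factory=list)

    def batch_sizes(self) -> list[int]:
        return [len(self.assignment[b]) for b in range(self.n_batches)]

    def all_sample_ids(self) -> list[str]:
        return [sid for b in range(self.n_batches) for sid in self.assignment[b]]


def n_batches_for_capacity(n_samples: int, capacity: int) -> int:
    """Smallest number of batches so no batch exceeds ``capacity`` samples."""
    if capacity < 1:
        raise ValidationError(f"capacity must be >= 1, got {capacity}")
    if n_samples < 1:
        raise ValidationError(f"n_samples must be >= 1, got {n_samples}")
    return math.ceil(n_samples / capacity)


def _strata(cohort: Cohort, covariates: list[str]) -> dict[tuple[str, ...], list[str]]:
    """Joint-category strata in declared category cross-product order."""
    for name in covariates:
        cohort.covariate(name)
    if not covariates:
        return {(): cohort.sample_ids()}
    label_rows = {name: cohort.labels(name) for name in covariates}
    buckets: dict[tuple[str, ...], list[str]] = {}
    for combo in product(*(cohort.covariate(n).categories for n in covariates)):
        buckets[combo] = []
    for i, sid in enumerate(cohort.sample_ids()):
        key = tuple(label_rows[name][i] for name in covariates)
        buckets[key].append(sid)
    return {k: v for k, v in buckets.items() if v}  # drop empty strata


def _deal_round_robin(
    ids: list[str], n_batches: int, start: int
) -> dict[int, list[str]]:
    out: dict[int, list[str]] = {b: [] for b in range(n_batches)}
    for j, sid in enumerate(ids):
        out[(start + j) % n_batches].append(sid)
    return out


def distribute_tail(
    tail_sample_ids: list[str], n_batches: int, seed: int
) -> dict[int, list[str]]:
    """Deal pooled tail samples round-robin across batches.

    The tail is shuffled, then dealt one-by-one starting from a seeded
    random batch, so batch tail sizes differ by at most 1 and no batch is
    systematically favoured.
    """
    if n_batches < 1:
        raise ValidationError(f"n_batches must be >= 1, got {n_batches}")
    rng = np.random.default_rng(seed)
    if not tail_sample_ids:
        return {b: [] for b in range(n_batches)}
    order = [tail_sample_ids[i] for i in rng.permutation(len(tail_sample_ids))]
    start = int(rng.integers(n_batches))
    return _deal_round_robin(order, n_batches, start)


def allocate_balanced(
    cohort: Cohort,
    strat_covariates: list[str],
    n_batches: int,
    seed: int,
    capacity: int | None = None,
) -> BatchAssignment:
    """Stratified balanced allocation of a cohort into ``n_batches`` batches.

    Every batch receives at least ``floor(c_s / n_batches)`` samples of each
    stratum *s* (with count ``c_s``); the pooled per-stratum remainders are
    then dealt round-robin by :func:`distribute_tail`.  Which samples fill
    which slot is decided by the seeded generator.

    If ``capacity`` is given and any resulting batch would exceed it, a
    :class:`~platedesign.errors.CapacityError` is raised rather than
    silently adding a batch; recompute with
    :func:`n_batches_for_capacity` instead.
    """
    if n_batches < 1:
        raise ValidationError(f"n_batches must be >= 1, got {n_batches}")
    rng = np.random.default_rng(seed)
    batches: dict[int, list[str]] = {b: [] for b in range(n_batches)}
    stratum_tails: list[list[str]] = []
    for ids in _strata(cohort, list(strat_covariates)).values():
        shuffled = [ids[i] for i in rng.permutation(len(ids))]
        base, rest = divmod(len(ids), n_batches)
        for b in range(n_batches):
            batches[b].extend(shuffled[b * base : (b + 1) * base])
        if rest:
            stratum_tails.append(shuffled[n_batches * base :])
    # One continuous round-robin deal over the pooled tail, with each
    # stratum's tail kept contiguous: a stratum has at most n_batches - 1
    # tail samples, so they always land in distinct batches, preserving the
    # <=1 per-stratum spread even when several strata have tails.
    if stratum_tails:
        tail_pool = [
            sid
            for g in rng.permutation(len(stratum_tails))
            for sid in stratum_tails[g]
        ]
        start = int(rng.integers(n_batches))
        for b, ids in _deal_round_robin(tail_pool, n_batches, start).items():
            batches[b].extend(ids)
    if capacity is not None:
        worst = max(len(v) for v in batches.values())
        if worst > capacity:
            raise CapacityError(
                f"balanced allocation puts {worst} samples in a batch but "
                f"capacity is {capacity}; recompute n_batches_for_capacity"
            )
    return BatchAssignment(
        n_batches=n_batches,
        assignment=batches,
        strat_covariates=list(strat_covariates),
    )


def allocate_complete_random(
    cohort: Cohort, n_batches: int, seed: int
) -> BatchAssignment:
    """Unstratified alternative: shuffle everything, deal as evenly as possible."""
    if n_batches < 1:
        raise ValidationError(f"n_batches must be >= 1, got {n_batches}")
    rng = np.random.default_rng(seed)
    ids = cohort.sample_ids()
    shuffled = [ids[i] for i in rng.permutation(len(ids))]
    base, rest = divmod(len(shuffled), n_batches)
    batches: dict[int, list[str]] = {}
    pos = 0
    for b in range(n_batches):
        take = base + (1 if b < rest else 0)
        batches[b] = shuffled[pos : pos + take]
        pos += take
    return BatchAssignment(n_batches=n_batches, assignment=batches, strat_covariates=[])
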