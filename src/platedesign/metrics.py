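"""Balance diagnostics for batch assignments and run orders.

All metrics are pure functions of their inputs (no randomness), so they can
double as test oracles.  Deviations are reported in percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .samples_io import Cohort
from .stratify import BatchAssignment

__all__ = [
    "BalanceReport",
    "longest_run",
    "count_runs_at_least",
    "batch_balance_report",
    "max_window_deviation",
]


@dataclass
class BalanceReport:
    """Per-batch category percentages for one covariate.

    ``per_batch_proportions`` has one row per batch (index "Plate 1", ...)
    and one column per category, in percent; non-empty rows sum to 100.
    Empty batches appear as flagged all-zero rows (listed in
    ``empty_batches``) rather than raising, so stress designs with tiny
    plates never abort diagnostics.
    """

    per_batch_proportions: pd.DataFrame
    max_abs_deviation_pct: float
    covariate: str
    empty_batches: list[int]


def longest_run(sequence: Sequence[str]) -> int:
    """Length of the longest constant-label run (0 for an empty sequence)."""
    return max((len(list(g)) for _, g in groupby(sequence)), default=0)


def count_runs_at_least(sequence: Sequence[str], k: int) -> int:
    """Number of maximal constant-label runs of length >= k."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    return sum(1 for _, g in groupby(sequence) if len(list(g)) >= k)


def batch_balance_report(
    assignment: BatchAssignment, cohort: Cohort, covariate: str
) -> BalanceReport:
    """Per-batch category percentages vs. the cohort-wide proportions."""
    spec = cohort.covariate(covariate)
    label_of = dict(zip(cohort.sample_ids(), cohort.labels(covariate)))
    categories = list(spec.categories)
    overall = pd.Series(
        [cohort.labels(covariate).count(c) for c in categories],
        index=categories,
        dtype=float,
    )
    overall_pct = 100.0 * overall / overall.sum()

    rows, empty = [], []
    for b in range(assignment.n_batches):
        ids = assignment.assignment[b]
        if not ids:
            empty.append(b)
            rows.append(pd.Series(0.0, index=categories))
            continue
        counts = pd.Series(0.0, index=categories)
        for sid in ids:
            counts[label_of[sid]] += 1
        rows.append(100.0 * counts / len(ids))
    table = pd.DataFrame(
        rows, index=[f"Plate {b + 1}" for b in range(assignment.n_batches)]
    )
    nonempty = table.drop(index=[f"Plate {b + 1}" for b in empty])
    deviation = float((nonempty - overall_pct).abs().to_numpy().max()) if len(nonempty) else 0.0
    return BalanceReport(
        per_batch_proportions=table,
        max_abs_deviation_pct=deviation,
        covariate=covariate,
        empty_batches=empty,
    )


def max_window_deviation(
    sequence: Sequence[str], cohort: Cohort, covariate: str, window: int
) -> float:
    """Worst sliding-window imbalance of a run order, in percentage points.

    For every window of ``window`` consecutive entries, the observed share
    of each category is compared with its cohort-wide share; the maximum
    absolute difference over all windows and categories is returned.
    """
    if window < 1 or window > len(sequence):
        raise ValidationError(
            f"window must be in [1, {len(sequence)}], got {window}"
        )
    spec = cohort.covariate(covariate)
    label_of = dict(zip(cohort.sample_ids(), cohort.labels(covariate)))
    labels = [label_of[sid] for sid in sequence]
    all_labels = cohort.labels(covariate)
    worst = 0.0
    for cat in spec.categories:
        expected = 100.0 * all_labels.count(cat) / len(all_labels)
        ind = np.fromiter((lab == cat for lab in labels), dtype=float)
        csum = np.concatenate([[0.0], np.cumsum(ind)])
        observed = 100.0 * (csum[window:] - csum[:-window]) / window
        worst = max(worst, float(np.abs(observed - expected).max()))
    return worst
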