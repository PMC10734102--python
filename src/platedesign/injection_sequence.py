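"""Build the final run order: randomized samples with QC evenly interleaved.

The injection sequence is designed independently of the plate layout: QC
samples physically sit together in their predefined wells, but their
*injections* are spread evenly through the run so instrument drift can be
tracked.  With ``n`` experimental and ``m`` QC injections, QC number ``j``
(1-based) is inserted after experimental sample number ``⌊j·n/m⌋`` — a
circular rule whose gaps differ by at most one and which closes the run
with a QC injection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConsistencyError, ValidationError
from .plate_layout import PlateLayout, QCPlacementPlan, WellPosition, format_well_label
from .samples_io import EXPERIMENTAL

__all__ = [
    "InjectionEntry",
    "InjectionSequence",
    "qc_insertion_points",
    "interpolate_qc",
    "build_qc_schedule",
    "assemble",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InjectionEntry:
    """One injection: 1-based order, sample, type, plate and well."""

    order: int
    sample_id: str
    sample_type: str
    plate_index: int  # 0-based internally
    position: WellPosition

    def well_label(self, layout: PlateLayout) -> str:
        return format_well_label(layout.spec, self.position)


@dataclass
class InjectionSequence:
    """The ordered run list of one plate."""

    entries: list[InjectionEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    def experimental_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries if e.sample_type == EXPERIMENTAL]


def qc_insertion_points(n_experimental: int, n_qc: int) -> list[int]:
    """Experimental index (1-based) after which each QC injection goes.

    Entry ``j`` (1-based) is ``⌊j·n/m⌋``; consecutive gaps differ by at
    most 1 and the last QC lands at the end of the run.
    """
    if n_qc < 1:
        return []
    n, m = n_experimental, n_qc
    points = np.arange(1, m + 1, dtype=np.int64) * n // m
    return points.tolist()


def interpolate_qc(
    experimental_order: Sequence[str],
    qc_schedule: Sequence[tuple[str, str]],
) -> list[tuple[str, str]]:
    """Insert QC injections evenly into a randomized experimental order.

    ``qc_schedule`` is an ordered list of (QC sample ID, QC type); the
    result is the merged run as (sample ID, sample type) pairs with
    experimental entries typed :data:`~platedesign.samples_io.EXPERIMENTAL`
    and their relative order unchanged.  If there are more QC than
    experimental samples, one QC follows each experimental sample and the
    surplus is appended at the end (with a logged warning).
    """
    n, m = len(experimental_order), len(qc_schedule)
    if n == 0 and m == 0:
        raise ValidationError("nothing to sequence: no samples and no QC")
    if m == 0:
        return [(sid, EXPERIMENTAL) for sid in experimental_order]
    if m > n:
        logger.warning(
            "more QC injections (%d) than experimental samples (%d); "
            "surplus QC appended at the end of the run", m, n,
        )
        points = qc_insertion_points(n, n) + [n] * (m - n)
    else:
        points = qc_insertion_points(n, m)
    out: list[tuple[str, str]] = []
    next_qc = 0
    for i in range(n):
        out.append((experimental_order[i], EXPERIMENTAL))
        while next_qc < m and points[next_qc] == i + 1:
            out.append(tuple(qc_schedule[next_qc]))
            next_qc += 1
    while next_qc < m:
        out.append(tuple(qc_schedule[next_qc]))
        next_qc += 1
    return out


def build_qc_schedule(
    plan: QCPlacementPlan, plate_index: int
) -> list[tuple[str, str]]:
    """Per-plate QC injection schedule, round-robin across QC types.

    Types are interleaved in plan order ({Blank: 2, LTR: 2} → Blank, LTR,
    Blank, LTR) so no single QC type clusters.  IDs are synthesized
    deterministically as ``<type>_<plate>_<ordinal>`` (plate 1-based) so
    re-runs are diff-stable.
    """
    remaining = {qc_type: count for qc_type, count in plan.qc_types}
    emitted = dict.fromkeys(remaining, 0)
    schedule: list[tuple[str, str]] = []
    while any(v > 0 for v in remaining.values()):
        for qc_type, _ in plan.qc_types:
            if remaining[qc_type] > 0:
                emitted[qc_type] += 1
                remaining[qc_type] -= 1
                schedule.append(
                    (f"{qc_type}_{plate_index + 1}_{emitted[qc_type]}", qc_type)
                )
    return schedule


def assemble(
    batch: Sequence[str],
    layout: PlateLayout,
    plan: QCPlacementPlan,
    plate_index: int,
    qc_lead_in: int = 0,
) -> InjectionSequence:
    """Join the interleaved run order with wells from the plate layout.

    ``qc_lead_in`` moves that many QC injections from the schedule to the
    very start of the run (a common bench practice for conditioning the
    column); the remainder is interleaved by :func:`interpolate_qc`.
    """
    schedule = build_qc_schedule(plan, plate_index)
    if qc_lead_in < 0 or qc_lead_in > len(schedule):
        raise ValidationError(
            f"qc_lead_in must be in [0, {len(schedule)}], got {qc_lead_in}"
        )
    lead, rest = list(schedule[:qc_lead_in]), list(schedule[qc_lead_in:])
    run = list(lead)
    if batch or rest:
        run += interpolate_qc(batch, rest)
    well_of = {sid: pos for pos, sid in layout.wells.items()}
    entries = []
    for order0, (sid, stype) in enumerate(run):
        if sid not in well_of:
            raise ConsistencyError(
                f"sequenced sample {sid!r} has no well on plate {plate_index + 1}"
            )
        entries.append(
            InjectionEntry(
                order=order0 + 1,
                sample_id=sid,
                sample_type=stype,
                plate_index=plate_index,
                position=well_of[sid],
            )
        )
    return InjectionSequence(entries=entries)
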