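"""Plate geometry and the sample→well mapping, independent of run order.

Modern autosamplers inject in any user-defined order, so where a sample
sits on the plate can be chosen for bench convenience (QC samples grouped
in one column) while the injection order is designed separately for
statistical balance.  This module owns only the geometry side.

Well labels are the y-label immediately followed by the x-label ("a1");
parsing is case-insensitive.  Indices are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import CapacityError, FormatError, ValidationError

__all__ = [
    "PlateSpec",
    "WellPosition",
    "QCPlacementPlan",
    "PlateLayout",
    "builtin_plate",
    "ordered_positions",
    "assign_positions",
    "parse_well_label",
    "format_well_label",
]


@dataclass(frozen=True)
class PlateSpec:
    """Plate geometry: axis sizes and the label alphabet of each axis."""

    name: str
    x_count: int
    x_labels: tuple[str, ...]
    y_count: int
    y_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        for axis, count, labels in (
            ("x", self.x_count, self.x_labels),
            ("y", self.y_count, self.y_labels),
        ):
            if count < 1:
                raise ValidationError(f"{axis}_count must be >= 1")
            if len(labels) != count:
                raise ValidationError(
                    f"{axis}_labels has {len(labels)} entries, expected {count}"
                )
            if len(set(labels)) != count:
                raise ValidationError(f"duplicate {axis}-axis labels")

    @property
    def capacity(self) -> int:
        return self.x_count * self.y_count


@dataclass(frozen=True)
class WellPosition:
    """A well, addressed by 0-based (y, x) grid indices."""

    y_index: int
    x_index: int


@dataclass(frozen=True)
class QCPlacementPlan:
    """Where QC samples sit on each plate and how many of each type.

    ``qc_types`` is an ordered list of (QC type name, count per plate);
    ``predefined_region`` is ``"first_column"``, ``"last_column"`` or an
    explicit list of wells; ``fill_direction`` orders both the QC region
    traversal and the experimental fill.
    """

    qc_types: tuple[tuple[str, int], ...] = ()
    predefined_region: str | tuple[WellPosition, ...] = "first_column"
    fill_direction: str = "horizontal"
    max_experimental_capacity: int | None = None

    def __post_init__(self) -> None:
        if self.fill_direction not in {"horizontal", "vertical"}:
            raise ValidationError(
                f"fill_direction must be horizontal or vertical, "
                f"got {self.fill_direction!r}"
            )
        if any(count < 0 for _, count in self.qc_types):
            raise ValidationError("QC counts must be >= 0")

    @property
    def total_qc(self) -> int:
        return sum(count for _, count in self.qc_types)

    def validate_against(self, spec: PlateSpec) -> None:
        if self.max_experimental_capacity is not None:
            if self.total_qc + self.max_experimental_capacity > spec.capacity:
                raise CapacityError(
                    f"{self.total_qc} QC wells + "
                    f"{self.max_experimental_capacity} experimental exceed "
                    f"plate capacity {spec.capacity}"
                )


@dataclass
class PlateLayout:
    """The sample→well mapping of one plate (injective by construction)."""

    spec: PlateSpec
    wells: dict[WellPosition, str]

    def __post_init__(self) -> None:
        if len(self.wells) > self.spec.capacity:
            raise CapacityError(
                f"{len(self.wells)} wells mapped on a "
                f"{self.spec.capacity}-well plate"
            )
        ids = list(self.wells.values())
        if len(set(ids)) != len(ids):
            raise ValidationError("a sample occupies two wells of one plate")
        for pos in self.wells:
            if not (0 <= pos.y_index < self.spec.y_count and 0 <= pos.x_index < self.spec.x_count):
                raise ValidationError(f"well {pos} outside plate bounds")

    def well_of(self, sample_id: str) -> WellPosition:
        for pos, sid in self.wells.items():
            if sid == sample_id:
                return pos
        raise ValidationError(f"sample {sample_id!r} not on this plate")


#: Built-in plate templates: standard 96-well (12×8, columns 1–12, rows a–h)
#: and 384-well (24×16, columns 1–24, rows a–p) microplates.
_BUILTIN: dict[str, PlateSpec] = {
    "96": PlateSpec(
        name="96",
        x_count=12,
        x_labels=tuple(str(i) for i in range(1, 13)),
        y_count=8,
        y_labels=tuple("abcdefgh"),
    ),
    "384": PlateSpec(
        name="384",
        x_count=24,
        x_labels=tuple(str(i) for i in range(1, 25)),
        y_count=16,
        y_labels=tuple("abcdefghijklmnop"),
    ),
}


def builtin_plate(name: str) -> PlateSpec:
    """Return a built-in plate template ("96" or "384")."""
    try:
        return _BUILTIN[str(name)]
    except KeyError:
        raise ValidationError(
            f"unknown plate template {name!r}; built-ins: {sorted(_BUILTIN)}"
        ) from None


def ordered_positions(spec: PlateSpec, direction: str = "horizontal") -> list[WellPosition]:
    """Every well once: row-major ("horizontal") or column-major ("vertical")."""
    if direction == "horizontal":
        return [
            WellPosition(y, x) for y in range(spec.y_count) for x in range(spec.x_count)
        ]
    if direction == "vertical":
        return [
            WellPosition(y, x) for x in range(spec.x_count) for y in range(spec.y_count)
        ]
    raise ValidationError(
        f"direction must be horizontal or vertical, got {direction!r}"
    )


def format_well_label(spec: PlateSpec, position: WellPosition) -> str:
    """Render a well as y-label followed by x-label, e.g. "a1"."""
    return spec.y_labels[position.y_index] + spec.x_labels[position.x_index]


def parse_well_label(spec: PlateSpec, label: str) -> WellPosition:
    """Inverse of :func:`format_well_label`; case-insensitive."""
    low = label.strip().lower()
    # longest y-label first so multi-character alphabets parse unambiguously
    for y, ylab in sorted(
        enumerate(spec.y_labels), key=lambda t: -len(t[1])
    ):
        if low.startswith(ylab.lower()):
            rest = low[len(ylab):]
            for x, xlab in enumerate(spec.x_labels):
                if rest == xlab.lower():
                    return WellPosition(y_index=y, x_index=x)
    raise FormatError(f"cannot parse well label {label!r} on plate {spec.name!r}")


def _region_positions(
    plan: QCPlacementPlan, spec: PlateSpec
) -> list[WellPosition]:
    region = plan.predefined_region
    if region == "first_column":
        cols = [WellPosition(y, 0) for y in range(spec.y_count)]
    elif region == "last_column":
        cols = [WellPosition(y, spec.x_count - 1) for y in range(spec.y_count)]
    else:
        cols = list(region)
        for pos in cols:
            if not (0 <= pos.y_index < spec.y_count and 0 <= pos.x_index < spec.x_count):
                raise ValidationError(f"QC region well {pos} outside plate bounds")
        return cols
    if plan.fill_direction == "horizontal":
        # a single column has one well per row either way; keep row order
        return cols
    return cols


def assign_positions(
    batch_sample_ids: Sequence[str],
    qc_sample_ids_by_type: Mapping[str, Sequence[str]],
    plan: QCPlacementPlan,
    spec: PlateSpec,
) -> PlateLayout:
    """Lay one batch out on a plate: QC in the predefined region, then samples.

    QC wells are filled grouped by type, in plan order, traversing the
    region in the plan's fill direction.  Experimental samples fill the
    remaining wells in :func:`ordered_positions` order, skipping QC wells.
    The result depends only on the sample *sets*, never on injection order.
    """
    qc_ids = [
        sid
        for qc_type, _ in plan.qc_types
        for sid in qc_sample_ids_by_type.get(qc_type, [])
    ]
    extra = [
        sid
        for qc_type, ids in qc_sample_ids_by_type.items()
        if qc_type not in {t for t, _ in plan.qc_types}
        for sid in ids
    ]
    qc_ids.extend(extra)
    region = _region_positions(plan, spec)
    if len(qc_ids) > len(region):
        raise ValidationError(
            f"QC region has {len(region)} wells but {len(qc_ids)} QC samples "
            f"are planned"
        )
    wells: dict[WellPosition, str] = dict(zip(region, qc_ids))
    taken = set(region[: len(qc_ids)]) | set(region) if plan.predefined_region not in (
        "first_column",
        "last_column",
    ) else set(region[: len(qc_ids)])
    # explicit regions reserve every listed well; built-in column regions
    # release unused wells back to the experimental fill
    free = [
        pos
        for pos in ordered_positions(spec, plan.fill_direction)
        if pos not in taken
    ]
    if len(batch_sample_ids) > len(free):
        raise CapacityError(
            f"{len(batch_sample_ids)} experimental samples but only "
            f"{len(free)} free wells ({len(qc_ids)} QC wells reserved on a "
            f"{spec.capacity}-well plate)"
        )
    wells.update(zip(free, batch_sample_ids))
    return PlateLayout(spec=spec, wells=wells)
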