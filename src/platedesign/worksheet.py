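"""Instrument-ready worksheet export and JSON project persistence.

Different LC/MS instruments want different column headers in their import
tables, so the worksheet is produced through a *field map*: an ordered list
of (internal field, output header) pairs.  Internal fields are

    sample_id, sample_type, batch, plate, well_label, injection_order,
    global_order, covariate:<name>

``injection_order`` restarts at 1 on every plate; ``global_order`` numbers
the whole run.  The whole design (cohort, parameters, batch assignment,
layouts, sequences) persists losslessly to a schema-versioned JSON project
file so long-running studies can be reloaded and re-exported identically.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Any

import pandas as pd

from .errors import FormatError, SchemaError, ValidationError
from .injection_sequence import InjectionEntry, InjectionSequence
from .plate_layout import (
    PlateLayout,
    PlateSpec,
    QCPlacementPlan,
    WellPosition,
    format_well_label,
    parse_well_label,
)
from .samples_io import Cohort, CovariateSpec, Sample
from .stratify import BatchAssignment

__all__ = [
    "FieldMap",
    "DesignProject",
    "builtin_field_maps",
    "export_worksheet",
    "read_worksheet",
    "save_project",
    "load_project",
]

SCHEMA_VERSION = 1

#: Internal fields every field map may reference (plus covariate:<name>).
CORE_FIELDS = (
    "sample_id",
    "sample_type",
    "batch",
    "plate",
    "well_label",
    "injection_order",
    "global_order",
)


@dataclass(frozen=True)
class FieldMap:
    """Ordered mapping of internal fields to instrument column headers."""

    name: str
    columns: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        headers = [h for _, h in self.columns]
        if len(set(headers)) != len(headers):
            raise ValidationError(f"field map {self.name!r}: duplicate headers")
        fields = {f for f, _ in self.columns}
        for required in ("sample_id", "injection_order"):
            if required not in fields:
                raise ValidationError(
                    f"field map {self.name!r} must map {required!r}"
                )
        for f in fields:
            if f not in CORE_FIELDS and not f.startswith("covariate:"):
                raise ValidationError(f"unknown internal field {f!r}")

    @property
    def headers(self) -> list[str]:
        return [h for _, h in self.columns]


def builtin_field_maps() -> list[FieldMap]:
    """Built-in presets; "generic" maps every core field to itself."""
    return [
        FieldMap(
            name="generic",
            columns=tuple((f, f) for f in CORE_FIELDS),
        )
    ]


@dataclass
class DesignProject:
    """A complete plate design: inputs, parameters and every derived artifact."""

    cohort: Cohort
    parameters: dict[str, Any]
    assignment: BatchAssignment
    layouts: list[PlateLayout]
    sequences: list[InjectionSequence]
    created: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc)
        .strftime("%Y-%m-%dT%H:%M:%SZ")
    )

    def validate(self) -> None:
        if not (len(self.layouts) == len(self.sequences) == self.assignment.n_batches):
            raise ValidationError(
                "plates, sequences and batches must correspond one-to-one"
            )
        known = set(self.cohort.sample_ids())
        for plate, (layout, seq) in enumerate(zip(self.layouts, self.sequences)):
            placed = set(layout.wells.values())
            for entry in seq.entries:
                if entry.position not in layout.wells:
                    raise ValidationError(
                        f"plate {plate + 1}: sequenced well not on layout"
                    )
            for sid in self.assignment.assignment[plate]:
                if sid not in known:
                    raise ValidationError(f"unknown sample {sid!r} in batch")
                if sid not in placed:
                    raise ValidationError(
                        f"plate {plate + 1}: batch sample {sid!r} has no well"
                    )

    def injection_rows(self) -> list[dict[str, Any]]:
        """One dict per injection, all plates concatenated in plate order."""
        label_rows = {
            name: dict(zip(self.cohort.sample_ids(), self.cohort.labels(name)))
            for name in self.cohort.covariate_names
        }
        rows = []
        global_order = 0
        for plate_i, (layout, seq) in enumerate(zip(self.layouts, self.sequences)):
            for entry in sorted(seq.entries, key=lambda e: e.order):
                global_order += 1
                row: dict[str, Any] = {
                    "sample_id": entry.sample_id,
                    "sample_type": entry.sample_type,
                    "batch": str(plate_i + 1),
                    "plate": str(plate_i + 1),
                    "well_label": format_well_label(layout.spec, entry.position),
                    "injection_order": entry.order,
                    "global_order": global_order,
                }
                for name, mapping in label_rows.items():
                    row[f"covariate:{name}"] = mapping.get(entry.sample_id, "")
                rows.append(row)
        return rows


def export_worksheet(
    project: DesignProject,
    field_map: FieldMap,
    dest: str | Path | IO,
    format: str = "csv",
) -> None:
    """Write the run list as an instrument worksheet (CSV or XLSX).

    One row per injection, all plates concatenated, sorted by
    (plate, injection order); headers exactly as mapped, in map order.
    Output is byte-stable for a fixed project.
    """
    project.validate()
    rows = project.injection_rows()
    data = {
        header: [row.get(internal, "") for row in rows]
        for internal, header in field_map.columns
    }
    frame = pd.DataFrame(data, columns=field_map.headers)
    if format == "csv":
        frame.to_csv(dest, index=False, lineterminator="\n")
    elif format == "xlsx":
        frame.to_excel(dest, index=False, sheet_name="worksheet")
    else:
        raise FormatError(f"unsupported worksheet format {format!r}")


def read_worksheet(
    source: str | Path | IO, field_map: FieldMap, format: str | None = None
) -> list[dict[str, Any]]:
    """Read a worksheet back into records keyed by internal field names."""
    if format is None:
        suffix = Path(str(source)).suffix.lower() if isinstance(source, (str, Path)) else ""
        format = "xlsx" if suffix in {".xlsx", ".xls"} else "csv"
    if format == "csv":
        frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    elif format == "xlsx":
        frame = pd.read_excel(source, sheet_name=0, dtype=str).fillna("")
    else:
        raise FormatError(f"unsupported worksheet format {format!r}")
    if list(frame.columns) != field_map.headers:
        raise FormatError(
            f"worksheet header {list(frame.columns)!r} does not match field "
            f"map {field_map.name!r} ({field_map.headers!r})"
        )
    internal_of = {header: internal for internal, header in field_map.columns}
    records = []
    for _, row in frame.iterrows():
        rec = {internal_of[h]: row[h] for h in field_map.headers}
        for key in ("injection_order", "global_order"):
            if key in rec:
                rec[key] = int(rec[key])
        records.append(rec)
    return records


# --- JSON project persistence -------------------------------------------------

def _spec_to_json(spec: PlateSpec) -> dict:
    return {
        "name": spec.name,
        "x_count": spec.x_count,
        "x_labels": list(spec.x_labels),
        "y_count": spec.y_count,
        "y_labels": list(spec.y_labels),
    }


def _spec_from_json(obj: dict) -> PlateSpec:
    return PlateSpec(
        name=obj["name"],
        x_count=obj["x_count"],
        x_labels=tuple(obj["x_labels"]),
        y_count=obj["y_count"],
        y_labels=tuple(obj["y_labels"]),
    )


def _cohort_to_json(cohort: Cohort) -> dict:
    return {
        "covariates": [
            {"name": c.name, "categories": list(c.categories)}
            for c in cohort.covariates
        ],
        "samples": [
            {
                "sample_id": s.sample_id,
                "sample_type": s.sample_type,
                "covariates": dict(s.covariates),
            }
            for s in cohort.samples
        ],
    }


def _cohort_from_json(obj: dict) -> Cohort:
    return Cohort(
        samples=[
            Sample(
                sample_id=s["sample_id"],
                sample_type=s["sample_type"],
                covariates=dict(s["covariates"]),
            )
            for s in obj["samples"]
        ],
        covariates=[
            CovariateSpec(name=c["name"], categories=tuple(c["categories"]))
            for c in obj["covariates"]
        ],
    )


def save_project(project: DesignProject, path: str | Path) -> None:
    """Persist a design project as schema-versioned JSON."""
    project.validate()
    doc = {
        "schema_version": SCHEMA_VERSION,
        "created": project.created,
        "parameters": project.parameters,
        "cohort": _cohort_to_json(project.cohort),
        "assignment": {
            "n_batches": project.assignment.n_batches,
            "strat_covariates": list(project.assignment.strat_covariates),
            "batches": [
                project.assignment.assignment[b]
                for b in range(project.assignment.n_batches)
            ],
        },
        "plates": [
            {
                "spec": _spec_to_json(layout.spec),
                "wells": {
                    format_well_label(layout.spec, pos): sid
                    for pos, sid in layout.wells.items()
                },
                "sequence": [
                    {
                        "order": e.order,
                        "sample_id": e.sample_id,
                        "sample_type": e.sample_type,
                        "well": format_well_label(layout.spec, e.position),
                    }
                    for e in seq.entries
                ],
            }
            for layout, seq in zip(project.layouts, project.sequences)
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_project(path: str | Path) -> DesignProject:
    """Inverse of :func:`save_project`; raises SchemaError on bad files."""
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaError(f"cannot read project file {path}: {exc}") from exc
    try:
        version = doc["schema_version"]
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"project schema version {version} unsupported "
                f"(expected {SCHEMA_VERSION})"
            )
        cohort = _cohort_from_json(doc["cohort"])
        batches = doc["assignment"]["batches"]
        assignment = BatchAssignment(
            n_batches=doc["assignment"]["n_batches"],
            assignment={i: list(ids) for i, ids in enumerate(batches)},
            strat_covariates=list(doc["assignment"]["strat_covariates"]),
        )
        layouts, sequences = [], []
        for plate_i, plate in enumerate(doc["plates"]):
            spec = _spec_from_json(plate["spec"])
            wells = {
                parse_well_label(spec, label): sid
                for label, sid in plate["wells"].items()
            }
            layouts.append(PlateLayout(spec=spec, wells=wells))
            sequences.append(
                InjectionSequence(
                    entries=[
                        InjectionEntry(
                            order=e["order"],
                            sample_id=e["sample_id"],
                            sample_type=e["sample_type"],
                            plate_index=plate_i,
                            position=parse_well_label(spec, e["well"]),
                        )
                        for e in plate["sequence"]
                    ]
                )
            )
        project = DesignProject(
            cohort=cohort,
            parameters=doc["parameters"],
            assignment=assignment,
            layouts=layouts,
            sequences=sequences,
            created=doc["created"],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"malformed project file {path}: {exc}") from exc
    project.validate()
    return project
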