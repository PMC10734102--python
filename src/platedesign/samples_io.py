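"""Sample tables: reading, writing, and the built-in demonstration cohort.

A *cohort* is an ordered list of samples plus the categorical covariate
definitions used for stratification and randomization.  Tables are plain
CSV (RFC 4180, UTF-8, header row) or XLSX (first worksheet) with one row
per sample: a sample-ID column, a sample-type column and up to three
categorical covariate columns — the layout a bench scientist would keep in
a spreadsheet.

Blank covariate cells are recorded under the literal category ``Unknown``
so that missing demographic data participates in stratification as its own
stratum rather than being dropped.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Sample type of ordinary (non-QC) study samples.
EXPERIMENTAL = "EXPERIMENTAL"

#: Recognised header spellings, lower-cased with spaces/underscores stripped.
SAMPLE_ID_ALIASES = {"sampleid", "id", "sample", "samplename"}
SAMPLE_TYPE_ALIASES = {"sampletype", "type"}

#: Category label recorded for blank covariate cells.
UNKNOWN_LABEL = "Unknown"


@dataclass(frozen=True)
class Sample:
    """One physical sample: unique ID, type, and categorical covariates."""

    sample_id: str
    sample_type: str = EXPERIMENTAL
    covariates: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class CovariateSpec:
    """A categorical covariate: its name and the ordered category labels.

    Category order is the order of first appearance in the source table and
    is stored explicitly so that downstream labels (block-permutation
    letters, report columns) are reproducible.
    """

    name: str
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValidationError(f"covariate {self.name!r} has no categories")
        if len(set(self.categories)) != len(self.categories):
            raise ValidationError(
                f"covariate {self.name!r} has duplicate categories"
            )


@dataclass
class Cohort:
    """An ordered sample list with its covariate definitions."""

    samples: list[Sample]
    covariates: list[CovariateSpec]

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.covariates]

    def covariate(self, name: str) -> CovariateSpec:
        for spec in self.covariates:
            if spec.name == name:
                return spec
        raise ValidationError(f"unknown covariate {name!r}")

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def labels(self, covariate: str) -> list[str]:
        """Category label of every sample for one covariate, in cohort order."""
        self.covariate(covariate)
        return [s.covariates.get(covariate, UNKNOWN_LABEL) for s in self.samples]

    def validate(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if any(not i for i in ids):
            raise ValidationError("empty sample_id")
        dupes = sorted({i for i, n in Counter(ids).items() if n > 1})
        if dupes:
            raise ValidationError(f"duplicate sample IDs: {', '.join(dupes)}")
        declared = {c.name: set(c.categories) for c in self.covariates}
        for s in self.samples:
            for name, label in s.covariates.items():
                if name not in declared:
                    raise ValidationError(
                        f"sample {s.sample_id!r} uses undeclared covariate {name!r}"
                    )
                if label not in declared[name]:
                    raise ValidationError(
                        f"sample {s.sample_id!r}: label {label!r} not among "
                        f"declared categories of {name!r}"
                    )


def _normalise_header(name: str) -> str:
    return str(name).strip().lower().replace(" ", "").replace("_", "").replace("-", "")


def _read_frame(source, fmt: str | None) -> pd.DataFrame:
    if fmt is None:
        suffix = Path(str(source)).suffix.lower() if isinstance(source, (str, Path)) else ""
        fmt = "xlsx" if suffix in {".xlsx", ".xls"} else "csv"
    if fmt == "csv":
        return pd.read_csv(source, dtype=str, keep_default_na=False)
    if fmt == "xlsx":
        return pd.read_excel(source, sheet_name=0, dtype=str).fillna("")
    raise FormatError(f"unsupported sample-table format {fmt!r}")


def read_sample_table(source: str | Path | IO, format: str | None = None) -> Cohort:
    """Read a sample table (CSV or XLSX) into a :class:`Cohort`.

    Column matching is case-insensitive and tolerant of spaces/underscores
    ("Sample ID" == "sample_id").  Every column that is neither the ID nor
    the type column becomes a categorical covariate whose categories are
    recorded in first-appearance order.  Blank cells map to ``Unknown``.
    """
    frame = _read_frame(source, format)
    id_col = type_col = None
    covariate_cols: list[str] = []
    for col in frame.columns:
        norm = _normalise_header(col)
        if id_col is None and norm in SAMPLE_ID_ALIASES:
            id_col = col
        elif type_col is None and norm in SAMPLE_TYPE_ALIASES:
            type_col = col
        else:
            covariate_cols.append(col)
    if id_col is None:
        raise FormatError(
            f"no sample-ID column found among {list(frame.columns)!r}"
        )
    if len(frame) == 0:
        raise ValidationError("sample table has a header but no data rows")

    samples = []
    for _, row in frame.iterrows():
        covs = {}
        for col in covariate_cols:
            value = str(row[col]).strip()
            covs[str(col).strip()] = value if value else UNKNOWN_LABEL
        stype = str(row[type_col]).strip() if type_col is not None else ""
        samples.append(
            Sample(
                sample_id=str(row[id_col]).strip(),
                sample_type=stype or EXPERIMENTAL,
                covariates=covs,
            )
        )
    specs = []
    for col in covariate_cols:
        name = str(col).strip()
        seen: dict[str, None] = {}
        for s in samples:
            seen.setdefault(s.covariates[name], None)
        specs.append(CovariateSpec(name=name, categories=tuple(seen)))
    return Cohort(samples=samples, covariates=specs)


def write_sample_table(cohort: Cohort, dest: str | Path | IO, format: str = "csv") -> None:
    """Write a cohort back to a table; round-trips through read_sample_table."""
    cohort.validate()
    columns = {"sample_id": cohort.sample_ids(),
               "sample_type": [s.sample_type for s in cohort.samples]}
    for spec in cohort.covariates:
        columns[spec.name] = cohort.labels(spec.name)
    frame = pd.DataFrame(columns)
    if format == "csv":
        frame.to_csv(dest, index=False, lineterminator="\n")
    elif format == "xlsx":
        frame.to_excel(dest, index=False, sheet_name="samples")
    else:
        raise FormatError(f"unsupported sample-table format {format!r}")


#: Marginal category counts of the built-in 1300-sample demonstration cohort:
#: a simulated clinical study with a balanced two-arm treatment, three-level
#: gender (including missing entries) and four age groups.
CASE_STUDY_MARGINALS: dict[str, dict[str, int]] = {
    "gender": {"Male": 615, "Female": 434, "Unknown": 251},
    "treatment": {"treatment": 650, "placebo": 650},
    "age": {"Kids": 169, "Teenager": 351, "Middle-Aged": 481, "Older": 299},
}


def generate_case_study_cohort(seed: int) -> Cohort:
    """Generate the built-in 1300-sample demonstration cohort.

    Marginal counts per covariate are fixed exactly (see
    :data:`CASE_STUDY_MARGINALS`); the joint distribution is produced by
    independently shuffling each covariate column with the seeded generator
    and zipping the columns, so different seeds differ only in how the
    covariate values are paired.
    """
    rng = np.random.default_rng(seed)
    n = sum(next(iter(CASE_STUDY_MARGINALS.values())).values())
    columns: dict[str, list[str]] = {}
    for name, counts in CASE_STUDY_MARGINALS.items():
        pool = [label for label, c in counts.items() for _ in range(c)]
        assert len(pool) == n
        columns[name] = [pool[i] for i in rng.permutation(n)]
    width = len(str(n))
    samples = [
        Sample(
            sample_id=f"S{i + 1:0{width}d}",
            sample_type=EXPERIMENTAL,
            covariates={name: columns[name][i] for name in CASE_STUDY_MARGINALS},
        )
        for i in range(n)
    ]
    specs = [
        CovariateSpec(name=name, categories=tuple(counts))
        for name, counts in CASE_STUDY_MARGINALS.items()
    ]
    return Cohort(samples=samples, covariates=specs)


def covariate_counts(cohort: Cohort, covariate: str) -> dict[str, int]:
    """Category → count for one covariate; counts sum to ``len(cohort)``."""
    spec = cohort.covariate(covariate)
    counts = Counter(cohort.labels(covariate))
    return {cat: counts.get(cat, 0) for cat in spec.categories}
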