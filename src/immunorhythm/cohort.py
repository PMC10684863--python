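"""Cohort data model: subject-level frequency tables and age-group binning.

The pipeline's universal input is a subject-level table with an opaque
subject id, sex, age in months and the twelve phenotype frequencies
(percent of gated cells).  Subjects are binned into ordered age groups;
the default scheme follows the six consecutive pediatric groups spanning
9 months to 18 years.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import LINEAGES, PHENOTYPES

__all__ = [
    "AgeGroupScheme",
    "CohortTable",
    "ValidationIssue",
    "ValidationReport",
    "DEFAULT_SCHEME",
    "assign_age_group",
    "read_cohort",
    "write_cohort",
    "group_counts",
]

#: Accepted spellings for the sex column, canonicalized to 'male'/'female'.
SEX_MAP: dict[str, str] = {
    "m": "male", "male": "male", "0": "male",
    "f": "female", "female": "female", "1": "female",
}

#: Default tolerance (percentage points) on the per-lineage sum-to-100
#: invariant; gated frequencies are typically rounded to one decimal.
LINEAGE_SUM_TOL = 1.0


@dataclass(frozen=True)
class AgeGroupScheme:
    """Ordered, contiguous, half-open month intervals labelling age groups.

    ``bins[i]`` covers ``[bins[i].start, bins[i].stop)`` months.  Adjacency
    of groups is defined by list order.
    """

    labels: tuple[str, ...]
    edges: tuple[int, ...]  # len == len(labels) + 1, strictly ascending

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.labels) + 1:
            raise ValueError("edges must have one more entry than labels")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly ascending")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    @property
    def span(self) -> tuple[int, int]:
        return self.edges[0], self.edges[-1]

    def interval(self, label: str) -> tuple[int, int]:
        i = self.labels.index(label)
        return self.edges[i], self.edges[i + 1]

    def assign(self, age_months: int) -> str:
        lo, hi = self.span
        if not lo <= age_months < hi:
            raise ValueError(
                f"age {age_months} months outside scheme span [{lo}, {hi})"
            )
        i = int(np.searchsorted(self.edges, age_months, side="right")) - 1
        return self.labels[i]

    def assign_series(self, ages: pd.Series) -> pd.Categorical:
        """Vectorized binning; raises if any age falls outside the span."""
        lo, hi = self.span
        bad = ages[(ages < lo) | (ages >= hi)]
        if len(bad):
            raise ValueError(
                f"{len(bad)} age(s) outside scheme span [{lo}, {hi}): "
                f"e.g. {bad.iloc[0]}"
            )
        cut = pd.cut(ages, bins=list(self.edges), labels=list(self.labels),
                     right=False, ordered=True)
        return cut

    def adjacent_pairs(self) -> list[tuple[str, str]]:
        """(earlier, later) label pairs in scheme order."""
        return list(zip(self.labels, self.labels[1:]))


# "2Yrs" means age-2 children (24-35 months), which forces the first group
# to end at 23 months; 18-year-olds end at 227 months.
DEFAULT_SCHEME = AgeGroupScheme(
    labels=("9Mths-1Yr", "2Yrs", "3-4Yrs", "5-7Yrs", "8-10Yrs", "11-18Yrs"),
    edges=(9, 24, 36, 60, 96, 132, 228),
)


def assign_age_group(age_months: int, scheme: AgeGroupScheme = DEFAULT_SCHEME) -> str:
    """Map an age in months to its unique age-group label."""
    return scheme.assign(age_months)


@dataclass
class ValidationIssue:
    row: int | None  # 0-based data row, None for table-level issues
    subject_id: str | None
    kind: str
    message: str

    def to_json(self) -> str:
        return json.dumps(
            {"row": self.row, "subject_id": self.subject_id,
             "kind": self.kind, "message": self.message}
        )


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    def add(self, row: int | None, subject_id: str | None, kind: str,
            message: str) -> None:
        self.issues.append(ValidationIssue(row, subject_id, kind, message))

    def __len__(self) -> int:
        return len(self.issues)

    def __bool__(self) -> bool:
        return bool(self.issues)

    def to_json_lines(self) -> str:
        return "\n".join(i.to_json() for i in self.issues)

    def __str__(self) -> str:
        if not self.issues:
            return "validation: OK (no issues)"
        lines = [f"validation: {len(self.issues)} issue(s)"]
        for i in self.issues:
            where = f"row {i.row}" if i.row is not None else "table"
            sid = f" [{i.subject_id}]" if i.subject_id else ""
            lines.append(f"  {where}{sid} {i.kind}: {i.message}")
        return "\n".join(lines)


class CohortTable:
    """A validated subject-level table plus its age-group scheme.

    The backing store is a :class:`pandas.DataFrame` with columns
    ``subject_id``, ``sex``, ``age_months`` and the twelve phenotypes in
    canonical order, one row per subject.
    """

    REQUIRED = ("subject_id", "sex", "age_months") + PHENOTYPES

    def __init__(self, data: pd.DataFrame, scheme: AgeGroupScheme = DEFAULT_SCHEME,
                 report: ValidationReport | None = None):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        df = data.loc[:, list(self.REQUIRED)].reset_index(drop=True).copy()
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].unique()
            raise ValueError(f"duplicate subject ids: {list(dupes[:5])}")
        df["subject_id"] = df["subject_id"].astype(str)
        df["sex"] = df["sex"].astype(str)
        bad_sex = set(df["sex"]) - {"male", "female"}
        if bad_sex:
            raise ValueError(f"non-canonical sex values: {sorted(bad_sex)}")
        df["age_months"] = df["age_months"].astype(int)
        df[list(PHENOTYPES)] = df[list(PHENOTYPES)].astype(float)
        # binning must succeed for every row
        df["age_group"] = scheme.assign_series(df["age_months"])
        self.data = df
        self.scheme = scheme
        self.report = report if report is not None else ValidationReport()

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, group: str | None = None, stratum: str = "ALL") -> pd.DataFrame:
        """Rows of one age group (or all) within a sex stratum."""
        df = self.data
        if group is not None:
            if group not in self.scheme.labels:
                raise KeyError(f"unknown age group {group!r}")
            df = df[df["age_group"] == group]
        if stratum != "ALL":
            if stratum not in ("male", "female"):
                raise ValueError(f"stratum must be ALL/male/female, got {stratum!r}")
            df = df[df["sex"] == stratum]
        return df

    def frequencies(self, group: str | None = None, stratum: str = "ALL") -> pd.DataFrame:
        return self.subset(group, stratum)[list(PHENOTYPES)]


def _canonical_sex(value: object, sex_map: Mapping[str, str]) -> str | None:
    key = str(value).strip().lower()
    return sex_map.get(key)


def validate_rows(df: pd.DataFrame, tol: float = LINEAGE_SUM_TOL) -> ValidationReport:
    """Collect range and lineage-closure violations row by row."""
    report = ValidationReport()
    freqs = df[list(PHENOTYPES)]
    out_of_range = (freqs < 0) | (freqs > 100)
    for row in np.nonzero(out_of_range.any(axis=1).to_numpy())[0]:
        cols = list(freqs.columns[out_of_range.iloc[row].to_numpy()])
        report.add(int(row), str(df["subject_id"].iloc[row]), "range",
                   f"frequencies outside [0, 100]: {cols}")
    for lineage, members in LINEAGES.items():
        sums = freqs[list(members)].sum(axis=1)
        bad = np.nonzero((sums - 100).abs().to_numpy() > tol)[0]
        for row in bad:
            report.add(int(row), str(df["subject_id"].iloc[row]), "lineage_sum",
                       f"{lineage} frequencies sum to {sums.iloc[row]:.2f}, "
                       f"expected 100 +/- {tol}")
    return report


def read_cohort(path: str | Path, scheme: AgeGroupScheme = DEFAULT_SCHEME, *,
                column_map: Mapping[str, str] | None = None,
                sex_map: Mapping[str, str] | None = None,
                tol: float = LINEAGE_SUM_TOL,
                strict: bool = False) -> CohortTable:
    """Read a subject-level CSV into a validated :class:`CohortTable`.

    Column names are matched case-insensitively; ``column_map`` renames
    non-standard headers (source name -> canonical name).  Rows violating
    the range or lineage-closure invariants are collected into
    ``table.report``; with ``strict=True`` any violation raises.
    """
    sex_map = dict(SEX_MAP) if sex_map is None else {k.lower(): v for k, v in sex_map.items()}
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    lower = {c.lower(): c for c in df.columns}
    rename = {}
    for canon in CohortTable.REQUIRED:
        if canon in df.columns:
            continue
        src = lower.get(canon.lower())
        if src is None:
            raise ValueError(f"missing required column {canon!r} in {path}")
        rename[src] = canon
    df = df.rename(columns=rename)

    for col in PHENOTYPES + ("age_months",):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(bad.index[bad.isna() & df[col].notna()][0])
            raise ValueError(
                f"unparseable value in column {col!r}, data row {row} "
                f"(file line {row + 2}): {df[col].iloc[row]!r}"
            ) from exc

    sexes = df["sex"].map(lambda v: _canonical_sex(v, sex_map))
    if sexes.isna().any():
        row = int(sexes.index[sexes.isna()][0])
        raise ValueError(
            f"unrecognized sex value {df['sex'].iloc[row]!r} at data row {row}; "
            f"accepted: {sorted(set(sex_map))}"
        )
    df["sex"] = sexes

    report = validate_rows(df, tol=tol)
    if strict and report:
        raise ValueError(f"cohort failed strict validation:\n{report}")
    return CohortTable(df, scheme=scheme, report=report)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write the cohort as plain CSV (round-trips through read_cohort)."""
    out = cohort.data.drop(columns=["age_group"])
    out.to_csv(path, index=False, float_format="%.10g")


def group_counts(cohort: CohortTable, by_sex: bool = False) -> pd.DataFrame | pd.Series:
    """Subject counts per age group, optionally split male/female.

    Counts always sum to the cohort size.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    df = cohort.data
    if by_sex:
        tab = (df.groupby(["age_group", "sex"], observed=False)
                 .size().unstack("sex", fill_value=0))
        return tab.reindex(columns=["male", "female"], fill_value=0)
    return df.groupby("age_group", observed=False).size()
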