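"""Readers and writers for the four interchange tables.

All tables are UTF-8, comma-delimited, one header row, decimal point
regardless of locale. Schemas:

* ``exposure.csv``:   factor_id,sex,level_id,proportion,exposure_year
* ``rr.csv``:         factor_id,cancer_type_id,sex,level_id,rr,significant
* ``incidence.csv``:  cancer_type_id,subtype_of,sex,year,cases
* ``direct_paf.csv``: factor_id,cancer_type_id,sex,paf
* ``attribution.csv`` (output):
  factor_id,cancer_type_id,sex,paf,attributable_cases,cases with
  ``__combined__`` rows per (cancer type, sex) and one ``__overall__``
  summary row.

The reference exposure level may appear explicitly (level_id
``"reference"``) or be left implicit; both are normalised to an explicit
reference with p = 1 - sum(others). Writers are lossless: reading back a
written table reproduces it field by field to full precision.
"""

from __future__ import annotations

import csv
import io
import os

import pandas as pd

from .exceptions import TableValidationError
from .types import (
    COMBINED_FACTOR,
    OVERALL_CANCER,
    OVERALL_FACTOR,
    OVERALL_SEX,
    AttributionRow,
    AttributionTable,
    DirectPafEntry,
    ExposureDistribution,
    IncidenceRecord,
    RelativeRiskEntry,
)

EXPOSURE_COLUMNS = ["factor_id", "sex", "level_id", "proportion", "exposure_year"]
RR_COLUMNS = ["factor_id", "cancer_type_id", "sex", "level_id", "rr", "significant"]
INCIDENCE_COLUMNS = ["cancer_type_id", "subtype_of", "sex", "year", "cases"]
DIRECT_PAF_COLUMNS = ["factor_id", "cancer_type_id", "sex", "paf"]
ATTRIBUTION_COLUMNS = ["factor_id", "cancer_type_id", "sex", "paf",
                       "attributable_cases", "cases"]


def _read_frame(path: str | os.PathLike, columns: list[str]) -> pd.DataFrame:
    path = os.fspath(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False,
                         skip_blank_lines=True, comment="#")
    except pd.errors.EmptyDataError:
        raise TableValidationError("file is empty", file=path) from None
    if list(df.columns) != columns:
        raise TableValidationError(
            f"header mismatch: expected {columns}, found {list(df.columns)}",
            file=path, column=",".join(df.columns))
    if len(df) == 0:
        raise TableValidationError("table has a header but no rows", file=path)
    return df


def _as_float(value: str, *, path: str, row: int, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise TableValidationError(
            f"cannot parse {value!r} as a number",
            file=path, row=row, column=column) from None


def _as_int(value: str, *, path: str, row: int, column: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise TableValidationError(
            f"cannot parse {value!r} as an integer",
            file=path, row=row, column=column) from None


def _as_bool(value: str, *, path: str, row: int, column: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise TableValidationError(
        f"cannot parse {value!r} as a boolean (use true/false)",
        file=path, row=row, column=column)


def _reraise_with_location(exc: TableValidationError, *, path: str,
                           row: int | None = None) -> TableValidationError:
    return TableValidationError(exc.args[0].split(" [")[0], file=path,
                                row=row, column=exc.column)


# ---------------------------------------------------------------------------
# exposure


def read_exposure_table(path: str | os.PathLike) -> list[ExposureDistribution]:
    """Read prevalence proportions and return one distribution per
    (factor, sex), with the reference level materialised."""
    path = os.fspath(path)
    df = _read_frame(path, EXPOSURE_COLUMNS)
    grouped: dict[tuple[str, str], list[tuple[str, float]]] = {}
    first_row: dict[tuple[str, str], int] = {}
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        p = _as_float(rec.proportion, path=path, row=i, column="proportion")
        if not (0.0 <= p <= 1.0):
            raise TableValidationError(
                f"proportion {p} outside [0, 1] for factor {rec.factor_id!r}",
                file=path, row=i, column="proportion")
        _as_int(rec.exposure_year, path=path, row=i, column="exposure_year")
        key = (rec.factor_id, rec.sex)
        grouped.setdefault(key, []).append((rec.level_id, p))
        first_row.setdefault(key, i)
    out = []
    for (factor_id, sex), levels in grouped.items():
        try:
            out.append(ExposureDistribution.from_nonreference(factor_id, sex, levels))
        except TableValidationError as exc:
            raise _reraise_with_location(exc, path=path,
                                         row=first_row[(factor_id, sex)]) from None
    return out


def read_exposure_years(path: str | os.PathLike) -> dict[str, int]:
    """Return the exposure-data vintage (calendar year) per factor.

    A factor must carry a single consistent year across its rows.
    """
    path = os.fspath(path)
    df = _read_frame(path, EXPOSURE_COLUMNS)
    years: dict[str, int] = {}
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        year = _as_int(rec.exposure_year, path=path, row=i, column="exposure_year")
        prev = years.setdefault(rec.factor_id, year)
        if prev != year:
            raise TableValidationError(
                f"factor {rec.factor_id!r} mixes exposure years {prev} and {year}",
                file=path, row=i, column="exposure_year")
    return years


def write_exposure_table(distributions: list[ExposureDistribution],
                         path: str | os.PathLike,
                         exposure_years: dict[str, int]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(EXPOSURE_COLUMNS)
        for dist in distributions:
            for level_id, p in dist.levels:
                w.writerow([dist.factor_id, dist.sex, level_id, repr(float(p)),
                            exposure_years[dist.factor_id]])


# ---------------------------------------------------------------------------
# relative risks


def read_rr_table(path: str | os.PathLike) -> list[RelativeRiskEntry]:
    path = os.fspath(path)
    df = _read_frame(path, RR_COLUMNS)
    out = []
    seen: set[tuple] = set()
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        rr = _as_float(rec.rr, path=path, row=i, column="rr")
        sig = _as_bool(rec.significant, path=path, row=i, column="significant")
        key = (rec.factor_id, rec.cancer_type_id, rec.sex, rec.level_id)
        if key in seen:
            raise TableValidationError(
                f"duplicate RR row for {key}", file=path, row=i)
        seen.add(key)
        try:
            out.append(RelativeRiskEntry(
                factor_id=rec.factor_id, cancer_type_id=rec.cancer_type_id,
                sex=rec.sex, level_id=rec.level_id, rr=rr, significant=sig))
        except TableValidationError as exc:
            raise _reraise_with_location(exc, path=path, row=i) from None
    return out


def write_rr_table(entries: list[RelativeRiskEntry],
                   path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RR_COLUMNS)
        for e in entries:
            w.writerow([e.factor_id, e.cancer_type_id, e.sex, e.level_id,
                        repr(float(e.rr)), "true" if e.significant else "false"])


# ---------------------------------------------------------------------------
# incidence


def read_incidence_table(path: str | os.PathLike) -> list[IncidenceRecord]:
    path = os.fspath(path)
    df = _read_frame(path, INCIDENCE_COLUMNS)
    out = []
    seen: set[tuple] = set()
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        year = _as_int(rec.year, path=path, row=i, column="year")
        cases = _as_int(rec.cases, path=path, row=i, column="cases")
        key = (rec.cancer_type_id, rec.sex, year)
        if key in seen:
            raise TableValidationError(
                f"duplicate incidence row for {key}", file=path, row=i)
        seen.add(key)
        subtype_of = rec.subtype_of or None
        try:
            out.append(IncidenceRecord(
                cancer_type_id=rec.cancer_type_id, sex=rec.sex, year=year,
                cases=cases, subtype_of=subtype_of))
        except TableValidationError as exc:
            raise _reraise_with_location(exc, path=path, row=i) from None
    _check_subtype_consistency(out, path)
    return out


def _check_subtype_consistency(records: list[IncidenceRecord], path: str) -> None:
    by_key = {(r.cancer_type_id, r.sex, r.year): r.cases for r in records}
    for r in records:
        if r.subtype_of is None:
            continue
        parent = by_key.get((r.subtype_of, r.sex, r.year))
        if parent is not None and r.cases > parent:
            raise TableValidationError(
                f"subtype {r.cancer_type_id!r} has {r.cases} cases, exceeding "
                f"parent {r.subtype_of!r} ({parent}) for {r.sex}/{r.year}",
                file=path, column="cases")


def write_incidence_table(records: list[IncidenceRecord],
                          path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(INCIDENCE_COLUMNS)
        for r in records:
            w.writerow([r.cancer_type_id, r.subtype_of or "", r.sex,
                        r.year, r.cases])


# ---------------------------------------------------------------------------
# direct PAFs


def read_direct_paf_table(path: str | os.PathLike) -> list[DirectPafEntry]:
    path = os.fspath(path)
    df = _read_frame(path, DIRECT_PAF_COLUMNS)
    out = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        paf = _as_float(rec.paf, path=path, row=i, column="paf")
        try:
            out.append(DirectPafEntry(
                factor_id=rec.factor_id, cancer_type_id=rec.cancer_type_id,
                sex=rec.sex, paf=paf))
        except TableValidationError as exc:
            raise _reraise_with_location(exc, path=path, row=i) from None
    return out


def write_direct_paf_table(entries: list[DirectPafEntry],
                           path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(DIRECT_PAF_COLUMNS)
        for e in entries:
            w.writerow([e.factor_id, e.cancer_type_id, e.sex, repr(float(e.paf))])


# ---------------------------------------------------------------------------
# attribution table


def attribution_to_frame(table: AttributionTable) -> pd.DataFrame:
    rows = []
    for r in table.rows + table.combined:
        rows.append((r.factor_id, r.cancer_type_id, r.sex, r.paf,
                     r.attributable_cases, r.cases))
    rows.append((OVERALL_FACTOR, OVERALL_CANCER, OVERALL_SEX, table.overall_paf,
                 table.total_attributable, table.total_cases))
    return pd.DataFrame(rows, columns=ATTRIBUTION_COLUMNS)


def write_attribution_table(table: AttributionTable,
                            path: str | os.PathLike) -> None:
    """Write the attribution table, its combined rows and the overall
    summary row to one CSV, losslessly."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(ATTRIBUTION_COLUMNS)
    for r in table.rows + table.combined:
        w.writerow([r.factor_id, r.cancer_type_id, r.sex, repr(float(r.paf)),
                    repr(float(r.attributable_cases)), r.cases])
    w.writerow([OVERALL_FACTOR, OVERALL_CANCER, OVERALL_SEX,
                repr(float(table.overall_paf)),
                repr(float(table.total_attributable)), table.total_cases])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def read_attribution_table(path: str | os.PathLike) -> AttributionTable:
    path = os.fspath(path)
    df = _read_frame(path, ATTRIBUTION_COLUMNS)
    table = AttributionTable()
    saw_overall = False
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        paf = _as_float(rec.paf, path=path, row=i, column="paf")
        attr = _as_float(rec.attributable_cases, path=path, row=i,
                         column="attributable_cases")
        cases = _as_int(rec.cases, path=path, row=i, column="cases")
        if rec.factor_id == OVERALL_FACTOR:
            table.total_cases = cases
            table.total_attributable = attr
            saw_overall = True
            continue
        row = AttributionRow(factor_id=rec.factor_id,
                             cancer_type_id=rec.cancer_type_id, sex=rec.sex,
                             paf=paf, attributable_cases=attr, cases=cases)
        (table.combined if rec.factor_id == COMBINED_FACTOR else table.rows
         ).append(row)
    if not saw_overall:
        raise TableValidationError("attribution table lacks the overall "
                                   f"summary row ({OVERALL_FACTOR})", file=path)
    return table
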